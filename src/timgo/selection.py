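"""Statistical machinery between raw encodings and the classifiers.

- Welch two-sample t-tests select sequence fragments (k-mers, motifs)
  whose occurrence differs between activated and non-activated genes
  (raw p < 0.05, deliberately without multiple-testing correction).
- A logistic regression of activation on enhancer-TLS distance supplies
  per-record activation probabilities used to weight PROMOTER features,
  which also disambiguates insertion events that share one promoter.
- Fisher-score ranking, greedy mRMR (MID variant), and incremental
  feature selection drive the second-layer meta-feature choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentFilter:
    """Fragments retained by the two-sample t-test at level alpha."""

    vocabulary: tuple[str, ...]
    kept_indices: tuple[int, ...]
    pvalues: tuple[float, ...]  # aligned with kept_indices
    alpha: float = 0.05

    @property
    def kept_fragments(self) -> tuple[str, ...]:
        return tuple(self.vocabulary[i] for i in self.kept_indices)

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix)[:, list(self.kept_indices)]

    def to_frame(self) -> pd.DataFrame:
        """Retained fragments sorted by p-value (for reporting)."""
        df = pd.DataFrame(
            {"fragment": self.kept_fragments, "pvalue": self.pvalues}
        ).sort_values("pvalue", kind="mergesort")
        return df.reset_index(drop=True)


def significant_fragments(
    counts_pos: np.ndarray,
    counts_neg: np.ndarray,
    vocabulary: list[str],
    alpha: float = 0.05,
) -> FragmentFilter:
    """Welch t-test per fragment between the two groups; keep p < alpha.

    Fragments with zero variance in both groups carry no signal and are
    dropped regardless of their means.  Raw (uncorrected) p-values are
    used by design.
    """
    counts_pos = np.asarray(counts_pos, dtype=float)
    counts_neg = np.asarray(counts_neg, dtype=float)
    if counts_pos.shape[0] < 2 or counts_neg.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    if counts_pos.shape[1] != counts_neg.shape[1] or counts_pos.shape[1] != len(vocabulary):
        raise ValueError("count matrices and vocabulary disagree on fragment count")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(counts_pos, counts_neg, axis=0, equal_var=False)
    zero_var = (counts_pos.var(axis=0) == 0) & (counts_neg.var(axis=0) == 0)
    p = np.where(zero_var, 1.0, p)
    p = np.nan_to_num(p, nan=1.0)
    kept = np.flatnonzero(p < alpha)
    return FragmentFilter(
        vocabulary=tuple(vocabulary),
        kept_indices=tuple(int(i) for i in kept),
        pvalues=tuple(float(x) for x in p[kept]),
        alpha=alpha,
    )


@dataclass(frozen=True)
class DistanceModel:
    """Logistic model P(activation) = 1 / (1 + exp(-(b0 + b1 * distance)))."""

    intercept: float
    slope: float
    intercept_se: float = float("nan")
    slope_se: float = float("nan")

    def predict_proba(self, distances_bp) -> np.ndarray:
        d = np.asarray(distances_bp, dtype=float)
        z = self.intercept + self.slope * d
        return 1.0 / (1.0 + np.exp(-z))


def fit_distance_logistic(distances_bp, labels) -> DistanceModel:
    """Maximum-likelihood logistic fit of activation on distance."""
    import statsmodels.api as sm

    y = np.asarray(labels, dtype=float)
    d = np.asarray(distances_bp, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; logistic fit is undefined")
    X = sm.add_constant(d)
    res = sm.Logit(y, X).fit(disp=0)
    return DistanceModel(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
    )


def weight_promoter_features(vector, model: DistanceModel, distance_bp: float) -> np.ndarray:
    """Scale a promoter feature vector by P(activation | distance).

    The scaling preserves direction and shrinks the norm by a factor in
    (0, 1]; two insertion events sharing one promoter but at different
    distances become numerically distinct.
    """
    p = float(model.predict_proba([distance_bp])[0])
    return np.asarray(vector, dtype=float) * p


def fscore(features: np.ndarray, labels) -> np.ndarray:
    """Fisher score per column, LIBSVM fselect convention.

    F = ((mean+ - mean)^2 + (mean- - mean)^2) / (var+ + var-) with sample
    (n-1) variances; columns constant within both classes get F = 0.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = X[y == 1], X[y == 0]
    mu, mu_p, mu_n = X.mean(axis=0), pos.mean(axis=0), neg.mean(axis=0)
    var_p = pos.var(axis=0, ddof=1) if len(pos) > 1 else np.zeros(X.shape[1])
    var_n = neg.var(axis=0, ddof=1) if len(neg) > 1 else np.zeros(X.shape[1])
    num = (mu_p - mu) ** 2 + (mu_n - mu) ** 2
    den = var_p + var_n
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))
    return f


def fscore_select(
    features: np.ndarray,
    labels,
    top_fraction: float | None = None,
    threshold: float | None = None,
) -> np.ndarray:
    """Column subset by Fisher score: top fraction or absolute threshold."""
    f = fscore(features, labels)
    if threshold is not None:
        return np.flatnonzero(f >= threshold)
    if top_fraction is None:
        top_fraction = 0.5
    order = np.argsort(-f, kind="mergesort")
    k = max(1, int(round(top_fraction * len(f))))
    return np.sort(order[:k])


def _discretize(col: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Equal-frequency binning; already-discrete columns pass through."""
    uniq = np.unique(col)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, col)
    qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.digitize(col, qs)


def mrmr_rank(features: np.ndarray, labels, n_bins: int = 3) -> list[int]:
    """Greedy mRMR ranking, mutual-information difference (MID) variant.

    Iteratively adds the column maximizing I(c; y) minus the mean mutual
    information with already-selected columns, on equal-frequency
    discretized values.  Ties break deterministically by column index, so
    the ranking is invariant to column order up to exact MI ties.  The
    first pick is the max-relevance column (no redundancy term yet).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n_cols = X.shape[1]
    disc = [_discretize(X[:, j], n_bins) for j in range(n_cols)]
    relevance = np.array([mutual_info_score(y, d) for d in disc])
    selected: list[int] = []
    remaining = list(range(n_cols))
    pair_mi = np.full((n_cols, n_cols), np.nan)
    while remaining:
        best_j, best_score = None, -np.inf
        for j in remaining:
            if selected:
                for s in selected:
                    if np.isnan(pair_mi[j, s]):
                        pair_mi[j, s] = pair_mi[s, j] = mutual_info_score(disc[j], disc[s])
                redundancy = float(np.mean([pair_mi[j, s] for s in selected]))
            else:
                redundancy = 0.0
            score = relevance[j] - redundancy
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


def incremental_selection(
    features: np.ndarray,
    labels,
    ranked_columns: list[int],
    learner_factory,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[int, list[float]]:
    """Smallest feature-prefix size attaining the maximum CV accuracy.

    Evaluates prefixes of the ranked column list by stratified k-fold CV
    with a fresh learner from ``learner_factory`` per fit; returns
    (best prefix size, accuracy per prefix).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    accuracies: list[float] = []
    for size in range(1, len(ranked_columns) + 1):
        cols = ranked_columns[:size]
        correct = 0
        for tr, te in folds:
            clf = learner_factory()
            clf.fit(X[np.ix_(tr, cols)], y[tr])
            correct += int((clf.predict(X[np.ix_(te, cols)]) == y[te]).sum())
        accuracies.append(correct / len(y))
    best = int(np.argmax(accuracies)) + 1  # argmax returns the first (smallest) max
    logger.info("incremental selection: best prefix %d (acc %.3f)", best, accuracies[best - 1])
    return best, accuracies
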