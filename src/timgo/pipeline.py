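"""The two-layer TIMgo model: 16 per-feature SVMs stacked into a LADTree.

First layer (one RBF-SVM per roster entry, trained on the balanced
training set):

====  ==============  ========
 #    encoding        region
====  ==============  ========
 1    CGI             PROMOTER
 2    CGI             MIDDLE
 3    DNP             PROMOTER
 4    DNP             MIDDLE
 5    TNP             PROMOTER
 6    TNP             MIDDLE
 7    Kmer + Motif    PROMOTER
 8    RevKmer + Motif PROMOTER
 9    Kmer            MIDDLE
10    RevKmer         MIDDLE
11    DACC            PROMOTER
12    DACC            MIDDLE
13    TACC            PROMOTER
14    TACC            MIDDLE
15    PseKNC          PROMOTER
16    PseKNC          MIDDLE
====  ==============  ========

Per model: Kmer/RevKmer/Motif columns pass a Welch-t-test fragment filter
(p < 0.05, fitted on the training fold only); features are scaled to
[-1, 1]; PROMOTER-region features are weighted by the fitted logistic
probability of activation at the record's enhancer distance; an RBF SVM
with Platt probability outputs is grid-searched by internal CV.  PseKNC
additionally selects its tuple size k per region by CV accuracy.

Each trained model contributes (predicted label, positive confidence,
negative confidence) per record -- 48 meta-features in the roster order
above -- which are mRMR-ranked, pruned by incremental selection, and fed
to the LogitBoost alternating decision tree.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from timgo.encoders.cgi import cgi_encode
from timgo.encoders.kmer import KmerSpec, kmer_count_matrix, kmer_vocabulary
from timgo.encoders.motif import (
    MotifLibrary,
    background_from_seqs,
    default_motif_library,
    motif_features,
    motif_scan,
)
from timgo.encoders.properties import (
    ACCParams,
    PropertyTable,
    acc_encode,
    load_dinucleotide_table,
    load_trinucleotide_table,
    property_encode,
)
from timgo.encoders.pseknc import PseKNCParams, pseknc_encode
from timgo.genome import Genome
from timgo.io_data import Dataset
from timgo.metrics import ConfusionMatrix, MetricsReport, confusion_metrics
from timgo.selection import (
    DistanceModel,
    FragmentFilter,
    fit_distance_logistic,
    incremental_selection,
    mrmr_rank,
    significant_fragments,
)
from timgo.sequences import extract_pair
from timgo.ladtree import LADTree, GradientBoostedStumps

logger = logging.getLogger(__name__)

#: deterministic first-layer roster: (encoder, region)
ROSTER: tuple[tuple[str, str], ...] = (
    ("cgi", "PROMOTER"),
    ("cgi", "MIDDLE"),
    ("dnp", "PROMOTER"),
    ("dnp", "MIDDLE"),
    ("tnp", "PROMOTER"),
    ("tnp", "MIDDLE"),
    ("kmer+motif", "PROMOTER"),
    ("revkmer+motif", "PROMOTER"),
    ("kmer", "MIDDLE"),
    ("revkmer", "MIDDLE"),
    ("dacc", "PROMOTER"),
    ("dacc", "MIDDLE"),
    ("tacc", "PROMOTER"),
    ("tacc", "MIDDLE"),
    ("pseknc", "PROMOTER"),
    ("pseknc", "MIDDLE"),
)


@dataclass
class PipelineConfig:
    """Tunable knobs of the two-layer pipeline (defaults = study scale)."""

    kmer_range: tuple[int, int] = (3, 6)
    pseknc_ks: tuple[int, ...] = (2, 3, 4, 5, 6)
    pseknc_lambda: int = 4
    pseknc_w: float = 0.2
    acc_lag: int = 4
    fragment_alpha: float = 0.05
    motif_p_threshold: float = 2.5e-4
    svm_c_grid: tuple[float, ...] = (0.5, 8.0, 128.0)
    svm_gamma_grid: tuple = ("scale", 2.0**-7, 2.0**-3)
    svm_inner_cv: int = 3
    n_boost: int = 10
    mrmr_bins: int = 3
    second_layer: str = "ladtree"  # or "gbstumps" (cross-check learner)
    oof_meta: bool = True  # out-of-fold meta-features for the second layer
    oof_folds: int = 5
    strict_degenerate: bool = False  # raise instead of prior-fallback


# ---------------------------------------------------------------------------
# feature encoding (label-independent; computed once per record set)


@dataclass
class FeatureEncodings:
    """All raw per-record encodings for a record set.

    Everything here depends only on the sequences and distances, never on
    the labels, so it can be computed once and shared across CV folds;
    label-dependent steps (fragment filters, scaling, weighting, SVM
    fits) are re-fitted per training fold.
    """

    n_records: int
    distances: np.ndarray
    kmer_vocab: list[str]
    revkmer_vocab: list[str]
    kmer: dict[str, np.ndarray]  # region -> (n, |vocab|)
    revkmer: dict[str, np.ndarray]
    motif_prom: np.ndarray  # (n, 4 * |lib|)
    n_motifs: int
    cgi: dict[str, np.ndarray]
    dnp: dict[str, np.ndarray]
    tnp: dict[str, np.ndarray]
    dacc: dict[str, np.ndarray]
    tacc: dict[str, np.ndarray]
    pseknc: dict[str, dict[int, np.ndarray]]  # region -> k -> (n, 4^k + lam)


def compute_encodings(
    dataset: Dataset,
    genome: Genome,
    config: PipelineConfig | None = None,
    motif_lib: MotifLibrary | None = None,
    di_table: PropertyTable | None = None,
    tri_table: PropertyTable | None = None,
) -> FeatureEncodings:
    """Encode every record of a dataset with all nine feature encodings."""
    cfg = config or PipelineConfig()
    lib = motif_lib or default_motif_library()
    di = di_table or load_dinucleotide_table()
    tri = tri_table or load_trinucleotide_table()

    pairs = [extract_pair(genome, r) for r in dataset]
    regions = {
        "PROMOTER": [p.promoter for p in pairs],
        "MIDDLE": [p.middle for p in pairs],
    }
    n = len(pairs)

    kspec = KmerSpec(*cfg.kmer_range, collapse_revcomp=False)
    rspec = KmerSpec(*cfg.kmer_range, collapse_revcomp=True)
    kvocab = kmer_vocabulary(kspec)
    rvocab = kmer_vocabulary(rspec)
    kmer = {reg: kmer_count_matrix(seqs, kspec, kvocab)[0] for reg, seqs in regions.items()}
    revkmer = {reg: kmer_count_matrix(seqs, rspec, rvocab)[0] for reg, seqs in regions.items()}

    background = background_from_seqs(regions["PROMOTER"])
    motif_rows = []
    for seq in regions["PROMOTER"]:
        hits = motif_scan(seq, lib, cfg.motif_p_threshold, background)
        motif_rows.append(motif_features(hits, len(lib), len(seq)))
    motif_prom = np.vstack(motif_rows)

    cgi = {reg: np.vstack([cgi_encode(s) for s in seqs]) for reg, seqs in regions.items()}
    dnp = {reg: np.vstack([property_encode(s, di) for s in seqs]) for reg, seqs in regions.items()}
    tnp = {reg: np.vstack([property_encode(s, tri) for s in seqs]) for reg, seqs in regions.items()}

    dacc_params = ACCParams(di, cfg.acc_lag)
    tacc_params = ACCParams(tri, cfg.acc_lag)
    dacc = {
        reg: np.vstack([_safe_acc(s, dacc_params) for s in seqs])
        for reg, seqs in regions.items()
    }
    tacc = {
        reg: np.vstack([_safe_acc(s, tacc_params) for s in seqs])
        for reg, seqs in regions.items()
    }

    pseknc: dict[str, dict[int, np.ndarray]] = {}
    for reg, seqs in regions.items():
        pseknc[reg] = {}
        for k in cfg.pseknc_ks:
            params = PseKNCParams(k=k, lam=cfg.pseknc_lambda, w=cfg.pseknc_w)
            pseknc[reg][k] = np.vstack([_safe_pseknc(s, params, di) for s in seqs])

    return FeatureEncodings(
        n_records=n,
        distances=dataset.distances.astype(float),
        kmer_vocab=kvocab,
        revkmer_vocab=rvocab,
        kmer=kmer,
        revkmer=revkmer,
        motif_prom=motif_prom,
        n_motifs=len(lib),
        cgi=cgi,
        dnp=dnp,
        tnp=tnp,
        dacc=dacc,
        tacc=tacc,
        pseknc=pseknc,
    )


def _safe_acc(seq: str, params: ACCParams) -> np.ndarray:
    """ACC vector, or zeros when the sequence is shorter than the lag."""
    try:
        return acc_encode(seq, params)
    except ValueError:
        logger.warning("sequence too short for ACC (lag %d); zero vector", params.lag)
        return np.zeros(params.n_features)


def _safe_pseknc(seq: str, params: PseKNCParams, table: PropertyTable) -> np.ndarray:
    try:
        return pseknc_encode(seq, params, table)
    except ValueError:
        logger.warning("sequence too short for PseKNC (lambda %d); zero vector", params.lam)
        return np.zeros(params.n_features)


# ---------------------------------------------------------------------------
# first layer


class _PriorModel:
    """Fallback for a degenerate (all-constant) feature matrix.

    Predicts the training class prior, so the model contributes an
    uninformative but well-formed meta-feature triple.
    """

    def __init__(self, p_pos: float):
        self.p_pos = p_pos

    def predict(self, X) -> np.ndarray:
        return np.full(len(X), int(self.p_pos >= 0.5))

    def predict_proba(self, X) -> np.ndarray:
        return np.tile([1 - self.p_pos, self.p_pos], (len(X), 1))


@dataclass
class FirstLayerModel:
    """One trained (encoder, region) SVM with its preprocessing state."""

    key: tuple[str, str]
    clf: object
    scaler_min: np.ndarray
    scaler_range: np.ndarray
    fragment_filter: FragmentFilter | None = None
    motif_filter: FragmentFilter | None = None
    pseknc_k: int | None = None
    weighted: bool = False
    cv_accuracy: float = float("nan")

    def transform(self, enc: FeatureEncodings, idx: np.ndarray, dist_model: DistanceModel) -> np.ndarray:
        X = _raw_matrix(self.key, enc, idx, self.fragment_filter, self.motif_filter, self.pseknc_k)
        X = (X - self.scaler_min) / self.scaler_range * 2.0 - 1.0
        if self.weighted:
            p = dist_model.predict_proba(enc.distances[idx])
            X = X * p[:, None]
        return X


def _raw_matrix(
    key: tuple[str, str],
    enc: FeatureEncodings,
    idx: np.ndarray,
    frag: FragmentFilter | None,
    motif_frag: FragmentFilter | None,
    pseknc_k: int | None,
) -> np.ndarray:
    encoder, region = key
    if encoder == "cgi":
        return enc.cgi[region][idx]
    if encoder == "dnp":
        return enc.dnp[region][idx]
    if encoder == "tnp":
        return enc.tnp[region][idx]
    if encoder == "dacc":
        return enc.dacc[region][idx]
    if encoder == "tacc":
        return enc.tacc[region][idx]
    if encoder == "pseknc":
        return enc.pseknc[region][pseknc_k][idx]
    if encoder in ("kmer", "revkmer"):
        mat = (enc.kmer if encoder == "kmer" else enc.revkmer)[region][idx]
        return frag.apply(mat) if frag is not None else mat
    if encoder in ("kmer+motif", "revkmer+motif"):
        base = enc.kmer if encoder.startswith("kmer") else enc.revkmer
        mat = base[region][idx]
        kpart = frag.apply(mat) if frag is not None else mat
        mpart = _motif_block(enc.motif_prom[idx], motif_frag, enc.n_motifs)
        return np.hstack([kpart, mpart])
    raise KeyError(key)


def _motif_block(motif_mat: np.ndarray, motif_frag: FragmentFilter | None, n_motifs: int) -> np.ndarray:
    if motif_frag is None:
        return motif_mat
    cols: list[int] = []
    for mi in motif_frag.kept_indices:
        cols.extend(range(4 * mi, 4 * mi + 4))  # keep the motif's 4-stat block
    return motif_mat[:, cols]


def _fit_svm(X: np.ndarray, y: np.ndarray, cfg: PipelineConfig, seed: int):
    """Grid-search an RBF SVM, then Platt-calibrate the winning settings."""
    from sklearn.calibration import CalibratedClassifierCV
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.svm import SVC

    n_min = min(np.bincount(y))
    cv = min(cfg.svm_inner_cv, n_min)
    if cv < 2:
        params = {"C": 1.0, "gamma": "scale"}
        score = float("nan")
    else:
        grid = GridSearchCV(
            SVC(kernel="rbf"),
            {"C": list(cfg.svm_c_grid), "gamma": list(cfg.svm_gamma_grid)},
            cv=StratifiedKFold(cv, shuffle=True, random_state=seed),
            scoring="accuracy",
            n_jobs=1,
        )
        grid.fit(X, y)
        params, score = grid.best_params_, float(grid.best_score_)
    svc = SVC(kernel="rbf", **params)
    if cv >= 2:
        clf = CalibratedClassifierCV(
            svc,
            method="sigmoid",
            cv=StratifiedKFold(cv, shuffle=True, random_state=seed),
            ensemble=False,
        )
        clf.fit(X, y)
    else:
        # too few records to calibrate: fall back to a margin sigmoid
        clf = _MarginSigmoidSVC(svc).fit(X, y)
    return clf, score


class _MarginSigmoidSVC:
    """SVC with a fixed logistic link on the margin (tiny-data fallback)."""

    def __init__(self, svc):
        self.svc = svc

    def fit(self, X, y):
        self.svc.fit(X, y)
        return self

    def predict(self, X):
        return self.svc.predict(X)

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.svc.decision_function(X)))
        return np.column_stack([1 - p, p])


@dataclass
class FirstLayerBundle:
    """The 16 trained first-layer models plus the shared distance model."""

    models: list[FirstLayerModel]
    distance_model: DistanceModel

    def __post_init__(self) -> None:
        if len(self.models) != len(ROSTER):
            raise ValueError(f"bundle needs {len(ROSTER)} models, got {len(self.models)}")

    def meta_features(self, enc: FeatureEncodings, idx: np.ndarray) -> np.ndarray:
        """(n, 48) meta-matrix: per model (label, conf_pos, conf_neg)."""
        cols = []
        for m in self.models:
            X = m.transform(enc, idx, self.distance_model)
            proba = m.clf.predict_proba(X)
            label = (proba[:, 1] >= 0.5).astype(float)
            cols.extend([label, proba[:, 1], proba[:, 0]])
        return np.column_stack(cols)


META_FEATURE_NAMES: list[str] = [
    f"{enc}:{reg}:{part}"
    for enc, reg in ROSTER
    for part in ("label", "conf_pos", "conf_neg")
]


def train_first_layer(
    enc: FeatureEncodings,
    labels: np.ndarray,
    train_idx: np.ndarray,
    cfg: PipelineConfig,
    seed: int,
) -> FirstLayerBundle:
    """Fit all 16 first-layer models on the given training indices.

    Every label-dependent step (distance logistic, fragment filters,
    scalers, SVM grids, PseKNC k choice) sees only ``train_idx``.
    """
    y = np.asarray(labels, dtype=int)
    ytr = y[train_idx]
    dist_model = fit_distance_logistic(enc.distances[train_idx], ytr)

    models: list[FirstLayerModel] = []
    for key in ROSTER:
        encoder, region = key
        frag = motif_frag = None
        pseknc_k = None
        if encoder in ("kmer", "kmer+motif", "revkmer", "revkmer+motif"):
            base = enc.kmer if encoder.startswith("kmer") else enc.revkmer
            vocab = enc.kmer_vocab if encoder.startswith("kmer") else enc.revkmer_vocab
            mat = base[region][train_idx]
            frag = significant_fragments(
                mat[ytr == 1], mat[ytr == 0], vocab, cfg.fragment_alpha
            )
            if not frag.kept_indices:
                frag = None  # nothing significant: keep the full vocabulary
        if encoder.endswith("+motif"):
            number_cols = enc.motif_prom[np.ix_(train_idx, range(0, 4 * enc.n_motifs, 4))]
            motif_names = [f"motif{m}" for m in range(enc.n_motifs)]
            motif_frag = significant_fragments(
                number_cols[ytr == 1], number_cols[ytr == 0], motif_names, cfg.fragment_alpha
            )
            if not motif_frag.kept_indices:
                motif_frag = None
        if encoder == "pseknc":
            pseknc_k = _select_pseknc_k(enc, y, train_idx, region, dist_model, cfg, seed)

        Xtr = _raw_matrix(key, enc, train_idx, frag, motif_frag, pseknc_k)
        lo, hi = Xtr.min(axis=0), Xtr.max(axis=0)
        rng = np.where(hi > lo, hi - lo, 1.0)
        Xs = (Xtr - lo) / rng * 2.0 - 1.0
        weighted = region == "PROMOTER"
        if weighted:
            Xs = Xs * dist_model.predict_proba(enc.distances[train_idx])[:, None]

        if np.all(Xs == Xs[0:1, :]):
            msg = f"first-layer model {key}: all-constant feature matrix"
            if cfg.strict_degenerate:
                raise ValueError(msg + " (strict mode)")
            logger.warning("%s; using class-prior fallback", msg)
            clf, cv_acc = _PriorModel(float(ytr.mean())), float("nan")
        else:
            clf, cv_acc = _fit_svm(Xs, ytr, cfg, seed)
        models.append(
            FirstLayerModel(
                key=key,
                clf=clf,
                scaler_min=lo,
                scaler_range=rng,
                fragment_filter=frag,
                motif_filter=motif_frag,
                pseknc_k=pseknc_k,
                weighted=weighted,
                cv_accuracy=cv_acc,
            )
        )
    return FirstLayerBundle(models, dist_model)


def _select_pseknc_k(
    enc: FeatureEncodings,
    y: np.ndarray,
    train_idx: np.ndarray,
    region: str,
    dist_model: DistanceModel,
    cfg: PipelineConfig,
    seed: int,
) -> int:
    """Pick the PseKNC tuple size by quick internal CV accuracy."""
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.svm import SVC

    ytr = y[train_idx]
    best_k, best_acc = cfg.pseknc_ks[0], -1.0
    for k in cfg.pseknc_ks:
        X = enc.pseknc[region][k][train_idx]
        lo, hi = X.min(axis=0), X.max(axis=0)
        rng = np.where(hi > lo, hi - lo, 1.0)
        Xs = (X - lo) / rng * 2.0 - 1.0
        if region == "PROMOTER":
            Xs = Xs * dist_model.predict_proba(enc.distances[train_idx])[:, None]
        if np.all(Xs == Xs[0:1, :]):
            continue
        cv = min(cfg.svm_inner_cv, min(np.bincount(ytr)))
        if cv < 2:
            continue
        acc = cross_val_score(
            SVC(kernel="rbf", C=1.0, gamma="scale"),
            Xs,
            ytr,
            cv=StratifiedKFold(cv, shuffle=True, random_state=seed),
            scoring="accuracy",
        ).mean()
        if acc > best_acc + 1e-9:
            best_k, best_acc = k, float(acc)
    return best_k


# ---------------------------------------------------------------------------
# full two-layer model


@dataclass
class TwoLayerModel:
    """Trained TIMgo pipeline: first layer + mRMR/IFS + boosted tree."""

    bundle: FirstLayerBundle
    meta_ranking: list[int]
    n_meta_selected: int
    second: object
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @property
    def selected_meta_columns(self) -> list[int]:
        return self.meta_ranking[: self.n_meta_selected]

    def predict_proba(self, enc: FeatureEncodings, idx: np.ndarray | None = None) -> np.ndarray:
        if idx is None:
            idx = np.arange(enc.n_records)
        meta = self.bundle.meta_features(enc, idx)
        return self.second.predict_proba(meta[:, self.selected_meta_columns])

    def predict(self, enc: FeatureEncodings, idx: np.ndarray | None = None) -> np.ndarray:
        return (self.predict_proba(enc, idx)[:, 1] >= 0.5).astype(int)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "TwoLayerModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not hold a TwoLayerModel")
        return model


def train_two_layer(
    enc: FeatureEncodings,
    labels: np.ndarray,
    train_idx: np.ndarray,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> TwoLayerModel:
    """Train the full pipeline on ``train_idx``.

    Meta-features for the second layer come from the first layer's
    predictions on its own training records (out-of-fold generation is
    available via ``cfg.oof_meta``); they are mRMR-ranked, the prefix is
    chosen by incremental selection with an SVM under CV, and the final
    learner is the LADTree (or the gradient-boosted-stump cross-check).
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    cfg = cfg or PipelineConfig()
    y = np.asarray(labels, dtype=int)
    train_idx = np.asarray(train_idx)
    bundle = train_first_layer(enc, y, train_idx, cfg, seed)

    if cfg.oof_meta:
        # stacking discipline: the second layer must see first-layer
        # predictions on records the first layer was NOT fitted on,
        # otherwise every overfit model looks perfect to the selector
        meta = np.zeros((len(train_idx), len(META_FEATURE_NAMES)))
        folds = min(cfg.oof_folds, min(np.bincount(y[train_idx])))
        skf = StratifiedKFold(max(folds, 2), shuffle=True, random_state=seed)
        for tr, te in skf.split(train_idx, y[train_idx]):
            sub = train_first_layer(enc, y, train_idx[tr], cfg, seed)
            meta[te] = sub.meta_features(enc, train_idx[te])
    else:
        meta = bundle.meta_features(enc, train_idx)

    ytr = y[train_idx]
    ranking = mrmr_rank(meta, ytr, n_bins=cfg.mrmr_bins)
    cv = min(5, min(np.bincount(ytr)))
    if cv >= 2:
        n_sel, _ = incremental_selection(
            meta,
            ytr,
            ranking,
            lambda: SVC(kernel="rbf", C=1.0, gamma="scale"),
            cv_folds=cv,
            seed=seed,
        )
    else:
        n_sel = len(ranking)

    if cfg.second_layer == "ladtree":
        second = LADTree(n_boost=cfg.n_boost)
    elif cfg.second_layer == "gbstumps":
        second = GradientBoostedStumps(n_boost=cfg.n_boost, seed=seed)
    else:
        raise ValueError(f"unknown second layer {cfg.second_layer!r}")
    second.fit(meta[:, ranking[:n_sel]], ytr)
    return TwoLayerModel(bundle, ranking, n_sel, second, cfg)


# ---------------------------------------------------------------------------
# evaluation


def kfold_cv(
    enc: FeatureEncodings,
    labels: np.ndarray,
    factory: Callable[[FeatureEncodings, np.ndarray, np.ndarray, int], object] | None = None,
    k: int = 5,
    seed: int = 0,
    cfg: PipelineConfig | None = None,
) -> tuple[ConfusionMatrix, MetricsReport, np.ndarray]:
    """Stratified k-fold CV of the full pipeline, pooled across folds.

    All selection/weighting/training happens inside each fold's training
    split.  Returns the pooled confusion matrix, its metrics, and the
    per-record out-of-fold predictions.  ``factory(enc, labels,
    train_idx, seed) -> fitted model with .predict(enc, idx)`` defaults
    to the full two-layer trainer.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, dtype=int)
    if factory is None:
        factory = lambda e, yy, tr, s: train_two_layer(e, yy, tr, cfg, seed=s)
    preds = np.full(len(y), -1, dtype=int)
    skf = StratifiedKFold(k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = factory(enc, y, tr, seed + fold)
        preds[te] = model.predict(enc, te)
    cm = ConfusionMatrix.from_predictions(y, preds)
    return cm, confusion_metrics(cm), preds


class DistanceOnlyClassifier:
    """Baseline: threshold the distance-logistic probability at 0.5."""

    def __init__(self, enc: FeatureEncodings, labels: np.ndarray, train_idx: np.ndarray, seed: int = 0):
        self.model = fit_distance_logistic(
            enc.distances[train_idx], np.asarray(labels)[train_idx]
        )

    def predict(self, enc: FeatureEncodings, idx: np.ndarray) -> np.ndarray:
        return (self.model.predict_proba(enc.distances[idx]) >= 0.5).astype(int)
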