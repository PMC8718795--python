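"""LogitBoost alternating decision tree (LADTree) for the second layer.

An alternating decision tree (ADTree) interleaves *prediction nodes*
(carrying additive real values) with *splitter nodes* (single-feature
threshold tests).  A new splitter may attach under any existing
prediction node, so the tree grows option-style rather than purely
depth-wise; the score of an instance is the sum of the values of every
prediction node on every path it satisfies, and the label is the sign of
that sum.

The tree is grown by LogitBoost: at each boosting iteration the working
response z = (y - p)/(p(1-p)) and weights w = p(1-p) are computed from
the current additive score F (with p = 1/(1 + exp(-2F))), and the
(precondition node, feature, threshold) triple whose weighted
least-squares regression stump most reduces the loss is attached, its
two leaf values halved per the LogitBoost update.

A gradient-boosted-stump learner with the same fit/predict contract is
provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-5


@dataclass
class _PredictionNode:
    value: float
    children: list["_Splitter"] = field(default_factory=list)


@dataclass
class _Splitter:
    feature: int
    threshold: float
    left: _PredictionNode  # x[feature] <= threshold
    right: _PredictionNode


class LADTree:
    """Alternating decision tree grown by LogitBoost.

    Parameters
    ----------
    n_boost:
        Number of boosting iterations, i.e. splitter nodes (default 10).
    max_thresholds:
        Candidate split thresholds per feature (quantile midpoints).
    """

    def __init__(self, n_boost: int = 10, max_thresholds: int = 32):
        self.n_boost = n_boost
        self.max_thresholds = max_thresholds
        self.root: _PredictionNode | None = None

    # -- training ---------------------------------------------------------

    def fit(self, X, y) -> "LADTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("LADTree needs both classes present in the labels")
        if not set(classes) <= {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        n = len(y)

        pos = y.sum()
        self.root = _PredictionNode(value=0.5 * np.log((pos + 1.0) / (n - pos + 1.0)))
        F = np.full(n, self.root.value)
        # leaves[i] = (prediction node, mask of training instances reaching it)
        leaves: list[tuple[_PredictionNode, np.ndarray]] = [
            (self.root, np.ones(n, dtype=bool))
        ]

        cand = self._candidate_thresholds(X)
        for _ in range(self.n_boost):
            p = 1.0 / (1.0 + np.exp(-2.0 * F))
            p = np.clip(p, _EPS, 1 - _EPS)
            w = p * (1.0 - p)
            z = (y - p) / w

            best = None  # (gain, leaf_idx, feat, thr, a, b)
            for li, (_, mask) in enumerate(leaves):
                if not mask.any():
                    continue
                wm, zm, Xm = w[mask], z[mask], X[mask]
                wz = wm * zm
                for f in range(X.shape[1]):
                    thrs = cand[f]
                    if len(thrs) == 0:
                        continue
                    col = Xm[:, f]
                    order = np.argsort(col, kind="mergesort")
                    cs_w = np.concatenate([[0.0], np.cumsum(wm[order])])
                    cs_wz = np.concatenate([[0.0], np.cumsum(wz[order])])
                    pos = np.searchsorted(col[order], thrs, side="right")
                    w_le, wz_le = cs_w[pos], cs_wz[pos]
                    w_gt, wz_gt = cs_w[-1] - w_le, cs_wz[-1] - wz_le
                    with np.errstate(divide="ignore", invalid="ignore"):
                        a = np.where(w_le > 0, wz_le / np.maximum(w_le, _EPS), 0.0)
                        b = np.where(w_gt > 0, wz_gt / np.maximum(w_gt, _EPS), 0.0)
                    gain = a**2 * w_le + b**2 * w_gt
                    j = int(np.argmax(gain))
                    if best is None or gain[j] > best[0] + 1e-12:
                        best = (float(gain[j]), li, f, float(thrs[j]), float(a[j]), float(b[j]))
            if best is None:
                break
            _, li, f, thr, a, b = best
            node, mask = leaves[li]
            left = _PredictionNode(0.5 * a)
            right = _PredictionNode(0.5 * b)
            node.children.append(_Splitter(f, thr, left, right))
            le_full = mask & (X[:, f] <= thr)
            gt_full = mask & ~(X[:, f] <= thr)
            F[le_full] += left.value
            F[gt_full] += right.value
            leaves.append((left, le_full))
            leaves.append((right, gt_full))
        return self

    def _candidate_thresholds(self, X: np.ndarray) -> list[np.ndarray]:
        cand = []
        for f in range(X.shape[1]):
            vals = np.unique(X[:, f])
            if len(vals) <= 1:
                cand.append(np.empty(0))
                continue
            mids = (vals[:-1] + vals[1:]) / 2.0
            if len(mids) > self.max_thresholds:
                qs = np.linspace(0, 1, self.max_thresholds)
                mids = np.unique(np.quantile(mids, qs))
            cand.append(mids)
        return cand

    # -- prediction -------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        if self.root is None:
            raise RuntimeError("LADTree is not fitted")
        X = np.asarray(X, dtype=float)
        scores = np.zeros(len(X))
        self._accumulate(self.root, np.ones(len(X), dtype=bool), X, scores)
        return scores

    def _accumulate(
        self, node: _PredictionNode, mask: np.ndarray, X: np.ndarray, scores: np.ndarray
    ) -> None:
        scores[mask] += node.value
        for sp in node.children:
            le = mask & (X[:, sp.feature] <= sp.threshold)
            self._accumulate(sp.left, le, X, scores)
            self._accumulate(sp.right, mask & ~(X[:, sp.feature] <= sp.threshold), X, scores)

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-2.0 * self.decision_function(X)))
        return np.column_stack([1 - p, p])

    @property
    def n_splitters(self) -> int:
        if self.root is None:
            return 0
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            for sp in node.children:
                count += 1
                stack.extend([sp.left, sp.right])
        return count


class GradientBoostedStumps:
    """Depth-1 gradient boosting behind the same contract as LADTree.

    Used as an independent cross-check of the second-layer learner, never
    as its implementation.
    """

    def __init__(self, n_boost: int = 10, seed: int = 0):
        from sklearn.ensemble import GradientBoostingClassifier

        self._clf = GradientBoostingClassifier(
            max_depth=1, n_estimators=n_boost, random_state=seed
        )

    def fit(self, X, y) -> "GradientBoostedStumps":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("needs both classes present in the labels")
        self._clf.fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        return self._clf.predict(X)

    def predict_proba(self, X) -> np.ndarray:
        return self._clf.predict_proba(X)
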