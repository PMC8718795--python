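"""Pseudo k-tuple nucleotide composition (PseKNC).

PseKNC combines local composition with global sequence-order information.
For a sequence R_1 R_2 ... R_L the feature vector of length 4^k + lambda
is

    x_u = f_u / (1 + w * sum_j theta_j)            u = 1 .. 4^k
    x_u = w * theta_(u - 4^k) / (1 + w * sum_j theta_j)   u = 4^k+1 .. 4^k+lambda

where f_u are k-tuple frequencies normalised to sum 1, w is the weight
factor, and the correlation factor of tier j is the mean squared
physicochemical difference between dinucleotides j apart:

    theta_j = (1 / (L-j-1)) * sum_i (1/mu) * sum_v
              [P_v(R_i R_{i+1}) - P_v(R_{i+j} R_{i+j+1})]^2

over the mu dinucleotide property indices P_v.  All components share one
denominator, so the vector always sums to 1; on a homopolymer every
theta_j is 0 and the vector degenerates to the pure frequency vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from timgo.encoders.properties import PropertyTable, _oligo_indices


@dataclass(frozen=True)
class PseKNCParams:
    """Tuple size k, correlation depth lambda, and weight w."""

    k: int = 2
    lam: int = 4
    w: float = 0.2

    def __post_init__(self) -> None:
        if not 1 <= self.k:
            raise ValueError("k must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    @property
    def n_features(self) -> int:
        return 4**self.k + self.lam


def _theta(seq: str, lam: int, table: PropertyTable) -> np.ndarray:
    """Correlation factors theta_1..theta_lam from dinucleotide properties."""
    if table.unit_length != 2:
        raise ValueError("PseKNC correlation factors need a dinucleotide table")
    std = table.standardized()
    idx = _oligo_indices(seq, 2)
    # positions with ambiguous bases break the property signal; drop them
    signal = std.values[:, idx[idx >= 0]]  # (mu, n_dinucs)
    n = signal.shape[1]
    thetas = np.zeros(lam)
    for j in range(1, lam + 1):
        if n - j < 1:
            break
        diff = signal[:, : n - j] - signal[:, j:]
        thetas[j - 1] = float(np.mean(np.mean(diff**2, axis=0)))
    return thetas


def pseknc_encode(seq: str, params: PseKNCParams, table: PropertyTable) -> np.ndarray:
    """PseKNC vector of length 4^k + lambda; components sum to 1.

    Raises when lambda >= L (the correlation tiers would run off the
    sequence).
    """
    L = len(seq)
    if params.lam >= L:
        raise ValueError(f"lambda={params.lam} must be < sequence length {L}")
    idx = _oligo_indices(seq, params.k)
    idx = idx[idx >= 0]
    n_tuples = 4**params.k
    freq = np.bincount(idx, minlength=n_tuples).astype(float)
    if freq.sum() > 0:
        freq /= freq.sum()
    thetas = _theta(seq, params.lam, table)
    denom = freq.sum() + params.w * thetas.sum()
    if denom == 0:
        return np.zeros(params.n_features)
    return np.concatenate([freq, params.w * thetas]) / denom
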