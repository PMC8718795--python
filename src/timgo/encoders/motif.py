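"""Cis-regulatory element scanning over PROMOTER sequences.

Each library entry is an IUPAC consensus string.  It is converted to a
position frequency model (degenerate positions uniform over their allowed
bases, pseudocount 0.01 on disallowed bases, renormalised), scored as
log2 odds against a 0-order background, and scanned over both strands.
Hits are retained where the exact score-distribution p-value -- computed
by dynamic programming over discretised scores, as motif scanners do --
is at or below the threshold.  The default threshold (2.5e-4) is the
loosest level at which an exact match to a 6-bp consensus -- the length
of common plant core elements such as the G-box CACGTG -- is still
retained under a uniform background, where its best achievable p-value
is 0.25^6 = 2.44e-4; stricter conventional thresholds silently discard
every hit of short motifs.

Per motif *i* the promoter is summarised by four statistics:

- ``Number``      hit count (0 when absent)
- ``Conserve``    mean log-odds score of the hits
- ``Orientation`` fraction of hits on the coding (+) strand
- ``Dis``         mean |TLS - hit site| in bp

with the three ratios defined as 0 when there are no hits, giving a
4 x |library| feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from timgo.genome import revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
_PSEUDOCOUNT = 0.01
_QUANT_BINS = 2000  # score discretisation for the p-value DP


@dataclass(frozen=True)
class MotifHit:
    motif_index: int
    position: int  # 0-based hit start within the promoter (+ strand coords)
    strand: str
    score: float
    pvalue: float


@dataclass
class MotifLibrary:
    """Named IUPAC consensus strings.

    The original plant cis-element collections (PLACE, RegSite) hold about
    2,087 entries; any TSV with ``name`` and ``consensus`` columns can be
    loaded in their place.
    """

    names: list[str] = field(default_factory=list)
    consensi: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.consensi:
            bad = set(c.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"consensus {c!r} has non-IUPAC symbols {sorted(bad)}")
        self.consensi = [c.upper() for c in self.consensi]

    def __len__(self) -> int:
        return len(self.names)


def load_motif_library(path) -> MotifLibrary:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"name", "consensus"} <= set(df.columns):
        raise ValueError("motif library TSV needs 'name' and 'consensus' columns")
    return MotifLibrary(list(df["name"]), list(df["consensus"]))


def default_motif_library() -> MotifLibrary:
    """Curated library of widely documented plant cis-element consensi."""
    with resources.as_file(resources.files("timgo.data") / "plant_motifs.tsv") as p:
        return load_motif_library(p)


def consensus_to_pfm(consensus: str) -> np.ndarray:
    """IUPAC string -> (length, 4) position frequency model."""
    pfm = np.full((len(consensus), 4), _PSEUDOCOUNT)
    for i, sym in enumerate(consensus):
        allowed = IUPAC[sym]
        for b in allowed:
            pfm[i, _BASE_IDX[b]] = 1.0 / len(allowed)
        pfm[i] /= pfm[i].sum()
    return pfm


def _log_odds(pfm: np.ndarray, background: np.ndarray) -> np.ndarray:
    return np.log2(pfm / background[None, :])


def background_from_seqs(seqs: list[str]) -> np.ndarray:
    """0-order base frequencies pooled over a sequence set (both strands)."""
    counts = np.zeros(4)
    for s in seqs:
        su = s.upper()
        for b, i in _BASE_IDX.items():
            counts[i] += su.count(b)
    counts = counts + counts[::-1]  # strand symmetrise (A<->T, C<->G)
    total = counts.sum()
    return counts / total if total else np.full(4, 0.25)


def score_pvalue_table(
    lom: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Exact null distribution of window scores under the background.

    Discretises each column of the log-odds matrix onto a shared integer
    grid and convolves column score distributions, returning
    ``(pval, offset, scale)`` where a raw score ``s`` maps to bin
    ``round((s - offset) / scale)`` and ``pval[bin]`` = P(score >= s).
    """
    m = lom.shape[0]
    col_min = lom.min(axis=1)
    offset = col_min.sum()
    span = (lom.max(axis=1) - col_min).sum()
    scale = span / _QUANT_BINS if span > 0 else 1.0
    q = np.rint((lom - col_min[:, None]) / scale).astype(int)
    size = q.max(axis=1).sum() + 1
    pdf = np.zeros(size)
    pdf[0] = 1.0
    for i in range(m):
        new = np.zeros(size)
        for b in range(4):
            s = q[i, b]
            if s == 0:
                new += background[b] * pdf
            else:
                new[s:] += background[b] * pdf[:-s]
        pdf = new
    pval = np.cumsum(pdf[::-1])[::-1]
    return pval, offset, scale


def _pvalues(scores: np.ndarray, pval: np.ndarray, offset: float, scale: float) -> np.ndarray:
    bins = np.rint((scores - offset) / scale).astype(int)
    bins = np.clip(bins, 0, len(pval) - 1)
    return pval[bins]


def _window_scores(seq_codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Scores of every window; -inf where the window contains N."""
    m = lom.shape[0]
    L = len(seq_codes)
    if L < m:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(seq_codes, m)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = lom[np.arange(m)[None, :], safe].sum(axis=1)
    scores[~valid] = -np.inf
    return scores


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int8)
    su = seq.upper()
    for b, i in _BASE_IDX.items():
        codes[np.frombuffer(su.encode(), dtype=np.uint8) == ord(b)] = i
    return codes


def motif_scan(
    promoter: str,
    lib: MotifLibrary,
    p_threshold: float = 2.5e-4,
    background: np.ndarray | None = None,
) -> list[MotifHit]:
    """Scan both strands of a promoter for every library motif.

    A palindromic site that scores identically on both strands at the same
    coordinates is reported once (+ strand).  Motifs longer than the
    sequence produce no hits.
    """
    if background is None:
        background = background_from_seqs([promoter])
    L = len(promoter)
    fwd = _encode(promoter)
    rev = _encode(revcomp(promoter))
    hits: list[MotifHit] = []
    for mi, consensus in enumerate(lib.consensi):
        m = len(consensus)
        if m > L:
            continue
        lom = _log_odds(consensus_to_pfm(consensus), background)
        pval, off, sc = score_pvalue_table(lom, background)

        plus_scores = _window_scores(fwd, lom)
        plus_p = _pvalues(plus_scores, pval, off, sc)
        plus_keep = np.flatnonzero((plus_p <= p_threshold) & np.isfinite(plus_scores))
        plus_pos = set(plus_keep.tolist())
        for i in plus_keep:
            hits.append(MotifHit(mi, int(i), "+", float(plus_scores[i]), float(plus_p[i])))

        minus_scores = _window_scores(rev, lom)
        minus_p = _pvalues(minus_scores, pval, off, sc)
        for i in np.flatnonzero((minus_p <= p_threshold) & np.isfinite(minus_scores)):
            start = L - int(i) - m  # + strand coordinates of the site
            if start in plus_pos and minus_scores[i] == plus_scores[start]:
                continue  # palindromic duplicate of an existing + hit
            hits.append(MotifHit(mi, start, "-", float(minus_scores[i]), float(minus_p[i])))
    return hits


def motif_features(
    hits: list[MotifHit],
    n_motifs: int,
    promoter_length: int,
    tls_offset: int = 0,
) -> np.ndarray:
    """4 x n_motifs vector: (Number, Conserve, Orientation, Dis) per motif.

    The TLS sits ``tls_offset`` bp past the promoter's 3' end (0 for the
    standard PROMOTER window), so a hit starting at position ``p`` lies
    ``promoter_length - p + tls_offset`` bp from the TLS.
    """
    out = np.zeros((n_motifs, 4))
    for h in hits:
        row = out[h.motif_index]
        row[0] += 1
        row[1] += h.score
        row[2] += 1.0 if h.strand == "+" else 0.0
        row[3] += promoter_length - h.position + tls_offset
    nz = out[:, 0] > 0
    out[nz, 1:] /= out[nz, 0:1]
    return out.ravel()


def motif_feature_names(lib: MotifLibrary) -> list[str]:
    names = []
    for n in lib.names:
        names.extend([f"{n}:number", f"{n}:conserve", f"{n}:orientation", f"{n}:dis"])
    return names
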