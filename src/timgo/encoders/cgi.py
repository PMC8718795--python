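"""CpG-island detection and the 5-dimensional CGI feature.

Detection follows the classic sliding-window convention (window 100 bp,
step 1, minimum island length 200 bp, GC >= 50%, observed/expected CpG
>= 0.6): an island is a maximal region, at least ``min_length`` long, in
which every fully contained window passes both the GC and the OE test.
The observed/expected ratio of a window is

    OE = count(CG) * window_length / (count(C) * count(G))

DNA methylation of promoter CpG islands suppresses transcription, so the
presence and placement of islands upstream of the TLS is informative
about whether an enhancer can activate the gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CpGIsland:
    """0-based half-open island coordinates with summary statistics."""

    start: int
    end: int  # exclusive
    gc_percent: float
    oe: float
    n_cpg: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CGIReport:
    """Aggregate island features for one sequence (all zero when empty)."""

    n_islands: int
    total_length: int
    mean_distance_to_tls: float
    mean_gc_percent: float
    mean_oe: float

    def to_vector(self) -> np.ndarray:
        return np.array(
            [
                self.n_islands,
                self.total_length,
                self.mean_distance_to_tls,
                self.mean_gc_percent,
                self.mean_oe,
            ],
            dtype=float,
        )


def _region_stats(seq: str, start: int, end: int) -> tuple[float, float, int]:
    sub = seq[start:end]
    c = sub.count("C")
    g = sub.count("G")
    cpg = sub.count("CG")
    n = end - start
    gc = 100.0 * (c + g) / n if n else 0.0
    oe = (cpg * n) / (c * g) if c and g else 0.0
    return gc, oe, cpg


def detect_cgis(
    seq: str,
    window: int = 100,
    min_length: int = 200,
    min_gc: float = 50.0,
    min_oe: float = 0.6,
) -> list[CpGIsland]:
    """Find CpG islands in ``seq``; empty when the window exceeds it."""
    seq = seq.upper()
    L = len(seq)
    if window > L:
        return []
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = codes == ord("C")
    is_g = codes == ord("G")
    is_cpg = np.zeros(L, dtype=bool)
    if L > 1:
        is_cpg[: L - 1] = is_c[: L - 1] & is_g[1:]

    def wsum(arr: np.ndarray, w: int) -> np.ndarray:
        cs = np.concatenate([[0], np.cumsum(arr)])
        return (cs[w:] - cs[: L - w + 1]).astype(float)

    c_w = wsum(is_c, window)
    g_w = wsum(is_g, window)
    # CG dinucleotides fully inside [i, i+window): a CG starting at the
    # window's last base extends past it and must not count
    cpg_w = wsum(is_cpg, window) - is_cpg[np.arange(L - window + 1) + window - 1]

    gc_ok = 100.0 * (c_w + g_w) / window >= min_gc
    oe = np.where((c_w > 0) & (g_w > 0), cpg_w * window / np.maximum(c_w * g_w, 1.0), 0.0)
    passing = gc_ok & (oe >= min_oe)

    islands: list[CpGIsland] = []
    i = 0
    n = len(passing)
    while i < n:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and passing[j + 1]:
            j += 1
        start, end = i, j + window  # half-open region
        if end - start >= min_length:
            gc, oe_val, cpg = _region_stats(seq, start, end)
            islands.append(CpGIsland(start, end, gc, oe_val, cpg))
        i = j + 1
    return islands


def cgi_features(islands: list[CpGIsland], seq_length: int, tls_offset: int = 0) -> CGIReport:
    """Aggregate islands into the 5-dim CGI feature.

    ``tls_offset`` places the TLS relative to the sequence 3' end (0 when
    the sequence ends immediately before the TLS, as the PROMOTER window
    does).  An island's distance to the TLS is measured from its 3' edge,
    so an island flush with the promoter's 3' end has distance 0.  All
    means are 0 when there are no islands.
    """
    if not islands:
        return CGIReport(0, 0, 0.0, 0.0, 0.0)
    dists = [(seq_length - isl.end) + tls_offset for isl in islands]
    return CGIReport(
        n_islands=len(islands),
        total_length=sum(isl.length for isl in islands),
        mean_distance_to_tls=float(np.mean(dists)),
        mean_gc_percent=float(np.mean([isl.gc_percent for isl in islands])),
        mean_oe=float(np.mean([isl.oe for isl in islands])),
    )


def cgi_encode(seq: str, **detect_kwargs) -> np.ndarray:
    """Convenience: detect islands in a promoter and return the 5-vector."""
    return cgi_features(detect_cgis(seq, **detect_kwargs), len(seq)).to_vector()
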