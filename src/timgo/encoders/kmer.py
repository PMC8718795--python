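"""Kmer and RevKmer occurrence-count encodings.

A k-mer feature counts sliding-window occurrences of each length-k
subsequence on the coding strand.  RevKmer collapses each k-mer with its
reverse complement into one strand-agnostic class, represented by the
lexicographically smaller member of the pair.

Vocabulary sizes: plain k-mers give 4^k entries per k; reverse-complement
classes give (4^k + 4^(k/2))/2 for even k (palindromes are their own
class) and 4^k/2 for odd k (no odd-length palindromes).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from timgo.genome import revcomp

BASES = "ACGT"


@dataclass(frozen=True)
class KmerSpec:
    """k-mer range and strand-collapse mode."""

    k_min: int
    k_max: int
    collapse_revcomp: bool = False

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError(f"k_min must be >= 1, got {self.k_min}")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")

    @property
    def ks(self) -> range:
        return range(self.k_min, self.k_max + 1)


def kmer_vocabulary(spec: KmerSpec) -> list[str]:
    """Ordered vocabulary for the spec, lexicographic within each k.

    With ``collapse_revcomp`` each entry is the canonical (lexicographically
    smaller) representative of a reverse-complement class.
    """
    vocab: list[str] = []
    for k in spec.ks:
        if spec.collapse_revcomp:
            seen: set[str] = set()
            for tup in product(BASES, repeat=k):
                s = "".join(tup)
                rc = revcomp(s)
                canon = min(s, rc)
                if canon not in seen:
                    seen.add(canon)
                    vocab.append(canon)
        else:
            vocab.extend("".join(t) for t in product(BASES, repeat=k))
    return vocab


def expected_vocabulary_size(spec: KmerSpec) -> int:
    """Closed-form vocabulary size for a spec."""
    total = 0
    for k in spec.ks:
        if spec.collapse_revcomp:
            pal = 4 ** (k // 2) if k % 2 == 0 else 0
            total += (4**k + pal) // 2
        else:
            total += 4**k
    return total


def _raw_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue  # ambiguous windows are skipped, not imputed
        counts[w] = counts.get(w, 0) + 1
    return counts


def kmer_counts(seq: str, spec: KmerSpec, vocabulary: list[str] | None = None) -> np.ndarray:
    """Occurrence-count vector over the vocabulary (or a subset of it).

    When collapsing, a class count is count(s) + count(revcomp(s)) for
    non-palindromic representatives and count(s) for palindromes.
    """
    if vocabulary is None:
        vocabulary = kmer_vocabulary(spec)
    raw: dict[str, int] = {}
    for k in {len(v) for v in vocabulary}:
        raw.update(_raw_counts(seq, k))
    out = np.zeros(len(vocabulary), dtype=np.int64)
    for j, v in enumerate(vocabulary):
        if spec.collapse_revcomp:
            rc = revcomp(v)
            c = raw.get(v, 0)
            if rc != v:
                c += raw.get(rc, 0)
            out[j] = c
        else:
            out[j] = raw.get(v, 0)
    return out


def kmer_count_matrix(
    seqs: list[str], spec: KmerSpec, vocabulary: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Stack :func:`kmer_counts` over sequences -> (n_seqs, |vocab|) matrix."""
    if vocabulary is None:
        vocabulary = kmer_vocabulary(spec)
    mat = np.vstack([kmer_counts(s, spec, vocabulary) for s in seqs])
    return mat, vocabulary
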