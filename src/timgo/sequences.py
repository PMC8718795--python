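"""PROMOTER and MIDDLE sequence extraction.

Two windows are analysed per (gene, insertion) event:

- PROMOTER: the 1,500 bp immediately upstream of the translation start
  site (TLS), reported 5'->3' on the gene's coding strand.  The TLS base
  itself is excluded.
- MIDDLE: 300 bp centered on the midpoint between the TLS and the 35S
  enhancer coordinate, also oriented on the gene's coding strand.  When
  the enhancer sits closer than 300 bp, the window is clipped to the
  TLS-enhancer interval.

Coordinates are 1-based inclusive throughout (GFF3 convention); windows
are clipped at contig boundaries with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from timgo.genome import Genome, revcomp
from timgo.io_data import GeneAnnotation, MutantRecord

logger = logging.getLogger(__name__)

PROMOTER_LENGTH = 1500
MIDDLE_LENGTH = 300


@dataclass(frozen=True)
class SequencePair:
    """The two analysis sequences for one mutant record."""

    promoter: str
    middle: str


def extract_promoter(genome: Genome, gene: GeneAnnotation, length: int = PROMOTER_LENGTH) -> str:
    """Upstream window of ``length`` bp on the gene's coding strand.

    For a + strand gene this is ``genome[tls-length .. tls-1]``; for a -
    strand gene the reverse complement of ``genome[tls+1 .. tls+length]``.
    """
    tls = gene.tls_position
    if gene.strand == "+":
        seq = genome.fetch(gene.chrom, tls - length, tls - 1)
    else:
        seq = revcomp(genome.fetch(gene.chrom, tls + 1, tls + length))
    if len(seq) < length:
        logger.warning(
            "promoter of %s clipped to %d bp at contig boundary", gene.gene_id, len(seq)
        )
    return seq


def extract_middle(
    genome: Genome,
    gene: GeneAnnotation,
    enhancer_position: int,
    length: int = MIDDLE_LENGTH,
) -> str:
    """Window centered between TLS and enhancer, on the coding strand.

    The midpoint is ``floor((tls + enhancer)/2)``; the window spans
    ``midpoint-length/2 .. midpoint+length/2-1``.  When the two anchors
    are closer than ``length`` the window is clipped to the bases strictly
    between them (both anchor bases excluded), so its length never exceeds
    the enhancer-TLS distance.
    """
    tls = gene.tls_position
    mid = (tls + enhancer_position) // 2
    half = length // 2
    start, end = mid - half, mid + half - 1
    lo, hi = min(tls, enhancer_position), max(tls, enhancer_position)
    if hi - lo < length:
        start, end = max(start, lo + 1), min(end, hi - 1)
    seq = genome.fetch(gene.chrom, start, end)
    return revcomp(seq) if gene.strand == "-" else seq


def extract_pair(genome: Genome, record: MutantRecord) -> SequencePair:
    """PROMOTER + MIDDLE for one record."""
    return SequencePair(
        promoter=extract_promoter(genome, record.gene),
        middle=extract_middle(genome, record.gene, record.enhancer_position),
    )


def write_pair_fasta(records: list[MutantRecord], genome: Genome, path) -> None:
    """Emit all PROMOTER/MIDDLE sequences as FASTA with structured IDs."""
    with open(path, "w") as fh:
        for r in records:
            pair = extract_pair(genome, r)
            fh.write(f">{r.record_id}|PROMOTER\n{pair.promoter}\n")
            fh.write(f">{r.record_id}|MIDDLE\n{pair.middle}\n")
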