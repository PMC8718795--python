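"""Mutant-table I/O, dataset filtering, and balanced train/test selection.

The experimental unit is one (gene, T-DNA insertion) event: a mutant line
in which RT-PCR established the expression status of a gene flanking the
insertion site.  Status vocabulary:

- ``Ac``  activated gene (positive class)
- ``NE``  no significant effect (relabelled ``NAc``, the negative class)
- ``ND``  non-detectable (dropped)
- ``Ko``  knockout -- T-DNA disrupted the gene body (dropped)

The mutant table is a headered TSV with columns ``line_id``, ``gene_id``,
``chrom``, ``tls``, ``strand``, ``enhancer_pos``, ``status``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STATUSES = frozenset({"Ac", "NE", "ND", "Ko"})
#: statuses retained after filtering, mapped to the binary label
LABEL_MAP = {"Ac": 1, "NAc": 0}

MUTANT_TABLE_COLUMNS = ["line_id", "gene_id", "chrom", "tls", "strand", "enhancer_pos", "status"]


class MutantTableError(ValueError):
    """Malformed mutant table (missing column, bad coordinate, bad status)."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene anchored by its translation start site (TLS).

    ``tls_position`` is the 1-based genomic coordinate of the first base of
    the start codon on ``chrom``; ``strand`` is ``+`` or ``-``.
    """

    gene_id: str
    chrom: str
    tls_position: int
    strand: str

    def __post_init__(self) -> None:
        if self.tls_position < 1:
            raise ValueError(f"tls_position must be >= 1, got {self.tls_position}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class MutantRecord:
    """One validated (gene, insertion) event with its expression status."""

    line_id: str
    gene: GeneAnnotation
    enhancer_position: int
    status: str

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUSES and self.status != "NAc":
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def distance_bp(self) -> int:
        """Absolute enhancer-to-TLS distance in bp."""
        return abs(self.enhancer_position - self.gene.tls_position)

    @property
    def label(self) -> int:
        """Binary label: Ac -> 1, NAc -> 0. Raises for unfiltered statuses."""
        return LABEL_MAP[self.status]

    @property
    def record_id(self) -> str:
        return f"{self.line_id}|{self.gene.gene_id}"


@dataclass
class Dataset:
    """Filtered record collection restricted to the Ac/NAc label set."""

    records: list[MutantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = [r.status for r in self.records if r.status not in LABEL_MAP]
        if bad:
            raise ValueError(f"Dataset restricted to Ac/NAc; found {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def distances(self) -> np.ndarray:
        return np.array([r.distance_bp for r in self.records], dtype=int)

    def class_counts(self) -> dict[str, int]:
        y = self.labels
        return {"Ac": int(y.sum()), "NAc": int(len(y) - y.sum())}


def read_mutant_table(path) -> list[MutantRecord]:
    """Read a headered TSV mutant table into records.

    Raises :class:`MutantTableError` on a missing column, a non-integer
    coordinate (naming the offending row), or an unknown status string.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in MUTANT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MutantTableError(f"mutant table missing column(s): {', '.join(missing)}")

    records: list[MutantRecord] = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # header is line 1
        try:
            tls = int(row["tls"])
            enh = int(row["enhancer_pos"])
        except (TypeError, ValueError) as exc:
            raise MutantTableError(f"row {rownum}: non-integer coordinate ({exc})") from None
        status = str(row["status"]).strip()
        if status not in VALID_STATUSES:
            raise MutantTableError(
                f"row {rownum}: unknown status {status!r}; expected one of {sorted(VALID_STATUSES)}"
            )
        try:
            gene = GeneAnnotation(str(row["gene_id"]), str(row["chrom"]), tls, str(row["strand"]))
        except ValueError as exc:
            raise MutantTableError(f"row {rownum}: {exc}") from None
        records.append(MutantRecord(str(row["line_id"]), gene, enh, status))
    return records


def write_mutant_table(records: list[MutantRecord], path) -> None:
    """Inverse of :func:`read_mutant_table` (NAc written back as NE)."""
    rows = []
    for r in records:
        rows.append(
            {
                "line_id": r.line_id,
                "gene_id": r.gene.gene_id,
                "chrom": r.gene.chrom,
                "tls": r.gene.tls_position,
                "strand": r.gene.strand,
                "enhancer_pos": r.enhancer_position,
                "status": "NE" if r.status == "NAc" else r.status,
            }
        )
    pd.DataFrame(rows, columns=MUTANT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_dataset(records: list[MutantRecord]) -> Dataset:
    """Drop ND and Ko records and relabel NE as NAc.

    ND calls carry no usable expression information and Ko genes are
    physically disrupted rather than enhancer-regulated, so both are
    removed before model construction.
    """
    kept: list[MutantRecord] = []
    n_dropped = 0
    for r in records:
        if r.status in ("ND", "Ko"):
            n_dropped += 1
            continue
        kept.append(replace(r, status="NAc") if r.status == "NE" else r)
    if n_dropped:
        logger.info("filter_dataset: dropped %d ND/Ko records, retained %d", n_dropped, len(kept))
    if not kept:
        raise ValueError("filtering removed every record; nothing to train on")
    return Dataset(kept)


def balanced_split(
    dataset: Dataset, n_train_per_class: int, seed: int
) -> tuple[Dataset, Dataset]:
    """Class-balanced training selection; the remainder is the test set.

    Draws exactly ``n_train_per_class`` records uniformly at random (under
    ``seed``) from each class for training; everything else becomes the
    independent test set.  Train and test are disjoint and their union is
    the input dataset.
    """
    rng = np.random.default_rng(seed)
    y = dataset.labels
    train_idx: list[int] = []
    for cls_name, cls in (("Ac", 1), ("NAc", 0)):
        members = np.flatnonzero(y == cls)
        if len(members) < n_train_per_class:
            raise ValueError(
                f"class {cls_name} has only {len(members)} records; "
                f"cannot draw {n_train_per_class}"
            )
        train_idx.extend(rng.choice(members, size=n_train_per_class, replace=False))
    train_set = set(train_idx)
    train = Dataset([dataset.records[i] for i in sorted(train_set)])
    test = Dataset([r for i, r in enumerate(dataset.records) if i not in train_set])
    return train, test
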