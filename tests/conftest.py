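"""Shared fixtures: toy genomes and small simulated screens."""

from __future__ import annotations

import numpy as np
import pytest

from timgo.genome import Genome
from timgo.io_data import GeneAnnotation, MutantRecord
from timgo.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def toy_contig() -> str:
    rng = np.random.default_rng(42)
    return "".join(rng.choice(list("ACGT"), size=10_000))


@pytest.fixture(scope="session")
def toy_genome(toy_contig) -> Genome:
    return Genome({"chr1": toy_contig})


@pytest.fixture()
def plus_gene() -> GeneAnnotation:
    return GeneAnnotation("gene1", "chr1", 2000, "+")


def make_records(n_ac: int, n_ne: int, n_nd: int = 0, n_ko: int = 0) -> list[MutantRecord]:
    """Synthetic records with distinct distances; status counts as given."""
    records = []
    statuses = ["Ac"] * n_ac + ["NE"] * n_ne + ["ND"] * n_nd + ["Ko"] * n_ko
    for i, status in enumerate(statuses):
        gene = GeneAnnotation(f"g{i}", "chr1", 5000, "+")
        records.append(MutantRecord(f"line{i}", gene, 5000 + 100 * (i + 1), status))
    return records


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-signal screen shared by pipeline-level tests."""
    return simulate_dataset(SimConfig(n_records=80, seed=11))
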