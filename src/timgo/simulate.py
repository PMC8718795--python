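"""Synthetic activation-tagging data: genome, annotation, mutant table.

Emulates the structure of a T-DNA activation-tagging screen so every
pipeline stage is testable without external data:

- one gene per synthetic contig, with a 35S-enhancer coordinate placed at
  a log-uniformly drawn distance from the TLS (default 200 bp - 40 kb);
- the activation label drawn Bernoulli(logistic(b0 + b1 * distance)),
  with b1 <= 0 so activation probability decays with distance;
- promoter sequences are i.i.d. with configurable GC content (default
  0.44, rice-like), then cis-element motifs are planted at label-dependent
  rates (e.g. the G-box CACGTG enriched in activated genes), uniform
  position, random orientation;
- a truth table records every latent draw.

Outputs are standard FASTA / GFF3 / TSV files consumed unchanged by the
rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from timgo.genome import Genome, revcomp, write_fasta
from timgo.io_data import Dataset, GeneAnnotation, MutantRecord
from timgo.sequences import PROMOTER_LENGTH

_GENE_LENGTH = 600
_MARGIN = 300


@dataclass(frozen=True)
class PlantedMotif:
    """A motif planted in promoters at label-dependent rates."""

    name: str
    consensus: str  # IUPAC
    p_ac: float  # planting probability in activated promoters
    p_nac: float

    def __post_init__(self) -> None:
        for p in (self.p_ac, self.p_nac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("planting probabilities must lie in [0, 1]")


#: default planted motifs: a strongly label-informative G-box, a medium
#: ABRE, and a label-neutral W-box
DEFAULT_PLANTED_MOTIFS = (
    PlantedMotif("G-box", "CACGTG", 0.9, 0.1),
    PlantedMotif("ABRE", "ACGTGKC", 0.6, 0.2),
    PlantedMotif("W-box", "TTGACY", 0.5, 0.5),
)


@dataclass
class SimConfig:
    """Study conditions for one simulated screen."""

    n_records: int = 300
    distance_min_bp: int = 200
    distance_max_bp: int = 40_000
    beta0: float = 1.5
    beta1: float = -1e-4  # per bp; <= 0 emulates the distance decay
    planted_motifs: tuple[PlantedMotif, ...] = DEFAULT_PLANTED_MOTIFS
    gc_content: float = 0.44
    seed: int = 0
    contig_length: int | None = None  # None: auto-size per record

    def __post_init__(self) -> None:
        if self.beta1 > 0:
            raise ValueError("beta1 must be <= 0 (activation decays with distance)")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.distance_min_bp < 1 or self.distance_max_bp < self.distance_min_bp:
            raise ValueError("invalid distance range")


@dataclass
class SimResult:
    """In-memory simulation output plus written file paths (if any)."""

    genome: Genome
    records: list[MutantRecord]
    truth: pd.DataFrame
    genome_path: Path | None = None
    gff_path: Path | None = None
    mutants_path: Path | None = None
    truth_path: Path | None = None

    @property
    def dataset(self) -> Dataset:
        from timgo.io_data import filter_dataset

        return filter_dataset(self.records)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)


_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _instantiate_motif(rng: np.random.Generator, consensus: str) -> str:
    return "".join(rng.choice(list(_IUPAC_CHOICES[s])) for s in consensus.upper())


def simulate_dataset(cfg: SimConfig, out_dir=None) -> SimResult:
    """Draw one synthetic screen; optionally write FASTA/GFF3/TSV files.

    Each record occupies its own contig with the gene placed so the full
    1,500-bp promoter fits; the enhancer coordinate sits at the drawn
    distance on the promoter-distal side for + strand genes and
    mirror-image for - strand genes.  Raises when ``cfg.contig_length``
    is too short for the required layout.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[MutantRecord] = []
    contigs: dict[str, str] = {}
    truth_rows = []
    gff_lines = ["##gff-version 3"]

    log_lo, log_hi = np.log(cfg.distance_min_bp), np.log(cfg.distance_max_bp)
    for i in range(cfg.n_records):
        d = int(np.exp(rng.uniform(log_lo, log_hi)))
        p_act = 1.0 / (1.0 + np.exp(-(cfg.beta0 + cfg.beta1 * d)))
        label = int(rng.random() < p_act)
        strand = "+" if rng.random() < 0.5 else "-"

        promoter = _random_seq(rng, PROMOTER_LENGTH, cfg.gc_content)
        planted = []
        for pm in cfg.planted_motifs:
            p = pm.p_ac if label else pm.p_nac
            if rng.random() < p:
                site = _instantiate_motif(rng, pm.consensus)
                if rng.random() < 0.5:
                    site = revcomp(site)
                pos = int(rng.integers(0, PROMOTER_LENGTH - len(site) + 1))
                promoter[pos : pos + len(site)] = np.frombuffer(site.encode(), dtype=np.uint8)
                planted.append(pm.name)
        promoter_str = promoter.tobytes().decode()

        left = _MARGIN + max(d, PROMOTER_LENGTH)
        chrom = f"synth_chr{i + 1}"
        if strand == "+":
            tls = left + 1  # promoter occupies [tls-1500, tls-1]
            enh = tls - d
            length = tls + _GENE_LENGTH + _MARGIN
            cds_start, cds_end = tls, tls + _GENE_LENGTH - 1
        else:
            tls = _MARGIN + _GENE_LENGTH  # CDS upstream, promoter downstream
            enh = tls + d
            length = tls + max(d, PROMOTER_LENGTH) + _MARGIN
            cds_start, cds_end = tls - _GENE_LENGTH + 1, tls
        if cfg.contig_length is not None:
            if length > cfg.contig_length:
                raise ValueError(
                    f"record {i}: layout needs {length} bp but contig_length="
                    f"{cfg.contig_length}"
                )
            length = cfg.contig_length

        contig = _random_seq(rng, length, cfg.gc_content)
        if strand == "+":
            contig[tls - 1 - PROMOTER_LENGTH : tls - 1] = promoter
        else:
            rc = np.frombuffer(revcomp(promoter_str).encode(), dtype=np.uint8)
            contig[tls : tls + PROMOTER_LENGTH] = rc
        contigs[chrom] = contig.tobytes().decode()

        gene_id = f"SynGene{i + 1:04d}"
        line_id = f"SimLine{i + 1:04d}"
        gene = GeneAnnotation(gene_id, chrom, tls, strand)
        records.append(MutantRecord(line_id, gene, enh, "Ac" if label else "NE"))
        gff_lines.extend(_gff_entries(chrom, gene_id, cds_start, cds_end, strand))
        truth_rows.append(
            {
                "line_id": line_id,
                "gene_id": gene_id,
                "distance_bp": d,
                "p_activation": p_act,
                "label": label,
                "strand": strand,
                "planted_motifs": ",".join(planted),
            }
        )

    truth = pd.DataFrame(truth_rows)
    result = SimResult(Genome(contigs), records, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.genome_path = out / "genome.fa"
        result.gff_path = out / "genes.gff3"
        result.mutants_path = out / "mutants.tsv"
        result.truth_path = out / "truth.tsv"
        write_fasta(contigs, result.genome_path)
        result.gff_path.write_text("\n".join(gff_lines) + "\n")
        from timgo.io_data import write_mutant_table

        write_mutant_table(records, result.mutants_path)
        truth.to_csv(result.truth_path, sep="\t", index=False)
    return result


def _gff_entries(chrom, gene_id, start, end, strand) -> list[str]:
    common = f"{chrom}\ttimgo_sim"
    return [
        f"{common}\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}",
        f"{common}\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}.1;Parent={gene_id}",
        f"{common}\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID={gene_id}.1.cds;Parent={gene_id}.1",
    ]


def distance_activation_curve(truth: pd.DataFrame, bin_edges_bp: list[float]) -> pd.DataFrame:
    """Per-distance-bin activated fraction from a truth table.

    Bins are half-open ``(lo, hi]``; empty bins are flagged rather than
    interpolated.
    """
    d = truth["distance_bp"].to_numpy(dtype=float)
    y = truth["label"].to_numpy(dtype=int)
    rows = []
    for lo, hi in zip(bin_edges_bp[:-1], bin_edges_bp[1:]):
        mask = (d > lo) & (d <= hi)
        n = int(mask.sum())
        rows.append(
            {
                "lo_bp": lo,
                "hi_bp": hi,
                "n": n,
                "ac_fraction": float(y[mask].mean()) if n else float("nan"),
                "empty": n == 0,
            }
        )
    return pd.DataFrame(rows)
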