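"""Synthetic activation-tagging screen generator."""

import numpy as np
import pytest

from timgo.annotations import read_gene_annotations
from timgo.genome import revcomp
from timgo.io_data import read_mutant_table
from timgo.selection import fit_distance_logistic
from timgo.sequences import extract_promoter
from timgo.simulate import (
    PlantedMotif,
    SimConfig,
    distance_activation_curve,
    simulate_dataset,
)


class TestGeneration:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimConfig(n_records=12, seed=5)
        a = simulate_dataset(cfg, tmp_path / "a")
        b = simulate_dataset(cfg, tmp_path / "b")
        for pa, pb in [
            (a.genome_path, b.genome_path),
            (a.gff_path, b.gff_path),
            (a.mutants_path, b.mutants_path),
            (a.truth_path, b.truth_path),
        ]:
            assert pa.read_bytes() == pb.read_bytes()

    def test_base_rate_matches_logistic_intercept(self):
        """With a flat distance effect and no motifs, the activated fraction
        is the logistic of the intercept alone."""
        cfg = SimConfig(n_records=1000, beta1=0.0, planted_motifs=(), seed=3)
        res = simulate_dataset(cfg)
        frac = res.truth["label"].mean()
        p = 1 / (1 + np.exp(-cfg.beta0))
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 1000)

    def test_planted_motif_enrichment_ratio(self):
        cfg = SimConfig(
            n_records=600,
            planted_motifs=(PlantedMotif("gbox", "CACGTG", 0.9, 0.1),),
            seed=4,
        )
        res = simulate_dataset(cfg)
        planted = res.truth["planted_motifs"].fillna("").str.contains("gbox")
        ac = res.truth["label"] == 1
        rate_ac = planted[ac].mean()
        rate_nac = planted[~ac].mean()
        assert 6 < rate_ac / rate_nac < 13  # ~9x enrichment

    def test_planted_site_present_in_extracted_promoter(self):
        cfg = SimConfig(
            n_records=40,
            planted_motifs=(PlantedMotif("gbox", "CACGTG", 1.0, 1.0),),
            seed=6,
        )
        res = simulate_dataset(cfg)
        for rec in res.records:
            prom = extract_promoter(res.genome, rec.gene)
            assert "CACGTG" in prom or revcomp("CACGTG") in prom

    def test_distance_recomputable_from_files(self, tmp_path):
        res = simulate_dataset(SimConfig(n_records=15, seed=7), tmp_path)
        back = read_mutant_table(res.mutants_path)
        truth_d = dict(zip(res.truth["line_id"], res.truth["distance_bp"]))
        for rec in back:
            assert rec.distance_bp == truth_d[rec.line_id]

    def test_gff_tls_matches_mutant_table(self, tmp_path):
        res = simulate_dataset(SimConfig(n_records=10, seed=8), tmp_path)
        ann = read_gene_annotations(res.gff_path)
        for rec in res.records:
            a = ann[rec.gene.gene_id]
            assert a.tls_position == rec.gene.tls_position
            assert a.strand == rec.gene.strand

    def test_infeasible_contig_length_errors(self):
        with pytest.raises(ValueError, match="contig_length"):
            simulate_dataset(SimConfig(n_records=5, contig_length=1000, seed=0))

    def test_positive_beta1_rejected(self):
        with pytest.raises(ValueError, match="beta1"):
            SimConfig(beta1=1e-4)


class TestDistanceCurve:
    def test_strong_decay_first_bin_above_last(self):
        res = simulate_dataset(SimConfig(n_records=800, beta1=-2e-4, seed=9))
        curve = distance_activation_curve(
            res.truth, [0, 2_000, 5_000, 10_000, 20_000, 40_000]
        )
        occupied = curve[~curve["empty"]]
        assert occupied["ac_fraction"].iloc[0] > occupied["ac_fraction"].iloc[-1]

    def test_flat_when_beta1_zero(self):
        res = simulate_dataset(
            SimConfig(n_records=1000, beta1=0.0, planted_motifs=(), seed=10)
        )
        curve = distance_activation_curve(res.truth, [0, 5_000, 40_000])
        fr = curve["ac_fraction"]
        assert abs(fr.iloc[0] - fr.iloc[1]) < 0.1

    def test_empty_bin_flagged(self):
        res = simulate_dataset(SimConfig(n_records=50, seed=11))
        curve = distance_activation_curve(res.truth, [0, 100, 40_000])
        assert curve.iloc[0]["empty"]  # distances start at 200 bp


class TestLogisticRecovery:
    def test_distance_model_recovered_within_three_se(self):
        cfg = SimConfig(n_records=1000, seed=13, planted_motifs=())
        res = simulate_dataset(cfg)
        model = fit_distance_logistic(
            res.truth["distance_bp"], res.truth["label"]
        )
        assert abs(model.slope - cfg.beta1) < 3 * model.slope_se
        assert abs(model.intercept - cfg.beta0) < 3 * model.intercept_se
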