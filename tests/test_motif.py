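"""IUPAC motif scanning and the 4-statistic motif encoding."""

import re
from itertools import product

import numpy as np
import pytest

from timgo.encoders.motif import (
    IUPAC,
    MotifHit,
    MotifLibrary,
    background_from_seqs,
    consensus_to_pfm,
    default_motif_library,
    motif_features,
    motif_scan,
    score_pvalue_table,
    _log_odds,
)

UNIFORM = np.full(4, 0.25)


def rand_promoter(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestScan:
    def test_exact_match_is_hit_at_planted_offset(self):
        rng = np.random.default_rng(1)
        prom = rand_promoter(rng, 500) + "CACGTG" + rand_promoter(rng, 200)
        hits = motif_scan(prom, MotifLibrary(["gbox"], ["CACGTG"]))
        assert any(h.position == 500 and h.strand == "+" for h in hits)

    def test_palindrome_counted_once(self):
        prom = "A" * 300 + "CACGTG" + "A" * 300  # palindromic site
        hits = motif_scan(prom, MotifLibrary(["gbox"], ["CACGTG"]), background=UNIFORM)
        at_site = [h for h in hits if h.position == 300]
        assert len(at_site) == 1 and at_site[0].strand == "+"

    @pytest.mark.parametrize(
        "site, expect_hit", [("CACGTG", True), ("CACGTT", True), ("CACGTA", False)]
    )
    def test_degenerate_consensus_matching(self, site, expect_hit):
        """CACGTK must match exactly the strings its IUPAC expansion allows
        (brute-force regex oracle)."""
        pattern = "".join(f"[{IUPAC[s]}]" for s in "CACGTK")
        assert bool(re.fullmatch(pattern, site)) == expect_hit
        seq = "A" * 60 + site + "A" * 60
        hits = motif_scan(
            seq, MotifLibrary(["m"], ["CACGTK"]), p_threshold=5e-4, background=UNIFORM
        )
        assert any(h.position == 60 and h.strand == "+" for h in hits) == expect_hit

    def test_motif_longer_than_sequence_gives_no_hits(self):
        assert motif_scan("ACGT", MotifLibrary(["m"], ["CACGTGCACGTG"])) == []

    def test_hit_fits_inside_promoter(self):
        rng = np.random.default_rng(7)
        prom = rand_promoter(rng, 400)
        lib = default_motif_library()
        for h in motif_scan(prom, lib):
            assert h.position + len(lib.consensi[h.motif_index]) <= len(prom)

    def test_pvalue_dp_matches_enumeration(self):
        """Exact DP p-value of the maximum score vs brute-force enumeration
        of all 4^m windows under a uniform background."""
        consensus = "CACG"
        lom = _log_odds(consensus_to_pfm(consensus), UNIFORM)
        pval, off, sc = score_pvalue_table(lom, UNIFORM)
        max_score = lom.max(axis=1).sum()
        dp_p = pval[int(round((max_score - off) / sc))]
        enum_p = sum(
            0.25 ** len(consensus)
            for w in product(range(4), repeat=len(consensus))
            if lom[np.arange(len(consensus)), list(w)].sum() >= max_score - 1e-9
        )
        assert np.isclose(dp_p, enum_p, rtol=1e-6)


class TestFeatures:
    def test_all_plus_hits_orientation_one(self):
        hits = [MotifHit(0, 100, "+", 5.0, 1e-5), MotifHit(0, 200, "+", 7.0, 1e-6)]
        vec = motif_features(hits, n_motifs=1, promoter_length=1500)
        number, conserve, orientation, dis = vec
        assert number == 2 and orientation == 1.0
        assert conserve == 6.0  # mean score

    def test_absent_motif_is_all_zero(self):
        vec = motif_features([], n_motifs=2, promoter_length=1500)
        assert vec.tolist() == [0.0] * 8

    def test_mean_distance_by_hand(self):
        # hits 100 bp and 300 bp upstream of the TLS -> Dis = 200
        L = 1500
        hits = [
            MotifHit(0, L - 100, "+", 1.0, 1e-5),
            MotifHit(0, L - 300, "-", 1.0, 1e-5),
        ]
        vec = motif_features(hits, n_motifs=1, promoter_length=L)
        assert vec[3] == 200.0
        assert vec[2] == 0.5  # one of two hits on the coding strand

    def test_background_strand_symmetric(self):
        bg = background_from_seqs(["ACGTACGTAAAA"])
        assert np.isclose(bg[0], bg[3]) and np.isclose(bg[1], bg[2])
        assert np.isclose(bg.sum(), 1.0)
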