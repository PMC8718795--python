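"""DNP/TNP composition-property encodings and DACC/TACC covariances."""

import numpy as np
import pytest

from timgo.encoders.properties import (
    ACCParams,
    PropertyTable,
    acc_encode,
    load_dinucleotide_table,
    load_trinucleotide_table,
    property_encode,
)


@pytest.fixture(scope="module")
def di_table():
    return load_dinucleotide_table()


@pytest.fixture(scope="module")
def tri_table():
    return load_trinucleotide_table()


@pytest.fixture()
def tiny_table():
    # 2 properties over dinucleotides, simple integer values
    vals = np.vstack([np.arange(16, dtype=float), np.arange(16, dtype=float)[::-1]])
    return PropertyTable(2, ["p1", "p2"], vals)


SEQ = "ACGTACGTTGCAACGTGGCCAATT" * 5


class TestPropertyEncode:
    def test_bundled_table_dimensions(self, di_table, tri_table):
        assert property_encode(SEQ, di_table).shape == (240,)
        assert property_encode(SEQ, tri_table).shape == (768,)
        assert di_table.n_properties == 15 and tri_table.n_properties == 12

    def test_single_composition_sequence(self, di_table):
        vec = property_encode("AAAA", di_table)
        mat = vec.reshape(15, 16)
        # only the AA column (index 0) is populated, with frequency 1
        assert np.allclose(mat[:, 0], di_table.values[:, 0])
        assert np.allclose(mat[:, 1:], 0.0)

    def test_frequencies_weight_properties(self, tiny_table):
        vec = property_encode("AACC", tiny_table)  # dinucs AA, AC, CC
        mat = vec.reshape(2, 16)
        idx = {"AA": 0, "AC": 1, "CC": 5}
        for d, j in idx.items():
            assert np.isclose(mat[0, j], (1 / 3) * tiny_table.values[0, j])

    def test_table_tsv_roundtrip(self, tmp_path, tiny_table):
        p = tmp_path / "t.tsv"
        with open(p, "w") as fh:
            fh.write("oligo\tp1\tp2\n")
            for j, o in enumerate(tiny_table.oligos):
                fh.write(f"{o}\t{tiny_table.values[0, j]}\t{tiny_table.values[1, j]}\n")
        back = PropertyTable.from_tsv(p)
        np.testing.assert_allclose(back.values, tiny_table.values)

    def test_incomplete_table_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("oligo\tp1\nAA\t1.0\n")
        with pytest.raises(ValueError, match="missing oligos"):
            PropertyTable.from_tsv(p)


class TestACC:
    def test_published_dimensions(self, di_table, tri_table):
        assert acc_encode(SEQ, ACCParams(di_table, 4)).shape == (900,)
        assert acc_encode(SEQ, ACCParams(tri_table, 4)).shape == (576,)

    def test_homopolymer_covariances_vanish(self, di_table):
        vec = acc_encode("A" * 100, ACCParams(di_table, 4))
        assert np.abs(vec).max() < 1e-12

    def test_too_short_sequence_errors(self, di_table):
        with pytest.raises(ValueError, match="lag"):
            acc_encode("ACGT", ACCParams(di_table, 4))

    def test_standardization_invariance(self):
        """Affine rescaling of a property row leaves the encoding unchanged."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(2, 16))
        scaled = np.vstack([3.0 * base[0] + 7.0, base[1]])
        seq = "ACGTTGCATTACGGCA"
        v1 = acc_encode(seq, ACCParams(PropertyTable(2, ["a", "b"], base), 2))
        v2 = acc_encode(seq, ACCParams(PropertyTable(2, ["a", "b"], scaled), 2))
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_matches_naive_loop_oracle(self, tiny_table):
        """Vectorized covariances vs an independent index-by-index loop."""
        seq = "ACGTTGCATT"
        lag = 2
        got = acc_encode(seq, ACCParams(tiny_table, lag))

        std = tiny_table.standardized()
        oligos = std.oligos
        units = [seq[i : i + 2] for i in range(len(seq) - 1)]
        sig = np.array([[std.values[p, oligos.index(u)] for u in units] for p in range(2)])
        W = sig.shape[1]
        means = sig.mean(axis=1)
        expected = []
        for p in range(2):  # auto
            for g in range(1, lag + 1):
                s = sum(
                    (sig[p, i] - means[p]) * (sig[p, i + g] - means[p])
                    for i in range(W - g)
                )
                expected.append(s / (W - g))
        for p1 in range(2):  # cross
            for p2 in range(2):
                if p1 == p2:
                    continue
                for g in range(1, lag + 1):
                    s = sum(
                        (sig[p1, i] - means[p1]) * (sig[p2, i + g] - means[p2])
                        for i in range(W - g)
                    )
                    expected.append(s / (W - g))
        np.testing.assert_allclose(got, expected, atol=1e-12)
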