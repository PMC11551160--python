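"""Encoder unit and property tests, including independent brute-force
oracles for the covariance descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rna5hmc import (
    EncoderConfig,
    RnaSequence,
    canonical_rc_kmers,
    default_dinucleotide_table,
    default_trinucleotide_table,
    encode_dcc,
    encode_kmer,
    encode_pse_dnc,
    encode_pse_tnc,
    encode_rc_kmer,
    encode_sequence,
    encode_tac,
    encode_tcc,
    property_profile,
    reverse_complement,
)
from rna5hmc.encoders import PropertyTable, kmer_words

rna_text = st.text(alphabet="ACGU", min_size=6, max_size=30)

CFG = EncoderConfig()


# ---------------------------------------------------------------- oracles
def brute_force_auto_cov(profile, lag):
    """Direct double-loop mean-centered auto-covariance, 1/(N-lag)."""
    n = len(profile)
    mean = sum(profile) / n
    total = 0.0
    for i in range(n - lag):
        total += (profile[i] - mean) * (profile[i + lag] - mean)
    return total / (n - lag)


def brute_force_cross_cov(p1, p2, lag):
    n = len(p1)
    m1 = sum(p1) / n
    m2 = sum(p2) / n
    total = 0.0
    for i in range(n - lag):
        total += (p1[i] - m1) * (p2[i + lag] - m2)
    return total / (n - lag)


def brute_force_rc_classes(k):
    """Enumerate all 4^k words, merge each with its reverse complement."""
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    classes = set()
    for w in kmer_words(k):
        rc = "".join(comp[c] for c in reversed(w))
        classes.add(min(w, rc))
    return sorted(classes)


# ------------------------------------------------------------ composition
class TestKmer:
    def test_single_word(self):
        fv = encode_kmer(RnaSequence("s", "AAAA"), 2)
        d = dict(zip(fv.names, fv.values))
        assert d["kmer:AA"] == 1.0
        assert sum(v for k, v in d.items() if k != "kmer:AA") == 0.0

    def test_overlapping_windows(self):
        fv = encode_kmer(RnaSequence("s", "ACGU"), 2)
        d = dict(zip(fv.names, fv.values))
        for w in ("AC", "CG", "GU"):
            assert d[f"kmer:{w}"] == pytest.approx(1 / 3)

    def test_default_dimension_and_order(self):
        fv = encode_kmer(RnaSequence("s", "ACGUACGU"), 2)
        assert len(fv) == 16
        assert list(fv.names) == [f"kmer:{w}" for w in kmer_words(2)]

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="length"):
            encode_kmer(RnaSequence("s", "AC"), 3)

    @given(rna_text)
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one_nonnegative(self, text):
        fv = encode_kmer(RnaSequence("s", text), 2)
        assert np.all(fv.values >= 0)
        assert fv.values.sum() == pytest.approx(1.0, abs=1e-12)


class TestReverseComplement:
    def test_palindrome(self):
        assert reverse_complement(RnaSequence("s", "ACGU")).residues == "ACGU"

    def test_complement_rule(self):
        assert reverse_complement(RnaSequence("s", "AAAA")).residues == "UUUU"

    @given(rna_text)
    @settings(max_examples=50, deadline=None)
    def test_involution(self, text):
        s = RnaSequence("s", text)
        assert reverse_complement(reverse_complement(s)) == s


class TestRcKmer:
    @pytest.mark.parametrize("k,expected", [(1, 2), (2, 10), (3, 32)])
    def test_canonical_class_counts(self, k, expected):
        classes = canonical_rc_kmers(k)
        assert len(classes) == expected
        assert classes == brute_force_rc_classes(k)

    def test_k1_classes(self):
        assert canonical_rc_kmers(1) == ["A", "C"]

    def test_single_class(self):
        fv = encode_rc_kmer(RnaSequence("s", "AAAA"), 2)
        d = dict(zip(fv.names, fv.values))
        assert d["rckmer:AA"] == 1.0

    def test_default_dimension(self):
        assert len(encode_rc_kmer(RnaSequence("s", "ACGUGC"), 2)) == 10

    @given(rna_text)
    @settings(max_examples=50, deadline=None)
    def test_rc_invariance(self, text):
        s = RnaSequence("s", text)
        a = encode_rc_kmer(s, 2)
        b = encode_rc_kmer(reverse_complement(s), 2)
        np.testing.assert_allclose(a.values, b.values, atol=1e-15)

    def test_plain_kmer_not_rc_invariant(self):
        s = RnaSequence("s", "AAAACG")
        a = encode_kmer(s, 2)
        b = encode_kmer(reverse_complement(s), 2)
        assert not np.allclose(a.values, b.values)


class TestPseComposition:
    def test_psednc_matches_kmer_values(self):
        s = RnaSequence("s", "ACGUACGUACGUA")
        np.testing.assert_array_equal(
            encode_pse_dnc(s).values, encode_kmer(s, 2).values
        )
        assert len(encode_pse_dnc(s)) == 16

    def test_psetnc_matches_3mer_values(self, rng):
        text = "".join(rng.choice(list("ACGU"), size=41))
        s = RnaSequence("s", text)
        np.testing.assert_array_equal(
            encode_pse_tnc(s).values, encode_kmer(s, 3).values
        )
        assert len(encode_pse_tnc(s)) == 64

    def test_homopolymer_cases(self):
        assert dict(
            zip(*[encode_pse_dnc(RnaSequence("s", "CCCC")).names,
                  encode_pse_dnc(RnaSequence("s", "CCCC")).values])
        )["psednc:CC"] == 1.0
        assert dict(
            zip(*[encode_pse_tnc(RnaSequence("s", "GGGG")).names,
                  encode_pse_tnc(RnaSequence("s", "GGGG")).values])
        )["psetnc:GGG"] == 1.0


# ------------------------------------------------------- property tables
class TestPropertyTables:
    @pytest.mark.parametrize(
        "table", [default_dinucleotide_table(), default_trinucleotide_table()],
        ids=["di", "tri"],
    )
    def test_standardized_zero_mean_unit_sd(self, table):
        words = kmer_words(table.granularity)
        mat = np.array([table.values[w] for w in words])
        np.testing.assert_allclose(mat.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(mat.std(axis=0), 1.0, atol=1e-9)

    def test_property_counts_for_default_dimensions(self):
        assert len(default_dinucleotide_table().property_names) == 6
        assert len(default_trinucleotide_table().property_names) == 2

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            PropertyTable(2, ("p",), {"AA": np.array([1.0])})

    def test_profile_constant_on_homopolymer(self):
        table = default_dinucleotide_table()
        prof = property_profile(RnaSequence("s", "AAAA"), table, "roll")
        assert len(prof) == 3
        assert np.ptp(prof) == 0.0

    def test_profile_length(self):
        s = RnaSequence("s", "ACGU" * 10 + "A")  # 41 nt
        assert len(property_profile(s, default_trinucleotide_table(), "roll")) == 39

    def test_unknown_property_errors(self):
        with pytest.raises(KeyError, match="bogus"):
            property_profile(
                RnaSequence("s", "ACGU"), default_dinucleotide_table(), "bogus"
            )


# ----------------------------------------------------------- covariances
class TestCovarianceEncoders:
    @pytest.mark.parametrize(
        "encoder,expected",
        [(encode_tac, 4), (encode_tcc, 4), (encode_dcc, 60)],
        ids=["tac", "tcc", "dcc"],
    )
    def test_default_dimensions(self, encoder, expected):
        assert len(encoder(RnaSequence("s", "ACGUACGUACGU"), CFG)) == expected

    @pytest.mark.parametrize(
        "encoder", [encode_tac, encode_tcc, encode_dcc], ids=["tac", "tcc", "dcc"]
    )
    def test_vanish_on_homopolymer(self, encoder):
        fv = encoder(RnaSequence("s", "A" * 12), CFG)
        np.testing.assert_allclose(fv.values, 0.0, atol=1e-15)

    def test_tac_matches_brute_force(self, rng):
        table = default_trinucleotide_table()
        for _ in range(100):
            n = int(rng.integers(6, 21))
            s = RnaSequence("s", "".join(rng.choice(list("ACGU"), size=n)))
            fv = encode_tac(s, CFG)
            d = dict(zip(fv.names, fv.values))
            for prop in table.property_names:
                profile = property_profile(s, table, prop).tolist()
                for lag in (1, 2):
                    assert d[f"tac:{prop}@lag{lag}"] == pytest.approx(
                        brute_force_auto_cov(profile, lag), abs=1e-12
                    )

    def test_tcc_matches_brute_force(self, rng):
        table = default_trinucleotide_table()
        for _ in range(100):
            n = int(rng.integers(6, 21))
            s = RnaSequence("s", "".join(rng.choice(list("ACGU"), size=n)))
            fv = encode_tcc(s, CFG)
            d = dict(zip(fv.names, fv.values))
            p = {u: property_profile(s, table, u).tolist() for u in table.property_names}
            for u1 in table.property_names:
                for u2 in table.property_names:
                    if u1 == u2:
                        continue
                    for lag in (1, 2):
                        assert d[f"tcc:{u1}*{u2}@lag{lag}"] == pytest.approx(
                            brute_force_cross_cov(p[u1], p[u2], lag), abs=1e-12
                        )

    def test_dcc_matches_brute_force(self, rng):
        table = default_dinucleotide_table()
        props = table.property_names
        for _ in range(100):
            n = int(rng.integers(5, 21))
            s = RnaSequence("s", "".join(rng.choice(list("ACGU"), size=n)))
            fv = encode_dcc(s, CFG)
            d = dict(zip(fv.names, fv.values))
            p = {u: property_profile(s, table, u).tolist() for u in props}
            # spot-check a fixed subset of ordered pairs to keep this fast
            for u1, u2 in (("shift", "roll"), ("roll", "shift"), ("tilt", "twist")):
                for lag in (1, 2):
                    assert d[f"dcc:{u1}*{u2}@lag{lag}"] == pytest.approx(
                        brute_force_cross_cov(p[u1], p[u2], lag), abs=1e-12
                    )

    def test_cross_cov_order_matters(self, rng):
        s = RnaSequence("s", "ACGGUUACGGCA")
        fv = encode_tcc(s, CFG)
        d = dict(zip(fv.names, fv.values))
        assert d["tcc:roll*twist@lag1"] != pytest.approx(
            d["tcc:twist*roll@lag1"], abs=1e-9
        )

    def test_too_short_errors_name_minimum(self):
        with pytest.raises(ValueError, match="at least 5"):
            encode_tac(RnaSequence("s", "ACGU"), CFG)


# ----------------------------------------------------------------- hybrid
class TestHybridContract:
    def test_total_dimension_174(self):
        s = RnaSequence("s", "ACGUACGUACGUACGU")
        assert len(encode_sequence(s, CFG)) == 174

    def test_blocks_equal_standalone_encoders(self):
        s = RnaSequence("s", "GCAUGGCAUGACGUA")
        hybrid = encode_sequence(s, CFG)
        offset = 0
        for name, encoder in [
            ("kmer", lambda: encode_kmer(s, 2)),
            ("rc_kmer", lambda: encode_rc_kmer(s, 2)),
            ("pse_dnc", lambda: encode_pse_dnc(s)),
            ("pse_tnc", lambda: encode_pse_tnc(s)),
            ("tac", lambda: encode_tac(s, CFG)),
            ("tcc", lambda: encode_tcc(s, CFG)),
            ("dcc", lambda: encode_dcc(s, CFG)),
        ]:
            block = encoder()
            np.testing.assert_array_equal(
                hybrid.values[offset : offset + len(block)], block.values
            )
            offset += len(block)
        assert offset == 174

    def test_purity_bit_identical(self):
        s = RnaSequence("s", "ACGUGGCAUGCCAUG")
        a = encode_sequence(s, CFG)
        b = encode_sequence(s, CFG)
        assert a.names == b.names
        assert np.array_equal(a.values, b.values)
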