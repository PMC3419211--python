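"""Feature computations against hand-derived and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtident.dataset import FEATURE_NAMES
from hgtident.features import (
    build_composition,
    chi2_bias,
    delta_star,
    feature_vector,
    gc_by_position,
    gene_kmer_counts,
    js_divergence,
    karlin_codon_bias,
    kmer_deviation,
)
from hgtident.seqio import GeneRecord, GenomeBundle

from .oracle import (
    oracle_chi2,
    oracle_delta_star,
    oracle_js,
    oracle_kmer_dev,
)


def bundle_of(*seqs: str) -> GenomeBundle:
    return GenomeBundle("test", [GeneRecord(f"g{i}", s) for i, s in enumerate(seqs)])


# a 17-nt linearized de Bruijn sequence containing each dinucleotide once
DEBRUIJN2 = "AACAGATCCGCTGGTTA"


class TestComposition:
    def test_single_gene_symmetrized_counts(self):
        bg = build_composition(bundle_of("ATG"))
        # ATG + revcomp CAT
        np.testing.assert_array_equal(bg.kmer_counts[1], [2, 1, 1, 2])
        np.testing.assert_array_equal(bg.kmer_counts_raw[1], [1, 0, 1, 1])

    def test_duplication_leaves_frequencies(self):
        one = build_composition(bundle_of("ATGACC"))
        two = build_composition(bundle_of("ATGACC", "ATGACC"))
        for k in (1, 2, 3):
            np.testing.assert_allclose(one.kmer_freq(k), two.kmer_freq(k))

    def test_n_excluded_from_counts(self):
        bg = build_composition(bundle_of("ATGNAA"))
        # raw dinucs of ATGNAA: AT, TG, AA (GN and NA dropped)
        raw = bg.kmer_counts_raw[2]
        assert raw.sum() == 3

    def test_debruijn_dinucleotides_are_uniform(self):
        counts = gene_kmer_counts(DEBRUIJN2, 2, symmetrize=False)
        np.testing.assert_array_equal(counts, np.ones(16))


class TestDeltaStar:
    def test_zero_on_self(self):
        b = bundle_of("ATGACCGTA")
        assert delta_star("ATGACCGTA", build_composition(b)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_of_tables(self):
        a, b = "AATTAATTAATT", "ACGTACGTACGT"
        d1 = delta_star(a, build_composition(bundle_of(b)))
        d2 = delta_star(b, build_composition(bundle_of(a)))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_against_brute_force(self):
        gene, bg_seq = "AATT" * 25, "ACGT" * 25
        got = delta_star(gene, build_composition(bundle_of(bg_seq)))
        assert got == pytest.approx(oracle_delta_star(gene, [bg_seq]), abs=1e-12)


class TestKarlinCodonBias:
    def test_zero_on_self(self):
        b = bundle_of("ATGAAAGGG")
        assert karlin_codon_bias("ATGAAAGGG", build_composition(b)) == pytest.approx(0.0)

    def test_two_codon_hand_value(self):
        # gene: Lys = AAA, AAG at 0.5 each; background Lys usage all-AAA
        bg = build_composition(bundle_of("AAAAAA"))
        assert karlin_codon_bias("AAAAAG", bg) == pytest.approx(1.0)

    def test_upper_bound_two(self):
        rng = np.random.default_rng(0)
        bg = build_composition(bundle_of("".join(rng.choice(list("ACGT"), 300))))
        for _ in range(20):
            gene = "".join(rng.choice(list("ACGT"), 90))
            assert karlin_codon_bias(gene, bg) <= 2.0 + 1e-12


class TestGcByPosition:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGGGG", (0.5, 0.5, 1.0)),
            ("ATTATA", (0.0, 0.0, 0.0)),
            ("GCGCGC", (1.0, 1.0, 1.0)),
        ],
    )
    def test_hand_counts(self, seq, expected):
        assert gc_by_position(seq) == pytest.approx(expected)

    def test_frame_violation_is_error(self):
        with pytest.raises(ValueError):
            gc_by_position("ATGA")


class TestChi2:
    def test_zero_on_self(self):
        b = bundle_of("ATGACCGTAACC")
        bg = build_composition(b)
        assert chi2_bias("ATGACCGTAACC", bg, "dinucleotide") == pytest.approx(0.0)
        assert chi2_bias("ATGACCGTAACC", bg, "codon") == pytest.approx(0.0)

    def test_uniform_background_hand_value(self):
        # AAAA has 3 AA dinucleotides; uniform background E_w = 3/16
        bg = build_composition(bundle_of(DEBRUIJN2))
        assert chi2_bias("AAAA", bg, "dinucleotide") == pytest.approx(15.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        gene = "".join(rng.choice(list("ACGT"), 120))
        bg_seq = "".join(rng.choice(list("ACGT"), 600))
        bg = build_composition(bundle_of(bg_seq))
        for unit in ("dinucleotide", "codon"):
            assert chi2_bias(gene, bg, unit) == pytest.approx(
                oracle_chi2(gene, [bg_seq], unit), abs=1e-9
            )

    def test_length_normalization_stable_under_doubling(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 999))
        bg = build_composition(bundle_of("".join(rng.choice(list("ACGT"), 3000))))
        one = chi2_bias(seq, bg, "dinucleotide")
        two = chi2_bias(seq + seq, bg, "dinucleotide")
        assert two == pytest.approx(one, abs=5e-3)  # O(1/n) junction effect


class TestJsDivergence:
    def test_zero_on_self(self):
        bg = build_composition(bundle_of("ATGACCGTAACC"))
        for unit in ("nucleotide", "dinucleotide", "codon"):
            assert js_divergence("ATGACCGTAACC", bg, unit) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_reach_one_bit(self):
        bg = build_composition(bundle_of("TTTTTT"))
        assert js_divergence("AAAAAA", bg, "nucleotide") == pytest.approx(1.0)

    def test_closed_form_point_mass_vs_uniform(self):
        bg = build_composition(bundle_of("ACGT" * 10))
        # P = (1,0,0,0), Q = uniform: JS = H(m) - 0.5*H(Q) with m = (5/8,1/8,1/8,1/8)
        m = np.array([5 / 8, 1 / 8, 1 / 8, 1 / 8])
        expected = -(m * np.log2(m)).sum() - 0.5 * 2.0
        assert js_divergence("A" * 40, bg, "nucleotide") == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        gene = "".join(rng.choice(list("ACGT"), 120))
        bg_seq = "".join(rng.choice(list("ACGT"), 600))
        bg = build_composition(bundle_of(bg_seq))
        for unit in ("nucleotide", "dinucleotide", "codon"):
            assert js_divergence(gene, bg, unit) == pytest.approx(
                oracle_js(gene, [bg_seq], unit), abs=1e-9
            )


class TestKmerDeviation:
    def test_zero_on_self_for_every_k(self):
        seq = "ATGACCGTAACCGGTTAA"
        bg = build_composition(bundle_of(seq))
        for k in range(1, 8):
            assert kmer_deviation(seq, bg, k) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_k1(self):
        bg = build_composition(bundle_of(DEBRUIJN2[:-1]))  # uniform mononucleotides
        # symmetrized AAAA -> (A: .5, T: .5); uniform background -> L1 = 1, /4
        assert kmer_deviation("AAAA", bg, 1) == pytest.approx(0.25)

    def test_symmetry_under_swap(self):
        a, b = "AATTAATTAATT", "ACGGACGGACGG"
        d1 = kmer_deviation(a, build_composition(bundle_of(b)), 2)
        d2 = kmer_deviation(b, build_composition(bundle_of(a)), 2)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_short_gene_is_error(self):
        bg = build_composition(bundle_of("ACGTACGTACGT"))
        with pytest.raises(ValueError, match="7"):
            kmer_deviation("ACGT", bg, 7)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        gene = "".join(rng.choice(list("ACGT"), 120))
        bg_seq = "".join(rng.choice(list("ACGT"), 600))
        bg = build_composition(bundle_of(bg_seq))
        for k in range(1, 8):
            assert kmer_deviation(gene, bg, k) == pytest.approx(
                oracle_kmer_dev(gene, [bg_seq], k), abs=1e-9
            )


class TestFeatureVector:
    def test_shape_order_and_finiteness(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), 150)) for _ in range(20)]
        bg = build_composition(bundle_of(*seqs))
        assert len(FEATURE_NAMES) == 15
        for s in seqs:
            v = feature_vector(s, bg)
            assert v.shape == (15,)
            assert np.all(np.isfinite(v))
            assert np.all(v >= 0)

    def test_self_comparison_all_zero(self):
        seq = "ATGACCGTAACCGGTTAACCA"
        v = feature_vector(seq, build_composition(bundle_of(seq)))
        np.testing.assert_allclose(v, 0.0, atol=1e-12)


DNA = st.text(alphabet="ACGT", min_size=30, max_size=120)


@settings(max_examples=25, deadline=None)
@given(DNA)
def test_divergences_nonnegative_and_zero_on_self(seq):
    """Every divergence-type feature is >= 0 and exactly 0 on self-comparison."""
    seq = seq[: 3 * (len(seq) // 3)]
    bg = build_composition(bundle_of(seq))
    assert delta_star(seq, bg) == pytest.approx(0.0, abs=1e-12)
    assert chi2_bias(seq, bg, "dinucleotide") == pytest.approx(0.0, abs=1e-12)
    for k in (1, 2, 3):
        assert kmer_deviation(seq, bg, k) == pytest.approx(0.0, abs=1e-12)
    for unit in ("nucleotide", "dinucleotide"):
        v = js_divergence(seq, bg, unit)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=15, deadline=None)
@given(DNA, DNA)
def test_features_invariant_to_gene_set_duplication(seq_a, seq_b):
    """Frequency-based features are unchanged when the whole bundle doubles."""
    # truncate in-frame and guarantee at least one sense codon
    seq_a = seq_a[: 3 * (len(seq_a) // 3)] + "GCA"
    seq_b = seq_b[: 3 * (len(seq_b) // 3)] + "GCA"
    bg1 = build_composition(bundle_of(seq_a, seq_b))
    bg2 = build_composition(bundle_of(seq_a, seq_b, seq_a, seq_b))
    np.testing.assert_allclose(feature_vector(seq_a, bg1), feature_vector(seq_a, bg2), atol=1e-9)
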