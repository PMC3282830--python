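"""Compositional statistics: frequencies, RCFV/RCV, class deviations,
skews and codon usage, each checked against independent naive oracles."""
import numpy as np
import pandas as pd
import pytest

from compspectra import (
    Alignment,
    PartitionScheme,
    PROTEIN,
    class_deviations,
    codon_usage,
    rcfv,
    rcv,
    skews,
    state_frequencies,
)
from compspectra.errors import AllMissingError, AlphabetError, ConfigurationError
from conftest import make_random_alignment
from _oracles import codon_counts_sliding, literal_rcfv, tally_frequencies


class TestStateFrequencies:
    def test_direct_count(self):
        a = Alignment(["x", "y"], ["AACG", "TTTT"])
        f = state_frequencies(a, "x")
        assert f.to_dict() == {"A": 0.5, "C": 0.25, "G": 0.25, "T": 0.0}

    def test_uncounted_symbols_excluded(self):
        a = Alignment(["x", "y"], ["A-?N", "ACGT"])
        f = state_frequencies(a, "x")
        assert f["A"] == 1.0 and f.sum() == 1.0

    def test_all_missing_taxon_is_an_error(self):
        a = Alignment(["x", "y"], ["--??", "ACGT"])
        with pytest.raises(AllMissingError):
            state_frequencies(a, "x")

    def test_matches_naive_tally(self, rng):
        for _ in range(20):
            aln = make_random_alignment(rng, 5, 30, gap_frac=0.1, ambig_frac=0.05)
            for t in aln.taxa:
                got = state_frequencies(aln, t).to_dict()
                want = tally_frequencies(aln.sequence(t), aln.alphabet.states)
                assert got == pytest.approx(want, abs=1e-15)

    def test_column_subset(self):
        a = Alignment(["x", "y"], ["ATAT", "CCCC"])
        f = state_frequencies(a, "x", columns=[1, 3])
        assert f["A"] == 1.0


class TestRcfv:
    def test_identical_sequences_give_zero(self):
        a = Alignment(list("abcd"), ["ACGT"] * 4)
        p = rcfv(a)
        assert p.total_rcfv == 0.0
        assert (p.taxon_rcfv == 0).all()

    def test_two_taxon_symmetric_case(self):
        p = rcfv(Alignment(["a", "b"], ["AAAA", "TTTT"]))
        assert p.total_rcfv == pytest.approx(1.0, abs=1e-15)
        assert p.taxon_rcfv.to_dict() == pytest.approx({"a": 0.5, "b": 0.5}, abs=1e-15)
        assert p.mean_frequencies["A"] == pytest.approx(0.5)

    def test_matches_literal_formula(self, rng):
        for _ in range(25):
            aln = make_random_alignment(rng, 5, 40, gap_frac=0.05, missing_frac=0.05)
            p = rcfv(aln)
            total, contrib, mu = literal_rcfv(
                {t: aln.sequence(t) for t in aln.taxa}, aln.alphabet.states
            )
            assert p.total_rcfv == pytest.approx(total, abs=1e-12)
            for t in aln.taxa:
                assert p.taxon_rcfv[t] == pytest.approx(contrib[t], abs=1e-12)

    def test_total_is_sum_of_contributions(self, random_alignment):
        p = rcfv(random_alignment)
        assert p.total_rcfv == sum(p.taxon_rcfv)

    def test_frequencies_sum_to_one(self, random_alignment):
        p = rcfv(random_alignment)
        assert np.allclose(p.frequencies.sum(axis=1), 1.0, atol=1e-12)

    def test_invariant_under_column_permutation_and_duplication(self, rng):
        aln = make_random_alignment(rng, 6, 30)
        p = rcfv(aln)
        perm = rng.permutation(aln.length)
        assert rcfv(aln.take_columns(perm)).total_rcfv == pytest.approx(
            p.total_rcfv, abs=1e-12
        )
        tripled = aln.take_columns(np.tile(np.arange(aln.length), 3))
        assert rcfv(tripled).total_rcfv == pytest.approx(p.total_rcfv, abs=1e-12)

    def test_values_track_taxon_labels_under_reordering(self, rng):
        aln = make_random_alignment(rng, 6, 30)
        p = rcfv(aln)
        shuffled = aln.subset_taxa(list(reversed(aln.taxa)))
        q = rcfv(shuffled)
        for t in aln.taxa:
            assert q.taxon_rcfv[t] == pytest.approx(p.taxon_rcfv[t], abs=1e-12)

    def test_dropping_most_deviant_taxon_reduces_heterogeneity(self, rng):
        for _ in range(10):
            aln = make_random_alignment(rng, 7, 50)
            p = rcfv(aln)
            worst = p.taxon_rcfv.idxmax()
            rest = aln.subset_taxa([t for t in aln.taxa if t != worst])
            assert rcfv(rest).total_rcfv <= p.total_rcfv + 1e-12

    def test_all_missing_taxon_named(self):
        a = Alignment(["good", "bad"], ["ACGT", "----"])
        with pytest.raises(AllMissingError, match="bad"):
            rcfv(a)

    def test_protein_alphabet_supported(self):
        a = Alignment(["x", "y"], ["MKLV", "MKIV"], alphabet=PROTEIN)
        p = rcfv(a)
        assert p.total_rcfv > 0
        assert set(p.frequencies.columns) == set(PROTEIN.states)


class TestRcv:
    def test_identical_sequences_give_zero(self):
        assert rcv(Alignment(list("ab"), ["ACGT", "ACGT"])) == 0.0

    def test_hand_computed_value(self):
        # counts A: (4, 0), T: (0, 4); mean 2 each; sum|dev| = 8; n*Lbar = 8
        assert rcv(Alignment(["a", "b"], ["AAAA", "TTTT"])) == pytest.approx(1.0)

    def test_equals_rcfv_on_gap_free_equal_lengths(self, rng):
        for _ in range(10):
            aln = make_random_alignment(rng, 5, 24)  # no gaps/missing
            assert rcv(aln) == pytest.approx(rcfv(aln).total_rcfv, abs=1e-12)


class TestClassDeviations:
    def test_at_binning_hides_a_t_bias(self):
        table = class_deviations(Alignment(["a", "b"], ["AAAA", "TTTT"]), "AT_GC")
        assert (table["freq_AT"] == 1.0).all()
        assert (table["deviation"] == 0.0).all()

    def test_ry_binning_exposes_purine_bias(self):
        table = class_deviations(Alignment(["a", "b"], ["AAAA", "TTTT"]), "R_Y")
        assert table.loc["a", "freq_R"] == 1.0
        assert table.loc["b", "freq_R"] == 0.0
        assert (table["deviation"] == 0.5).all()

    def test_matches_brute_force_binning(self, rng):
        classes = {"AT_GC": {"AT": "ATW", "GC": "GCS"}, "R_Y": {"R": "AGR", "Y": "CTY"}}
        for scheme, mapping in classes.items():
            aln = make_random_alignment(rng, 5, 60, gap_frac=0.05, ambig_frac=0.06)
            table = class_deviations(aln, scheme)
            names = list(mapping)
            freqs = {}
            for t in aln.taxa:
                seq = aln.sequence(t)
                counts = {
                    name: sum(seq.count(ch) for ch in chars)
                    for name, chars in mapping.items()
                }
                tot = sum(counts.values())
                freqs[t] = {name: counts[name] / tot for name in names}
            mean0 = np.mean([freqs[t][names[0]] for t in aln.taxa])
            for t in aln.taxa:
                assert table.loc[t, f"freq_{names[0]}"] == pytest.approx(
                    freqs[t][names[0]], abs=1e-12
                )
                assert table.loc[t, "deviation"] == pytest.approx(
                    abs(freqs[t][names[0]] - mean0), abs=1e-12
                )

    def test_complementary_pair_closure(self, rng):
        """dev(AT) == dev(GC) per taxon: with two classes any change in one
        is the exact opposite change in the other."""
        aln = make_random_alignment(rng, 6, 50, gap_frac=0.1)
        table = class_deviations(aln, "AT_GC")
        mean_gc = table["freq_GC"].mean()
        assert np.allclose(
            table["deviation"], (table["freq_GC"] - mean_gc).abs(), atol=1e-12
        )


class TestSkews:
    def test_all_a_sequence_boundary_and_undefined(self):
        row = skews(Alignment(["x", "y"], ["AAAA", "ACGT"]), taxon="x")
        assert row["A-T"] == 1.0 and row["A-G"] == 1.0
        assert np.isnan(row["G-C"]) and np.isnan(row["C-T"])

    def test_equal_frequencies_give_zero(self):
        row = skews(Alignment(["x", "y"], ["ACGT", "ACGT"]), taxon="x")
        assert (row == 0.0).all()

    def test_printed_formula_substitution(self):
        # mu_C = 0.3, mu_T = 0.1 -> C-T skew = 0.2/0.4 = 0.5
        seq = "C" * 3 + "T" * 1 + "A" * 3 + "G" * 3
        row = skews(Alignment(["x", "y"], [seq, "ACGT" + "ACGT" * 1 + "AC"]), taxon="x")
        assert row["C-T"] == pytest.approx(0.5, abs=1e-12)

    def test_defined_skews_bounded(self, rng):
        for _ in range(10):
            aln = make_random_alignment(rng, 6, 40, gap_frac=0.1)
            table = skews(aln)
            vals = table.to_numpy()
            finite = vals[~np.isnan(vals)]
            assert ((finite >= -1) & (finite <= 1)).all()

    def test_antisymmetry_under_state_swap(self, rng):
        """Swapping the two states of a pair negates the skew."""
        aln = make_random_alignment(rng, 4, 60)
        swapped = Alignment(
            aln.taxa,
            [aln.sequence(t).translate(str.maketrans("AT", "TA")) for t in aln.taxa],
        )
        assert np.allclose(
            skews(aln)["A-T"], -skews(swapped)["A-T"], atol=1e-12
        )

    def test_undefined_is_nan_not_zero(self):
        row = skews(Alignment(["x", "y"], ["AAGG", "AAGG"]), taxon="x")
        assert np.isnan(row["C-T"])
        assert row["A-G"] == 0.0  # a real balanced value stays 0

    def test_protein_alphabet_rejected(self):
        a = Alignment(["x", "y"], ["MK", "MV"], alphabet=PROTEIN)
        with pytest.raises(AlphabetError):
            skews(a)


class TestCodonUsage:
    def _scheme(self, length, frame=1):
        return PartitionScheme.from_ranges({"g": [(1, length)]}, frames={"g": frame})

    def test_simple_count(self):
        a = Alignment(["x", "y"], ["ATGATG", "ATGCCC"])
        table = codon_usage(a, self._scheme(6))
        assert table.loc["x", "ATG"] == 2
        assert table.loc["y", "CCC"] == 1

    def test_trailing_partial_codon_dropped_with_warning(self):
        a = Alignment(["x", "y"], ["ATGA", "ATGC"])
        with pytest.warns(UserWarning, match="partial codon"):
            table = codon_usage(a, self._scheme(4))
        assert table.loc["x", "ATG"] == 1
        assert table.loc["x"].sum() == 1

    def test_frame_offsets_skip_leading_columns(self):
        a = Alignment(["x", "y"], ["AATGATG", "AATGATG"])
        table = codon_usage(a, self._scheme(7, frame=3))
        # frame 3: first column is codon position 3; codons start at column 2
        assert table.loc["x", "ATG"] == 2
        assert table.loc["x"].sum() == 2

    def test_ambiguous_codons_skipped(self):
        a = Alignment(["x", "y"], ["ATGN-GATG", "ATGATGATG"])
        table = codon_usage(a, self._scheme(9))
        assert table.loc["x"].sum() == 2  # middle codon contains N and -

    def test_missing_frame_is_a_configuration_error(self):
        a = Alignment(["x", "y"], ["ATGATG", "ATGATG"])
        with pytest.raises(ConfigurationError):
            codon_usage(a, PartitionScheme.from_ranges({"g": [(1, 6)]}))

    def test_matches_sliding_window_oracle(self, rng):
        for frame in (1, 2, 3):
            aln = make_random_alignment(rng, 4, 31, gap_frac=0.05, ambig_frac=0.05)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = codon_usage(aln, self._scheme(31, frame))
            for t in aln.taxa:
                want = codon_counts_sliding(aln.sequence(t), frame)
                got = {c: int(v) for c, v in table.loc[t].items() if v}
                assert got == dict(want)
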