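"""Tests for the codon-preserving permutation under-representation test."""
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bivirome import motifs as mo
from bivirome._codons import CODON_TO_AA, SENSE_CODONS, translate
from bivirome.motifs import MotifSpec
from bivirome.simulate import gen_cds, gen_depleted_cds

codon_lists = st.lists(st.sampled_from(SENSE_CODONS), min_size=2, max_size=120)


class TestStripAndValidate:
    def test_terminal_stop_removed(self):
        assert mo.strip_and_validate_cds("ATGAAATAA") == ["ATG", "AAA"]
        assert mo.strip_and_validate_cds("ATGTGA") == ["ATG"]

    def test_no_stop_accepted(self):
        assert mo.strip_and_validate_cds("ATGAAA") == ["ATG", "AAA"]

    def test_errors(self):
        with pytest.raises(ValueError):
            mo.strip_and_validate_cds("ATGAA")  # non-triplet
        with pytest.raises(ValueError):
            mo.strip_and_validate_cds("ATGTAAAAATAA")  # internal stop


class TestShuffle:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(codon_lists, st.integers(0, 2**31 - 1))
    def test_invariants(self, codons, seed):
        """Translation, length, and the per-base multiset are preserved."""
        out = mo.shuffle_third_positions(codons, seed=seed)
        assert len(out) == len(codons)
        assert translate("".join(out)) == translate("".join(codons))
        assert sorted("".join(out)) == sorted("".join(codons))

    def test_two_codon_lysine_box_reaches_both_orders(self):
        seen = {tuple(mo.shuffle_third_positions(["AAA", "AAG"], seed=s))
                for s in range(40)}
        assert seen == {("AAA", "AAG"), ("AAG", "AAA")}

    def test_singleton_groups_are_fixed(self):
        codons = ["ATG", "TGG", "ATG"]  # Met/Trp: unique codons
        for s in range(5):
            assert mo.shuffle_third_positions(codons, seed=s) == codons

    def test_split_box_ile_met_not_mixed(self):
        """ATA (Ile) and ATG (Met) share a prefix but must not exchange."""
        codons = ["ATA", "ATG"] * 5
        for s in range(10):
            out = mo.shuffle_third_positions(codons, seed=s)
            assert out == codons  # within-group thirds are identical anyway
            assert translate("".join(out)) == translate("".join(codons))

    def test_seed_reproducible(self):
        codons = mo.strip_and_validate_cds(gen_cds(100, seed=5))
        assert mo.shuffle_third_positions(codons, seed=9) == \
            mo.shuffle_third_positions(codons, seed=9)


class TestCountMotif:
    def test_hand_counts(self):
        assert mo.count_motif("AATAA", "AA") == 2
        assert mo.count_motif("AATAA", "TA") == 1
        assert mo.count_motif("AATAA", "WA") == 3
        assert mo.count_motif("", "TA") == 0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=300),
           st.sampled_from(["WA", "AA", "CA", "GA", "TA"]))
    def test_matches_regex_oracle(self, seq, motif):
        first = "[AT]" if motif == "WA" else motif[0]
        expected = len(re.findall(f"(?=({first}A))", seq))
        assert mo.count_motif(seq, motif) == expected

    def test_spec_helpers(self):
        spec = MotifSpec.from_string("WA")
        assert spec.degenerate and spec.first_bases == {"A", "T"}
        with pytest.raises(ValueError):
            MotifSpec.from_string("GG")


class TestRepTrFrac:
    def test_hand_checked_lysine_case(self):
        """ATGAAA: A->G at codon-2 position 2 is Lys->Arg (nonsyn), at
        position 3 Lys->Lys (syn) => 1/2."""
        codons = mo.strip_and_validate_cds("ATGAAA")
        assert mo.reptrfrac(codons, "AA") == pytest.approx(0.5)

    def test_undefined_without_occurrences(self):
        assert mo.reptrfrac(["ATG", "CGG"], "TA") is None

    def test_fourfold_third_positions_all_synonymous(self):
        # GGA/CGA: A at a fourfold third position; GA occurrences only there
        assert mo.reptrfrac(["GGG", "GGA"], "GA") == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(codon_lists, st.sampled_from(["WA", "AA", "CA", "GA", "TA"]))
    def test_matches_scalar_oracle(self, codons, motif):
        """Vectorized repTrFrac equals a per-occurrence string recomputation."""
        seq = "".join(codons)
        spec = MotifSpec.from_string(motif)
        occ = [i for i in range(len(seq) - 1)
               if seq[i] in spec.first_bases and seq[i + 1] == "A"]
        got = mo.reptrfrac(codons, motif)
        if not occ:
            assert got is None
            return
        changed = 0
        for i in occ:
            p = i + 1
            cs = p - p % 3
            codon = seq[cs:cs + 3]
            mut = codon[:p % 3] + "G" + codon[p % 3 + 1:]
            changed += CODON_TO_AA[mut] != CODON_TO_AA[codon]
        assert got == pytest.approx(changed / len(occ))


class TestCdurTest:
    def test_deterministic_given_seed(self):
        seq = gen_cds(150, seed=8)
        a = mo.cdur_test(seq, "TA", n_shuffles=100, seed=3)
        b = mo.cdur_test(seq, "TA", n_shuffles=100, seed=3)
        assert (a.below_p, a.reptrfrac_p) == (b.below_p, b.reptrfrac_p)

    def test_classification_rule(self):
        assert mo._classify(0.03) == "under"
        assert mo._classify(0.97) == "over"
        assert mo._classify(0.5) == "neutral"
        assert mo._classify(None) == "neutral"

    def test_maximal_flag(self):
        r = mo.cdur_test(gen_depleted_cds(400, "TA", 1.0, seed=2), "TA",
                         n_shuffles=300, seed=4)
        assert r.below_class == "under"
        assert r.maximal == (r.below_class == "under"
                             and r.reptrfrac_class == "over")

    def test_degenerate_single_codon_amino_acids(self):
        """Met/Trp-only CDS: every shuffle is identical, so the strict-less
        below count is zero."""
        r = mo.cdur_test("ATG" + "TGG" * 10 + "ATG" * 5 + "TAA", "GA",
                         n_shuffles=50, seed=1)
        assert r.below_p == 0.0

    def test_depletion_detected(self):
        r = mo.cdur_test(gen_depleted_cds(500, "TA", 1.0, seed=11), "TA",
                         n_shuffles=300, seed=12)
        assert r.below_p < 0.05

    def test_midrank_bounds_strict_p(self):
        seq = gen_cds(80, seed=13)
        strict = mo.cdur_test(seq, "TA", n_shuffles=200, seed=14)
        mid = mo.cdur_test(seq, "TA", n_shuffles=200, seed=14, midrank=True)
        assert mid.below_p >= strict.below_p


class TestAggregate:
    def _report(self, orf_id, below_p, rtf_p):
        return mo.MotifReport(orf_id, "TA", 10, 0.5, 100, below_p, rtf_p,
                              mo._classify(below_p), mo._classify(rtf_p),
                              mo._classify(below_p) == "under"
                              and mo._classify(rtf_p) == "over")

    def test_percentages(self):
        reports = [self._report(f"o{i}", 0.01 if i < 4 else 0.5, 0.5)
                   for i in range(10)]
        groups = {f"o{i}": "inv" for i in range(10)}
        out = mo.aggregate_by_group(reports, groups)
        assert out.loc[0, "pct_under"] == pytest.approx(40.0)

    def test_empty_label_is_zero_row(self):
        reports = [self._report("o1", 0.01, 0.99)]
        groups = {"o1": "a", "o2": "b"}
        out = mo.aggregate_by_group(reports, groups)
        row_b = out[out.label == "b"].iloc[0]
        assert row_b.n == 0 and row_b.pct_under == 0.0

    def test_unlabeled_rejected(self):
        with pytest.raises(ValueError):
            mo.aggregate_by_group([self._report("o1", 0.5, 0.5)], {})

    def test_depleted_cohort_contrast(self):
        """TA-depleted sequences show a higher under-percentage than null."""
        reports, groups = [], {}
        for i in range(12):
            rid = f"d{i}"
            reports.append(mo.cdur_test(
                gen_depleted_cds(300, "TA", 1.0, seed=200 + i), "TA",
                n_shuffles=200, seed=i, orf_id=rid))
            groups[rid] = "depleted"
        for i in range(12):
            rid = f"n{i}"
            reports.append(mo.cdur_test(gen_cds(300, seed=300 + i), "TA",
                                        n_shuffles=200, seed=50 + i,
                                        orf_id=rid))
            groups[rid] = "null"
        out = mo.aggregate_by_group(reports, groups).set_index("label")
        assert out.loc["depleted", "pct_under"] > out.loc["null", "pct_under"]
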