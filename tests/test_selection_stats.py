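import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from evorate.selection_stats import (STOP_CODONS, classify_substitution,
                                     count_gene_polymorphisms, dnds_ng86,
                                     four_gamete_screen, is_stop, pnps,
                                     translate_codon, _site_tables,
                                     _CODON_INDEX)

SENSE_CODONS = sorted(set(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
) - STOP_CODONS)

sense_codon = st.sampled_from(SENSE_CODONS)


class TestTranslateCodon:
    @pytest.mark.parametrize("codon,aa", [
        ("ATG", "M"), ("TAA", "*"), ("TTT", "F"), ("TGG", "W"),
        ("TGA", "*"), ("TAG", "*"),
    ])
    def test_code_table(self, codon, aa):
        assert translate_codon(codon) == aa

    @pytest.mark.parametrize("codon", ["AT", "ATGA", "ANA", "AT-"])
    def test_illegal_input(self, codon):
        with pytest.raises(ValueError):
            translate_codon(codon)


class TestClassifySubstitution:
    @pytest.mark.parametrize("a,b,n,s", [
        ("TTT", "TTC", 0.0, 1.0),   # Phe -> Phe
        ("ATG", "ATA", 1.0, 0.0),   # Met -> Ile
        ("TTT", "GTA", 1.5, 0.5),   # average of the two 2-step pathways
        ("AAA", "AAA", 0.0, 0.0),
    ])
    def test_examples(self, a, b, n, s):
        result = classify_substitution(a, b)
        assert result.n_frac == pytest.approx(n)
        assert result.s_frac == pytest.approx(s)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("TAA", "TTT")

    @given(sense_codon, sense_codon)
    def test_symmetric(self, a, b):
        fwd = classify_substitution(a, b)
        rev = classify_substitution(b, a)
        assert fwd.n_frac == pytest.approx(rev.n_frac)
        assert fwd.s_frac == pytest.approx(rev.s_frac)

    @given(sense_codon, sense_codon)
    def test_fractions_bounded_by_hamming_distance(self, a, b):
        dist = sum(x != y for x, y in zip(a, b))
        result = classify_substitution(a, b)
        assert result.n_frac + result.s_frac == pytest.approx(dist)


class TestCountGenePolymorphisms:
    def test_identical_rows_unusable(self, make_alignment):
        est = count_gene_polymorphisms(make_alignment(["ATGTTT", "ATGTTT"]))
        assert (est.n_count, est.s_count) == (0.0, 0.0)
        assert not est.usable

    def test_single_synonymous_snp(self, make_alignment):
        est = count_gene_polymorphisms(make_alignment(["ATGTTT", "ATGTTC"]))
        assert est.n_count == 0.0
        assert est.s_count == 1.0
        assert est.ratio == 0.0
        assert est.usable and not est.s_corrected

    def test_majority_base_allele_counting(self, make_alignment):
        est = count_gene_polymorphisms(
            make_alignment(["TTT", "TTT", "TTA"]))
        assert est.n_count == 1.0
        assert est.s_count == 0.0

    def test_majority_tie_uses_reference_codon(self, make_alignment):
        # 2-2 tie: base is the reference row's codon (TTA); the single
        # distinct variant TTT is Leu->Phe, nonsynonymous
        est = count_gene_polymorphisms(
            make_alignment(["TTA", "TTA", "TTT", "TTT"]))
        assert (est.n_count, est.s_count) == (1.0, 0.0)

    def test_gap_and_stop_columns_excluded(self, make_alignment):
        est = count_gene_polymorphisms(
            make_alignment(["ATG---TAATTC", "ATGAAATACTTT"]))
        # codon 2 has gaps, codon 3 contains stop TAA; only 1 and 4 retained
        assert est.n_codons_used == 2
        assert est.s_count == 1.0

    def test_zero_retained_columns(self, make_alignment):
        est = count_gene_polymorphisms(make_alignment(["NNN", "AAA"]))
        assert not est.usable
        assert est.n_codons_used == 0

    def test_duplicating_a_row_changes_nothing(self, make_alignment,
                                               small_study):
        for aln in small_study.alignments[:10]:
            base = count_gene_polymorphisms(aln)
            doubled = make_alignment(aln.rows + [aln.rows[-1]],
                                     gene_id=aln.gene_id)
            dup = count_gene_polymorphisms(doubled)
            assert dup.n_count == pytest.approx(base.n_count)
            assert dup.s_count == pytest.approx(base.s_count)


class TestPnps:
    @pytest.mark.parametrize("n,s,ratio,corrected", [
        (3, 0, 3.0, True), (0, 5, 0.0, False), (2, 4, 0.5, False),
    ])
    def test_examples(self, n, s, ratio, corrected):
        assert pnps(n, s) == (ratio, corrected)

    def test_negative_input(self):
        with pytest.raises(ValueError):
            pnps(-1, 2)

    @given(st.floats(0, 100),
           st.one_of(st.just(0.0), st.floats(1e-6, 100)))
    def test_corrected_iff_zero_synonymous(self, n, s):
        ratio, corrected = pnps(n, s)
        assert corrected == (s == 0)
        assert math.isfinite(ratio)


class TestDndsNg86:
    def test_identical_rows_unusable(self, make_alignment):
        est = dnds_ng86(make_alignment(["ATGTTT", "ATGTTT"]))
        assert not est.usable
        assert est.ratio == 0.0

    def test_ttt_synonymous_site_count(self):
        _, s_sites = _site_tables()
        assert s_sites[_CODON_INDEX["TTT"]] == pytest.approx(1 / 3)

    def test_site_counts_sum_to_three_per_codon(self):
        n_sites, s_sites = _site_tables()
        for codon in SENSE_CODONS:
            idx = _CODON_INDEX[codon]
            assert n_sites[idx] + s_sites[idx] == pytest.approx(3.0)

    def test_requires_two_rows(self, make_alignment):
        with pytest.raises(ValueError):
            dnds_ng86(make_alignment(["AAA", "AAA", "AAA"]))

    def test_only_synonymous_differences_give_zero(self, make_alignment):
        # enough invariant codons that the synonymous proportion stays
        # well below the saturation bound
        est = dnds_ng86(make_alignment(["AAGGGA" + "AAAGGG" * 4,
                                        "AAAGGG" + "AAAGGG" * 4]))
        assert est.ratio == 0.0
        assert est.usable

    def test_only_nonsynonymous_differences_flagged(self, make_alignment):
        est = dnds_ng86(make_alignment(["AAATTT", "GAATTT"]))
        assert est.s_corrected
        assert est.ratio > 0

    def test_monotone_in_nonsynonymous_fraction(self, make_alignment):
        # 40 codons AAA; k nonsyn (AAA->GAA) and 8-k syn (AAA->AAG) diffs;
        # k=8 is excluded because dS=0 switches to the fallback rule
        ratios = []
        for k in range(0, 8):
            row_b = ["GAA"] * k + ["AAG"] * (8 - k) + ["AAA"] * 32
            est = dnds_ng86(make_alignment(["AAA" * 40, "".join(row_b)]))
            assert est.usable
            ratios.append(est.ratio)
        assert all(b > a for a, b in zip(ratios[:-1], ratios[1:]))


class TestFourGameteScreen:
    def test_two_rows_trivial(self, make_alignment):
        assert four_gamete_screen(
            make_alignment(["ATGAAA", "ATGAAC"])) == (0, False)

    def test_canonical_violation(self, make_alignment):
        rows = ["AAAACA", "AAAAGA", "GAAACA", "GAAAGA"]
        count, flagged = four_gamete_screen(make_alignment(rows))
        assert count == 1 and flagged

    def test_tree_compatible_mutations_clean(self, make_alignment):
        # mutations accumulated along a single lineage chain are always
        # compatible with a tree: no pair shows four gametes
        ancestor = list("ATGAAACCCGGGTTCAAA")
        rows = ["".join(ancestor)]
        for site, base in [(3, "G"), (7, "T"), (12, "A"), (16, "G"),
                           (4, "C")]:
            ancestor[site] = base
            rows.append("".join(ancestor))
        count, flagged = four_gamete_screen(make_alignment(rows))
        assert (count, flagged) == (0, False)
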