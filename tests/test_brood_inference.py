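"""Maternal-subtraction inference: worked cases, oracle equivalence, recovery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pgekit.brood_inference import (
    infer_brood,
    infer_locus,
    mean_alleles,
    summarize_family,
)
from pgekit.synthetic_data import BroodSimConfig, simulate_brood

from conftest import brute_force_paternal, make_brood


def one_locus_brood(mother_pair, offspring_pairs):
    return make_brood({"L1": mother_pair}, [{"L1": g} for g in offspring_pairs])


class TestInferLocus:
    def test_homozygous_mother_forces_subtraction(self):
        brood = one_locus_brood(("A", "A"), [("A", "B")] * 10)
        inf = infer_locus(brood, "L1")
        assert inf.maternal_transmitted == {"A"}
        assert inf.paternal_alleles == {"B"}
        assert inf.paternal_count == 1 and inf.maternal_count == 1
        assert not inf.shadowed

    def test_heterozygous_mother_single_father(self):
        brood = one_locus_brood(("A", "B"), [("A", "C")] * 5 + [("B", "C")] * 5)
        inf = infer_locus(brood, "L1")
        assert inf.maternal_transmitted == {"A", "B"}
        assert inf.paternal_alleles == {"C"}
        # the independent solver confirms {C} is the unique minimum
        oracle, _ = brute_force_paternal({"A", "B"}, [("A", "C")] * 5 + [("B", "C")] * 5)
        assert oracle == {"C"}

    def test_shadowed_paternal_allele(self):
        genotypes = [("A", "A")] * 5 + [("A", "B")] * 5
        brood = one_locus_brood(("A", "B"), genotypes)
        inf = infer_locus(brood, "L1")
        assert inf.paternal_alleles == {"A"}
        assert inf.shadowed == {"A"}
        assert inf.paternal_count == 1
        assert brute_force_paternal({"A", "B"}, genotypes)[0] == {"A"}

    def test_two_paternal_alleles_required(self):
        genotypes = [("A", "B")] * 6 + [("A", "C")] * 6
        brood = one_locus_brood(("A", "A"), genotypes)
        inf = infer_locus(brood, "L1")
        assert inf.paternal_alleles == {"B", "C"}
        assert inf.paternal_count == 2
        assert brute_force_paternal({"A", "A"}, genotypes)[0] == {"B", "C"}

    def test_incompatible_offspring_flagged_and_excluded(self):
        brood = one_locus_brood(("A", "A"), [("A", "B")] * 9 + [("C", "D")])
        inf = infer_locus(brood, "L1")
        assert inf.incompatible_offspring == ("F1_O10",)
        assert inf.n_informative == 9
        assert inf.paternal_alleles == {"B"}
        assert inf.status == "ok"

    def test_too_many_incompatible_marks_uncertain(self):
        brood = one_locus_brood(("A", "A"), [("A", "B")] * 6 + [("C", "D")] * 4)
        assert infer_locus(brood, "L1").status == "uncertain"

    def test_weakly_supported_second_allele_marks_uncertain(self):
        # one aberrant offspring demands a second paternal allele: suspicious
        brood = one_locus_brood(("A", "A"), [("A", "B")] * 19 + [("A", "C")])
        inf = infer_locus(brood, "L1")
        assert inf.paternal_alleles == {"B", "C"}
        assert inf.status == "uncertain"
        assert infer_locus(brood, "L1", min_allele_support=1).status == "ok"

    def test_missing_mother_skips_locus(self):
        brood = make_brood({"L1": None}, [{"L1": ("A", "B")}])
        assert infer_locus(brood, "L1").status == "mother_missing"


@st.composite
def random_brood_case(draw):
    alleles = ["A", "B", "C", "D", "E"]
    n_alleles = draw(st.integers(2, 5))
    pool = alleles[:n_alleles]
    mother = (draw(st.sampled_from(pool)), draw(st.sampled_from(pool)))
    n_off = draw(st.integers(1, 8))
    offspring = [
        (draw(st.sampled_from(pool)), draw(st.sampled_from(pool)))
        for _ in range(n_off)
    ]
    return mother, offspring


@given(random_brood_case())
def test_oracle_equivalence_on_random_broods(case):
    """The subset search agrees with exhaustive enumeration, set and count."""
    mother, offspring = case
    brood = one_locus_brood(mother, offspring)
    inf = infer_locus(brood, "L1", min_allele_support=1)
    expected, expected_bad = brute_force_paternal(set(mother), offspring)
    assert inf.paternal_alleles == expected
    assert len(inf.incompatible_offspring) == len(expected_bad)
    # the support guard may change status but never the inferred set
    assert infer_locus(brood, "L1").paternal_alleles == expected


@given(random_brood_case())
def test_minimality_of_paternal_set(case):
    """No proper subset of the inferred paternal set explains the brood."""
    mother, offspring = case
    brood = one_locus_brood(mother, offspring)
    inf = infer_locus(brood, "L1", min_allele_support=1)
    M = set(mother)
    compat = [g for g in offspring if set(g) & M]
    if not compat:
        return
    for a in inf.paternal_alleles:
        reduced = inf.paternal_alleles - {a}
        assert not all(
            (x in M and y in reduced) or (y in M and x in reduced)
            for x, y in compat
        )


@given(random_brood_case(), st.tuples(st.sampled_from("ABCDE"), st.sampled_from("ABCDE")))
def test_adding_offspring_never_shrinks_paternal_set(case, extra):
    mother, offspring = case
    before = infer_locus(one_locus_brood(mother, offspring), "L1", min_allele_support=1)
    after = infer_locus(one_locus_brood(mother, offspring + [extra]), "L1",
                        min_allele_support=1)
    assert len(after.paternal_alleles) >= len(before.paternal_alleles)


class TestSummaries:
    def test_all_single_allele_loci(self):
        brood = make_brood(
            {f"L{i}": ("A", "A") for i in range(1, 9)},
            [{f"L{i}": ("A", "B") for i in range(1, 9)}] * 4,
        )
        s = summarize_family(brood)
        assert (s.paternal.n_loci_1_allele, s.paternal.n_loci_2_alleles,
                s.paternal.n_loci_uncertain) == (8, 0, 0)

    def test_tallies_sum_to_locus_count(self):
        broods, _ = simulate_brood(BroodSimConfig(n_families=4), seed=9)
        for brood in broods:
            s = summarize_family(brood)
            assert s.maternal.total == len(brood.loci)
            assert s.paternal.total == len(brood.loci)

    def test_pge_families_have_no_two_allele_paternal_loci(self):
        cfg = BroodSimConfig(n_families=20, error_miscall=0, error_dropout=0)
        broods, _ = simulate_brood(cfg, seed=5)
        for brood in broods:
            assert summarize_family(brood).paternal.n_loci_2_alleles == 0

    def test_mendelian_heterozygous_father_detected(self):
        """Fully informative loci show 2 paternal alleles at rate 1 - 2^(1-n)."""
        n, n_fam = 6, 400
        cfg = BroodSimConfig(
            n_families=n_fam, brood_size=n, n_loci=2, transmission="Mendelian",
            error_miscall=0, error_dropout=0,
            fixed_mother_genotype=(("100", "100"), ("100", "100")),
            fixed_father_genotypes=(((("102", "104")), ("102", "104")),),
        )
        broods, _ = simulate_brood(cfg, seed=17)
        counts = [
            inf.paternal_count
            for b in broods
            for inf in infer_brood(b, min_allele_support=1)
        ]
        frac2 = np.mean([c == 2 for c in counts])
        expected = 1 - 2 ** (1 - n)
        se = np.sqrt(expected * (1 - expected) / len(counts))
        assert abs(frac2 - expected) < 3 * se + 1e-12


class TestMeanAlleles:
    def test_half_and_half_gives_1_5(self):
        from pgekit.brood_inference import InheritanceSummary, ParentTally

        s = InheritanceSummary("F1", "sp", ParentTally(4, 4, 0), ParentTally(4, 4, 0))
        assert mean_alleles([s], "sp", "paternal") == pytest.approx(1.5)
        assert mean_alleles([s], "sp", "maternal", method="pooled") == pytest.approx(1.5)

    def test_pge_fixed_point_is_one(self):
        from pgekit.brood_inference import InheritanceSummary, ParentTally

        s = [InheritanceSummary(f"F{i}", "sp", ParentTally(9, 0, 0), ParentTally(9, 0, 0))
             for i in range(3)]
        assert mean_alleles(s, "sp", "paternal") == 1.0

    def test_unknown_species_raises(self):
        from pgekit.brood_inference import InheritanceSummary, ParentTally

        s = InheritanceSummary("F1", "sp", ParentTally(4, 4, 0), ParentTally(4, 4, 0))
        with pytest.raises(ValueError):
            mean_alleles([s], "other", "paternal")
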