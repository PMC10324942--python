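"""Haplotype tables, the multiple-paternity chi-square, and the binomial GLMM."""

import numpy as np
import pytest
from scipy import stats

from pgekit.brood_inference import InheritanceSummary, ParentTally, infer_brood
from pgekit.synthetic_data import BroodSimConfig, simulate_brood
from pgekit.transmission_tests import (
    VERDICT_INCONCLUSIVE,
    VERDICT_MULTIPLE_PGE,
    VERDICT_SINGLE_NONPGE,
    HaplotypeTable,
    NotTestableError,
    build_haplotype_table,
    fit_parent_origin_model,
    single_father_chi2,
)

from conftest import make_brood


def two_locus_table(counts, family="F1"):
    """HaplotypeTable over father alleles {A,a} x {B,b} from a count mapping."""
    cells = [("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")]
    combo = {c: counts.get("".join(c), 0) for c in cells}
    return HaplotypeTable(
        family_id=family,
        loci=("L1", "L2"),
        locus_alleles={"L1": ("A", "a"), "L2": ("B", "b")},
        combo_counts=combo,
        n_complete=sum(combo.values()),
        n_excluded_ambiguous=0,
        n_excluded_missing=0,
    )


class TestBuildHaplotypeTable:
    def make_two_locus_brood(self, offspring_paternal):
        """Mother M/M at both loci; paternal alleles directly observable."""
        return make_brood(
            {"L1": ("M", "M"), "L2": ("M", "M")},
            [{"L1": ("M", p1), "L2": ("M", p2)} for p1, p2 in offspring_paternal],
        )

    def test_direct_tabulation(self):
        brood = self.make_two_locus_brood([("A", "B")] * 10 + [("a", "b")] * 10)
        table = build_haplotype_table(brood, infer_brood(brood))
        assert table.n_complete == 20
        assert table.combo_counts[("A", "B")] == 10
        assert table.combo_counts[("a", "b")] == 10
        assert table.combo_counts[("A", "b")] == 0
        assert table.combo_counts[("a", "B")] == 0

    def test_offspring_missing_a_locus_excluded(self):
        brood = make_brood(
            {"L1": ("M", "M"), "L2": ("M", "M")},
            [{"L1": ("M", "A"), "L2": ("M", "B")} for _ in range(5)]
            + [{"L1": ("M", "a"), "L2": ("M", "b")} for _ in range(5)]
            + [{"L1": ("M", "A"), "L2": None}],
        )
        table = build_haplotype_table(brood, infer_brood(brood))
        assert table.n_complete == 10
        assert table.n_excluded_missing == 1

    def test_fewer_than_two_loci_not_testable(self):
        brood = self.make_two_locus_brood([("A", "B")] * 20)
        with pytest.raises(NotTestableError, match="not testable"):
            build_haplotype_table(brood, infer_brood(brood))

    def test_two_father_pge_brood_shows_only_true_haplotypes(self):
        cfg = BroodSimConfig(
            n_families=10, n_loci=2, n_fathers=2, error_miscall=0, error_dropout=0,
            fixed_mother_genotype=(("100", "100"), ("100", "100")),
            fixed_father_genotypes=(
                (("102", "102"), ("104", "104")),
                (("106", "106"), ("108", "108")),
            ),
        )
        broods, truth = simulate_brood(cfg, seed=21)
        for brood, fam in zip(broods, truth.families):
            table = build_haplotype_table(brood, infer_brood(brood))
            observed = {c for c, n in table.combo_counts.items() if n > 0}
            true_haps = {tuple(h) for h in fam.transmitted_haplotypes}
            assert observed <= true_haps


class TestSingleFatherChi2:
    def test_worked_example_two_haplotypes(self):
        """Counts 10/0/0/10 against uniform 5: chi2 = 20, df 3, p ~ 1.7e-4."""
        res = single_father_chi2(two_locus_table({"AB": 10, "ab": 10}), alpha=0.01)
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 3
        assert res.p_value == pytest.approx(stats.chi2.sf(20, 3))
        assert res.p_value == pytest.approx(1.7e-4, rel=0.05)
        assert res.verdict == VERDICT_MULTIPLE_PGE

    def test_uniform_counts_do_not_reject(self):
        res = single_father_chi2(two_locus_table({"AB": 5, "Ab": 5, "aB": 5, "ab": 5}))
        assert res.chi2 == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.verdict == VERDICT_SINGLE_NONPGE

    def test_low_frequency_third_combo_attributed_to_error(self):
        """9/9/2/0: chi2 = 13.2, the rare combination is flagged, verdict multiple."""
        res = single_father_chi2(two_locus_table({"AB": 9, "ab": 9, "aB": 2}), alpha=0.01)
        assert res.chi2 == pytest.approx(13.2)
        assert res.p_value == pytest.approx(4.2e-3, rel=0.05)
        assert ("a", "B") in res.low_freq_combos
        assert res.n_combos_observed == 3
        assert res.verdict == VERDICT_MULTIPLE_PGE

    def test_small_brood_inconclusive(self):
        res = single_father_chi2(two_locus_table({"AB": 2, "ab": 2}), min_brood=5)
        assert res.verdict == VERDICT_INCONCLUSIVE
        assert res.p_exact is not None  # expected cells 1 < 5 triggers Monte Carlo

    def test_chi2_matches_direct_evaluation(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            counts = rng.integers(0, 15, size=4)
            if counts.sum() == 0:
                continue
            names = ["AB", "Ab", "aB", "ab"]
            res = single_father_chi2(two_locus_table(dict(zip(names, counts))))
            e = counts.sum() / 4
            assert res.chi2 == pytest.approx(((counts - e) ** 2 / e).sum())

    def test_monte_carlo_p_close_to_asymptotic_for_moderate_n(self):
        res = single_father_chi2(two_locus_table({"AB": 8, "Ab": 4, "aB": 2, "ab": 2}),
                                 seed=7)
        assert res.p_exact is not None
        assert res.p_exact == pytest.approx(res.p_value, abs=0.05)

    def test_verdict_invariant_to_relabeling_and_locus_order(self):
        brood = make_brood(
            {"L1": ("M", "M"), "L2": ("M", "M")},
            [{"L1": ("M", "A"), "L2": ("M", "B")} for _ in range(11)]
            + [{"L1": ("M", "a"), "L2": ("M", "b")} for _ in range(9)],
        )
        res = single_father_chi2(build_haplotype_table(brood, infer_brood(brood)))

        relabel = {"M": "300", "A": "x", "a": "y", "B": "q", "b": "z"}
        swapped = make_brood(
            {"L2": ("300", "300"), "L1": ("300", "300")},
            [{"L2": (relabel[g.calls["L2"].alleles[0]], relabel[g.calls["L2"].alleles[1]]),
              "L1": (relabel[g.calls["L1"].alleles[0]], relabel[g.calls["L1"].alleles[1]])}
             for g in brood.offspring],
        )
        res2 = single_father_chi2(build_haplotype_table(swapped, infer_brood(swapped)))
        assert res2.chi2 == pytest.approx(res.chi2)
        assert res2.verdict == res.verdict


def pge_vs_mendelian_summaries(rng, n_families=20, n_loci=9):
    """Summaries shaped like a PGE study: mothers het at ~half of loci."""
    out = []
    for i in range(n_families):
        m2 = rng.binomial(n_loci, 0.5)
        out.append(InheritanceSummary(
            f"F{i}", "spA" if i % 2 else "spB",
            maternal=ParentTally(n_loci - m2, m2, 0),
            paternal=ParentTally(n_loci, 0, 0),
        ))
    return out


class TestParentOriginModel:
    def test_positive_effect_recovered(self):
        rng = np.random.default_rng(0)
        res = fit_parent_origin_model(pge_vs_mendelian_summaries(rng))
        assert res.converged
        assert res.parent_effect.estimate > 0
        assert res.parent_effect.p_value < 0.001

    def test_symmetric_counts_give_null_effect(self):
        summaries = [
            InheritanceSummary(f"F{i}", "sp", ParentTally(5, 4, 0), ParentTally(5, 4, 0))
            for i in range(10)
        ]
        res = fit_parent_origin_model(summaries)
        assert abs(res.parent_effect.estimate) < 0.15
        assert res.parent_effect.p_value > 0.5

    def test_power_over_replicates(self):
        """Strict PGE fathers vs 50%-het mothers: effect detected nearly always."""
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            res = fit_parent_origin_model(pge_vs_mendelian_summaries(rng))
            hits += res.parent_effect.p_value < 0.05 and res.parent_effect.estimate > 0
        assert hits >= int(0.95 * n_rep)

    def test_agrees_with_lme4_glmer(self):
        """Independent cross-check against the reference mixed-model fitter."""
        cfg = BroodSimConfig(n_families=20, alleles_per_locus=2)
        broods, _ = simulate_brood(cfg, seed=13)
        from pgekit.brood_inference import summarize_family

        summaries = [summarize_family(b) for b in broods]
        ours = fit_parent_origin_model(summaries, backend="statsmodels")
        ref = fit_parent_origin_model(summaries, backend="lme4")
        assert ref.method == "glmm_lme4"
        a, b = ours.parent_effect, ref.parent_effect
        assert np.sign(a.estimate) == np.sign(b.estimate)
        assert abs(a.estimate - b.estimate) < 0.6
        assert (a.p_value < 0.01) == (b.p_value < 0.01)

    def test_too_few_families_raise(self):
        with pytest.raises(ValueError):
            fit_parent_origin_model([])
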