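"""Tests discriminating multiple PGE fathers from a single Mendelian father.

When a brood shows two paternal alleles at two or more loci, two explanations
compete.  Under PGE a father transmits one completely linked multilocus
haplotype, so two fathers (say contributing AB and ab at two loci) can only
ever produce the combinations AB and ab among offspring — never Ab or aB.  A
single non-PGE heterozygous father (aAbB) assorts independently across
unlinked loci and produces all combinations at equal frequency.  The
discriminator is a chi-square goodness-of-fit of the observed multilocus
paternal-allele combinations against that uniform expectation.

The module also fits the brood-level parent-of-origin comparison: a binomial
mixed model of (loci with 2 inherited alleles, loci with 1) per brood and
parent, with parent-of-origin and species as fixed effects and an
observation-level random intercept absorbing overdispersion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .brood_inference import (
    STATUS_OK,
    InheritanceSummary,
    LocusInheritance,
)
from .genotype_io import Brood

__all__ = [
    "HaplotypeTable",
    "TransmissionTestResult",
    "EffectEstimate",
    "ParentOriginModelResult",
    "NotTestableError",
    "build_haplotype_table",
    "single_father_chi2",
    "fit_parent_origin_model",
    "VERDICT_MULTIPLE_PGE",
    "VERDICT_SINGLE_NONPGE",
    "VERDICT_INCONCLUSIVE",
]

VERDICT_MULTIPLE_PGE = "consistent_with_multiple_PGE_fathers"
VERDICT_SINGLE_NONPGE = "single_nonPGE_father_not_rejected"
VERDICT_INCONCLUSIVE = "inconclusive"

DEFAULT_ALPHA = 0.01  # transmission was called non-random at P < 0.01 throughout


class NotTestableError(ValueError):
    """The brood does not meet the preconditions of the haplotype test."""


@dataclass(frozen=True)
class HaplotypeTable:
    """Counts of paternal multilocus allele combinations among offspring.

    Only loci with exactly two inferred paternal alleles enter; only
    offspring whose paternal allele is unambiguously resolvable at every
    listed locus contribute to ``n_complete``.  ``combo_counts`` covers all
    2^k cells, zeros included.
    """

    family_id: str
    loci: tuple[str, ...]
    locus_alleles: Mapping[str, tuple[str, str]]
    combo_counts: Mapping[tuple[str, ...], int]
    n_complete: int
    n_excluded_ambiguous: int
    n_excluded_missing: int

    @property
    def k(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class TransmissionTestResult:
    family_id: str
    chi2: float
    df: int
    p_value: float
    p_exact: float | None  # seeded Monte-Carlo multinomial p when any E < 5
    n_complete: int
    n_combos_observed: int
    low_freq_combos: tuple[tuple[str, ...], ...]
    verdict: str


def _resolve_paternal(call, maternal: frozenset[str], paternal: tuple[str, str]) -> str | None:
    """Resolve one offspring's paternal allele at one locus by subtraction.

    Returns the allele, or None when unresolvable (incompatible) or
    ambiguous (both alleles could be the paternal one).
    """
    x, y = call.alleles
    possible = set()
    if x in paternal and y in maternal:
        possible.add(x)
    if y in paternal and x in maternal:
        possible.add(y)
    if len(possible) == 1:
        return possible.pop()
    return None


def build_haplotype_table(
    brood: Brood,
    inferences: Sequence[LocusInheritance],
    min_loci: int = 2,
) -> HaplotypeTable:
    """Tabulate paternal multilocus combinations for a 2-allele brood.

    Raises :class:`NotTestableError` when fewer than *min_loci* loci carry
    two inferred paternal alleles, or no offspring is determinate at all of
    them.
    """
    qualifying = [
        inf for inf in inferences
        if inf.family_id == brood.family_id
        and inf.status == STATUS_OK
        and inf.paternal_count == 2
    ]
    if len(qualifying) < min_loci:
        raise NotTestableError(
            f"family {brood.family_id}: not testable — "
            f"{len(qualifying)} loci with 2 paternal alleles (need >= {min_loci})"
        )
    loci = tuple(inf.locus_id for inf in qualifying)
    locus_alleles = {
        inf.locus_id: tuple(sorted(inf.paternal_alleles)) for inf in qualifying
    }
    maternal = {inf.locus_id: inf.maternal_alleles for inf in qualifying}

    combos = {c: 0 for c in itertools.product(*(locus_alleles[l] for l in loci))}
    n_complete = n_ambiguous = n_missing = 0
    for off in brood.offspring:
        resolved = []
        state = "ok"
        for locus in loci:
            call = off.calls[locus]
            if call.missing:
                state = "missing"
                break
            p = _resolve_paternal(call, maternal[locus], locus_alleles[locus])
            if p is None:
                state = "ambiguous"
                break
            resolved.append(p)
        if state == "ok":
            combos[tuple(resolved)] += 1
            n_complete += 1
        elif state == "missing":
            n_missing += 1
        else:
            n_ambiguous += 1

    return HaplotypeTable(
        family_id=brood.family_id,
        loci=loci,
        locus_alleles=locus_alleles,
        combo_counts=combos,
        n_complete=n_complete,
        n_excluded_ambiguous=n_ambiguous,
        n_excluded_missing=n_missing,
    )


def single_father_chi2(
    table: HaplotypeTable,
    alpha: float = DEFAULT_ALPHA,
    min_brood: int = 5,
    low_freq_count: int = 1,
    low_freq_frac: float = 0.1,
    max_fathers: int = 2,
    mc_reps: int = 20000,
    seed: int | np.random.Generator | None = 0,
) -> TransmissionTestResult:
    """Chi-square test of multilocus combinations against independent assortment.

    Under a single non-PGE heterozygous father, unlinked loci assort
    independently, so the 2^k combinations are expected at equal frequency
    ``n_complete / 2^k``.  Rejection together with at most *max_fathers*
    major combinations (combinations with count <= *low_freq_count* or at most
    *low_freq_frac* of the brood are flagged as putative genotyping errors
    and not counted against the bound — but always retained in the
    chi-square) is reported as consistent with multiple PGE fathers.

    When any expected cell count is below 5, a seeded Monte-Carlo multinomial
    p-value is computed alongside the asymptotic one and used for the
    verdict.
    """
    cells = sorted(table.combo_counts)
    obs = np.array([table.combo_counts[c] for c in cells], dtype=float)
    n = int(obs.sum())
    if n == 0:
        raise NotTestableError(f"family {table.family_id}: empty haplotype table")
    k_cells = len(cells)
    expected = np.full(k_cells, n / k_cells)
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = k_cells - 1
    p_value = float(stats.chi2.sf(chi2, df))

    p_exact = None
    if expected.min() < 5:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sim = rng.multinomial(n, np.full(k_cells, 1.0 / k_cells), size=mc_reps)
        sim_chi2 = ((sim - expected) ** 2 / expected).sum(axis=1)
        p_exact = float((np.sum(sim_chi2 >= chi2 - 1e-9) + 1) / (mc_reps + 1))

    observed_combos = [c for c in cells if table.combo_counts[c] > 0]
    low_freq = tuple(
        c for c in observed_combos
        if table.combo_counts[c] <= low_freq_count
        or table.combo_counts[c] <= low_freq_frac * n
    )
    n_major = len(observed_combos) - len(low_freq)

    p_for_verdict = p_exact if p_exact is not None else p_value
    if n < min_brood:
        verdict = VERDICT_INCONCLUSIVE
    elif p_for_verdict < alpha:
        verdict = VERDICT_MULTIPLE_PGE if n_major <= max_fathers else VERDICT_INCONCLUSIVE
    else:
        verdict = VERDICT_SINGLE_NONPGE

    return TransmissionTestResult(
        family_id=table.family_id,
        chi2=chi2,
        df=df,
        p_value=p_value,
        p_exact=p_exact,
        n_complete=n,
        n_combos_observed=len(observed_combos),
        low_freq_combos=low_freq,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# Binomial mixed model: parent-of-origin effect on 2-allele inheritance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectEstimate:
    estimate: float
    se: float
    z: float
    p_value: float


@dataclass(frozen=True)
class ParentOriginModelResult:
    """Fit of 2-allele vs 1-allele locus counts on parent of origin and species.

    ``parent_maternal`` is the log-odds increase of a locus showing 2
    inherited alleles when the parent is the mother; strongly positive under
    PGE (fathers transmit a single haplotype).  When the mixed-model fit
    fails, an exact two-sided comparison of the pooled counts (Fisher) is
    reported instead with ``converged=False``.
    """

    effects: Mapping[str, EffectEstimate]
    converged: bool
    method: str  # "glmm_laplace", "glmm_lme4" or "fisher_fallback"
    n_observations: int
    vc_sd: float | None = None  # observation-level random-intercept SD

    @property
    def parent_effect(self) -> EffectEstimate:
        return self.effects["parent_maternal"]


def _expand_rows(summaries: Sequence[InheritanceSummary]):
    """Bernoulli expansion: one row per determinate locus, grouped per
    brood x parent observation (the observation-level random effect)."""
    y, maternal, species, group = [], [], [], []
    obs = 0
    for s in summaries:
        for parent_is_maternal, tally in ((1, s.maternal), (0, s.paternal)):
            n2, n1 = tally.n_loci_2_alleles, tally.n_loci_1_allele
            if n2 + n1 == 0:
                continue
            y.extend([1] * n2 + [0] * n1)
            maternal.extend([parent_is_maternal] * (n2 + n1))
            species.extend([s.species] * (n2 + n1))
            group.extend([obs] * (n2 + n1))
            obs += 1
    return (np.asarray(y, dtype=float), np.asarray(maternal, dtype=float),
            species, np.asarray(group), obs)


def fit_parent_origin_model(
    summaries: Sequence[InheritanceSummary],
    backend: str = "statsmodels",
) -> ParentOriginModelResult:
    """Fit the binomial GLMM of 2-allele inheritance on parent and species.

    The response is, per brood and parent, the vector of (loci with 2
    inherited alleles, loci with 1); fixed effects are parent of origin
    (maternal = 1) and species (when more than one is present); each
    brood x parent row carries its own random intercept.  ``backend`` may be
    ``"statsmodels"`` (Laplace/MAP fit, default) or ``"lme4"`` (glmer via
    Rscript, if R is available).  On failure the pooled-count Fisher exact
    comparison is returned, flagged as a fallback.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 families to fit the model")
    y, maternal, species, group, n_obs = _expand_rows(summaries)
    if len(y) == 0:
        raise ValueError("all loci uncertain; nothing to fit")
    if n_obs < 3:
        return _fisher_fallback(summaries, len(y))

    species_levels = sorted(set(species))
    exog_names = ["intercept", "parent_maternal"]
    cols = [np.ones_like(y), maternal]
    for level in species_levels[1:]:
        cols.append(np.asarray([1.0 if s == level else 0.0 for s in species]))
        exog_names.append(f"species_{level}")
    exog = np.column_stack(cols)

    try:
        if backend == "statsmodels":
            return _fit_statsmodels(y, exog, exog_names, group, n_obs)
        if backend == "lme4":
            return _fit_lme4(y, exog, exog_names, group, n_obs)
        raise ValueError(f"unknown backend {backend!r}")
    except ValueError:
        raise
    except Exception:
        return _fisher_fallback(summaries, len(y))


def _fit_statsmodels(y, exog, exog_names, group, n_obs) -> ParentOriginModelResult:
    import scipy.sparse as sp
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    class _DeterministicStart(BinomialBayesMixedGLM):
        # upstream draws the random-effect start point from the global RNG;
        # start at the prior mode instead so fits are reproducible
        def _get_start(self):
            return np.concatenate([
                np.zeros(self.k_fep), np.ones(self.k_vcp), np.zeros(self.k_vc),
            ])

    rows = np.arange(len(y))
    vc = sp.csr_matrix((np.ones(len(y)), (rows, group)), shape=(len(y), n_obs))
    model = _DeterministicStart(
        y, exog, exog_vc=vc, ident=np.zeros(n_obs, dtype=int),
        vcp_p=2.0, fe_p=2.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit_map()
    est, sd = np.asarray(fit.fe_mean), np.asarray(fit.fe_sd)
    if not (np.all(np.isfinite(est)) and np.all(np.isfinite(sd)) and np.all(sd > 0)):
        raise RuntimeError("non-finite mixed-model estimates")
    effects = {}
    for name, e, s in zip(exog_names, est, sd):
        z = e / s
        effects[name] = EffectEstimate(float(e), float(s), float(z),
                                       float(2 * stats.norm.sf(abs(z))))
    vc_sd = float(np.exp(np.asarray(fit.vcp_mean)[0])) if len(np.atleast_1d(fit.vcp_mean)) else None
    return ParentOriginModelResult(effects, True, "glmm_laplace", len(y), vc_sd)


def _fit_lme4(y, exog, exog_names, group, n_obs) -> ParentOriginModelResult:
    """Fit with lme4::glmer through Rscript; requires R with lme4 on PATH."""
    import json
    import subprocess
    import tempfile
    from pathlib import Path

    import pandas as pd

    df = pd.DataFrame({"y": y.astype(int), "obs": group})
    for j, name in enumerate(exog_names):
        if name != "intercept":
            df[name] = exog[:, j]
    fixed = " + ".join(n for n in exog_names if n != "intercept") or "1"
    rcode = f"""
    suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
    d <- read.csv(commandArgs(TRUE)[1]); d$obs <- factor(d$obs)
    m <- glmer(y ~ {fixed} + (1|obs), data=d, family=binomial)
    co <- summary(m)$coefficients
    cat(toJSON(list(names=rownames(co), est=co[,1], se=co[,2], z=co[,3], p=co[,4],
                    sd_obs=as.numeric(VarCorr(m)$obs[1])^0.5), digits=10))
    """
    with tempfile.TemporaryDirectory() as tmp:
        csv_path = Path(tmp) / "glmm.csv"
        df.to_csv(csv_path, index=False)
        out = subprocess.run(
            ["Rscript", "-e", rcode, str(csv_path)],
            capture_output=True, text=True, check=True,
        )
    res = json.loads(out.stdout)
    name_map = {"(Intercept)": "intercept"}
    effects = {}
    for rname, e, s, z, p in zip(res["names"], res["est"], res["se"], res["z"], res["p"]):
        effects[name_map.get(rname, rname)] = EffectEstimate(e, s, z, p)
    vc_sd = res["sd_obs"][0] if isinstance(res["sd_obs"], list) else res["sd_obs"]
    return ParentOriginModelResult(effects, True, "glmm_lme4", len(y), float(vc_sd))


def _fisher_fallback(summaries: Sequence[InheritanceSummary], n_rows: int) -> ParentOriginModelResult:
    m2 = sum(s.maternal.n_loci_2_alleles for s in summaries)
    m1 = sum(s.maternal.n_loci_1_allele for s in summaries)
    p2 = sum(s.paternal.n_loci_2_alleles for s in summaries)
    p1 = sum(s.paternal.n_loci_1_allele for s in summaries)
    odds_ratio, p = stats.fisher_exact([[m2, m1], [p2, p1]], alternative="two-sided")
    est = float(np.log(odds_ratio)) if 0 < odds_ratio < np.inf else float(np.sign(odds_ratio or -1) * np.inf)
    effects = {"parent_maternal": EffectEstimate(est, float("nan"), float("nan"), float(p))}
    return ParentOriginModelResult(effects, False, "fisher_fallback", n_rows, None)


def results_table(results: Iterable[TransmissionTestResult]):
    """Transmission test results as a DataFrame (the on-disk CSV layout)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "family": r.family_id,
            "k_loci": int(np.log2(r.df + 1)),
            "n_complete": r.n_complete,
            "chi2": r.chi2,
            "df": r.df,
            "p_value": r.p_value,
            "p_exact": r.p_exact if r.p_exact is not None else "NA",
            "n_combos": r.n_combos_observed,
            "verdict": r.verdict,
        })
    return pd.DataFrame(rows)
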