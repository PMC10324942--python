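"""End-to-end orchestration of the two analyses.

``run_inheritance`` chains brood inference, species-level allele-count means,
the parent-of-origin binomial GLMM and the per-family multiple-paternity
chi-square into one report answering: are these families transmitting
paternal alleles the way PGE predicts?

``run_expression`` chains SNP filtering, allele-bias classification and the
mother/son homozygosity comparison into a per-family verdict on paternal
silencing.

Reports are plain dicts (JSON-serializable) with a provenance block; given
identical inputs and seed they are deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import __version__
from .ase_bias import (
    BiasThresholds,
    classify_sample,
    compare_mother_sons,
    summarize_sample,
)
from .brood_inference import (
    DEFAULT_MAX_INCOMPATIBLE_FRAC,
    DEFAULT_MIN_ALLELE_SUPPORT,
    infer_brood,
    mean_alleles,
    summarize_family,
)
from .genotype_io import Brood, SnpCounts
from .transmission_tests import (
    DEFAULT_ALPHA,
    VERDICT_SINGLE_NONPGE,
    NotTestableError,
    build_haplotype_table,
    fit_parent_origin_model,
    single_father_chi2,
)

__all__ = ["RunConfig", "run_inheritance", "run_expression", "render_text_report"]

log = logging.getLogger("pgekit")

VERDICT_PGE = "PGE-consistent"
VERDICT_NO_PGE = "PGE rejected"
VERDICT_UNCLEAR = "inconclusive"


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters for a pipeline run.

    Defaults are the published thresholds where the source analysis states
    one: 5% other-base proportion, depth 40, het window [0.2, 0.8], hom
    below 0.1 / above 0.9, and alpha 0.01 for the transmission calls.
    ``mode="paper-faithful"`` keeps the mother/son comparison descriptive
    (no added significance test); ``mode="extended"`` (default) runs the
    two-proportion z-test.
    """

    alpha: float = DEFAULT_ALPHA
    max_incompatible_frac: float = DEFAULT_MAX_INCOMPATIBLE_FRAC
    min_allele_support: int = DEFAULT_MIN_ALLELE_SUPPORT
    min_brood: int = 5
    low_freq_count: int = 1
    glmm_backend: str = "statsmodels"
    thresholds: BiasThresholds = field(default_factory=BiasThresholds)
    mode: str = "extended"  # "paper-faithful" | "extended"
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {
        "package": "pgekit",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
    }


def run_inheritance(broods: Sequence[Brood], config: RunConfig | None = None) -> dict:
    """Run the full microsatellite inheritance analysis on a set of broods."""
    config = config or RunConfig()
    if not broods:
        raise ValueError("no broods supplied")

    inferences = {}
    summaries = []
    family_blocks = []
    for brood in broods:
        infs = infer_brood(brood, config.max_incompatible_frac, config.min_allele_support)
        inferences[brood.family_id] = infs
        summary = summarize_family(brood, infs)
        summaries.append(summary)
        for inf in infs:
            if inf.status != "ok":
                log.info("family %s locus %s scored %s", brood.family_id,
                         inf.locus_id, inf.status)
        family_blocks.append({
            "family": brood.family_id,
            "species": brood.species,
            "n_offspring": brood.n_offspring,
            "maternal": asdict(summary.maternal),
            "paternal": asdict(summary.paternal),
        })

    species_means = {}
    for species in sorted({b.species for b in broods}):
        species_means[species] = {
            parent: {
                method: mean_alleles(summaries, species, parent, method)
                for method in ("family_mean", "pooled")
            }
            for parent in ("maternal", "paternal")
        }

    model_block = None
    model_significant = None
    if len(summaries) >= 2:
        model = fit_parent_origin_model(summaries, backend=config.glmm_backend)
        pe = model.parent_effect
        model_significant = bool(pe.p_value < config.alpha and pe.estimate > 0)
        model_block = {
            "method": model.method,
            "converged": model.converged,
            "n_observations": model.n_observations,
            "vc_sd": model.vc_sd,
            "effects": {k: asdict(v) for k, v in model.effects.items()},
            "parent_effect_significant": model_significant,
        }

    rng = np.random.default_rng(config.seed)
    transmission_blocks = []
    any_single_father = False
    for brood in broods:
        try:
            table = build_haplotype_table(brood, inferences[brood.family_id])
        except NotTestableError as exc:
            log.info("%s", exc)
            continue
        result = single_father_chi2(
            table, alpha=config.alpha, min_brood=config.min_brood,
            low_freq_count=config.low_freq_count, seed=rng,
        )
        any_single_father |= result.verdict == VERDICT_SINGLE_NONPGE
        transmission_blocks.append({
            "family": result.family_id,
            "k_loci": table.k,
            "n_complete": result.n_complete,
            "chi2": result.chi2,
            "df": result.df,
            "p_value": result.p_value,
            "p_exact": result.p_exact,
            "n_combos_observed": result.n_combos_observed,
            "low_freq_combos": ["/".join(c) for c in result.low_freq_combos],
            "verdict": result.verdict,
        })

    if model_significant is None:
        overall = VERDICT_UNCLEAR
    elif not model_significant:
        overall = VERDICT_NO_PGE
    elif any_single_father:
        overall = VERDICT_UNCLEAR
    else:
        overall = VERDICT_PGE

    return {
        "provenance": _provenance(config),
        "analysis": "inheritance",
        "n_families": len(broods),
        "families": family_blocks,
        "species_mean_alleles": species_means,
        "parent_origin_model": model_block,
        "transmission_tests": transmission_blocks,
        "overall_verdict": overall,
    }


def run_expression(
    samples: Mapping[str, Sequence[SnpCounts]],
    families: Sequence[tuple[str, str, Sequence[str]]],
    config: RunConfig | None = None,
) -> dict:
    """Run the allele-specific expression analysis.

    *samples* maps sample id to its per-SNP counts; *families* lists
    ``(family_id, mother_sample, son_samples)``.  Every referenced sample
    must be present in *samples*.
    """
    config = config or RunConfig()
    if not families:
        raise ValueError("no families supplied")
    for family_id, mother, sons in families:
        for sid in (mother, *sons):
            if sid not in samples:
                raise ValueError(
                    f"family {family_id}: sample {sid!r} not found in the count tables"
                )

    calls = {}
    summaries = {}
    for sid, counts in samples.items():
        calls[sid] = classify_sample(counts, config.thresholds)
        summaries[sid] = summarize_sample(calls[sid])
        log.info("sample %s: %d het, %d hom, %d unclassified, %d filtered",
                 sid, summaries[sid].n_het, summaries[sid].n_hom,
                 summaries[sid].n_unclassified, summaries[sid].n_filtered)

    sample_blocks = {
        sid: {
            "n_het": s.n_het, "n_hom": s.n_hom, "n_unclassified": s.n_unclassified,
            "n_filtered_other": s.n_filtered_other, "n_filtered_depth": s.n_filtered_depth,
            "het_fraction": s.het_fraction,
            "het_fraction_classified": s.het_fraction_classified,
            "hom_fraction": s.hom_fraction,
        }
        for sid, s in summaries.items()
    }

    family_blocks = []
    n_detected = 0
    for family_id, mother, sons in families:
        report = compare_mother_sons(
            summaries[mother], [summaries[s] for s in sons],
            alpha=config.alpha, test=config.mode != "paper-faithful",
        )
        n_detected += report.silencing_signal
        family_blocks.append({
            "family": family_id,
            "mother": mother,
            "sons": list(sons),
            "comparisons": [asdict(c) for c in report.comparisons],
            "verdict": ("paternal silencing detected" if report.silencing_signal
                        else "biparental expression"),
        })

    return {
        "provenance": _provenance(config),
        "analysis": "expression",
        "samples": sample_blocks,
        "families": family_blocks,
        "n_families_with_silencing_signal": n_detected,
    }


def render_text_report(report: dict) -> str:
    """Human-readable rendering of a pipeline report."""
    lines = [
        f"pgekit {report['provenance']['version']} — {report['analysis']} analysis",
        f"seed {report['provenance']['seed']}, config {report['provenance']['config_hash']}",
        "",
    ]
    if report["analysis"] == "inheritance":
        for fam in report["families"]:
            m, p = fam["maternal"], fam["paternal"]
            lines.append(
                f"family {fam['family']} ({fam['species']}, n={fam['n_offspring']}): "
                f"maternal 1/2/unc = {m['n_loci_1_allele']}/{m['n_loci_2_alleles']}/"
                f"{m['n_loci_uncertain']}, paternal = {p['n_loci_1_allele']}/"
                f"{p['n_loci_2_alleles']}/{p['n_loci_uncertain']}"
            )
        lines.append("")
        for species, means in report["species_mean_alleles"].items():
            lines.append(
                f"{species}: mean alleles per brood — maternal "
                f"{means['maternal']['family_mean']:.2f}, paternal "
                f"{means['paternal']['family_mean']:.2f} (family-mean convention)"
            )
        model = report.get("parent_origin_model")
        if model:
            pe = model["effects"]["parent_maternal"]
            lines.append(
                f"parent-of-origin effect ({model['method']}): est = {pe['estimate']:.2f}, "
                f"s.e. = {pe['se']:.2f}, z = {pe['z']:.2f}, p = {pe['p_value']:.3g}"
            )
        for t in report["transmission_tests"]:
            lines.append(
                f"family {t['family']}: chi2 = {t['chi2']:.2f} (df {t['df']}), "
                f"p = {t['p_value']:.3g} -> {t['verdict']}"
            )
        lines.append("")
        lines.append(f"overall: {report['overall_verdict']}")
    else:
        for sid, s in report["samples"].items():
            lines.append(
                f"sample {sid}: het {s['het_fraction']:.1%} of scored SNPs "
                f"({s['n_het']} het / {s['n_hom']} hom / {s['n_unclassified']} unclassified)"
            )
        lines.append("")
        for fam in report["families"]:
            lines.append(f"family {fam['family']}: {fam['verdict']}")
            for c in fam["comparisons"]:
                lines.append(
                    f"  son {c['son_id']}: hom {c['son_hom_fraction']:.1%} vs mother "
                    f"{c['mother_hom_fraction']:.1%} (excess {c['hom_excess']:+.1%}, "
                    f"p = {c['p_value']:.3g})"
                )
    return "\n".join(lines) + "\n"
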