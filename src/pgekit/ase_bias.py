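"""Allele-bias classification of per-SNP expression counts.

At an expressed biallelic SNP the *allele bias* is the proportion of
reference-allele reads among reference + alternate reads.  A site expressing
both alleles sits near 0.5; a site expressing one allele (homozygous, or
heterozygous with one silenced copy) sits near 0 or 1.  Sites are classed
heterozygous when the bias lies in [0.2, 0.8], homozygous when it is below
0.1 or above 0.9, and unclassified in between; sites with too little depth
or too many non-ref/alt bases are filtered first.

If a significant part of the paternally derived genome in sons is silenced,
sons show an excess of homozygously expressed SNPs relative to their mother
— the comparison :func:`compare_mother_sons` quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotype_io import SnpCounts

__all__ = [
    "BiasCall",
    "SampleBiasSummary",
    "SonComparison",
    "FamilyAseReport",
    "BiasThresholds",
    "filter_snp",
    "classify_bias",
    "classify_sample",
    "summarize_sample",
    "compare_mother_sons",
    "bias_histogram",
    "CLS_HET",
    "CLS_HOM",
    "CLS_UNCLASSIFIED",
    "CLS_FILTERED_OTHER",
    "CLS_FILTERED_DEPTH",
]

CLS_HET = "het"
CLS_HOM = "hom"
CLS_UNCLASSIFIED = "unclassified"
CLS_FILTERED_OTHER = "filtered_other"
CLS_FILTERED_DEPTH = "filtered_depth"


@dataclass(frozen=True)
class BiasThresholds:
    """Classification and filtering thresholds.

    Defaults: heterozygous for bias in [0.2, 0.8] (boundaries inclusive),
    homozygous below 0.1 or above 0.9 (boundaries exclusive — they fall in
    the unclassified gap), sites dropped when non-ref/alt bases exceed 5% of
    reads or total depth is below 40.  ``bias_includes_other`` switches the
    bias denominator from ref+alt to ref+alt+other.
    """

    het_low: float = 0.2
    het_high: float = 0.8
    hom_low: float = 0.1
    hom_high: float = 0.9
    max_other_prop: float = 0.05
    min_depth: int = 40
    bias_includes_other: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.hom_low <= self.het_low <= self.het_high <= self.hom_high <= 1):
            raise ValueError("thresholds must satisfy 0 <= hom_low <= het_low "
                             "<= het_high <= hom_high <= 1")


DEFAULT_THRESHOLDS = BiasThresholds()


@dataclass(frozen=True)
class BiasCall:
    sample_id: str
    site_id: tuple[str, int]
    bias: float  # NaN when filtered
    cls: str


@dataclass(frozen=True)
class SampleBiasSummary:
    """Per-sample tallies over all examined sites.

    ``het_fraction`` uses het/(het+hom+unclassified); ``het_fraction_classified``
    uses het/(het+hom).  Both conventions are reported because published
    percentages rarely state which denominator they use.
    """

    sample_id: str
    n_het: int
    n_hom: int
    n_unclassified: int
    n_filtered_other: int
    n_filtered_depth: int

    @property
    def n_filtered(self) -> int:
        return self.n_filtered_other + self.n_filtered_depth

    @property
    def n_examined(self) -> int:
        return self.n_het + self.n_hom + self.n_unclassified + self.n_filtered

    @property
    def n_scored(self) -> int:
        return self.n_het + self.n_hom + self.n_unclassified

    @property
    def het_fraction(self) -> float:
        return self.n_het / self.n_scored if self.n_scored else float("nan")

    @property
    def hom_fraction(self) -> float:
        return self.n_hom / self.n_scored if self.n_scored else float("nan")

    @property
    def het_fraction_classified(self) -> float:
        n = self.n_het + self.n_hom
        return self.n_het / n if n else float("nan")


def filter_snp(c: SnpCounts, thresholds: BiasThresholds = DEFAULT_THRESHOLDS) -> str:
    """Return ``"pass"``, ``"filtered_other"`` or ``"filtered_depth"`` for a site."""
    total = c.total
    if total < thresholds.min_depth or total == 0:
        return CLS_FILTERED_DEPTH
    if c.other_count / total > thresholds.max_other_prop:
        return CLS_FILTERED_OTHER
    return "pass"


def classify_bias(c: SnpCounts, thresholds: BiasThresholds = DEFAULT_THRESHOLDS) -> BiasCall:
    """Classify a site that already passed filtering as het/hom/unclassified."""
    denom = c.total if thresholds.bias_includes_other else c.ref_count + c.alt_count
    if denom == 0:
        return BiasCall(c.sample_id, c.site_id, float("nan"), CLS_FILTERED_DEPTH)
    bias = c.ref_count / denom
    if thresholds.het_low <= bias <= thresholds.het_high:
        cls = CLS_HET
    elif bias < thresholds.hom_low or bias > thresholds.hom_high:
        cls = CLS_HOM
    else:
        cls = CLS_UNCLASSIFIED
    return BiasCall(c.sample_id, c.site_id, bias, cls)


def classify_sample(
    counts: Iterable[SnpCounts],
    thresholds: BiasThresholds = DEFAULT_THRESHOLDS,
) -> list[BiasCall]:
    """Filter then classify every site of a sample; one call per input site."""
    calls = []
    for c in counts:
        verdict = filter_snp(c, thresholds)
        if verdict != "pass":
            calls.append(BiasCall(c.sample_id, c.site_id, float("nan"), verdict))
        else:
            calls.append(classify_bias(c, thresholds))
    return calls


def summarize_sample(calls: Sequence[BiasCall]) -> SampleBiasSummary:
    if not calls:
        raise ValueError("no calls to summarize")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) != 1:
        raise ValueError(f"calls span multiple samples: {sorted(sample_ids)}")
    tally = {CLS_HET: 0, CLS_HOM: 0, CLS_UNCLASSIFIED: 0,
             CLS_FILTERED_OTHER: 0, CLS_FILTERED_DEPTH: 0}
    for c in calls:
        tally[c.cls] += 1
    return SampleBiasSummary(
        sample_id=sample_ids.pop(),
        n_het=tally[CLS_HET],
        n_hom=tally[CLS_HOM],
        n_unclassified=tally[CLS_UNCLASSIFIED],
        n_filtered_other=tally[CLS_FILTERED_OTHER],
        n_filtered_depth=tally[CLS_FILTERED_DEPTH],
    )


@dataclass(frozen=True)
class SonComparison:
    son_id: str
    son_hom_fraction: float
    mother_hom_fraction: float
    hom_excess: float  # son minus mother
    p_value: float  # one-sided two-proportion z-test (son hom > mother hom)
    significant: bool


@dataclass(frozen=True)
class FamilyAseReport:
    mother_id: str
    comparisons: tuple[SonComparison, ...]
    alpha: float
    silencing_signal: bool  # every son shows a significant homozygosity excess


def compare_mother_sons(
    mother: SampleBiasSummary,
    sons: Sequence[SampleBiasSummary],
    alpha: float = 0.01,
    test: bool = True,
) -> FamilyAseReport:
    """Test each son for an excess of homozygous expression over the mother.

    Marginal hom fractions (hom over het+hom+unclassified) are compared with
    a one-sided two-proportion z-test; a shared site universe is not
    required.  The family-level silencing signal is reported only when every
    son individually shows a significant excess.  With ``test=False`` only
    the descriptive differences are computed (p-values reported as NaN and
    significance as a simple direction check) — the comparison as published
    was descriptive.
    """
    from statsmodels.stats.proportion import proportions_ztest

    if mother.n_scored == 0:
        raise ValueError("mother has zero classified sites")
    comparisons = []
    for son in sons:
        if son.n_scored == 0:
            raise ValueError(f"son {son.sample_id} has zero classified sites")
        excess = son.hom_fraction - mother.hom_fraction
        if test:
            if son.hom_fraction == mother.hom_fraction:
                p = 1.0
            else:
                _, p = proportions_ztest(
                    count=[son.n_hom, mother.n_hom],
                    nobs=[son.n_scored, mother.n_scored],
                    alternative="larger",
                )
            significant = bool(p < alpha and excess > 0)
        else:
            p = float("nan")
            significant = excess > 0
        comparisons.append(SonComparison(
            son_id=son.sample_id,
            son_hom_fraction=son.hom_fraction,
            mother_hom_fraction=mother.hom_fraction,
            hom_excess=excess,
            p_value=float(p),
            significant=significant,
        ))
    signal = bool(comparisons) and all(c.significant for c in comparisons)
    return FamilyAseReport(mother.sample_id, tuple(comparisons), alpha, signal)


def bias_histogram(
    calls: Sequence[BiasCall],
    bin_width: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of bias values over scored sites (edges, counts).

    Mirrors the per-sample allele-bias histograms used to visualize
    uniparental vs biparental expression; filtered sites are excluded.
    """
    biases = np.array([c.bias for c in calls if not np.isnan(c.bias)])
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(biases, bins=edges)
    return edges, counts


def calls_table(calls: Iterable[BiasCall]):
    """Per-site calls as a DataFrame (the on-disk CSV layout)."""
    import pandas as pd

    return pd.DataFrame([
        {"sample": c.sample_id, "contig": c.site_id[0], "position": c.site_id[1],
         "bias": c.bias, "class": c.cls}
        for c in calls
    ])


def summary_table(summaries: Iterable[SampleBiasSummary]):
    import pandas as pd

    return pd.DataFrame([
        {"sample": s.sample_id, "n_het": s.n_het, "n_hom": s.n_hom,
         "n_unclassified": s.n_unclassified, "n_filtered_other": s.n_filtered_other,
         "n_filtered_depth": s.n_filtered_depth, "het_fraction": s.het_fraction,
         "het_fraction_classified": s.het_fraction_classified,
         "hom_fraction": s.hom_fraction}
        for s in summaries
    ])
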