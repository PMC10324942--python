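"""Per-locus inheritance inference by subtraction of the maternal genotype.

Males in scale insects with paternal genome elimination (PGE) are diploid but
transmit only their maternally inherited haplotype through sperm.  A brood of
male siblings therefore receives exactly one paternal allele per father at
every locus, whereas a Mendelian heterozygous father contributes two.  Because
fathers cannot be genotyped directly (families are field-collected galls),
the paternal contribution is reconstructed from the brood: each offspring
genotype must decompose as ``{m, p}`` with ``m`` one of the mother's alleles
and ``p`` a paternal allele, and the inferred paternal allele set is the
smallest set that explains every compatible offspring.

A paternal allele identical to a maternal allele is *shadowed*: it is
invisible to direct subtraction in offspring that also carry the maternal
copy, but the minimal-set search still recovers it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from statistics import mean
from typing import Iterable, Sequence

from .genotype_io import Brood

__all__ = [
    "LocusInheritance",
    "InheritanceSummary",
    "infer_locus",
    "infer_brood",
    "summarize_family",
    "mean_alleles",
    "inference_table",
]

#: Fraction of offspring at a locus that may be incompatible with the mother
#: (no shared allele; treated as genotyping error) before the locus is scored
#: "uncertain".
DEFAULT_MAX_INCOMPATIBLE_FRAC = 0.2

#: Minimum number of offspring that must *require* each allele of a
#: multi-allele paternal set.  A second paternal allele demanded by a single
#: offspring is more plausibly a genotyping error (miscall or dropout) than a
#: second father, so the locus is scored uncertain rather than 2-allele.
DEFAULT_MIN_ALLELE_SUPPORT = 2

STATUS_OK = "ok"
STATUS_UNCERTAIN = "uncertain"
STATUS_MOTHER_MISSING = "mother_missing"
STATUS_NO_DATA = "no_data"


@dataclass(frozen=True)
class LocusInheritance:
    """Inferred parental allele contributions at one locus of one family.

    ``paternal_alleles`` is the minimum-cardinality set explaining every
    compatible offspring; ``shadowed`` are its members that coincide with a
    maternal allele.  ``status`` is ``"ok"`` when the inference is trusted,
    ``"uncertain"`` when too many offspring were incompatible with the mother,
    and ``"mother_missing"``/``"no_data"`` when inference was impossible.
    """

    family_id: str
    locus_id: str
    maternal_alleles: frozenset[str]
    maternal_transmitted: frozenset[str]
    paternal_alleles: frozenset[str]
    shadowed: frozenset[str]
    incompatible_offspring: tuple[str, ...]
    n_informative: int
    status: str

    @property
    def paternal_count(self) -> int | None:
        """Number of inferred paternal alleles; ``None`` when uncertain."""
        if self.status != STATUS_OK:
            return None
        return len(self.paternal_alleles)

    @property
    def maternal_count(self) -> int | None:
        if self.status != STATUS_OK or not self.maternal_transmitted:
            return None
        return len(self.maternal_transmitted)


@dataclass(frozen=True)
class ParentTally:
    n_loci_1_allele: int
    n_loci_2_alleles: int
    n_loci_uncertain: int

    @property
    def total(self) -> int:
        return self.n_loci_1_allele + self.n_loci_2_alleles + self.n_loci_uncertain


@dataclass(frozen=True)
class InheritanceSummary:
    """Per-family tallies of 1-allele vs 2-allele inheritance for each parent."""

    family_id: str
    species: str
    maternal: ParentTally
    paternal: ParentTally

    def tally(self, parent: str) -> ParentTally:
        if parent == "maternal":
            return self.maternal
        if parent == "paternal":
            return self.paternal
        raise ValueError(f"parent must be 'maternal' or 'paternal', got {parent!r}")


def _explains_all(S: frozenset[str], genotypes: Sequence[tuple[str, str]],
                  maternal: frozenset[str]) -> bool:
    for x, y in genotypes:
        if not ((x in maternal and y in S) or (y in maternal and x in S)):
            return False
    return True


def infer_locus(
    brood: Brood,
    locus_id: str,
    max_incompatible_frac: float = DEFAULT_MAX_INCOMPATIBLE_FRAC,
    min_allele_support: int = DEFAULT_MIN_ALLELE_SUPPORT,
) -> LocusInheritance:
    """Infer maternal and paternal allele contributions at one locus.

    Offspring sharing no allele with the mother admit no ``{m, p}``
    decomposition for any paternal set; they are flagged incompatible
    (putative genotyping errors) and excluded.  Among the remaining
    offspring, every subset of the observed alleles is searched smallest
    first; ties at minimum cardinality prefer sets with the fewest alleles
    shared with the mother (novel alleles are the more parsimonious
    explanation under subtraction), then the lexicographically smallest
    label tuple.

    The locus is scored uncertain when more than *max_incompatible_frac* of
    the scored offspring are incompatible, or when the minimal paternal set
    has two or more alleles and any of them is required by fewer than
    *min_allele_support* offspring (set ``min_allele_support=1`` to disable
    this genotyping-error guard).
    """
    mother_call = brood.mother.calls[locus_id]
    if mother_call.missing:
        return LocusInheritance(
            brood.family_id, locus_id, frozenset(), frozenset(), frozenset(),
            frozenset(), (), 0, STATUS_MOTHER_MISSING,
        )
    maternal = mother_call.allele_set

    scored: list[tuple[str, tuple[str, str]]] = []
    for off in brood.offspring:
        call = off.calls[locus_id]
        if call.missing:
            continue
        scored.append((off.individual_id, (call.alleles[0], call.alleles[1])))
    if not scored:
        return LocusInheritance(
            brood.family_id, locus_id, maternal, frozenset(), frozenset(),
            frozenset(), (), 0, STATUS_NO_DATA,
        )

    incompatible = tuple(
        oid for oid, (x, y) in scored if x not in maternal and y not in maternal
    )
    compat = [(oid, g) for oid, g in scored if oid not in set(incompatible)]
    if not compat:
        return LocusInheritance(
            brood.family_id, locus_id, maternal, frozenset(), frozenset(),
            frozenset(), incompatible, 0, STATUS_UNCERTAIN,
        )

    genotypes = [g for _, g in compat]
    candidates = sorted({a for g in genotypes for a in g})
    best: frozenset[str] | None = None
    for k in range(1, len(candidates) + 1):
        feasible = [
            frozenset(S)
            for S in itertools.combinations(candidates, k)
            if _explains_all(frozenset(S), genotypes, maternal)
        ]
        if feasible:
            best = min(feasible, key=lambda S: (len(S & maternal), tuple(sorted(S))))
            break
    # every compatible offspring shares an allele with the mother, so the set
    # of its non-maternal alleles (or maternal ones, if fully maternal) always
    # yields a feasible S at some k; best is never None here
    assert best is not None

    transmitted = set()
    for x, y in genotypes:
        if x in maternal and y in best:
            transmitted.add(x)
        if y in maternal and x in best:
            transmitted.add(y)

    frac_bad = len(incompatible) / len(scored)
    status = STATUS_UNCERTAIN if frac_bad > max_incompatible_frac else STATUS_OK
    if status == STATUS_OK and len(best) >= 2 and min_allele_support > 1:
        # an allele is "required" by an offspring that S minus the allele
        # cannot explain; weakly supported extra alleles flag the locus
        for a in best:
            reduced = best - {a}
            support = sum(
                0 if _explains_all(reduced, [g], maternal) else 1 for g in genotypes
            )
            if support < min_allele_support:
                status = STATUS_UNCERTAIN
                break
    return LocusInheritance(
        family_id=brood.family_id,
        locus_id=locus_id,
        maternal_alleles=maternal,
        maternal_transmitted=frozenset(transmitted),
        paternal_alleles=best,
        shadowed=best & maternal,
        incompatible_offspring=incompatible,
        n_informative=len(compat),
        status=status,
    )


def infer_brood(
    brood: Brood,
    max_incompatible_frac: float = DEFAULT_MAX_INCOMPATIBLE_FRAC,
    min_allele_support: int = DEFAULT_MIN_ALLELE_SUPPORT,
) -> list[LocusInheritance]:
    """Run :func:`infer_locus` over every locus of a brood, in declared order."""
    return [
        infer_locus(brood, loc, max_incompatible_frac, min_allele_support)
        for loc in brood.loci
    ]


def summarize_family(
    brood: Brood,
    inferences: Sequence[LocusInheritance] | None = None,
    max_incompatible_frac: float = DEFAULT_MAX_INCOMPATIBLE_FRAC,
    min_allele_support: int = DEFAULT_MIN_ALLELE_SUPPORT,
) -> InheritanceSummary:
    """Tally 1-allele vs 2-allele inheritance per parent over a family's loci.

    Loci whose inference status is not ``"ok"`` count as uncertain for both
    parents (the per-parent determination rests on the same subtraction).
    """
    if inferences is None:
        inferences = infer_brood(brood, max_incompatible_frac, min_allele_support)
    tallies = {"maternal": [0, 0, 0], "paternal": [0, 0, 0]}  # [n1, n2, nunc]
    for inf in inferences:
        for parent, count in (("maternal", inf.maternal_count),
                              ("paternal", inf.paternal_count)):
            if count is None:
                tallies[parent][2] += 1
            elif count == 1:
                tallies[parent][0] += 1
            else:
                tallies[parent][1] += 1
    return InheritanceSummary(
        family_id=brood.family_id,
        species=brood.species,
        maternal=ParentTally(*tallies["maternal"]),
        paternal=ParentTally(*tallies["paternal"]),
    )


def mean_alleles(
    summaries: Iterable[InheritanceSummary],
    species: str,
    parent: str,
    method: str = "family_mean",
) -> float:
    """Mean number of alleles (1 or 2) a brood inherits from one parent.

    ``method="family_mean"`` (default) averages within each family over its
    determinate loci, then averages the family means; ``method="pooled"``
    pools all determinate loci across families.  Uncertain loci are excluded
    either way.
    """
    per_family: list[tuple[int, int]] = []  # (n1, n2)
    for s in summaries:
        if s.species != species:
            continue
        t = s.tally(parent)
        if t.n_loci_1_allele + t.n_loci_2_alleles > 0:
            per_family.append((t.n_loci_1_allele, t.n_loci_2_alleles))
    if not per_family:
        raise ValueError(f"no determinate loci for species {species!r}")
    if method == "family_mean":
        return mean((n1 + 2 * n2) / (n1 + n2) for n1, n2 in per_family)
    if method == "pooled":
        n1 = sum(a for a, _ in per_family)
        n2 = sum(b for _, b in per_family)
        return (n1 + 2 * n2) / (n1 + n2)
    raise ValueError(f"unknown method {method!r}")


def inference_table(inferences: Iterable[LocusInheritance]):
    """Per-locus inference results as a DataFrame (the on-disk CSV layout)."""
    import pandas as pd

    rows = []
    for inf in inferences:
        rows.append({
            "family": inf.family_id,
            "locus": inf.locus_id,
            "maternal_count": inf.maternal_count if inf.maternal_count is not None else "NA",
            "paternal_count": inf.paternal_count if inf.paternal_count is not None else "NA",
            "paternal_alleles": ";".join(sorted(inf.paternal_alleles)),
            "shadowed_flags": ";".join(sorted(inf.shadowed)),
            "n_incompatible": len(inf.incompatible_offspring),
            "n_informative": inf.n_informative,
            "status": inf.status,
        })
    return pd.DataFrame(rows)
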