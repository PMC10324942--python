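import itertools

import pytest
from hypothesis import HealthCheck, settings

from pgekit.genotype_io import Brood, GenotypeCall, IndividualGenotypes

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_brood(mother, offspring, family="F1", species="testsp"):
    """Build a Brood from per-locus allele pairs.

    *mother* maps locus -> (a, b) or None (missing); *offspring* is a list of
    such dicts.  All individuals must share the mother's locus keys.
    """
    loci = tuple(mother)

    def calls(indiv, genotype):
        out = {}
        for locus in loci:
            pair = genotype[locus]
            if pair is None:
                out[locus] = GenotypeCall(indiv, locus, (), missing=True)
            else:
                out[locus] = GenotypeCall(indiv, locus, (str(pair[0]), str(pair[1])))
        return IndividualGenotypes(indiv, out)

    return Brood(
        family_id=family,
        species=species,
        loci=loci,
        mother=calls(f"{family}_M", mother),
        offspring=tuple(
            calls(f"{family}_O{i + 1}", g) for i, g in enumerate(offspring)
        ),
    )


def brute_force_paternal(mother_alleles, offspring_genotypes):
    """Independent exhaustive solver for the minimal paternal allele set.

    Enumerates every subset of the alleles observed in mother-compatible
    offspring, smallest first, and applies the same tie-break as the
    package: fewest maternal-shared alleles, then lexicographic.  Returns
    (paternal_set, incompatible_indices).
    """
    M = frozenset(mother_alleles)
    compat, incompatible = [], []
    for i, g in enumerate(offspring_genotypes):
        if set(g) & M:
            compat.append(tuple(g))
        else:
            incompatible.append(i)
    if not compat:
        return frozenset(), incompatible
    alleles = sorted({a for g in compat for a in g})

    def ok(S):
        return all(
            (x in M and y in S) or (y in M and x in S) for x, y in compat
        )

    for k in range(1, len(alleles) + 1):
        feasible = [frozenset(c) for c in itertools.combinations(alleles, k)
                    if ok(frozenset(c))]
        if feasible:
            return (
                min(feasible, key=lambda S: (len(S & M), tuple(sorted(S)))),
                incompatible,
            )
    raise AssertionError("unreachable: compatible offspring always explainable")


@pytest.fixture
def simple_pge_brood():
    """Mother A/B, single PGE father transmitting C at both loci."""
    return make_brood(
        mother={"L1": ("A", "B"), "L2": ("A", "B")},
        offspring=[{"L1": ("A", "C"), "L2": ("B", "C")} for _ in range(5)]
        + [{"L1": ("B", "C"), "L2": ("A", "C")} for _ in range(5)],
    )
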