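"""Simulators for brood genotype tables and mother/son allele-count tables.

Two generative models are provided, each with a truth record sufficient to
recompute every expected pipeline output exactly:

* :func:`simulate_brood` draws microsatellite genotypes for families (one
  mother, one or more fathers, up to 20 male offspring) under either PGE
  transmission — each father passes a single multilocus haplotype, completely
  linked across loci, to all his offspring — or Mendelian transmission, where
  each paternal allele is a fair independent draw per locus.  Genotyping
  error is applied last: an allele miscall swaps a call to a random other
  allele of the locus, and dropout collapses a genotype to an apparent
  single-allele homozygote.

* :func:`simulate_ase` draws per-SNP read counts for a mother and her sons.
  Sons carry one maternal and one paternal allele; the paternal allele is
  transcriptionally silenced with probability ``f`` (the silencing
  fraction).  Expressed alleles emit reads at a negative-binomial depth;
  a small fraction of reads is redirected to the "other bases" column to
  mimic sequencing error.

Loci and sites are simulated unlinked/independent, as appropriate for
markers spread over many chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import Brood, GenotypeCall, IndividualGenotypes, SnpCounts

__all__ = [
    "BroodSimConfig",
    "AseSimConfig",
    "BroodTruth",
    "FamilyTruth",
    "AseTruth",
    "AseSimResult",
    "simulate_brood",
    "simulate_ase",
    "study_design_configs",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Brood simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BroodSimConfig:
    """Generative parameters for a set of simulated families.

    Defaults mirror a realistic microsatellite family study of gall-forming
    scale insects: broods of up to 20 male offspring, 9 polymorphic loci,
    6 equifrequent alleles per locus, and small genotyping error rates
    (1% allele miscall, 2% allelic dropout).
    """

    n_families: int = 13
    species: str = "C_echiniformis"
    brood_size: int = 20
    n_loci: int = 9
    alleles_per_locus: int = 6
    allele_freqs: tuple[float, ...] | None = None  # None = uniform
    transmission: str = "PGE"  # "PGE" | "Mendelian"
    n_fathers: int = 1
    father_weights: tuple[float, ...] | None = None  # None = equal mating
    error_miscall: float = 0.01
    error_dropout: float = 0.02
    family_prefix: str = "FAM"
    #: Optional overrides (one allele-pair per locus) for calibration runs
    #: that must condition on known parental genotypes.
    fixed_mother_genotype: tuple[tuple[str, str], ...] | None = None
    fixed_father_genotypes: tuple[tuple[tuple[str, str], ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.transmission not in ("PGE", "Mendelian"):
            raise ValueError(f"transmission must be PGE or Mendelian, got {self.transmission!r}")
        if self.n_families < 1 or self.brood_size < 1 or self.n_loci < 1:
            raise ValueError("n_families, brood_size and n_loci must be positive")
        if self.n_fathers < 1:
            raise ValueError("n_fathers must be >= 1")
        for p in (self.error_miscall, self.error_dropout):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")
        if self.father_weights is not None:
            w = np.asarray(self.father_weights, dtype=float)
            if len(w) != self.n_fathers or (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("father_weights must be n_fathers non-negative values summing to 1")
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, dtype=float)
            if len(f) != self.alleles_per_locus or (f < 0).any() or not np.isclose(f.sum(), 1.0):
                raise ValueError("allele_freqs must match alleles_per_locus and sum to 1")


@dataclass(frozen=True)
class FamilyTruth:
    """Generative truth for one simulated family (pre-error genotypes)."""

    family_id: str
    mother_genotype: tuple[tuple[str, str], ...]  # per locus
    father_genotypes: tuple[tuple[tuple[str, str], ...], ...]  # father x locus
    transmitted_haplotypes: tuple[tuple[str, ...], ...] | None  # PGE only: father x locus
    father_of_offspring: tuple[int, ...]
    offspring_genotypes: tuple[tuple[tuple[str, str], ...], ...]  # offspring x locus


@dataclass(frozen=True)
class BroodTruth:
    config: BroodSimConfig
    seed_used: int | None
    families: tuple[FamilyTruth, ...]


def _allele_labels(n: int) -> list[str]:
    # fragment-length-like labels; opaque to the inference
    return [str(100 + 2 * i) for i in range(n)]


def simulate_brood(cfg: BroodSimConfig, seed=None) -> tuple[list[Brood], BroodTruth]:
    """Simulate families under the configured transmission model.

    Deterministic for a fixed config and integer *seed*: the same inputs
    always produce byte-identical tables when written out.
    """
    rng = _rng(seed)
    labels = _allele_labels(cfg.alleles_per_locus)
    freqs = (np.asarray(cfg.allele_freqs, dtype=float) if cfg.allele_freqs is not None
             else np.full(cfg.alleles_per_locus, 1.0 / cfg.alleles_per_locus))
    weights = (np.asarray(cfg.father_weights, dtype=float) if cfg.father_weights is not None
               else np.full(cfg.n_fathers, 1.0 / cfg.n_fathers))
    loci = [f"L{i + 1}" for i in range(cfg.n_loci)]

    def draw_genotype() -> tuple[str, str]:
        i, j = rng.choice(cfg.alleles_per_locus, size=2, p=freqs)
        return (labels[i], labels[j])

    broods: list[Brood] = []
    truths: list[FamilyTruth] = []
    for fam_idx in range(cfg.n_families):
        fam_id = f"{cfg.family_prefix}{fam_idx + 1:03d}"
        if cfg.fixed_mother_genotype is not None:
            mother_gt = tuple(cfg.fixed_mother_genotype)
        else:
            mother_gt = tuple(draw_genotype() for _ in loci)
        if cfg.fixed_father_genotypes is not None:
            father_gts = tuple(tuple(f) for f in cfg.fixed_father_genotypes)
        else:
            father_gts = tuple(
                tuple(draw_genotype() for _ in loci) for _ in range(cfg.n_fathers)
            )

        if cfg.transmission == "PGE":
            # one completely linked haplotype per father, shared by all his sons
            hap_choice = rng.integers(0, 2, size=(cfg.n_fathers, cfg.n_loci))
            transmitted = tuple(
                tuple(father_gts[f][l][hap_choice[f, l]] for l in range(cfg.n_loci))
                for f in range(cfg.n_fathers)
            )
        else:
            transmitted = None

        father_of = tuple(int(f) for f in rng.choice(cfg.n_fathers, size=cfg.brood_size, p=weights))
        offspring_gts = []
        for o in range(cfg.brood_size):
            f = father_of[o]
            gt = []
            for l in range(cfg.n_loci):
                m = mother_gt[l][rng.integers(0, 2)]
                if cfg.transmission == "PGE":
                    p = transmitted[f][l]
                else:
                    p = father_gts[f][l][rng.integers(0, 2)]
                gt.append((m, p))
            offspring_gts.append(tuple(gt))
        offspring_gts = tuple(offspring_gts)

        truths.append(FamilyTruth(fam_id, mother_gt, father_gts, transmitted,
                                  father_of, offspring_gts))
        broods.append(_observe_family(cfg, rng, fam_id, loci, labels,
                                      mother_gt, offspring_gts))

    truth = BroodTruth(cfg, seed if isinstance(seed, int) else None, tuple(truths))
    return broods, truth


def _observe_family(cfg, rng, fam_id, loci, labels, mother_gt, offspring_gts) -> Brood:
    """Apply genotyping error to true genotypes and assemble a Brood."""

    def observe(indiv_id: str, gt: Sequence[tuple[str, str]]) -> IndividualGenotypes:
        calls = {}
        for l, locus in enumerate(loci):
            a, b = gt[l]
            if cfg.error_miscall > 0:
                if rng.random() < cfg.error_miscall:
                    a = labels[rng.integers(0, len(labels) - 1)]
                    if a == gt[l][0]:
                        a = labels[-1]
                if rng.random() < cfg.error_miscall:
                    b = labels[rng.integers(0, len(labels) - 1)]
                    if b == gt[l][1]:
                        b = labels[-1]
            if cfg.error_dropout > 0 and a != b and rng.random() < cfg.error_dropout:
                kept = a if rng.random() < 0.5 else b
                calls[locus] = GenotypeCall(indiv_id, locus, (kept, kept),
                                            from_single_allele=True)
            else:
                calls[locus] = GenotypeCall(indiv_id, locus, (a, b))
        return IndividualGenotypes(indiv_id, calls)

    mother = observe(f"{fam_id}_M", mother_gt)
    offspring = tuple(
        observe(f"{fam_id}_O{o + 1:02d}", offspring_gts[o])
        for o in range(len(offspring_gts))
    )
    return Brood(fam_id, cfg.species, tuple(loci), mother, offspring)


def study_design_configs(
    multiple_father_families: Mapping[str, int] | None = None,
) -> list[BroodSimConfig]:
    """Configs emulating the two-species field study design.

    7 *C. campanidorsalis* families scored at 8 loci and 13 *C. echiniformis*
    families at 9 loci, broods of up to 20 male offspring, PGE transmission.
    *multiple_father_families* maps species to the number of families given
    two fathers (default: 1 of 7 and 3 of 13, matching the multiply-mated
    broods the inference is expected to flag).
    """
    multi = {"C_campanidorsalis": 1, "C_echiniformis": 3}
    if multiple_father_families:
        multi.update(multiple_father_families)
    designs = [("C_campanidorsalis", 7, 8, "CAM"), ("C_echiniformis", 13, 9, "ECH")]
    configs = []
    for species, n_fam, n_loci, prefix in designs:
        n_multi = multi.get(species, 0)
        if n_multi > n_fam:
            raise ValueError(f"{species}: more multi-father families than families")
        if n_fam - n_multi:
            configs.append(BroodSimConfig(
                n_families=n_fam - n_multi, species=species, n_loci=n_loci,
                transmission="PGE", n_fathers=1, family_prefix=f"{prefix}_S",
            ))
        if n_multi:
            configs.append(BroodSimConfig(
                n_families=n_multi, species=species, n_loci=n_loci,
                transmission="PGE", n_fathers=2, family_prefix=f"{prefix}_D",
            ))
    return configs


# ---------------------------------------------------------------------------
# ASE simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AseSimConfig:
    """Generative parameters for mother/son allele-specific expression counts.

    ``silencing_fraction`` is the probability that a son's paternally
    inherited allele is transcriptionally silent at a site; ``f=0`` is full
    biparental expression, ``f=1`` complete paternal silencing.  Depth is
    negative-binomial with the given mean and dispersion (shape) to mimic
    RNA-seq overdispersion; ``seq_error`` is the per-read probability of
    landing in the "other bases" column.
    """

    n_sites: int = 5000
    n_sons: int = 2
    maternal_het_rate: float = 0.6
    silencing_fraction: float = 0.0
    #: Probability the paternal allele differs from the son's maternally
    #: inherited allele; None matches the maternal het rate so that sons and
    #: mothers are equally heterozygous when nothing is silenced.
    paternal_divergence: float | None = None
    depth_mean: float = 100.0
    depth_dispersion: float = 5.0
    seq_error: float = 0.005
    mother_id: str = "mother"
    son_prefix: str = "son"
    contig: str = "tig1"

    def __post_init__(self) -> None:
        for name in ("maternal_het_rate", "silencing_fraction", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.paternal_divergence is not None and not 0.0 <= self.paternal_divergence <= 1.0:
            raise ValueError("paternal_divergence must lie in [0, 1]")
        if self.n_sites < 1 or self.n_sons < 1:
            raise ValueError("n_sites and n_sons must be positive")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be positive")


@dataclass(frozen=True)
class AseTruth:
    """Per-site generative truth: genotypes (0=ref, 1=alt) and silencing flags."""

    config: AseSimConfig
    mother_genotype: np.ndarray  # (n_sites, 2)
    son_maternal_allele: np.ndarray  # (n_sons, n_sites)
    son_paternal_allele: np.ndarray  # (n_sons, n_sites)
    silenced: np.ndarray  # (n_sons, n_sites) bool


@dataclass(frozen=True)
class AseSimResult:
    mother: list[SnpCounts]
    sons: list[list[SnpCounts]]
    truth: AseTruth

    @property
    def all_samples(self) -> dict[str, list[SnpCounts]]:
        out = {self.truth.config.mother_id: self.mother}
        for son in self.sons:
            out[son[0].sample_id] = son
        return out


def _emit_counts(rng, sample_id, cfg, ref_prob: np.ndarray) -> list[SnpCounts]:
    """Draw (ref, alt, other) per site given the expressed ref fraction."""
    n = cfg.n_sites
    p_nb = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
    depth = rng.negative_binomial(cfg.depth_dispersion, p_nb, size=n)
    other = rng.binomial(depth, cfg.seq_error)
    informative = depth - other
    ref = rng.binomial(informative, ref_prob)
    alt = informative - ref
    return [
        SnpCounts(sample_id, cfg.contig, i + 1, int(ref[i]), int(alt[i]), int(other[i]))
        for i in range(n)
    ]


def simulate_ase(cfg: AseSimConfig, seed=None) -> AseSimResult:
    """Simulate mother and son per-SNP counts under a paternal-silencing model.

    Sites are ascertained biallelic SNPs.  The mother is heterozygous
    (ref/alt) at each site with ``maternal_het_rate``, otherwise homozygous
    ref or alt with equal probability.  Each son inherits one maternal allele
    (fair draw) and one paternal allele that differs from it with probability
    ``paternal_divergence`` (default: the maternal het rate, so unsilenced
    sons are as heterozygous as their mother); the paternal allele is
    silenced with probability ``silencing_fraction``, in which case only the
    maternal allele emits reads.
    """
    rng = _rng(seed)
    n = cfg.n_sites
    divergence = (cfg.paternal_divergence if cfg.paternal_divergence is not None
                  else cfg.maternal_het_rate)

    het = rng.random(n) < cfg.maternal_het_rate
    hom_alt = rng.random(n) < 0.5
    # allele codes: 0 = ref, 1 = alt; mother genotype ordered (allele_a, allele_b)
    mother_gt = np.zeros((n, 2), dtype=np.int8)
    mother_gt[het, 1] = 1
    mother_gt[~het, 0] = hom_alt[~het]
    mother_gt[~het, 1] = hom_alt[~het]

    mother_ref_prob = 1.0 - mother_gt.mean(axis=1)  # 1, 0.5, or 0
    mother_counts = _emit_counts(rng, cfg.mother_id, cfg, mother_ref_prob)

    son_maternal = np.empty((cfg.n_sons, n), dtype=np.int8)
    son_paternal = np.empty((cfg.n_sons, n), dtype=np.int8)
    silenced = np.empty((cfg.n_sons, n), dtype=bool)
    sons = []
    for s in range(cfg.n_sons):
        pick = rng.integers(0, 2, size=n)
        son_maternal[s] = mother_gt[np.arange(n), pick]
        flip = rng.random(n) < divergence
        son_paternal[s] = son_maternal[s] ^ flip
        silenced[s] = rng.random(n) < cfg.silencing_fraction
        # expressed ref fraction: maternal allele only when silenced, else
        # the mean of the two expressed alleles (0, 0.5 or 1 in ref coding)
        expressed_alt = np.where(
            silenced[s],
            son_maternal[s].astype(float),
            (son_maternal[s] + son_paternal[s]) / 2.0,
        )
        sons.append(_emit_counts(rng, f"{cfg.son_prefix}{s + 1}", cfg, 1.0 - expressed_alt))

    truth = AseTruth(cfg, mother_gt, son_maternal, son_paternal, silenced)
    return AseSimResult(mother_counts, sons, truth)
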