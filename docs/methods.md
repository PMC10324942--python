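# Methods

## The inference problem

In scale insects with paternal genome elimination (PGE), males are diploid
but eliminate or silence the chromosomes they inherited from their father;
sperm carry only the maternally derived haplotype. Families can be collected
from the field as a mother plus a brood of her sons, but fathers cannot be
sampled, and one brood may have several fathers. `pgekit` infers the
paternal contribution indirectly, from two data types: microsatellite
genotypes of mother + sons, and allele-specific expression (ASE) counts at
SNPs in mother + sons.

## Brood inference by maternal subtraction

Let *M* be the mother's allele set at a locus (1 or 2 labels; alleles are
opaque strings compared only for equality, since fragment-length magnitudes
carry no information for this inference). Every son genotype {x, y} must
decompose as {m, p} with m ∈ M and p drawn from the paternal pool. The
inference returns the **minimum-cardinality set S** of observed alleles such
that all mother-compatible sons decompose; it is found by exhaustive subset
search over the alleles observed in compatible sons, smallest cardinality
first. With ≤ ~10 distinct alleles per locus this is instantaneous, and an
independent brute-force enumeration is used in the test suite to confirm
exactness.

Choices a maintainer should know about:

* **Tie-breaking.** Among equal-cardinality solutions, the set sharing the
  fewest alleles with the mother wins (a paternal allele identical to a
  maternal one — a *shadowed* allele — is the less parsimonious reading of a
  subtraction), then ties break lexicographically on the label tuple. This
  makes the inference deterministic and invariant to input order.
* **Incompatible sons.** A son sharing no allele with the mother cannot be
  decomposed under any S; it is flagged as a putative genotyping error,
  excluded, and counted. A locus with > 20% incompatible sons
  (`max_incompatible_frac`, configurable) is scored *uncertain*.
* **Weakly supported alleles.** When |S| ≥ 2 and some allele of S is
  *required* by fewer than `min_allele_support = 2` sons (i.e. S minus that
  allele explains all but < 2 of them), the locus is scored uncertain rather
  than 2-allele: a single aberrant son is far more plausibly a miscall or
  dropout than evidence of a second father. This guard is what keeps the
  1–2% simulated genotyping-error rates from inflating the paternal allele
  counts; it can be disabled (`min_allele_support=1`), and the error-free
  closed-form recovery properties in the tests are stated for the pure
  minimal-set inference with the guard off.
* **Apparent homozygotes.** A single-peak call is stored as {a, a} with a
  flag (dropout cannot be excluded); inference treats it as homozygous.

Per family, loci are tallied into 1-allele / 2-allele / uncertain per parent
(the maternal count is the number of maternal alleles actually used in
decompositions). The species-level mean allele count averages within family
over determinate loci and then across families (`family_mean`); pooling all
loci (`pooled`) is also reported, since published means rarely state the
convention.

## Discriminating multiple PGE fathers from one Mendelian father

A brood with 2 paternal alleles at k ≥ 2 loci admits two explanations. Under
PGE, each father transmits one completely linked multilocus haplotype, so
two fathers yield at most 2 of the 2^k paternal-allele combinations. A
single heterozygous non-PGE father assorts unlinked loci independently
(microsatellite panels of this size on genomes with many chromosomes make
linkage between marker loci unlikely), giving all 2^k combinations at equal
frequency n/2^k.

The test resolves each son's paternal allele per locus by subtraction (sons
where both alleles could be paternal are excluded; all-or-none across the k
loci), tabulates all 2^k cells including zeros, and computes the χ²
goodness-of-fit statistic with df = 2^k − 1. Numerical choices:

* **Small samples.** When any expected count is below 5 the asymptotic p is
  unreliable; a Monte-Carlo multinomial p-value (20,000 draws, seeded,
  add-one correction) is computed alongside and used for the verdict.
* **Low-frequency combinations.** Observed combinations with count ≤ 1 or
  ≤ 10% of the brood are flagged as putative genotyping errors. They stay
  in the χ² but do not count against the "≤ 2 major combinations" bound
  that, together with rejection at α = 0.01, yields the verdict
  *consistent with multiple PGE fathers*. Rejection with > 2 major
  combinations, or broods under `min_brood = 5`, are *inconclusive*.
* Calibration under the null (single Mendelian father, brood 20, 2 loci) is
  checked by simulation: the rejection rate at α = 0.05 sits within
  5% ± 1.5% over 2,000 replicates, and power against two disjoint-allele
  PGE fathers is ~100% (the minimum attainable χ² for a 20-son brood split
  over two linked haplotypes is already 20).

## Parent-of-origin mixed model

Whether broods inherit fewer alleles from fathers than mothers is tested
with a binomial GLMM. Each brood × parent contributes the pair (loci with 2
inherited alleles, loci with 1); fixed effects are parent of origin
(maternal = 1) and species; an observation-level random intercept absorbs
extra-binomial variation between broods. The package expands the pairs to
Bernoulli rows sharing a random intercept per observation — an identical
likelihood — and fits the model with the statsmodels Bayesian mixed GLM by
Laplace approximation (posterior mode with weak N(0, 2²) priors; the random
start point upstream is replaced by the prior mode so fits are exactly
reproducible). Posterior SDs from the Laplace fit run somewhat smaller than
`glmer` Wald standard errors; an `lme4` backend through `Rscript` is
provided and the test suite cross-checks the two on simulated data (same
sign, significance, and estimates within ~0.6 log-odds). If the fit fails,
the pooled 2×2 counts are compared by Fisher's exact test and flagged as a
fallback.

## ASE bias classification and the mother/son comparison

For each SNP and sample, allele bias is b = ref/(ref + alt). Sites are
first filtered: depth (ref+alt+other) < 40, or other-base proportion > 5%.
Classification: heterozygous expression for b ∈ [0.2, 0.8] (boundaries
inclusive), homozygous for b < 0.1 or b > 0.9 (boundaries exclusive — the
gaps (0.1, 0.2) and (0.8, 0.9) are *unclassified*). The boundary handling
is an arbitrary but documented fixed choice. The bias denominator can
optionally include other bases (`bias_includes_other`), but defaults to
ref+alt since other-heavy sites are already removed. Fractions are reported
with the unclassified sites in the denominator (het/(het+hom+unclassified))
and without, because published percentages rarely state which is meant.

Paternal silencing predicts an excess of homozygous expression in sons.
Each son's hom fraction is compared with the mother's marginal hom fraction
by a one-sided two-proportion z-test (a shared site universe is not
required); the family-level *silencing signal* is declared only when every
son shows a significant excess at α = 0.01. The test is an addition to what
is usually a descriptive comparison, so `mode="paper-faithful"` disables it
and reports differences only.

## Synthetic data

The simulators define the study conditions the pipeline is validated under.

**Broods.** Defaults: 13 families (a `study_design_configs()` helper builds
the two-species layout of 7 families × 8 loci plus 13 families × 9 loci,
with 1 and 3 two-father families respectively), brood size 20, 9 unlinked
loci, 6 equifrequent alleles per locus. Mothers and fathers are drawn from
the allele frequencies; under PGE each father commits to one transmitted
haplotype (one allele per locus, fully linked) shared by all his sons;
under Mendelian transmission each paternal allele is a fair independent
draw per locus. Genotyping error is applied last to every individual:
allele miscall (ε_call = 0.01, replacement uniform over the other alleles)
and dropout of heterozygotes to apparent single-peak homozygotes
(ε_drop = 0.02); both rates are plausible for manually scored
microsatellites but are not estimates. Calibration runs can pin parental
genotypes (`fixed_mother_genotype` / `fixed_father_genotypes`) so that the
χ² null is exactly a uniform multinomial.

**ASE counts.** Sites are ascertained biallelic SNPs: the mother is
heterozygous with rate 0.6 (mirroring the het fractions seen in real
mother transcriptomes), sons inherit one maternal allele (fair draw) plus a
paternal allele that differs from it with probability equal to the maternal
het rate — this matched divergence makes unsilenced sons exactly as
heterozygous as their mother, which is the null the comparison needs. The
paternal allele is silenced with probability f. Depth is negative binomial
(mean 100, dispersion 5) to mimic RNA-seq overdispersion; 0.5% of reads are
redirected to the other-bases column.

What the simulations do **not** emulate: population allele-frequency
structure at SNPs (sites are exchangeable), mapping bias toward the
reference allele, locus-specific expression levels or cis-regulatory
variation, linkage between SNPs on one transcript, and partial or
tissue-specific silencing of individual chromosomes. Passing recovery tests
therefore validates the inference logic and its calibration, not robustness
to every artifact of real RNA-seq data.

## Problem sizes used in validation

Oracle agreement: 500 random broods (≤ 8 sons, ≤ 5 alleles). PGE fixed
point: 1,000 error-free families. Mendelian contrast: 1,000 families × 2
fully informative loci against the closed form 1 − 2^(1−n). χ² calibration:
2,000 null broods; power: 500. Classifier contract: 10,000 random count
triples. Silencing recovery: 120 replicates per f ∈ {0, 1} at 5,000 sites
(60 in the acceptance script), and a 5-point f grid × 200 replicates × 800
sites for monotonicity of the homozygosity excess. The mixed-model power
check runs 40 replicate fits of the 20-family design.

## Known limitations

* The inference is deterministic subtraction, not likelihood-based sibship
  reconstruction; it does not estimate the number of fathers beyond the
  ≤ 2-haplotype consistency check, and it cannot phase which allele is
  paternal when both of a son's alleles are maternal-compatible.
* The χ² discriminator assumes unlinked marker loci and equal mating
  proportions enter only through power, not validity.
* The Laplace GLMM fit shrinks estimates slightly toward zero relative to
  `glmer`; for publication-grade coefficients use the `lme4` backend.
* ASE classification operates on marginal per-sample counts; without the
  father's genotype, "homozygous expression" conflates true homozygosity
  with monoallelic expression, which is exactly why the mother is the
  within-family control.
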