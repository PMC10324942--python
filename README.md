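# pgekit

Inference of **paternal genome elimination (PGE)** from family genotype data,
and of paternal-genome **silencing** from allele-specific expression (ASE)
counts.

Under PGE, males are diploid but transmit only their maternally inherited
chromosomes through sperm. In insects such as scale insects this cannot be
observed directly in field-collected material, but it leaves two signatures
that *can* be measured:

1. **Transmission.** Genotype a mother and a brood of her sons at
   microsatellite loci. Subtracting the maternal genotype from each son's
   genotype reconstructs the paternal contribution. A PGE father passes a
   single haplotype to every son (one paternal allele per locus per father,
   completely linked across loci); a Mendelian heterozygous father passes
   two alleles that assort independently.
2. **Expression.** Count RNA-seq reads over reference and alternate alleles
   at SNPs in a mother and her sons. If the paternal genome of sons is
   transcriptionally silenced, sons show an excess of homozygously expressed
   SNPs relative to their mother.

`pgekit` implements both inference chains plus simulators for the two data
types, so every stage can be validated against known generative truth.

## What it computes

* **Brood inference** (`pgekit.brood_inference`) — for each family and locus,
  the minimum-cardinality paternal allele set *S* such that every
  mother-compatible son genotype decomposes as {*m*, *p*} with *m* a maternal
  and *p* ∈ *S* a paternal allele (exhaustive subset search, smallest set
  first; ties prefer alleles not shared with the mother). Sons sharing no
  allele with the mother are flagged as genotyping errors; loci whose extra
  paternal alleles rest on a single son are scored *uncertain*.
* **Multiple-paternity test** (`pgekit.transmission_tests`) — for broods with
  2 paternal alleles at ≥ 2 loci, a χ² goodness-of-fit of the observed
  multilocus paternal-allele combinations against the uniform expectation
  *n*/2^k from one non-PGE heterozygous father, df = 2^k − 1, with a seeded
  Monte-Carlo multinomial p-value when expected cell counts are small. Two
  PGE fathers can only produce 2 of the 2^k combinations.
* **Parent-of-origin model** — a binomial mixed model of (loci with 2
  inherited alleles, loci with 1) per brood × parent, with parent-of-origin
  and species as fixed effects and an observation-level random intercept
  (fitted by Laplace approximation; an lme4/`glmer` backend via `Rscript` is
  available).
* **ASE bias classification** (`pgekit.ase_bias`) — allele bias
  *b* = ref/(ref+alt); heterozygous for *b* ∈ [0.2, 0.8], homozygous for
  *b* < 0.1 or *b* > 0.9, after removing sites with > 5% other bases or
  depth < 40; per-son one-sided two-proportion z-test for an excess of
  homozygous expression over the mother.
* **Simulators** (`pgekit.synthetic_data`) — broods under PGE or Mendelian
  transmission with configurable fathers, allele frequencies and genotyping
  error; mother/son SNP counts under a silencing fraction *f* ∈ [0, 1], with
  truth records for recovery testing.

## Worked example

Simulate six single-father PGE families (brood size 20, 9 loci, realistic
genotyping error) and run the full inheritance analysis:

```sh
pgekit simulate-broods --seed 11 --out demo/pge --n-families 6
pgekit run-inheritance --broods demo/pge/broods.csv --out demo/run --seed 1
```

```
family FAM001 (C_echiniformis, n=20): maternal 1/2/unc = 1/5/3, paternal = 5/1/3
family FAM002 (C_echiniformis, n=20): maternal 1/2/unc = 0/5/4, paternal = 5/0/4
...
C_echiniformis: mean alleles per brood — maternal 1.92, paternal 1.03 (family-mean convention)
parent-of-origin effect (glmm_laplace): est = 4.58, s.e. = 0.74, z = 6.23, p = 4.8e-10

overall: PGE-consistent
```

Each family line tallies loci where the brood inherited 1 allele, 2 alleles,
or an uncertain number from each parent. Mothers (mostly heterozygous here)
transmit close to 2 alleles per locus; PGE fathers transmit ~1, and the
mixed-model parent-of-origin effect (log-odds of a 2-allele locus, maternal
vs paternal) is strongly positive — the PGE signature.

A brood whose mother mated with *two* PGE males shows 2 paternal alleles at
several loci, but the combinations are locked into the two paternal
haplotypes:

```sh
pgekit simulate-broods --seed 12 --out demo/multi --n-families 2 --n-fathers 2 --n-loci 4
pgekit test-transmission --broods demo/multi/broods.csv --out demo/transmission.csv --seed 1
```

```
family,k_loci,n_complete,chi2,df,p_value,p_exact,n_combos,verdict
FAM001,2,19,19.95,3,1.7e-04,1.0e-04,2,consistent_with_multiple_PGE_fathers
FAM002,3,19,57.21,7,5.4e-10,5.0e-05,2,consistent_with_multiple_PGE_fathers
```

Only 2 of the 4 (or 8) possible combinations are observed, inheritance is
decidedly non-random (p < 0.01), so these broods reflect multiple mating by
PGE males rather than a Mendelian father.

The expression side works the same way: `pgekit simulate-ase` writes
mother/son count tables under a chosen silencing fraction, and
`pgekit run-expression` classifies each SNP and tests each son for a
homozygosity excess, reporting "paternal silencing detected" or "biparental
expression" per family.

## Layout

```
src/pgekit/
  genotype_io.py        brood CSV + ASEReadCounter/minimal count dialects
  brood_inference.py    maternal-subtraction inference, per-family summaries
  transmission_tests.py haplotype tables, χ² discriminator, binomial GLMM
  ase_bias.py           SNP filtering, bias classification, mother/son tests
  synthetic_data.py     brood and ASE simulators with truth records
  workflow.py, cli.py   orchestration and the pgekit command-line surface
```

See `docs/methods.md` for the models, their assumptions, and the numerical
choices.
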