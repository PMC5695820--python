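# admixscan

Admixture mapping of quantitative traits in admixed cohorts: local-ancestry
association scans under multi-component linear mixed models, ancestry-specific
allele-frequency estimation, conditional fine-mapping, and the analytic power
theory that motivates the approach.

## The problem

In admixed populations such as US Hispanics/Latinos — a three-way mixture of
European, African, and Amerindian ancestries — trait-associated alleles whose
frequencies differ between the ancestral populations leave a signal in *local
ancestry*: the count (0, 1 or 2) of chromosome copies an individual inherited
from a given ancestry over a genomic interval (an LAI). Admixture mapping
regresses the trait on these counts across the genome. It complements standard
GWAS: the causal variant need not be genotyped or imputed, and the number of
intervals (~1.5 × 10⁴) is far below the number of variants, reducing the
multiple-testing burden.

The package implements the full workflow used in blood-pressure admixture
mapping of large Hispanic/Latino cohort studies, plus a synthetic-cohort
generator with known ground truth so every stage is testable without any
restricted data:

1. **Phenotype preparation** — +10/+5 mmHg medication adjustment of SBP/DBP,
   derived traits PP = SBP − DBP and MAP = DBP + PP/3, measurement-consistency
   (≥ 5 mmHg), range (SBP < 80, DBP < 50), and missing-data exclusions with an
   audited reason log, and winsorization of PP at mean + 6 SD.
2. **Null mixed model** — for trait *y* with covariates *X* (sex, age, centre,
   sampling weight, 5 ancestry PCs):

   *y* = *Xβ* + *g* + *h* + *u* + *e*, where
   *g* ~ N(0, σ²₍kin₎ **K**) is a polygenic effect over the kinship matrix
   **K**, *h* ~ N(0, σ²₍hh₎ **Z**ₕ**Z**ₕ′) and *u* ~ N(0, σ²₍blk₎ **Z**ᵦ**Z**ᵦ′)
   are shared household and census-block effects, and *e* is the residual.
   Variance components are estimated by REML
   (`AdmixtureMixedModel(...).fit()` → `MixedModelResults`).
3. **Genome scan** — 1-df Wald tests of each ancestry's LAI counts (and joint
   2-df tests of two ancestries) with variance components held at the null
   fit; significance at the genome-wide admixture level 5.68 × 10⁻⁵;
   contiguous significant LAIs merged into association regions; simpleM
   effective-number-of-traits from the trait correlation matrix.
4. **Fine-mapping** — a step-wise candidate ladder (p-value rungs
   10⁻⁶ … 10⁻², with group-EAF-difference filters 0.2/0.15/0.1/0.05 at the
   lenient rungs), correlation pruning at |r| ≤ 0.4, conditional admixture
   scans adjusting for lead-variant dosages, and classification of how much
   of the LAI signal the candidates explain.
5. **Ancestry-specific EAFs** — EM estimation of per-ancestry effect-allele
   frequencies from unphased dosages and local-ancestry diplotypes.
6. **Power theory** — in a two-ancestry model the population admixture-mapping
   slope is β₁p₁ − β₂p₂ (the causal effect down-weighted by the ancestral
   allele-frequency difference, and nonzero under effect-size heterogeneity
   even at equal frequencies); analytic two-sided power from the Wald
   noncentrality n·b²·Var(Z)/σ²₍resid₎ for both the ancestry-count and the
   dosage test.
7. **Replication** — one-sided tests in the discovery direction with
   Bonferroni thresholds (0.05/6 = 0.008 for six tests).

## Worked example

```python
from admixscan.theory import TwoAncestryModel, power_compare

m = TwoAncestryModel(q=0.5, p1=0.9, p2=0.1, beta1=0.3, beta2=0.3,
                     sigma2=1.0, n=500)
pc = power_compare(m, causal_typed=False)
print(f"admixture slope   : {pc.slope_admixture:.3f}")
print(f"admixture power   : {pc.power_admixture:.3f}")
print(f"association power : {pc.power_association:.3f}")
```

prints

```
admixture slope   : 0.240
admixture power   : 0.964
association power : 0.000
```

With an 80-point ancestral allele-frequency contrast and the causal variant
untyped, testing local ancestry detects the locus with 96% power while
association testing cannot see it at all — the regime where admixture mapping
dominates.

Running the full synthetic pipeline:

```bash
admixscan run --seed 3 --out runs/demo
```

simulates a two-group (Mainland/Caribbean-style) three-ancestry cohort with a
planted causal variant, prepares the four BP traits, fits the null mixed
models, scans Amerindian LAI counts, merges significant regions, walks the
fine-mapping ladder, and reports — for the demo seed — the planted variant
admitted at the 10⁻⁶ rung, selected as the lead after pruning, and a "full"
classification (the conditional lead-LAI p-value rises from ~10⁻⁹ to ~0.6
once the variant is adjusted for).

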