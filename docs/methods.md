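# Methods

This note documents the models, numerical choices, and limitations behind
`admixscan`, in the order the pipeline runs them.

## Synthetic cohort generator

The generator produces an admixed cohort with a fully known data-generating
process so that every downstream estimator can be validated against planted
truth.

**Local ancestry.** Each haplotype is a mosaic of ancestry tracts along a
chromosome measured in Morgans. Switch points follow a homogeneous Poisson
process with rate equal to the number of generations since admixture (per
Morgan), and each tract's ancestry is drawn independently from the
individual's admixture proportions. Individual proportions are drawn from a
Dirichlet distribution centred at the genetic-analysis-group profile
(concentration 30 by default), which creates the continuous ancestry gradient
that principal components adjust for. Default group profiles emulate the
Mainland/Caribbean contrast: a "Mainland" group at (0.45 European, 0.10
African, 0.45 Amerindian) and a "Caribbean" group at (0.65, 0.27, 0.08).
Intervals are equal-width in genetic distance, emitted as 0-based half-open
physical coordinates at 1 cM/Mb. The model has no background LD, no drift,
and no recombination-map heterogeneity; it realises exactly the
independent-chromosome assumptions of the power theory below, which is the
point — passing tests show the estimators are correct under that law, not
that real LD patterns are handled.

**Genotypes.** A variant is defined by per-ancestry effect-allele
frequencies p_k; each haplotype carries the allele with probability p_k of
its ancestry at the covering interval, and the dosage is the sum over the
two copies. The generator also records, per individual, the allele count
split by ancestral background — the quantity the ancestry-specific effects
act on.

**Phenotypes.** The trait model is the generative counterpart of the
analysis LMM: intercept + covariate effects (age 0.35 mmHg/yr, sex 4 mmHg,
a centre offset) + Σ_k β_k × (ancestry-k allele count) + kinship + household
+ block + residual Gaussian effects. Kinship is realised through sibling
pairs sharing a household (relationship 0.5 on the unit-diagonal scale);
additional two-person households of *unrelated* individuals are generated
because they are what identifies the household variance apart from the
kinship variance (sibling-pair covariance is 0.5σ²_kin + σ²_hh, unrelated
cohabitants share only σ²_hh). Sibling local-ancestry tracts are drawn
independently — the kinship random effect stands for genome-wide polygenic
background, not for sharing at the focal interval. Default variance
components (4, 6, 2, 120 mmHg²) give an SBP standard deviation near 11.5
mmHg with modest familial and household clustering, in line with
epidemiological BP data.

Anti-hypertensive treatment is drawn from a logistic model in the latent
SBP (midpoint 140 mmHg, scale 8); treated individuals' *measured* pressures
are 10/5 mmHg below the latent value, so the standard +10/+5 adjustment in
the preparation step recovers the latent scale exactly. Device-summary and
raw-measure means are both emitted, with a small rate (0.5%) of discordant
pairs to exercise the consistency filter.

**Planted causal effect.** The default demonstration variant has ancestry
allele frequencies (0.1, 0.1, 0.5) — a 0.4 Amerindian-vs-other contrast —
and per-allele effect 9 mmHg on every background. The effect size is chosen
from the Wald noncentrality formula so that a cohort of ~1,000–1,400
simulated individuals has ≳95% power at the genome-wide admixture level:
the simulations run at roughly a tenth of the real cohort size, and the
planted slope (9 × 0.4 = 3.6 mmHg per ancestry count) preserves the
detection noncentrality that a ~1 mmHg slope has at full scale. Effect
sizes this large are not typical of BP variants; they are a deliberate
scaled-down-design choice, not a claim about genetic architecture.

## Phenotype preparation

Rules are applied in a fixed order, and each dropped record carries the
first rule it failed: (1) device-vs-raw mean disagreement ≥ 5 mmHg on
either trait; (2) missing outcomes or covariates (including the medication
flag); (3) SBP < 80 or DBP < 50, strict inequalities, on the
medication-adjusted scale; (4) negative pulse pressure. PP values above
mean + 6 SD — both moments computed on the sample retained after all
exclusions — are replaced by exactly that cap, leaving the sample size
unchanged, and MAP is recomputed from the capped PP. The procedure is
idempotent.

MAP is computed as DBP + PP/3, the physiological definition of mean
arterial pressure; the alternative DBP − PP/3 (which would place MAP below
DBP) is available behind a flag for comparison with sources that print the
formula that way.

## Null mixed model and tests

REML is maximised over the log-variances with L-BFGS-B (bounds at ±
generous multiples of the phenotypic variance act as the non-negativity
constraint; a component landing on the lower bound is reported as zero).
Starting values split the phenotypic variance equally across active
components, so fits are deterministic. Components whose design matrix
equals the identity (identity kinship, all-singleton clusters) are dropped
up front — they are exactly confounded with the residual. With no random
structure at all the REML optimum is closed-form (σ̂² = RSS/(n−p)) and the
model takes that path directly. Convergence tolerance is 1e-8 on the
relative restricted likelihood. Asymptotic variance-component standard
errors, when requested, come from the REML expected information
I_ij = tr(P G_i P G_j)/2.

Marker and LAI tests are Wald tests of focal columns appended to the null
design with variance components held at the null fit — the standard
mixed-model GWAS device; the null covariance is factorized once and reused
for every test, and a per-marker refit is available by refitting the model
with the marker in the design. Sampling weights enter as a fixed covariate
among the adjustments rather than as observation weights. A focal column
whose projected sum of squares is below 1e-8 of its unprojected value is
declared collinear and reported by name. Monomorphic LAIs are emitted with
NaN statistics and a flag rather than dropped, so scan row counts are
conserved.

The 2-df joint test models the counts of two ancestries together against
the baseline of the third; the three count columns sum to 2, so testing
all three is a collinearity error by construction.

## Scan, regions, simpleM

Significance uses the genome-wide admixture-mapping threshold 5.68 × 10⁻⁵
as a configured constant (its derivation, from the autocorrelation of
local-ancestry processes, is outside this package's scope). Significant
LAIs merge into regions when strictly adjacent on a chromosome (no gap
tolerance); the lead LAI is the smallest p, ties broken leftmost. The
effective number of traits is the simpleM estimate: the smallest m such
that the top-m eigenvalues of the trait correlation matrix capture ≥ 99.5%
of total variance.

## Ancestry-specific allele-frequency EM

Treating local ancestry as known, each chromosome copy carries the effect
allele with probability p_k of its ancestry and the genotype is the
unphased sum. The only latent structure is which copy of a mixed-ancestry
heterozygote carries the allele; the E-step assigns it with posterior odds
p_a(1−p_b) : p_b(1−p_a), and the M-step divides expected allele counts by
ancestry chromosome counts. Initialisation at the pooled frequency,
tolerance 1e-8 on the log-likelihood, maximum 1000 iterations; ascent is
asserted at every iteration. Imputed (non-integer) dosages are rounded to
the nearest integer by default — the likelihood is defined on allele
counts — with a flag to exclude them instead. Ancestries with zero
chromosomes at the variant return NaN.

## Fine-mapping ladder, pruning, conditional scans

The candidate ladder walks p-value rungs 10⁻⁶, 10⁻⁵, 10⁻⁴ (admission on p
alone, in any of the overall/Mainland/Caribbean analyses), then the lenient
rungs 10⁻³ and 10⁻² under decreasing group-EAF-difference requirements 0.2,
0.15, 0.1, 0.05 between the groups with the highest and lowest proportion
of the tested ancestry. The search stops after the first completed step
that admits at least one candidate (a flag accumulates across all steps
instead). The EAF-difference sequence ends at 0.05 — consistent with the
"at least 5%" most-lenient rule — and is configurable.

Pruning builds a graph with edges at |Pearson r| > 0.4 between candidate
dosages and keeps, per connected component (single linkage), the variant
with the smallest p (ties: smallest position); zero-variance dosages have
undefined correlation and are treated as unlinked. Conditional scans re-run
the LAI tests with lead dosages as extra fixed covariates at the null
variance components; leads collinear with the design are dropped with a
warning and reported. A region's signal is classified **full**ly explained
if the conditional lead-LAI p leaves the suggestive range entirely
(≥ 0.01), **partial** if it rises above genome-wide significance but stays
below 0.01, **none** otherwise; both cutpoints are configurable, and raw
p-values are always reported alongside, since no sharp numeric rule exists
for "completely explained".

## Power theory

The two-ancestry model enumerates the 16-point joint law of the two
chromosomes' (ancestry, allele) states: per chromosome, ancestry 1 with
probability q, allele with probability p₁ or p₂ by ancestry, contribution
β₁ or β₂ per allele. The population regression slope of the trait on the
ancestry-1 count is β₁p₁ − β₂p₂ (β(p₁−p₂) at equal effects); the package
computes it by enumeration and asserts agreement with the closed form to
1e-12. Power uses the Wald noncentrality n·b²·Var(Z)/Var(y|Z) and the
two-sided normal formula 1 − Φ(z₁₋α/₂ − √NCP) + Φ(−z₁₋α/₂ − √NCP). When
the causal variant is untyped and no proxy is modelled, the association
arm's power is reported as 0 — the regime where admixture mapping
dominates. The α parameter is exposed so the multiple-testing contrast
(5.68 × 10⁻⁵ for ~1.5 × 10⁴ intervals versus 5 × 10⁻⁸ genome-wide) is
directly computable.

## Replication

One-sided p-values take the tail fixed by the discovery effect sign
(normal reference by default; Student-t behind a flag for small cohorts),
and significance is declared at α/m. The complementary-tails identity
p₊ + p₋ = 1 holds exactly.

## Problem sizes and verification

The test suite and the acceptance script run entirely on simulated data at
desk scale: estimand recovery at n = 5,000 (structureless model,
closed-form REML path); Wald calibration on a ~1,150-person clustered
cohort with 2,000 permutation tests and 500 2-df statistics; power theory
verified against 2,000-replicate Monte Carlo at three grid points;
fine-mapping across 20 seeded ~1,000-person replicates. REML
parameter-recovery uses ~1,100-person replicates with information-based
intervals. These sizes were chosen so the whole suite completes in minutes;
the statistical checks (coverage, calibration bands, Monte-Carlo SE
margins) are scale-aware, so shrinking n widens the tolerances rather than
weakening the assertions.

## Known limitations

- The tract model ignores background LD, drift since admixture, and
  recombination-map structure; ancestry tracts of siblings are independent.
- Local ancestry is treated as known everywhere (no propagation of
  inference uncertainty).
- The EM does not jointly model multiple variants, and the conditional
  analysis adjusts for dosages linearly only.
- Binary traits and group-specific residual variances are out of scope.
- The genome-wide threshold is a constant, not re-derived per dataset.
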