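# Methods

## Design

`triomr` implements a two-sample, intergenerational, within-family
drug-target MR analysis. Sample 1 is an exposure GWAS of unrelated
individuals providing marginal SNV–SBP associations; sample 2 is a cohort
of mother-father-offspring trios providing SNV–outcome associations
conditional on the family's genotypes. The causal diagram the design
assumes: maternal genotype → maternal SBP (modifiable through the drug
target) → intrauterine environment → offspring outcome, with two
competing paths that must be blocked — transmission of the allele itself
to the offspring (handled by conditioning on offspring genotype) and
familial/assortment structure (probed by the paternal negative control,
estimated in the same joint regression). The estimand is the effect of a
10-mm-Hg decrease in maternal SBP, acting through one drug target, on the
offspring outcome.

## Synthetic cohort

The generator emulates the data-generating process the analysis assumes,
with every parameter recorded in a `TruthRecord` that round-trips through
YAML.

**Genotypes.** Each gene region is simulated as founder haplotypes from a
Gaussian-copula AR(1) process: a latent standard-normal sequence with
lag-one correlation `ld_r` is thresholded at each SNV's allele-frequency
quantile. One parameter per region gives monotonically tunable adjacent
r², which is all LD clumping needs. Parents draw two haplotypes each from
the founder pool; offspring inherit exactly one whole regional haplotype
per parent (fair coin), so there is no within-region recombination and no
mutation — regions are gene-scale (kb–hundreds of kb), where recombination
within a single meiosis is negligible. Mendelian consistency is therefore
exact by construction, and `mendelian_consistency()` audits it from the
dosage matrices alone (a parent with dosage 0/1/2 can transmit {0}/{0,1}/{1}
alleles).

**Exposure GWAS.** A separate sample of unrelated individuals is drawn
from the same founder frequencies under an independent random substream,
so the two samples share no individual (the two-sample property). SBP is
intercept + Σ dosage·β_snp + Normal noise, and each SNV gets an
*unadjusted* per-SNV least-squares regression — beta, SE, normal-reference
p-value, EAF, n — matching how GWAS summary statistics are produced.
Simulating individuals rather than writing analytic SEs means the summary
statistics inherit realistic, correlated sampling noise; the analytic
shortcut appears only inside tests as an oracle (expected
F ≈ n·R²/(1−R²)+1).

**Outcomes.** Effects are injected through mm-Hg allele scores
(score = Σ dosage·β_snp per role) with slope −β₁₀/10 per role, so the
true causal effect per 10-mm-Hg *decrease* equals β₁₀ exactly and
parameter-recovery checks need no unit conversion. Binary outcomes pass
the same linear predictor through a logistic link (the truth is then a
log-OR). Covariates — offspring sex ~ Bernoulli(0.489), parental ages
Normal(30.2, 5) and Normal(32.8, 5) years, a 3-level genotyping batch, 20
standard-normal principal components — are independent of genotype by
default; their effect sizes are configurable per outcome. The printed SDs
of parental age in the emulated cohort's descriptive table are implausible
for ages (they would imply negative ages under a Normal), so a 5-year SD
is used; covariates only enter as nuisance terms, so this choice does not
affect any estimand.

**What the generator does not emulate:** genotyping error, missingness,
imputation uncertainty, X-chromosome inheritance, assortative mating,
population stratification correlated with genotype, and selection into
the cohort. Passing tests therefore demonstrate that the *estimator and
pipeline* are correct under the design's assumptions, not that those
assumptions hold in any real cohort.

## Analysis parameters

| Parameter | Default | Role |
| --- | --- | --- |
| significance threshold | P < 5×10⁻⁸ (strict `<`) | genome-wide instrument filter |
| clump threshold | r² < 0.01 | greedy LD pruning, lowest p as index, ties by (chrom, pos) |
| clump window | 10 Mb | pairs farther apart (or cross-chromosome) treated as unlinked |
| palindrome MAF rule | drop if MAF > 0.42 (strict `>`) in **either** dataset | strand-ambiguity screen |
| weak-instrument flag | any F ≤ 10 | relevance diagnostic |
| CI critical value | 1.959964 (normal) | summary-data MR convention, not t |

The LD reference for clumping is the pooled mother+father dosages of the
trio cohort — parents approximate an unrelated population sample, and a
desk-scale panel cannot estimate genome-wide LD, hence the unlinked
assumption outside the window. The MAF>0.42 rule is applied to both
datasets because the frequency-concordance inference fails if *either*
frequency is too close to 0.5 (the conservative reading). Identifier
matching is case-insensitive with whitespace stripped; indels and
multi-allelic records are dropped as incompatible rather than guessed.

## Estimation

One joint regression per (SNV, outcome) supplies the maternal, paternal
and offspring coefficients simultaneously, guaranteeing the negative
control is internally consistent with the primary estimate (same sample,
same covariates, same fit). Continuous outcomes: OLS with classical SEs
(df = n − p). Binary outcomes: logistic regression by IRLS (statsmodels
GLM; max 100 iterations, deviance tolerance 1e-8) with Wald SEs;
non-convergence or separation surfaces as `converged=False` and excludes
the record downstream — no Firth or penalized fallback, so sparse-event
outcomes keep their honestly wide intervals. Rank-deficient designs abort
with the collinear columns named (pivoted-QR detection). Parental age
enters linearly; batch as dummies against the first level.

The Wald SE is first-order delta only (exposure uncertainty ignored), the
standard two-sample approximation when the exposure GWAS is much larger
than the outcome sample; with the default simulation sizes the neglected
term is a few percent of the ratio variance, and the observed CI coverage
(93–96% across seeds) stays inside the accepted band. IVW is fixed-effect
only: with at most a handful of SNVs per target, random-effects or
heterogeneity modelling is unidentifiable, so none is offered (nor Egger,
median or mode estimators, which need many more instruments).

## Numerical and reproducibility choices

- Every stochastic component draws from a named substream
  (`panel:<region>`, `trios`, `gwas`, `outcomes`) derived from one master
  seed via CRC32-keyed `SeedSequence`s, so enlarging one stage never
  perturbs another and reruns are bit-identical.
- A single-pair IVW call delegates to the Wald-ratio code path so the
  reduction is exact to the bit, not merely to rounding.
- All TSVs carry a `# seed=` header and floats at 12 significant digits,
  making run directories diffable and checksum-stable.
- Monomorphic SNVs in the simulated GWAS are flagged and excluded before
  any downstream stage; an SBP residual SD of 19 mm Hg and mean of
  135 mm Hg are scenario defaults (the exposure GWAS's phenotype variance
  is a configuration value, not an estimated quantity).

## Evaluation experiment sizes

The repeated-simulation experiments (`triomr.experiments`, also driven by
`scripts/acceptance.py`) use 200 replicates of 5 000 trios with a 3-SNV
instrument (per-allele effect 1 mm Hg, MAF 0.3, no LD) and a
50 000-participant exposure GWAS. At these sizes the Monte-Carlo SE of
the mean maternal estimate is ≈0.014 on a true effect of 0.5, small
enough to detect any meaningful bias while keeping a full evaluation
under a minute on one CPU. The weak-instrument experiment sizes the
per-allele effect from the variance decomposition
R² = 2p(1−p)β²/var(SBP) to explain 0.1% of exposure variance, giving an
expected F near 51 at n = 50 000. The bundled demo scenario (3 000 trios,
20 000 GWAS participants, 58 SNVs over five target genes) chooses causal
effect sizes whose expected F lies in the 40–100 range, comparable to the
mean instrument strength reported for real antihypertensive-target
instruments, so the funnel retains each intended instrument with margin
while its high-LD neighbours are removed by clumping.

## Known limitations

- The estimator label is univariable per-target MR on trio-conditional
  outcome associations; no multivariable MR across exposures is offered.
- Strand resolution never consults a reference genome; palindromic SNVs
  near MAF 0.5 are simply lost.
- The provenance funnel records counts, not per-SNV audit trails of every
  removed variant's r² partner.
- Negative-control contrasts report a difference, SE, z and p, but the
  design intends qualitative comparison; with realistic power the
  contrast is rarely decisive on its own.
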