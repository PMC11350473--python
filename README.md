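# triomr

Intergenerational within-family drug-target Mendelian randomization (MR)
for assessing whether a maternally mediated exposure — systolic blood
pressure (SBP) lowered through antihypertensive drug targets — has a
causal effect on offspring perinatal outcomes.

Drugs cannot be trialled in pregnancy, so the package uses genetics as a
stand-in: variants in or near the gene encoding a drug's protein target
proxy pharmacological perturbation of that target, and the *maternal*
genotype instruments the in-utero exposure. Because offspring inherit half
their alleles from the mother, a naive maternal analysis is confounded by
direct genetic inheritance; the design therefore conditions every
SNV-outcome association on the paternal and offspring genotypes in
mother-father-offspring trios, and uses the paternal estimate — which
shares the familial confounding structure but cannot act through the
intrauterine environment — as a negative control.

The package is aimed at genetic epidemiologists who want to prototype,
teach, or stress-test this design. Individual-level trio cohorts are
access-restricted, so a first-class synthetic-cohort module generates trio
genotypes (exact Mendelian transmission, tunable linkage disequilibrium),
an independent exposure-GWAS sample, and outcomes with known causal
structure, making every stage of the pipeline testable offline against
ground truth.

## Model

For instrument SNV *i*, let β̂ᵢˣ be its marginal effect on SBP (mm Hg per
effect allele) from an exposure GWAS of unrelated individuals, and β̂ᵢʸ
the maternal-genotype coefficient from the trio-conditional regression

  y = α + βₘ Gₘ + βₚ G_f + βₒ Gₒ + γᵀC + ε,

where y is the offspring outcome, Gₘ, G_f, Gₒ are maternal, paternal and
offspring dosages, and C collects offspring sex, parental ages, genotyping
batch and 20 ancestry principal components (logistic link for binary
outcomes). After harmonizing both datasets to a common effect allele
(palindromic SNVs resolved by allele-frequency concordance and discarded
when MAF > 0.42), the per-SNV causal estimate is the Wald ratio
θ̂ᵢ = β̂ᵢʸ / β̂ᵢˣ with delta-method SE σᵢ = se(β̂ᵢʸ)/|β̂ᵢˣ|. Multi-SNV
targets (same drug subclass, same mechanism of action) are combined by
fixed-effect inverse-variance weighting,

  θ̂ = Σ wᵢ θ̂ᵢ / Σ wᵢ,  wᵢ = (β̂ᵢˣ / se(β̂ᵢʸ))²,  se(θ̂) = (Σ wᵢ)^(−1/2),

which reduces exactly to the Wald ratio for a single SNV. Estimates are
reported per 10-mm-Hg *decrease* in SBP (multiplying by −10), the
magnitude of a typical antihypertensive treatment effect, and exponentiated
to odds ratios for binary outcomes. Instrument strength is screened with
F = (β̂ᵢˣ/se(β̂ᵢˣ))², flagging any F ≤ 10.

Instruments are derived by a reproducible funnel: SNVs inside the mapped
gene regions (drug subclass → gene → GRCh37 coordinates) → intersection of
exposure and outcome datasets → genome-wide significance (P < 5×10⁻⁸,
strict) → greedy LD clumping at r² < 0.01 → grouping by drug subclass,
splitting subclasses whose genes have conflicting mechanisms of action.

## Worked example

The bundled demo scenario simulates 3 000 trios and an independent
20 000-participant SBP GWAS over five antihypertensive target genes:

```sh
triomr run-all --config src/triomr/data/demo_scenario.yaml --seed 1 --out demo_run
```

The derivation funnel (written to `demo_run/provenance.json`) retains 7
instrument SNVs from 58 simulated — 3 in *CACNB2* and one each in
*SCNN1D*, *EDNRA*, *KCNJ11* and *ADRB1* — in 5 drug targets; the
vasodilator subclass splits into an endothelin-receptor-antagonist
(*EDNRA*) and a potassium-channel-opener (*KCNJ11*) target because the
mechanisms conflict. `demo_run/forest_report.txt` then shows, e.g. for the
null outcome `birth_weight_z` (true effect 0):

```
Outcome: birth_weight_z
  [maternal]
    Beta-adrenoceptor blocking drugs [beta-1 adrenoceptor antagonist] (ADRB1): +0.08 (-0.26 to +0.42) per 10-mm-Hg decrease, wald n_snps=1 mean F=98.8
    Calcium channel blockers [calcium channel antagonist] (CACNB2): -0.08 (-0.33 to +0.17) per 10-mm-Hg decrease, ivw n_snps=3 mean F=59.6
    ...
```

— all CIs cover the true null. For the binary positive-control outcome
`hypertensive_disorders` (true log-OR −2.5 per 10 mm Hg acting through the
maternal score) the maternal estimates are strongly protective, e.g.

```
Calcium channel blockers [calcium channel antagonist] (CACNB2): OR 0.11 (0.07 to 0.19) per 10-mm-Hg decrease, ivw n_snps=3 mean F=59.6
```

while the corresponding paternal (negative-control) odds ratios sit near 1,
exactly the maternal/paternal asymmetry the design is meant to detect.
`results.tsv` holds the same numbers as a tidy table (one row per
target × outcome × role).

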