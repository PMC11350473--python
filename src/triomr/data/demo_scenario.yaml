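# Bundled demo scenario: a desk-scale synthetic trio cohort plus an
# independent synthetic SBP exposure GWAS, sized to run end to end in
# seconds while exercising every pipeline stage (region extraction,
# genome-wide significance filtering, LD clumping, mechanism grouping,
# trio-conditional association, harmonization including a palindromic
# instrument, Wald/IVW estimation and the paternal negative control).
n_trios: 3000
n_gwas: 20000
gwas_noise_sd: 19.0   # SBP residual SD (mm Hg)
gwas_intercept: 135.0 # SBP mean (mm Hg)

regions:
  # CACNB2 spans ~400 kb: three causal SNVs far enough apart to survive
  # clumping at r^2 < 0.01, each with significant high-LD neighbours that
  # the clump step removes.
  - region_id: CACNB2
    chrom: "10"
    n_snvs: 35
    start: 18432000
    spacing: 11000
    maf: 0.30
    ld_r: 0.87
    causal: {0: 1.5, 17: 1.5, 34: 1.5}
  - region_id: SCNN1D
    chrom: "1"
    n_snvs: 6
    start: 1216000
    spacing: 1800
    maf: 0.25
    ld_r: 0.87
    causal: {2: 1.6}
  - region_id: EDNRA
    chrom: "4"
    n_snvs: 8
    start: 148405000
    spacing: 7000
    maf: 0.30
    ld_r: 0.87
    causal: {3: 1.8}
    palindromic: [3]  # strand-ambiguous A/T instrument, inferable (MAF < 0.42)
  - region_id: KCNJ11
    chrom: "11"
    n_snvs: 5
    start: 17407000
    spacing: 900
    maf: 0.35
    ld_r: 0.87
    causal: {2: 1.5}
  - region_id: ADRB1
    chrom: "10"
    n_snvs: 4
    start: 115803700
    spacing: 900
    maf: 0.30
    ld_r: 0.87
    causal: {1: 1.8}

outcomes:
  - name: birth_weight_z
    kind: continuous
    beta_m10: 0.0
    beta_p10: 0.0
    beta_o10: 0.0
    noise_sd: 1.0
  - name: gestational_age_days
    kind: continuous
    beta_m10: 2.0      # days per 10-mm-Hg decrease in maternal SBP score
    beta_p10: 0.0
    beta_o10: 0.0
    noise_sd: 12.0
    intercept: 280.0
  - name: developmental_score
    kind: continuous
    beta_m10: 0.0
    beta_p10: 0.0
    beta_o10: 0.0
    noise_sd: 1.5
    intercept: 7.5
    covariate_effects: {sex: 0.2, batch_b2: 0.1}
  - name: hypertensive_disorders
    kind: binary
    beta_m10: -2.5     # log-OR per 10-mm-Hg decrease (positive control)
    beta_p10: 0.0
    beta_o10: 0.0
    intercept: -2.586  # logit of ~7% prevalence

thresholds:
  p_threshold: 5.0e-8
  r2_threshold: 0.01
  maf_threshold: 0.42
  f_threshold: 10.0
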