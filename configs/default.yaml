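# Default synthetic study: one healthy-control cohort plus two nemaline-
# myopathy-like cohorts (ACTA1, TNNT1).  Load with
#   fibreomics simulate --config configs/default.yaml --out <dir> --seed N
# Every field of the generator truth is listed; delete the disease cohorts
# for a control-only study.

universe:                  # protein universe shared by all cohorts
  n_proteins: 1500         # size of the quantifiable protein-group universe
  baseline_mean: 14.0      # mean per-protein baseline (log2 LFQ)
  baseline_sd: 2.0         # spread of baselines across proteins (log2)
  tau_min: 0.2             # per-protein fibre-to-fibre SD, lower bound (log2)
  tau_max: 0.6             # ... upper bound
  n_effect_proteins: 100   # proteins with a true type-I-vs-IIa difference
  effect_size: 1.5         # |delta| of that difference (log2; half up, half down)
  n_core_proteins: 200     # abundant proteins detected in every fibre
  myh_base_log2: 17.0      # total myosin-heavy-chain intensity (log2)
  myh_noise_sd: 0.3        # fibre-to-fibre SD of total MYH (log2)
  myh_iso_noise_sd: 0.15   # per-isoform measurement SD (log2)
  myh_dirichlet_conc: 300.0  # tightness of per-fibre isoform mixtures

cohorts:
- condition: control
  participant_prefix: C
  n_participants: 8        # biopsies
  fibres_per_participant: 11
  subtype_probs: {I: 0.45, I/IIa: 0.10, IIa: 0.45}
  participant_sd: 0.3      # additive participant random effect (log2)
  dropout: true
  dropout_midpoint: 14.5   # log2 intensity at 50% detection probability
  dropout_slope: 1.5       # logistic width of the detection curve
  srx_base: 54.5           # mean SRX percentage
  srx_noise_sd: 32.0       # SD of SRX around the base (clipped to [0, 100])
  effect_attenuation: 1.0  # lambda: 1 = full subtype effects
  sign_flip_proteins: []
  t1_mean: 2.0             # fast (DRX) time constant, seconds
  t1_sd: 0.4
  t2_mean: 150.0           # slow (SRX) time constant, seconds
  t2_sd: 25.0
  trace_sigma: 0.02        # per-frame Gaussian noise on normalised traces

- condition: ACTA1         # type-I-enriched disease cohort
  participant_prefix: A
  n_participants: 3
  fibres_per_participant: 10
  subtype_probs: {I: 0.80, I/IIa: 0.10, IIa: 0.10}
  participant_sd: 0.3
  dropout: true
  dropout_midpoint: 14.5
  dropout_slope: 1.5
  srx_base: 38.4           # homogenised SRX regime
  srx_noise_sd: 8.6
  effect_attenuation: 0.3  # subtype effects shrunk to 30%
  sign_flip_proteins: []
  t1_mean: 2.0
  t1_sd: 0.4
  t2_mean: 150.0
  t2_sd: 25.0
  trace_sigma: 0.02

- condition: TNNT1         # type-IIa-enriched disease cohort
  participant_prefix: T
  n_participants: 3
  fibres_per_participant: 10
  subtype_probs: {I: 0.10, I/IIa: 0.10, IIa: 0.80}
  participant_sd: 0.3
  dropout: true
  dropout_midpoint: 14.5
  dropout_slope: 1.5
  srx_base: 33.0
  srx_noise_sd: 14.8
  effect_attenuation: 0.3
  sign_flip_proteins: []
  t1_mean: 2.0
  t1_sd: 0.4
  t2_mean: 150.0
  t2_sd: 25.0
  trace_sigma: 0.02

# SRX ~ protein couplings: protein id -> {subtype or "all": beta}, where beta
# is in SRX percentage points per SD of the protein's log2 abundance, e.g.
#   couplings: {P00050: {I: 0.8, IIa: -0.8}}
couplings: {}

# MANT-ATP chase acquisition grid: every 5 s to 90 s, then every 10 s to 390 s
grid_step_early: 5.0
grid_early_end: 90.0
grid_step_late: 10.0
grid_total_end: 390.0
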