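# Methods

## Myosin-state quantification (MANT-ATP chase)

A resting skinned myofibre loaded with fluorescent MANT-ATP and chased with
unlabelled ATP loses fluorescence as myosin heads exchange their bound
nucleotide. Heads in the disordered-relaxed state (DRX) exchange within
seconds; heads in the super-relaxed state (SRX) take minutes. The normalised
intensity is modelled as

    f(t) = 1 − P1·(1 − exp(−t/T1)) − P2·(1 − exp(−t/T2))

fitted by trust-region nonlinear least squares (`scipy.optimize.least_squares`,
tolerances 1e−15) with the components relabelled so T1 ≤ T2; P1 then reads as
the DRX fraction and P2 as the SRX fraction.

Choices that matter:

* **Normalisation.** Each frame's mean over three sampled regions has the
  frame's background subtracted; the series is divided by the t = 0 value,
  so `normalised[0] == 1` by construction. Traces whose t = 0 signal is not
  positive are rejected as degenerate.
* **Acquisition grid.** Default: every 5 s to 90 s, then every 10 s to
  390 s (49 frames). The late-phase endpoint is read as five further
  minutes after the 90 s dense phase; the wording of such protocols is
  ambiguous between "5 min total" and "5 min more", so the grid is fully
  configurable (`build_timegrid`).
* **Unconstrained amplitudes.** Nothing forces P1 + P2 = 1, and SRX% is
  reported as raw 100·P2 without renormalisation. Time constants are kept
  in (1e−3, 1e5) s purely for solver stability; both bounds are
  configurable.
* **Initialisation.** (P1, T1, P2, T2) = (0.5, 2 s, 0.5, 150 s): equal
  amplitude split at typical fast/slow relaxed-state time scales. The fit is
  insensitive to swapping the fast/slow initial components because of the
  T1 ≤ T2 relabelling.
* **Identifiability diagnostic.** An unconstrained double-exponential is
  ill-posed for near-single-exponential traces: with essentially no fast
  (or no slow) phase, one time constant escapes the acquisition window, or
  both collapse onto each other, and the amplitudes trade off freely —
  fitted SRX values of several hundred percent can result. A fit is flagged
  `identifiable = False` when a time constant sits at the solver bounds,
  when T2 exceeds 10× the acquisition span (indistinguishable from linear
  drift), or when T2 < 3·T1 (single-exponential ridge). The parameters are
  still reported; summaries in `scripts/acceptance.py` use identifiable
  fits only. Minimum 8 frames for the 4-parameter fit.
* **SRX clusters.** low ≤ 35%, high ≥ 65%, mid otherwise; both boundaries
  inclusive, both configurable.
* **Group comparisons.** One-way ANOVA with Tukey HSD post hoc
  (`statsmodels`). Groups with zero pooled within-group variance but
  distinct means are reported as exact separation (F = ∞, p = 0) with a
  warning rather than an error.

## Proteome QC and fibre typing

The protein-group matrix is a DIA-style TSV (metadata columns then one LFQ
column per run). Zeros and blanks are treated as censored, not as measured
zeros — the label-free DIA convention. Values are log2-transformed for all
downstream analysis.

PCA QC runs on the complete-case protein submatrix (proteins quantified in
every fibre) — the only deterministic reading of "PCA omitting missing
values" that needs no imputation. A fibre is an outlier when the robust
z-score of its Euclidean distance d from the median PC1–PC2 point,
(d − median d)/(1.4826·MAD d), exceeds `k_mad` (default 5). This replaces
the visual-inspection outlier call of interactive workflows with a
reproducible rule; raw d/MAD was rejected because it flags ordinary points
of a homogeneous cloud at any usable threshold. The rule assumes a roughly
homogeneous cohort: on a mixed control + disease matrix the conditions
separate in PC space and the rule will flag the sparser condition's fringe,
so QC is best run per cohort.

Fibre typing uses the **raw-scale** relative abundances of MYH7/MYH2/MYH1
(log2 values are back-transformed before ratioing; a missing isoform
contributes zero; a fibre with none of the three is untypeable). The call is
scale-invariant by construction. A fibre is a pure type (I, IIa, IIx) when
its dominant isoform fraction reaches `pure_threshold`, else the hybrid of
its top two isoforms in slow→fast canonical order. The threshold is not a
published constant; 0.7 reproduces the three observed classes (I, I/IIa,
IIa) on realistic mixtures and is exposed in every interface, with
`threshold_sensitivity` for sweeps. The non-adjacent MYH7 + MYH1 combination
is labelled I/IIx by the same top-two rule and logged, since it indicates an
unusual fibre.

## Pseudo-bulk differential abundance

Fibre-level values are collapsed to one **median log2 value per protein per
participant per group** before testing, so participants — not fibres — are
the unit of replication; hybrid fibres are excluded from pure-subtype
contrasts. The pseudo-bulk matrix is quantile-normalised: the reference
distribution is the across-column mean of sorted complete-row values;
complete columns map rank-for-rank (tie groups receive the mean of their
member target values); columns with missing cells interpolate the reference
at their observed average ranks. The normalisation happens after
aggregation, on "all samples" (pseudo-bulk columns) at once.

Each protein is then tested with a two-group linear model — paired
(participant-blocked) for within-cohort contrasts such as control type I ∼
type IIa and the SRX high ∼ low contrast, unpaired for cross-cohort
contrasts — with empirical-Bayes variance moderation: sample variances are
modelled as scaled-F around a prior s0² with d0 prior degrees of freedom,
estimated by method of moments on log s²_g (trigamma inversion by Brent
root-finding); the posterior variance is the weighted average
(d0·s0² + d_g·s²_g)/(d0 + d_g) and the moderated t has d0 + d_g degrees of
freedom. When the log variances show no excess dispersion the prior df is
infinite and the prior variance is the plain mean of the sample variances,
so exactly equal variances squeeze to themselves. With fewer than 5 testable
proteins the fit falls back to the ordinary t, logged.

Significance is the composite π-value

    π = p^|log2FC|   (equivalently 10^(−s), s = |log2FC|·(−log10 p))

called at π < 0.05, strict inequality, deliberately **unadjusted** for
multiple testing: the package mirrors an exploratory workflow whose outputs
are candidate lists, not confirmatory claims. The scorer is a pluggable
callable. The SRX-cluster contrast restricts to participants contributing
fibres to *both* the low and high cluster and is paired within participant.

## SRX ∼ proteome correlation

Analyses use fibres carrying both assays ("dual" fibres), minus QC outliers.
Presence floors: ≥ 22 dual fibres for the across-all-fibres analysis; for
subtype-resolved analyses a protein must additionally be quantified in
≥ 10 fibres of *each* pure subtype, so the type I and type IIa coefficient
lists cover the same proteins. Correlations are Spearman with average ranks;
two-sided p is an exact full-permutation enumeration for n ≤ 9 and the
t-approximation above, clipped into (0, 1]. DRX correlations are emitted
against 100 − SRX (exactly sign-flipped when the generator constrains
P1 + P2 = 1). Hybrid fibres count in the "all" scope only. Correlations are
unadjusted, like the differential calls.

Significant per-subtype coefficient profiles (ρ_typeI, ρ_typeIIa) are
clustered agglomeratively (complete linkage, Euclidean metric); the flat
clustering is selected by an explicit `k` or cut height rather than visual
inspection, and the dendrogram is serialised as Newick text.

## Divergence shrinkage

Given the control type I ∼ type IIa contrast and a disease cross-contrast
(e.g. ACTA1-type I ∼ TNNT1-type IIa), the control significant set is
intersected with the disease tested universe and split into **maintained**
(still significant at α) and **lost**. Fold-change attenuation is reported
two ways: the count of proteins with strictly |disease FC| < |control FC|,
and median |disease FC|/|control FC| ratios over (a) the maintained subset
and (b) all identified pairs. The maintained-only ratio is winner's-curse
biased upward at small cohort sizes — proteins only stay significant when
their measured fold change is large — so the identified-pairs ratio is the
consistent estimator of a global attenuation factor and is the one to quote;
both appear in the report. Sign flips are flagged separately from
attenuation, as flipped divergence is a qualitatively different phenomenon
from shrunken divergence.

## Synthetic-data generator

The generator emulates the dual-assay study design with fully known truth;
all randomness flows from one master seed through spawned child streams, so
outputs are bit-reproducible.

* **Proteome.** 1500 protein groups with log2 baselines μ_p ~ N(14, 2²) and
  per-protein fibre SDs τ_p ~ U(0.2, 0.6); additive participant effects
  (SD 0.3 log2); 100 effect proteins at |δ| = 1.5 log2 (half up, half down)
  expressed fully in type I fibres, half in I/IIa hybrids, not in type IIa.
  Detection is abundance-dependent logistic dropout,
  P(observed) = expit((value − 14.5)/1.5), a left-censoring-like model of
  label-free DIA missingness calibrated to ≈ 780 detected proteins per
  fibre; 200 "core" proteins (plus the MYH rows and any SRX-coupled
  proteins) are dropout-exempt, modelling the abundant sarcomeric set seen
  in every run — without such a core no protein is complete across ~90
  fibres and complete-case PCA would be impossible, which real single-fibre
  data does not show.
* **Fibre types.** Subtypes drawn per fibre (control 45/10/45% I, I/IIa,
  IIa); MYH7/MYH2/MYH1 intensities follow tight per-subtype Dirichlet
  mixtures of a shared total-myosin intensity with small per-isoform noise.
* **SRX.** srx = clip(base + Σ_p β_{p,scope}·z_p + N(0, σ_SRX), 0, 100),
  where z_p is the protein's standardised log2 value and the coupling scope
  is the fibre's subtype (fallback "all") — so subtype-divergent couplings
  (β_I > 0 > β_IIa) are expressible. Control base/σ: 54.5/32 (percent).
  Decay traces are generated from the model with P2 = SRX/100,
  P1 = 1 − P2 (so DRX = 100 − SRX exactly in truth), T1 ~ N(2, 0.4) s,
  T2 ~ N(150, 25) s and per-frame noise σ = 0.02, re-anchored to 1 at t = 0;
  the emitted raw ROI/background columns re-normalise to the series exactly.
* **Disease.** Cohorts with every δ multiplied by λ ∈ [0, 1] (optional
  per-protein sign flips), homogenised SRX (ACTA1-like: 38.4 ± 8.6,
  type-I-enriched; TNNT1-like: 33.0 ± 14.8, type-IIa-enriched), 3
  participants × 10 fibres per condition.

What the generator does **not** emulate: peptide-level quantification and
protein inference, intensity-dependent (heteroscedastic multiplicative)
measurement error, batch/acquisition-order effects, correlated protein
modules beyond the planted effect set, fibre size/length covariates, and
imaging artefacts (bleaching, focus drift). Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not robustness to every artefact of real acquisitions.

Clipping the SRX truth at 0/100 intentionally produces a tail of
single-phase fibres whose unconstrained fits are unstable — a real property
of this assay/model combination that the `identifiable` diagnostic exists
to catch.

## Problem sizes and tolerances

Default synthetic studies use 8 control participants × 11 fibres (≈ 88
fibres, ≈ 1500 proteins) and 3 + 3 disease participants — the scale the
pipeline targets. Test simulations use these sizes or smaller; the
acceptance script's null calibration uses 500 proteins at 4 vs 4 columns
and its noisy decay recovery uses 200 traces. Noiseless decay recovery is
asserted to 1e−6 (observed ≈ 1e−11); statistical checks use binomial 95%
confidence bands at fixed seeds; the end-to-end attenuation check allows
±0.1 around λ = 0.3 for the identified-pairs ratio and compares the lost
fraction against an independent Monte-Carlo power oracle within ±0.15.

## Known limitations

* The moderated model tests two groups with at most a participant blocking
  factor; no general design matrices or covariates.
* No imputation, batch correction, or multiple-testing adjustment (the
  latter by design, mirrored from the exploratory workflow; downstream
  users should treat hit lists accordingly).
* The PCA outlier rule assumes one roughly homogeneous cohort per run.
* Quantile normalisation with heavy missingness leans on the complete-row
  reference; with very few complete rows the reference is noisy.
* Fibre typing considers MYH7/MYH2/MYH1 only; developmental/extraocular
  isoforms are out of scope.
* Exact Spearman p-values are enumerated only to n = 9 (9! permutations);
  above that the t-approximation is used.
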