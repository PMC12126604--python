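# fibreomics

Single human myofibres can now be split in two: one fragment assayed for
myosin biochemical state by a MANT-ATP chase, the other profiled by
label-free DIA proteomics. `fibreomics` is the analysis layer for such
dual-assay experiments. It quantifies, for every fibre, the fraction of
myosin heads in the slow-ATP-turnover super-relaxed state (SRX) versus the
disordered-relaxed state (DRX), types each fibre from its myosin heavy-chain
isoform profile, tests protein abundance differences between fibre subtypes
and myosin-state clusters at the participant (pseudo-bulk) level, correlates
same-fibre SRX with protein abundance, and measures how much the normal
type I ∼ type IIa molecular divergence shrinks in diseased (nemaline
myopathy-like) muscle. A ground-truth synthetic-data generator makes every
stage testable end to end.

## The models

**Myosin state.** Fluorescence of MANT-ATP chased out of a relaxed fibre is
background-subtracted, averaged over three regions, normalised to the t = 0
frame, and fitted (unconstrained nonlinear least squares) to

```
f(t) = 1 − P1·(1 − e^(−t/T1)) − P2·(1 − e^(−t/T2)),   T1 ≤ T2
```

with DRX% = 100·P1 (fast phase) and SRX% = 100·P2 (slow phase). Fibres are
clustered as low (≤35%), mid, or high (≥65%) SRX.

**Differential abundance.** log2 LFQ values are aggregated to one median per
protein per participant per group, quantile-normalised, and tested with a
two-group linear model whose per-protein variances are squeezed by empirical
Bayes: s̃²_g = (d0·s0² + d_g·s²_g)/(d0 + d_g), with the prior (d0, s0²)
estimated by method of moments on the log sample variances. Calls use the
composite π-value π = p^|log2FC| (< 0.05, unadjusted by design).

**Phenotype–proteome correlation.** Spearman's ρ (average ranks; exact
permutation p for n ≤ 9) between per-fibre SRX% and each protein passing
presence floors (≥ 22 dual fibres overall; ≥ 10 fibres of each pure subtype
for subtype-resolved analyses), plus hierarchical clustering of the
(ρ_typeI, ρ_typeIIa) profiles.

## Worked example

```python
from fibreomics import decay, simulate
from fibreomics.qc import log2_transform, protein_counts
from fibreomics.fibretype import type_fibres, rank_and_summarise

study = simulate.simulate_study(simulate.control_study_config(), seed=1)

fit = decay.DoubleExponentialDecay(study.traces[0]).fit()
print(fit.summary())
```

```
Double-exponential MANT-ATP chase fit: C1_f01
----------------------------------------------------
  P1 (fast/DRX amplitude) :   0.280758   -> DRX  28.08%
  T1 (fast time constant) :     2.4417 s
  P2 (slow/SRX amplitude) :   0.742607   -> SRX  74.26%
  T2 (slow time constant) :   150.3833 s
  RSS                     : 1.6166e-02  (49 frames)
  converged               : True
```

28% of this fibre's myosin heads are in the fast DRX state and 74% in the
slow SRX state (the unconstrained amplitudes need not sum to 100%);
`decay.classify_srx(fit).label` puts it in the `high` SRX cluster. The same
study's proteome side:

```python
m = log2_transform(study.matrix)
counts, summ = protein_counts(m)          # -> 784 +- 45 proteins per fibre
calls = type_fibres(study.matrix)
_, composition = rank_and_summarise(calls, m.annotations)
print(composition.round(3))
```

```
label          I  I/IIa    IIa
condition
control    0.545  0.114  0.341
```

i.e. 54.5% of fibres typed as slow (type I), 11.4% hybrid I/IIa and 34.1%
fast (type IIa) from their MYH7/MYH2/MYH1 relative abundances.

## Command line

The same stages are available as a pipeline:

```
fibreomics simulate  --out sim --seed 5 --disease
fibreomics fit-decay --traces sim/traces.csv --out fits.tsv
fibreomics qc        --pg sim/pg_matrix.tsv --annot sim/annotations.csv --out qc
fibreomics fibretype --pg sim/pg_matrix.tsv --annot sim/annotations.csv --out types.tsv
fibreomics diffabund --pg sim/pg_matrix.tsv --annot sim/annotations.csv \
                     --types types.tsv --contrast typeI_vs_typeIIa --out da_ctrl.tsv
fibreomics correlate --pg sim/pg_matrix.tsv --annot sim/annotations.csv \
                     --fits fits.tsv --types types.tsv --out corr
fibreomics shrinkage --control da_ctrl.tsv --disease da_dis.tsv --out shrink.tsv
```

An annotated generator configuration ships in `configs/default.yaml`.

## Documentation

`docs/methods.md` describes the statistical models, the synthetic-data
generator and its defaults, numerical choices, and known limitations.
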