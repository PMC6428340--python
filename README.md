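# spikecal

Maximum-likelihood calibration of RNA-seq counts against external RNA
spike-ins, for measuring **absolute cellular RNA abundance** and detecting
condition-dependent changes in total transcriptome size.

Most RNA-seq normalisations (median-of-ratios size factors, TMM, quantile
methods) assume that most genes do not change and that total cellular RNA is
constant across conditions. When a treatment changes the amount of RNA per
cell globally — faster-growing yeast, an oncogene driving transcriptional
amplification, a signalling perturbation shrinking the transcriptome — those
normalisations silently remove the effect and report spuriously symmetric
up/down regulation. `spikecal` instead anchors every library to a pool of
synthetic spike-in RNAs (e.g. the 92-molecule ERCC mix spanning ~10⁶-fold in
concentration) added in known amounts to a known number of cells, so counts
become abundances in attomoles or molecules per cell.

## The model

Counts within a library are modelled as one multinomial draw whose expected
proportions are shared across libraries. For spike-in *i* with known amount
*n*ᵢ and relative yield αᵢ (expected counts per molecule relative to a
reference spike-in; α₁ ≡ 1), maximum likelihood gives closed forms:

- pooled proportions  *f*ᵢ = Σⱼ *y*ᵢⱼ / Σᵢⱼ *y*ᵢⱼ
- calibration constant  νⱼ = *f*₁ · *L*ⱼˢᴵ / *n*₁  (counts per amol, or per
  molecule-per-cell; *L*ⱼˢᴵ is library *j*'s total spike-in count)
- nominal abundance  *z*ᵢⱼ = *y*ᵢⱼ / νⱼ  for native transcripts
- spike-in abundance  *z*ᵢ = (*n*₁/*f*₁) *f*ᵢ, hence yields αᵢ = *z*ᵢ/*n*ᵢ

Residual per-library scale errors (pipetting, dilution, cell count, RNA
extraction) are absorbed by a correction factor δⱼ — a within-condition
median-of-ratios with geometric mean 1 — and corrected abundances are
*z*ᵢⱼ/δⱼ. Biological noise is gamma-Poisson: counts are NB(μ, *a*) with
variance μ + μ²/*a*, with the shape *a* estimated per condition by adjusted
profile likelihood. On top of this sit:

- **cross-validation**: leave one condition out, treat its spike-ins as
  unknowns, infer their molecules per cell, and compare the Mean Fold Error
  against Monte-Carlo resamples of the multinomial model (MFE/MFE_syn ≈ 1
  means the calibration error is pure sampling noise);
- **growth-rate fits**: per-transcript NB regression of abundance on growth
  rate γ with mean exp(φ₀ + φ₁[γ − γ̄]), likelihood-ratio tests with
  parametric-bootstrap p-values and Benjamini–Hochberg FDR;
- **pairwise differential abundance** on the calibrated (ν·δ) scale, with
  median-of-ratios sizing available as a comparison mode to demonstrate how
  it hides global amplification;
- **yield modelling**: log-linear regression of α on spike-in length, GC
  content and folding energy;
- a **synthetic-data generator** that emulates a full study (ERCC-like mix,
  multinomial spike-in counts, NB native counts, injected δ errors) for
  validation and benchmarking.

## Worked example

Simulate a three-condition chemostat-style study (growth rates 0.12, 0.20,
0.30 h⁻¹, every transcript responding with φ₁ = 5.6), calibrate it, and fit
the growth-rate response:

```python
import numpy as np
import spikecal as sc

cfg = sc.SimulationConfig(
    gamma={"c1": 0.12, "c2": 0.20, "c3": 0.30},
    phi1_mean=5.6, phi1_sd=0.0, n_transcripts=300,
)
ds = sc.simulate_dataset(cfg, seed=42)

calib = sc.calibrate(ds.spikein_counts, ds.annotation)
print("reference:", calib.reference_id, " f1=%.4f" % calib.f[calib.reference_index])
print("nu:", np.round(calib.nu, 1))

conds = np.array([ds.library_meta[l].condition for l in ds.native_counts.library_ids])
keep = sc.detection_filter(ds.native_counts)
y = ds.native_counts.counts[keep]
d = sc.compute_delta(sc.counts_to_abundance(y, calib.nu, pseudocount=1.0), conds)
print("delta:", np.round(d, 3))

gam = np.array([ds.library_meta[l].growth_rate for l in ds.native_counts.library_ids])
a = sc.estimate_shape(y[:, conds == "c1"], (calib.nu * d)[conds == "c1"])
fit = sc.fit_growth_model(y, gam, calib.nu * d, a)
print("shape a (c1): %.1f" % a)
print("median phi1: %.2f" % np.median(fit.phi1))
print("implied fold 0.12->0.30: %.2f" % sc.fold_change_from_phi(np.median(fit.phi1), 0.12, 0.30))

res = sc.mfe_ratio_mc(ds.spikein_counts, ds.annotation, "c2", cells=cfg.cells,
                      trials=200, seed=1)
print("LOCO c2: MFE=%.3f mean ratio=%.3f" % (res.mfe_lab, res.mean_ratio))
```

prints

```
reference: SYN-00046  f1=0.1335
nu: [50.9 44.  54.  50.7 59.5 50.5 35.8 44.8 38. ]
delta: [1.271 1.074 0.732 1.114 0.7   1.283 1.01  1.145 0.865]
shape a (c1): 25.5
median phi1: 5.94
implied fold 0.12->0.30: 2.91
LOCO c2: MFE=1.279 mean ratio=1.036
```

Reading the output: νⱼ converts each library's counts to attomoles (1/ν is
amol per count); δⱼ are the recovered per-library preparation errors
(within-condition geometric mean 1); the NB shape â ≈ 25 matches the
generating value; the median fitted φ₁ of 5.94 implies a ~2.9-fold rise in
abundance from the slowest to the fastest growth rate (true value 5.6 →
2.7-fold; the small excess is the cross-condition part of the injected
library errors, which δ cannot remove by construction). The leave-one-
condition-out MFE ratio near 1 says the spike-in inference error is
explained by multinomial sampling alone.

The same steps are scriptable from the shell:

```sh
spikecal simulate --out study/ --seed 42
spikecal calibrate --spikein study/spikein_counts.tsv --rna study/native_counts.tsv \
    --annotation study/annotation.tsv --meta study/library_meta.tsv --out results/
spikecal crossval --spikein study/spikein_counts.tsv --annotation study/annotation.tsv \
    --meta study/library_meta.tsv --cells 1e7 --trials 1000 --seed 1 --out results/
```

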