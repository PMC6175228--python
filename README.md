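# fastwhiten

Accurate modelling and removal of temporal correlations in rapidly sampled
fMRI time series, and serial-correlation-aware measurement of functional
sensitivity.

## The problem

Accelerated (multiband) fMRI acquisitions shorten the volume repetition
time, delivering many more samples per scan — but the samples are no longer
independent. If the serial correlation of the noise is mis-modelled, the
standard error of every GLM parameter estimate is underestimated, t-scores
are inflated, and false-positive rates rise. The classical noise model —
white noise plus a first-order autoregressive (AR(1)) component — is
adequate at conventional repetition times but fails as the sampling
interval drops below about 1.5 s.

`fastwhiten` implements, for Python:

* the **FAST covariance-component dictionary**: Toeplitz components with
  entries `C[i,j] = |i-j|^n · exp(-α|i-j|)` (and a unit diagonal for the
  n = 0 shapes), at dyadic decay rates `α = 8/2^q, q = 1..p` and derivative
  orders `n = 0..2` — a 3p-component basis able to capture serial
  correlation at many timescales;
* **ReML estimation** of the mixture `V = Σᵢ λᵢ Cᵢ` by Fisher scoring on
  the restricted variational free energy, with the sample covariance pooled
  over voxels surviving an omnibus F-test on the task regressors;
* **prewhitened GLM fitting**: `W = V̂^{-1/2}`, `β̂ = (WX)⁻WY`,
  `σ̂² = e'e / trace(R)`, and t-scores
  `t = c'β̂ / (σ̂ η)` with `η = sqrt(c'(WX)⁻(WX)⁻ᵀc)`;
* the proposed sensitivity metric **t₀**, the t-score testing the mean
  signal (intercept contrast), alongside the conventional weighted temporal
  SNR `tSNR_w = c₀'β̂/σ̂ · √N`. When the noise is white and the design is
  an intercept alone, `η₀ = 1/√N` and the two coincide; with genuine serial
  correlation, t₀ correctly deflates while tSNR_w overestimates the benefit
  of faster sampling;
* the **evaluation battery**: a Ljung-Box whiteness screen on GLM residuals
  (all lags to 20 on the first 100 points, FDR-corrected), residual power
  spectra, precision-vs-√n stability analysis, and free-energy comparison
  of competing dictionaries (differences above 3 nats count as strong
  evidence);
* a **simulator** of block-design BOLD series (HRF-convolved blocks, AR(1)
  noise of known marginal sd, optional physiological sinusoids) with a
  decimation scheme that trades sampling interval against sample count at
  fixed scan duration, plus Gaussian draws from arbitrary component
  mixtures for parameter-recovery experiments.

Design matrices include HRF-convolved task blocks, a discrete-cosine drift
basis implementing a 128 s high-pass filter, 12 Fourier cardiac/respiratory
phase regressors with 2 amplitude regressors, and an intercept.

## Worked example

Simulate a 50-voxel block-design run at TR = 1.4 s (306 samples) with
AR(0.4) noise, fit the GLM with AR(1)+white prewhitening, and screen the
residuals:

```
$ fastwhiten simulate --preset mb2 --seed 42 --n-voxels 50 \
      --out series.tsv --truth truth.json
wrote series.tsv (50 voxels x 306 samples, dt=1.4 s)

$ fastwhiten fit --data series.tsv --design series_design.tsv \
      --model ar1 --out stats.tsv
wrote stats.tsv; mean t0=957.904, mean tSNR_w=1762.928

$ fastwhiten diagnose --data series.tsv --design series_design.tsv --model none
proportion of voxels with residual serial correlation: 0.980

$ fastwhiten diagnose --data series.tsv --design series_design.tsv --model ar1
proportion of voxels with residual serial correlation: 0.000
```

Without a noise model, 98% of voxels retain significant residual
autocorrelation; prewhitening with the estimated AR(1)+white mixture
removes it everywhere. The gap between the mean t₀ (958) and the mean
weighted tSNR (1763) is the sensitivity overestimation incurred by ignoring
serial correlation: tSNR_w assumes all 306 samples are independent, t₀ does
not.

Free-energy model comparison on the same data ranks dictionaries while
penalising complexity:

```
$ fastwhiten compare --data series.tsv --design series_design.tsv \
      --basis ar1 --basis fast:p=2 --basis fast:p=3
ar1:decay=0.2: F=49740.744 (dF=+0.000)
fast:p=2: F=49744.397 (dF=+3.654, strong)
fast:p=3: F=49713.672 (dF=-27.072, strong)
winner: fast:p=2
```

The 6-component dictionary wins (the fixed 0.2 decay of the AR basis does
not match the simulated 0.4), while the larger 9-component dictionary is
penalised for unneeded complexity.

The same analyses are available as library functions
(`fastwhiten.reml_fit`, `fastwhiten.compare_models`,
`fastwhiten.whiteness_screen`, `fastwhiten.sensitivity_experiment`, ...);
see `docs/methods.md` for the underlying model and the numerical choices.

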