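# Methods

## Observation model

A voxel's time course of length N is modelled as

    y = X β + ε,    ε ~ N(0, σ² V)

where X is the design matrix (task regressors convolved with the canonical
HRF, discrete-cosine drift columns, optional physiological nuisance
regressors, and an intercept), σ² a voxel-specific variance, and V an N×N
autocorrelation matrix shared across voxels. Inference uses prewhitening:
with W satisfying W'W = V⁻¹, the whitened model WY = WXβ + Wε has spherical
errors, β̂ = (WX)⁻WY are generalised-least-squares estimates, the residual
variance is σ̂² = e'e / trace(R) with e = RWY and R the whitened
residual-forming matrix, and

    t = c'β̂ / (σ̂ η),   η = sqrt(c'(WX)⁻(WX)⁻ᵀ c).

W is taken as the symmetric principal inverse square root of V (the
defining property fixes W only up to an orthogonal factor; the symmetric
root is deterministic and conventional). Eigenvalues of V are floored at
1e-8 of the largest before inversion, so mildly indefinite estimated
mixtures whiten gracefully. trace(R) equals N − rank(WX) because the
post-whitening error covariance is taken to be the identity; no
Satterthwaite adjustment is applied anywhere.

Voxels whose residual variance vanishes to machine precision (σ̂² below
1e-24 of the whitened data's mean square) are flagged and reported with
infinite t rather than raising, so noise-free synthetic fixtures pass
through the pipeline.

## Serial-correlation model

V is expressed as an unconstrained mixture V = Σᵢ λᵢ Cᵢ over a fixed
component dictionary:

* **AR(1)+white**: the identity plus a Toeplitz matrix with entries
  ρ^|i−j|. The decay ρ is fixed (default 0.2, the conventional value) and
  the mixture weights carry all the data adaptation.
* **FAST**: for p timescales, components C^{nα} with entries
  |i−j|ⁿ e^{−α|i−j|} off the diagonal (diagonal 1 for n = 0, exactly 0 for
  n = 1, 2), α = 8/2^q for q = 1..p, n = 0..2 — 3p components ordered by
  timescale then derivative order, so dictionaries of increasing p are
  nested. p ≤ 9 is enforced; beyond that the components are so collinear
  that estimation is never useful.

Components are stored densely and verified (symmetry, Toeplitz) rather than
exploited — the series handled here have at most a few thousand samples.
No per-component trace normalisation is applied; any scale is absorbed by
the weights.

## ReML estimation and free energy

The sample covariance S is pooled over voxels surviving an omnibus F-test
on the task regressors (default α = 0.001; if nothing survives, all voxels
are used with a warning), each voxel's series scaled to unit mean square
first. The number of pooled voxels acts as the effective observation count.

Restriction is implemented by projecting S and the components onto an
orthonormal basis K of the orthogonal complement of col(X):
S_r = K'SK, Q_r = K'QK. The objective per hyperparameter vector λ is the
reduced-space Gaussian log-likelihood

    L(λ) = −N/2 [ log det C_r + tr(C_r⁻¹ S_r) + m log 2π ],  C_r = Σ λᵢQ_rᵢ

which is exactly the standard ReML likelihood (the projection supplies the
log det X'C⁻¹X term). Each λᵢ carries a Gaussian prior with mean 0 and
variance e⁸ — flat enough to be uninformative, but regularising directions
the data cannot identify. Weights are unconstrained reals; definiteness of
the resulting V̂ is handled at whitening time by the eigenvalue floor.

Maximisation is Fisher scoring: gradient
−N/2 [tr(C_r⁻¹Q_rᵢ) − tr(Q_rᵢ C_r⁻¹S_rC_r⁻¹)] − λᵢ/e⁸, expected curvature
N/2 tr(C_r⁻¹Q_rᵢC_r⁻¹Q_rⱼ) + δᵢⱼ/e⁸. Steps that would leave the
positive-definite cone or decrease the penalised objective are halved (up
to 16 times); the ascent stops when the predicted improvement falls below
1e-2 nats (converged) or after 64 iterations (flagged, not raised). The
condition number of the Fisher information is recorded and a warning issued
above 1e10 — large FAST dictionaries genuinely produce rank-deficient
posteriors, and this surfacing is intentional.

The reported free energy is the Laplace bound at the mode: the penalised
objective plus ½(tr(Σ/e⁸) − k) − ½ log det(P_λ e⁸), where P_λ is the
posterior precision and Σ its inverse. Constant terms common to all
dictionaries on the same data cancel; only differences are meaningful, and
differences above 3 nats are labelled strong evidence. The fitted V̂ is
trace-normalised to N before whitening, separating correlation shape from
variance scale.

A brute-force check (dense grid search over two-component mixtures at
n = 16) confirms the ascent attains the global optimum to better than 1e-3
nats; scaling S by c > 0 scales λ̂ by c and leaves the normalised V̂
unchanged.

## Diagnostics

**Whiteness screen.** For each voxel, the first 100 residual samples are
demeaned and the Ljung-Box statistic Q(h) = m(m+2) Σₖ ρ̂ₖ²/(m−k) referred
to χ²_h, at every lag h = 1..20. P-values are FDR-corrected by the
Benjamini-Hochberg step-up at q = 0.05 jointly across voxels *and* lags
(the conservative pooling); a voxel counts as rejecting if any lag
survives. No degrees-of-freedom correction is made for fitted GLM
parameters — the screen's null calibration is instead verified empirically
(rejection rate 3–8% at nominal 5% on white noise). The alternative
single-omnibus reading (one lag-20 statistic per voxel) is available by
calling `ljung_box_q` directly.

**Spectra.** Residual power spectra use a segment-averaged periodogram
(50% overlap, mean-detrended segments) averaged over voxels; flat spectra
indicate successful whitening.

**Stability.** The precision of the mean-signal estimate, 1/SE(intercept),
should grow linearly in √n for a well-conditioned noise model. Series and
design are truncated to 5 equally spaced lengths from 100 samples upward,
V re-estimated at each length, and precision regressed on √n; R² near 1
indicates stability, while over-parameterised dictionaries (e.g. 27
components on short series) degrade it — that degradation is a finding, not
a failure, and is reported with the conditioning warning.

## Simulator

`simulate_block_series` generates baseline + effect·regressor + AR(1)
noise: default 100 voxels × 1,024 samples at a 1 s base interval, baseline
100, a 1% effect organised as 16 blocks of 32 s on / 32 s off (the base
interval is forced by 16 × 64 s spanning the 1,024 samples), AR coefficient
0.4, marginal noise sd 1. Choices worth noting:

* The boxcar is built at microtime (interval/16), convolved with a
  unit-*sum* canonical HRF kernel (double gamma: peak delay 6 s, undershoot
  delay 16 s, unit dispersions, 6:1 amplitude ratio, 32 s support,
  unit-peak when returned by `canonical_hrf` itself), and read out at
  mid-volume times. Unit-sum normalisation of the convolution kernel makes
  a sustained block plateau at 1 regardless of microtime, so "1% effect"
  means a true 1% plateau signal change.
* AR(1) noise starts from its stationary distribution (no burn-in),
  matching the stationarity the Toeplitz model assumes. "sd 1" is read as
  the marginal standard deviation (innovation sd √(1−φ²)); the
  innovation-scale reading is available via `sd_is_innovation`.
* `decimate_series` keeps samples 1, 1+d, 1+2d, … and scales the sampling
  interval by d, emulating a fixed-duration scan at a coarser rate;
  decimated AR(φ) noise is exactly AR(φ^d).
* `noise_sign` flips the sign of the noise draw. Running one seed with +1
  and −1 gives an antithetic pair; averaging statistics over the pair
  cancels all noise terms that are odd in the draw, which is the dominant
  Monte-Carlo error in t-score means. The decimation experiment's
  acceptance checks average 8 such pairs: the smallest true increment of
  tSNR_w/t_task along the decimation grid (≈ +1.3 between d = 6 and d = 5,
  where serial correlation has almost vanished) is several times smaller
  than the single-run Monte-Carlo error (≈ 4) but ~6 standard errors above
  zero after antithetic averaging.
* Sinusoidal cardiac (~1 Hz) and respiratory (~0.3 Hz) confounds with
  slowly wandering frequency, plus a slow drift, are available for
  diagnostics tests; they are deliberately simple and are not part of the
  decimation experiment.

What the simulator does *not* emulate: spatial structure and smoothing,
motion, scanner drift nonstationarity, g-factor noise amplification, or
genuinely multi-timescale physiological noise. Passing tests therefore
demonstrate correctness of the estimators under their own assumptions, not
performance on real scanner data.

## Problem sizes

The test-suite and acceptance-script experiments use desk-scale sizes
chosen to keep Monte-Carlo error well below the asserted margins: 500
voxels × 300 samples for the whiteness screens, 5,000 voxels × 64 samples
for parameter recovery, 20 replicates of 500 × 64 for the complexity
penalty, the full printed 100 × 1,024 configuration (8 antithetic pairs)
for the decimation experiment, and a 400-sample grid for the stability
analysis.

## Known limitations

* A single global V is shared by all voxels; spatially varying serial
  correlation is out of scope.
* Voxel-wise (non-pooled) hyperparameter estimation, MCMC posteriors and
  EM alternatives are not provided.
* The Ljung-Box screen tests residual autocorrelation only; it has no power
  against heteroscedasticity or non-Gaussianity.
* Free-energy constants are implementation-specific; compare F only across
  dictionaries fitted by this package on the same pooled covariance.
* Raw physiological waveform peak detection is not implemented; phases are
  supplied per volume (or synthesised).
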