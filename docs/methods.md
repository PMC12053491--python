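# Methods

## Signal model and what the generator emulates

The synthetic generator produces

```
value(t) = trend(t) + A e^{-d t} cos(2π (t − φ)/P) + x_t  [+ e_t]
```

with `trend` a polynomial in hours (degree ≤ 4 by default), a cosine
parameterized by its **peak time** φ (all downstream comparisons are
peak-to-peak, so the phase parameter is directly the quantity the phase
metrics estimate), optional exponential damping `d` (default 0: sustained
oscillation), and AR(1) noise `x_t = α x_{t−1} + z_t` with Gaussian
innovations. The AR(1) state starts from its stationary distribution
(variance σ²/(1−α²)), so simulated noise is stationary from sample one and
calibration statistics need no burn-in. Optional extra white noise `e_t`
applies only while the *trend* is below a density cutoff, emulating the
surface-reflection noise of optically thin young cultures; gating on the
deterministic trend rather than the noisy value keeps generation
reproducible.

Defaults describe the study conditions the package is built around:
2-minute sampling (`dt = 1/30 h`), 10 days, a 24 h oscillation of 3 a.u.,
trend `20 + 2.98 t + 0.005 t²` a.u. (a lag-free culture growing ~3 a.u./h),
α = 0.7 and innovation s.d. 0.2 a.u. (stationary s.d. ≈ 0.28 a.u., clearly
visible against the 3 a.u. oscillation but not dominant). The traces these
defaults imitate are real in their broad statistical structure only: real
backscatter noise need not be exactly AR(1), its trend need not be
polynomial, and instrument artifacts (step changes after handling the
flask, condensation, drift of the optics) are not modeled. Tests passing
on synthetic data therefore validate the *analysis machinery* — its
statistics, calibration and bookkeeping — not the adequacy of the signal
model for any particular instrument.

All randomness flows from a single integer seed; derived series (null
batches, entrainment pairs) take child seeds from a seed sequence, so any
configuration is bit-reproducible.

## Conditioning

Detrending fits the polynomial on time rescaled to [−1, 1] (a degree-4
Vandermonde system over ~300 h is numerically ill-conditioned in raw
hours) and reports coefficients in the hour basis. The residual is
mean-centered to exactly zero mean.

Smoothing is a centered moving average. For an even window `w` (the
default 100) a plain `w`-point average is necessarily half a sample
off-center, so the classic centered even-order filter is used instead:
`w+1` taps with the two end taps at half weight. This filter is symmetric
(zero phase), exact on affine signals, and trims `w/2` samples per side —
at the default 2-min sampling, 50 samples ≈ 1.7 h per side. Odd windows
use the plain boxcar. Series too short to smooth are rejected rather than
passed through silently.

Peak detection reports strict local maxima separated by at least
`min_separation_h` (greedy, higher peak wins; leftmost sample on
plateaus). A pure separation rule cannot reject a small noise bump sitting
in a trough ≥ 12 h from both true peaks, so an optional prominence
threshold (off by default) is available for peak *matching* tasks.

## Wavelet analysis and red-noise significance

The Morlet CWT uses the analytic mother wavelet with ω₀ = 6 (the standard
choice balancing time and frequency resolution; exposed as a parameter)
and the normalization `sqrt(δt/s)·ψ0`, under which white noise of variance
σ² has expected power σ² at every scale. Scales follow the dyadic grid
`s_j = s0·2^{j·dj}` with `s0 = 2δt`, `dj = 0.125`, spanning
Fourier-equivalent periods up to 64 h by default (period = scale ×
4π/(ω₀+√(2+ω₀²)) ≈ 1.033 × scale). The transform is computed by FFT
cross-correlation zero-padded past 2N−1, which equals the defining direct
summation to machine precision (no circular wrap); the direct-summation
oracle in the test suite verifies this at 1e−6.

Cells closer than √2·s to either end are inside the cone of influence
(e-folding distance of the Morlet envelope); they are flagged and excluded
from the per-scale time-averaged "global" power used for significance
calls. The global summary is the time **mean** (not max) of power per
scale — the conventional global wavelet spectrum.

The null background is AR(1) with normalized spectrum
`P_k = (1−α²)/(1+α²−2α cos(2πk/N))`, evaluated at the (fractional)
frequency index matching each scale's equivalent period. Null wavelet
power normalized by series variance is distributed as ½·P_k·χ²₂, so the
pointwise level at quantile q is `variance · ½ · P_k · χ²₂(q)`. α = 0
recovers a flat white-Gaussian background (the mean of P_k over the
frequency circle is 1 up to an O(αᴺ) correction). α is estimated as
`max(0, (r₁ + √max(r₂,0))/2)` from the sample lag-1/lag-2
autocorrelations. No multiple-testing correction is applied across
periods: the 95% curve is pointwise, and the Monte-Carlo coverage check
measures exactly that pointwise property (95 ± 1% on pure AR(1) null
series with known α).

**Significance after smoothing.** The rhythm decision is made on the
moving-averaged signal, and this matters: the filter drives the sample
lag-1 autocorrelation toward 1 regardless of the underlying noise color,
and an AR(1) background fitted to the smoothed series badly underestimates
the null power near 24 h (in simulation, ~40% of oscillation-free series
were called rhythmic that way). The pipeline therefore (i) estimates α on
the pre-smoothing residual, where AR(1) is the intended model, and
(ii) multiplies the background spectrum by the smoothing filter's squared
frequency response |H(f)|², renormalized to unit mean over the frequency
circle, before applying the χ²₂ level. With this correction the null
false-positive rate in simulation is at the nominal few-percent level
while wild-type-like series remain detected with large margins. The
uncorrected path remains available (and is the correct one for signals
that were never filtered, e.g. the calibration experiment).

One conservative bias is inherited from the variance scaling: for strongly
rhythmic series the signal inflates the variance estimate and hence the
threshold. Detection margins at the default conditions are large enough
(observed ≈ 3× threshold at 24 h) that this costs no sensitivity.

## Fourier period and Q10

The period estimate is the reciprocal frequency of the selected peak of
the real-FFT **magnitude** spectrum (magnitude vs power is irrelevant for
peak ranking), zero-padded to 4× the sample count, which refines the
frequency grid to `1/(4 N δt)`. Candidate peaks are strict local maxima
with no prominence filter; the estimate is the highest-magnitude peak
whose period lies in the circadian plausibility band (default 18–32 h —
exposed as configuration), and its rank among all peaks is reported so a
"second-highest peak" selection is visible in the output. Zero padding
interpolates but never relocates spectral mass: padded and unpadded
estimates agree within one unpadded bin, a property the tests assert. The
function requires a mean-centered input (|mean| ≤ 0.25·s.d., a loose
heuristic that rejects obviously un-detrended traces while passing any
reasonable oscillation signal).

Q10 is computed from frequencies, `(R₂/R₁)^{10/(T₂−T₁)}`, with inputs
ordered internally so T₂ > T₁ (the formula is invariant under the swap).
Reports round to two decimals, the customary reporting precision.

## Phase metrics

Peak-based (not cross-correlation-based) by design: the experiments being
emulated compare peak times directly. Each peak of series A is matched to
the nearest peak of series B in time wrapped to (−P/2, P/2], and the
offset is the circular mean of the wrapped differences; a boundary offset
(exactly half a period, e.g. 12 h of 24 h) is reported as +P/2. Degree-4
detrending perturbs cosine peak times by up to about one sample (the
polynomial absorbs a little oscillation, phase-dependently), so
sample-accurate phase recovery is specified on mean-centered smoothed
signals; after full detrending the offset is accurate to ~2 samples.

The phosphorylation-cycle summary fits a degree-5 polynomial to per-time
replicate means (an outlier-insensitive smooth of a single cycle) and
takes its maximum on a 0.01 h grid restricted to the sampled interval —
outside it a degree-5 polynomial diverges and its extrema are meaningless.

The growth-rate estimate is the OLS slope of the *raw* backscatter from a
start time onward (the oscillation averages out over whole cycles); it
needs ≥ 10 samples past the start.

## Problem sizes and numerical choices

Simulation-based tests use 10-day series at 2-min sampling (7201 samples)
for recovery checks, 20 series per arm; the coverage calibration uses 200
AR(1) series of 4096 samples. These sizes give standard errors comfortably
inside the asserted tolerances (e.g. the pooled coverage estimate has
Monte-Carlo scatter ≈ 0.05 percentage points across seeds). Wavelet kernel
FFTs are cached per transform geometry, so batch experiments cost one
signal FFT plus one inverse FFT per scale. Ties in peak detection resolve
to the leftmost plateau sample; degenerate inputs (constant series,
too-short series, non-uniform grids) raise typed errors rather than
returning approximations.

## Known limitations

- The AR(1)-plus-filter background is still a model; structured
  disturbances (sampling events, temperature steps) are neither modeled
  nor repaired — non-uniform input is rejected, not patched.
- The significance curve is pointwise; scanning many periods inflates the
  family-wise error rate, which the calibration quantifies but does not
  correct.
- Period resolution is limited by record length: ~0.6 h per padded bin at
  24 h over 10 days. Estimates are quantized at that scale.
- The phospho fit assumes a single cycle within the sampled window; it is
  not a periodic model and cannot represent multiple cycles.
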