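# Methods

`dcsflow` implements the complete data-processing chain of a continuous-wave
diffuse correlation spectroscopy (DCS) instrument in software: photon-count
binning, multi-tau estimation of the intensity autocorrelation g2(τ),
validity gating, Nelder–Mead fitting of the semi-infinite
correlation-diffusion model to extract the blood flow index (BFI, αD_B), and
windowed pipelines with post-processing (moving average, spectral peak
detection).  A synthetic speckle photon-stream generator makes the whole
chain testable without an instrument.  This note records the model, the
numerical choices, and what the synthetic tests do and do not demonstrate.

## The correlation-diffusion model

For a homogeneous semi-infinite medium probed in reflectance at
source–detector separation ρ, the normalized field autocorrelation is

    g1(τ) = [exp(−r1·K(τ))/r1 − exp(−rb·K(τ))/rb] / H,
    K(τ)  = sqrt(A + B·αD_B·τ),

with A = 3µs′µa, B = 6µs′²κ0², κ0 = 2πn/λ, z0 = 1/µs′,
r1 = sqrt(z0² + ρ²), zb = (2/3µs′)(1+Reff)/(1−Reff),
rb = sqrt((2zb+z0)² + ρ²), and H the bracket evaluated at τ = 0.  The
measured intensity autocorrelation follows the Siegert relation
g2 = 1 + β·g1², with coherence factor β set by the detection optics.  The
fitted free parameters are αD_B (cm²/s) and β; everything else is fixed by
the optical properties and geometry.

Conventions chosen where the physics leaves latitude:

* κ0 is the wave number **in the medium** (κ0 = 2πn_medium/λ) with a default
  tissue index of 1.4.  This is the common convention in the DCS literature;
  both the index and the wavelength are configurable.
* Reff defaults to the standard diffuse-optics polynomial
  −1.440n⁻² + 0.710n⁻¹ + 0.668 + 0.0636n in the relative index
  n = n_medium/n_outside (≈ 0.53 for tissue/air).  An explicit
  `reff_override` reproduces any fixed choice.
* Units are cm, s, and cm²/s throughout; wavelengths are accepted in nm at
  the interface and stored in cm.
* g1 is clipped at 0 from below (floating cancellation at very large lags
  can leave a ~1e−17 negative residue), and the identity g1 = 1 is enforced
  exactly wherever B·αD_B·τ = 0 (zero lag or a static medium) instead of
  relying on bit-level agreement between two exp/sqrt code paths.

## Multi-tau correlation

Counts are accumulated in uniform base bins (1 µs default).  The lag
schedule is quasi-logarithmic: a 16-delay first stage at the base bin,
then stages of 8 delays each at successively doubled bin widths, each
stage's lag indices continuing contiguously after the previous stage's
maximum (k = 9..16 at each doubling with the default layout).  The two
standard presets are 80 delays (8 stages, max lag 4.096 ms) for
physiological work and liquid phantoms, and 120 delays (13 stages, max lag
131.072 ms) for the slow decays of near-static solid phantoms.  The exact
stage layout is configuration, not hard-coded, so alternative multi-tau
layouts can be expressed.

Normalization is symmetric: per lag k in a stage with Ns coarse samples,
g2(k) = G(k)·Ms / (Md(k)·Mdel(k)) with G the raw product accumulator, Md
and Mdel the direct and delayed monitor sums over the same index range
i = 0..Ns−k−1 (no wraparound or zero padding), and Ms = Ns − k.  This makes
g2 ≡ 1 exact for constant input and invariant under integer rescaling of
the counts.  Coarsening is by pairwise **summation** (not averaging): the
normalization cancels the factor and integer sums stay exact in float64.

The streaming accumulator (`MultiTauAccumulator`) consumes chunks and
carries per-stage history across chunk boundaries, so arbitrary chunkings
reproduce the one-shot result exactly; accumulators reset per measurement
window.  An independent direct-summation correlator
(`brute_force_correlate`) recomputes every scheduled lag from the full
series in O(N·L) and serves as the oracle: the two agree to ≤ 1e−12
relative on randomized series of all kinds.

A per-lag estimator subtlety: stage-s lags report the correlation of
bin-averaged intensity at the coarse bin width, evaluated against the model
at the nominal lag k·Δs.  With lag indices ≥ 9 per stage the induced bias
is at the few-per-mille level, far below the shot-noise floor of realistic
windows, and is left uncorrected.

## Curve validity gate

Before fitting, a curve must have a plausible intercept
(first g2 ∈ (1.05, 2.0)) and a decayed tail (|last g2 − 1| < 0.1).  The
bounds are configurable; the defaults accept β ∈ (0.05, 1) curves and
reject dark/faulty detectors (intercept ≈ 1 or below) and undecayed curves
whose lag range is too short for the flow being measured.  Gated-out
windows become missing values, never aborts.

## Nelder–Mead fitting

The objective is the mean squared error between measured and model g2 over
**all** scheduled lags.  The simplex is a triangle in (β, log10 αD_B)
space — αD_B spans decades, so simplex geometry is far better conditioned
in the log coordinate.  Classical coefficients (reflect 1, expand 2,
contract 0.5, shrink 0.5) and standard accept/reject rules are used, with
candidates clipped to box bounds β ∈ (0, 1.2], αD_B ∈ [1e−12, 1e−5] cm²/s
(prevents overflow in the model and covers the phantom-to-physiology
range).  Ties in the best/good/worst sort are broken toward smaller αD_B
for determinism.

Termination: relative MSE spread |MSE(worst) − MSE(best)| / max(MSE(best),
1e−30) < 1e−4, or 100 iterations.  The defaults recover noiseless curves to
~1e−6 relative in ≤ 55 iterations from the default initial simplex
(β, αD_B) = (0.40, 1e−9), (0.55, 1e−8), (0.45, 5e−8) — vertices chosen to
span the expected result range, which is also the practical safeguard
against the method's known weakness for local minima.  A degenerate
(zero-area) simplex aborts the fit as invalid input.  If bounds clipping
collapses the simplex mid-run the current best vertex is returned as
converged; in practice this occurs only for pathological inputs.

Known degenerate input: a curve that is flat at 1 + β over the whole lag
range (lags far below the decay) pins β but leaves αD_B unidentified — the
fit slides it toward the insensitive region at the lower bound.  The gate's
tail check rejects such curves in pipeline use.

## Synthetic speckle streams

The simulator emulates the photon stream of an APD behind a single-mode
fiber:

1. **Field.**  Each of `n_modes` detected speckle modes is a proper complex
   Gaussian process whose autocovariance equals the model g1 for the
   instantaneous flow state.  Blocks of samples are generated exactly by
   circulant embedding: the covariance at lags 0..m/2 (evaluated from the
   model, m a power of two ≥ 2× the block length) is extended symmetrically,
   its FFT eigenvalues clipped at zero against round-off, and complex
   white noise colored in the spectral domain.  The block intensity is the
   sum of squared mode magnitudes, so the ensemble intensity autocorrelation
   is 1 + (1/n_modes)·g1²: β = 1/n_modes **exactly**.  Arbitrary β would
   need unequal mode weights and is deliberately not offered — integer mode
   counts keep the truth value exact for tests.
2. **Counts.**  Photon counts per 1 µs bin are Poisson with mean
   proportional to the bin-integrated intensity, normalized by the ensemble
   intensity mean so the expected rate equals `mean_count_rate`
   (doubly-stochastic statistics: speckle fluctuations plus shot noise).
   The per-bin draws are realized as one Poisson total placed by the
   inverse CDF of the per-bin means — exactly equivalent, and much faster
   at 10⁶ bins/s.  An optional uniform dark-count rate (default 0) adds an
   uncorrelated background; dead time and afterpulsing are not modeled.
3. **Nonstationarity.**  Time-varying flow (cuff occlusion, pulsatile
   modulation) is quasi-static: each block uses αD_B at its midpoint.
   Physiological modulation (~1–2 Hz) is 3–4 orders of magnitude slower
   than speckle decorrelation (~10–100 µs), so the approximation is
   excellent.  Blocks are mutually independent; only lag products spanning
   a block boundary lose correlation, and block lengths are kept ≥ 100×
   the decorrelation time (0.125 s for constant flow, 20 ms for pulsatile,
   0.1 s for the cuff profile) so the effect is negligible against
   sampling noise.  `field_dt` must be ≤ 1/10 of the fastest 1/e
   decorrelation time or the spec is rejected.

What the simulator does **not** emulate: real detector artifacts
(afterpulsing, dead time), laser intensity drift, probe-motion artifacts,
layered or heterogeneous tissue, and the true mapping from red-blood-cell
dynamics to αD_B.  Passing end-to-end tests therefore demonstrate that the
estimator chain is self-consistent under the model's own assumptions — not
that the model is an accurate description of any particular tissue.

### Scenario presets

* `solid_phantom` — αD_B = 1e−10 cm²/s in silicone-phantom optics
  (µs′ = 17.2, µa = 0.23 cm⁻¹); near-static, for the 120-delay schedule.
* `liquid_phantom_series` — four constant-flow specs at 1.25e−9 … 1.25e−10
  cm²/s (a decade, strictly decreasing) in Intralipid-like optics
  (µs′ = 20, µa = 0.14 cm⁻¹), emulating a viscosity (methyl-cellulose)
  series.  The values sit slightly above typical phantom BFIs so each decay
  completes within the 80-delay schedule's 4.1 ms lag range and passes the
  tail gate.
* `cuff_ischemia` — 10 s baseline at 1e−8 cm²/s, 25 s occlusion at 15% of
  baseline, release with a 2.2× hyperemic overshoot relaxing back with a
  5 s time constant (60 s total).
* `pulsatile` — sinusoidal modulation of αD_B (base 1e−8 cm²/s, fractional
  amplitude 0.3) at 1.45 Hz, a resting heart rate; 60 s at 2×10⁵ counts/s
  (a realistic rate for fast DCS, where 20 ms windows need the photons).

The default count rate elsewhere is 10⁵ counts/s — typical DCS practice;
instrument count rates are application-specific.

## Pipeline

Windows are non-overlapping, aligned to the stream start, of length
1/measurement_rate; the trailing partial window is dropped and logged, so
total processed counts are conserved.  Each window is correlated, gated,
and fitted independently; failures yield NaN with a recorded reason.  The
window must cover the correlator schedule's minimum support (largest lag
plus 8 coarsest-stage samples): the 80-delay preset fits a 20 ms (50 Hz)
window, while the 120-delay preset requires ≥ 6.3 s windows and is refused
at 50 Hz with an explicit error.

The moving average is a centered, NaN-aware box filter (truncated at the
edges, length-preserving); missing values are excluded from each local mean
and never silently interpolated, except inside `bfi_spectrum` where linear
interpolation is applied explicitly and flagged in the result.  The
spectrum is the one-sided FFT magnitude of the mean-removed segment
(≥ 4 s required); the dominant peak is reported above 0.5 Hz, excluding DC
and the drift band.

## Problem sizes used in the shipped checks

The test suite and the acceptance script regenerate everything they
measure: randomized correlator-oracle comparisons on series of ~2×10⁵–10⁶
bins; noiseless recovery on a 3×4 (β, αD_B) grid; four 30 s constant-flow
streams at 10⁵ counts/s processed as 30×1 s windows each; one 60 s
pulsatile stream processed as 3000×20 ms windows; one 60 s cuff stream at
1 Hz.  These sizes give sampling errors comfortably inside the asserted
tolerances (e.g. end-to-end BFI recovery lands within a few percent against
a 15% bound) while keeping a full run in minutes on one CPU.

## Known limitations

* The semi-infinite homogeneous model only; no two-layer, Monte Carlo, or
  learned forward models.
* Autocorrelation of a single detector channel; no cross-correlation.
* β is restricted to 1/integer in the simulator (exactness over
  flexibility).
* The fit uses all scheduled lags with uniform weight; no lag-segment
  selection or noise-model weighting.
* The gate's "expected range" bounds are heuristics; they are configurable
  and should be tuned to the instrument in real deployments.
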