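# dcsflow

A software implementation of the complete data-processing chain of a
continuous-wave **diffuse correlation spectroscopy (DCS)** instrument.

DCS monitors microvascular blood perfusion non-invasively: coherent
near-infrared light is multiply scattered in tissue, and the motion of red
blood cells makes the detected speckle intensity fluctuate.  The decay rate
of the temporal intensity autocorrelation g2(τ) encodes the flow.  Fitting
g2 with the semi-infinite solution of the correlation-diffusion equation
yields the **blood flow index** (BFI, written αD_B, in cm²/s), the standard
flow surrogate used for bedside monitoring of cerebral and muscle
perfusion.

`dcsflow` provides, as a library plus a CLI:

* **photon binning** — arrival timestamps to uniform counts (1 µs default);
* **multi-tau correlator** — quasi-logarithmic lag schedule (80- and
  120-delay presets: a 16-delay first stage plus 8 delays per doubled-bin
  stage), symmetric normalization, streaming chunked input, and an exact
  direct-summation reference correlator as oracle;
* **analyzer** — Nelder–Mead minimization of the mean squared error between
  measured and model g2 over (β, αD_B), with a configurable curve-validity
  gate;
* **pipeline** — windowed counts → correlation → gate → fit → BFI time
  series at a chosen measurement rate (e.g. 1 Hz or 50 Hz), with NaN-aware
  moving average and spectral peak detection (heart rate from pulsatile
  flow);
* **simulator** — synthetic APD-like photon streams whose statistics follow
  g2 = 1 + β·g1² exactly (circulant-embedded complex Gaussian speckle modes,
  β = 1/n_modes, Poisson shot noise, constant / cuff-occlusion / pulsatile
  flow profiles), so the whole chain is testable with no instrument.

## The model

    g2(τ) = 1 + β·g1(τ)²                      (Siegert relation)
    g1(τ) = [e^{−r1·K(τ)}/r1 − e^{−rb·K(τ)}/rb] / H
    K(τ)  = sqrt(A + B·αD_B·τ)

with A = 3µs′µa, B = 6µs′²κ0², κ0 = 2πn/λ, z0 = 1/µs′,
r1 = sqrt(z0²+ρ²), zb = (2/3µs′)(1+Reff)/(1−Reff),
rb = sqrt((2zb+z0)²+ρ²), H = g1-numerator at τ = 0.  Free parameters:
αD_B and β.  See `docs/methods.md` for conventions, numerical choices, and
limitations.

## Worked example

Simulate 10 s of constant-flow speckle photons at 10⁵ counts/s (two
detected modes, so β = 0.5) and process it at 1 Hz:

```python
import numpy as np
from dcsflow import (
    ConstantFlow, OpticalConfig, PipelineConfig, SimulationSpec,
    run_pipeline, simulate_photon_stream,
)

spec = SimulationSpec(
    optics=OpticalConfig.from_nm(mu_a=0.1, mu_s_prime=10.0, rho=1.0),
    flow_profile=ConstantFlow(1e-8),   # truth: BFI = 1e-8 cm^2/s
    duration=10.0, mean_count_rate=1e5, n_modes=2, seed=42,
)
stream = simulate_photon_stream(spec)
config = PipelineConfig(optics=spec.optics, measurement_rate=1.0)
series = run_pipeline(stream, config)
print(f"windows fitted: {sum(s == 'ok' for s in series.gate_status)}/{len(series)}")
print(f"mean BFI:  {np.nanmean(series.alpha_db):.3e} cm^2/s")
print(f"mean beta: {np.nanmean(series.beta):.3f}")
```

Output:

```
windows fitted: 10/10
mean BFI:  1.005e-08 cm^2/s
mean beta: 0.499
```

All ten 1 s windows pass the validity gate; the fitted BFI recovers the
simulated 1e−8 cm²/s to 0.5% and the coherence factor recovers
β = 1/n_modes = 0.5.

The same chain is available from the shell.  With a `config.toml` like

```toml
[optics]
mu_a = 0.1          # absorption, 1/cm
mu_s_prime = 10.0   # reduced scattering, 1/cm
rho_cm = 1.0        # source-detector separation, cm
wavelength_nm = 785.0
```

run:

```
dcsflow simulate pulsatile --seed 3 -o counts.csv
dcsflow pipeline counts.csv --config config.toml --rate 50 --smooth 15 -o bfi.csv
dcsflow spectrum bfi.csv            # -> dominant peak at 1.450 Hz
```

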