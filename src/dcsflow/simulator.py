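"""Synthetic speckle photon streams for testing the processing chain.

Emulates the signal an avalanche photodiode (APD) delivers in a diffuse
correlation spectroscopy measurement, so the correlator, analyzer and
pipeline can be exercised without hardware:

1.  The detected optical field is modeled as the sum of ``n_modes``
    independent proper complex Gaussian processes, each with normalized
    autocorrelation equal to the semi-infinite model's g1 for the
    (instantaneous) flow state.  Each block of field samples is synthesized
    exactly by circulant embedding of the target covariance.  The intensity
    I = sum_m |E_m|^2 then has ensemble autocorrelation
    g2(tau) = 1 + (1/n_modes) * g1(tau)^2, i.e. coherence factor
    beta = 1/n_modes exactly (fully developed speckle; integer mode count).
2.  Photon counts per time bin are drawn from a Poisson law with mean
    proportional to the local intensity (doubly stochastic / shot noise),
    scaled so the ensemble mean rate equals ``mean_count_rate``.

Nonstationary flow (cuff occlusion, pulsatile modulation) is simulated
quasi-statically: each synthesis block uses the flow state at its midpoint.
This is accurate because physiological modulation (~1-2 Hz) is orders of
magnitude slower than speckle decorrelation (~10-100 us).  Blocks are
independent, which only perturbs lag products spanning a block boundary;
block lengths are kept >= 100x the decorrelation time so the effect is
negligible against sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, List, Optional, Union

import numpy as np

from .correlator import PhotonCountSeries
from .model import (
    ModelConstants,
    OpticalConfig,
    _g1_values,
    decorrelation_time,
    derive_constants,
)

__all__ = [
    "ConstantFlow",
    "SinusoidalFlow",
    "CuffFlow",
    "SimulationSpec",
    "synthesize_speckle_intensity",
    "sample_photon_counts",
    "simulate_photon_stream",
    "scenario_presets",
    "SCENARIO_NAMES",
]


# --- flow profiles -------------------------------------------------------


@dataclass(frozen=True)
class ConstantFlow:
    """Steady flow at a fixed alpha_Db (cm^2/s)."""

    alpha_db: float

    def alpha_db_at(self, t: float) -> float:
        return self.alpha_db

    @property
    def is_constant(self) -> bool:
        return True


@dataclass(frozen=True)
class SinusoidalFlow:
    """Pulsatile flow: alpha_Db(t) = base * (1 + amplitude_frac*sin(2 pi f t)).

    Emulates the cardiac modulation of blood flow; ``frequency_hz`` is the
    heart rate (~1-2 Hz), ``amplitude_frac`` the fractional pulsatility.
    """

    base: float
    frequency_hz: float
    amplitude_frac: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.amplitude_frac < 1:
            raise ValueError("amplitude_frac must be in [0, 1)")

    def alpha_db_at(self, t: float) -> float:
        return self.base * (
            1.0 + self.amplitude_frac * math.sin(2.0 * math.pi * self.frequency_hz * t)
        )

    @property
    def is_constant(self) -> bool:
        return False


@dataclass(frozen=True)
class CuffFlow:
    """Arterial cuff-occlusion profile: baseline, suppression, hyperemia.

    alpha_Db is ``baseline`` for ``baseline_s`` seconds, drops to
    ``occlusion_frac * baseline`` while the cuff is inflated for
    ``occlusion_s`` seconds, then overshoots on release (reactive hyperemia)
    to ``(1 + overshoot_frac) * baseline`` and relaxes exponentially back to
    baseline with time constant ``recovery_tau_s``.
    """

    baseline: float
    baseline_s: float = 10.0
    occlusion_s: float = 25.0
    occlusion_frac: float = 0.15
    overshoot_frac: float = 1.2
    recovery_tau_s: float = 5.0

    def alpha_db_at(self, t: float) -> float:
        if t < self.baseline_s:
            return self.baseline
        if t < self.baseline_s + self.occlusion_s:
            return self.occlusion_frac * self.baseline
        dt = t - (self.baseline_s + self.occlusion_s)
        return self.baseline * (
            1.0 + self.overshoot_frac * math.exp(-dt / self.recovery_tau_s)
        )

    @property
    def is_constant(self) -> bool:
        return False


FlowProfile = Union[ConstantFlow, SinusoidalFlow, CuffFlow]


# --- simulation spec -----------------------------------------------------


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to synthesize one photon stream.

    ``n_modes`` sets the coherence factor beta = 1/n_modes.  ``field_dt`` is
    the field sampling step and must resolve the fastest decorrelation time
    (<= 1/10 of it).  ``count_bin_width`` is the photon-counting bin (1 us
    default, a typical hardware counter resolution) and must be an integer
    multiple of ``field_dt``.  ``block_dt`` bounds memory and sets the
    quasi-static update rate for nonstationary profiles; ``None`` selects an
    adequate default.
    """

    optics: OpticalConfig
    flow_profile: FlowProfile
    duration: float
    mean_count_rate: float = 1e5
    n_modes: int = 2
    field_dt: float = 1e-6
    count_bin_width: float = 1e-6
    dark_count_rate: float = 0.0
    block_dt: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_count_rate <= 0:
            raise ValueError("mean_count_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.field_dt <= 0:
            raise ValueError("field_dt must be positive")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.dark_count_rate < 0:
            raise ValueError("dark_count_rate must be >= 0")
        q = self.count_bin_width / self.field_dt
        if abs(q - round(q)) > 1e-9 or round(q) < 1:
            raise ValueError(
                "count_bin_width must be a positive integer multiple of field_dt"
            )

    @property
    def beta(self) -> float:
        """Coherence factor implied by the mode count."""
        return 1.0 / self.n_modes


def _fastest_decorrelation(spec: SimulationSpec, constants: ModelConstants) -> float:
    """1/e decorrelation time at the largest alpha_Db the profile reaches."""
    profile = spec.flow_profile
    if profile.is_constant:
        alpha_max = profile.alpha_db_at(0.0)
    else:
        t_grid = np.linspace(0.0, spec.duration, 2001)
        alpha_max = max(profile.alpha_db_at(float(t)) for t in t_grid)
    if alpha_max == 0:
        return math.inf
    return decorrelation_time(constants, alpha_max)


def _default_block_dt(spec: SimulationSpec, tau_c: float) -> float:
    """Block length: generous for constant flow, 20 ms for modulated flow."""
    floor = 100.0 * tau_c if math.isfinite(tau_c) else 0.0
    if spec.flow_profile.is_constant:
        block = max(0.125, floor)
    else:
        block = max(0.02, floor)
    return min(block, spec.duration)


def _embedding_scale(
    constants: ModelConstants, alpha_db: float, n_samples: int, field_dt: float
) -> np.ndarray:
    """Spectral amplitudes sqrt(lambda/m) of the circulant embedding.

    Cached on the most recent argument set: successive constant-flow blocks
    reuse the same eigenvalues.
    """
    key = (id(constants), alpha_db, n_samples, field_dt)
    if _embedding_scale._key == key:
        return _embedding_scale._value
    m = 1 << max(4, int(math.ceil(math.log2(2 * n_samples))))
    half = m // 2
    lags = np.arange(half + 1) * field_dt
    cov = _g1_values(constants, alpha_db, lags)
    row = np.concatenate([cov, cov[half - 1 : 0 : -1]])  # symmetric, length m
    lam = np.clip(np.fft.fft(row).real, 0.0, None)
    value = np.sqrt(lam / m)
    _embedding_scale._key, _embedding_scale._value = key, value
    return value


_embedding_scale._key = None
_embedding_scale._value = None


def _speckle_block(
    constants: ModelConstants,
    alpha_db: float,
    n_samples: int,
    field_dt: float,
    n_modes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One intensity block via circulant embedding of the field covariance.

    Each mode is a proper complex Gaussian sequence whose autocovariance at
    lags 0..n_samples-1 equals g1 for the given flow state.  The covariance
    is embedded in a symmetric circulant of power-of-two length m >= 2n
    (fast FFTs; the extra lags are evaluated from the model, so the
    embedding's eigenvalues are nonnegative up to round-off and are clipped
    at 0).  The block intensity is the sum of squared magnitudes over modes,
    ensemble mean ``n_modes``.
    """
    scale = _embedding_scale(constants, alpha_db, n_samples, field_dt)
    m = len(scale)
    # CN(0,1) spectral amplitudes for all modes at once
    w = rng.standard_normal((n_modes, 2, m)) * math.sqrt(0.5)
    z = np.fft.fft(scale * (w[:, 0] + 1j * w[:, 1]), axis=-1)[:, :n_samples]
    return np.einsum("ij,ij->j", z.real, z.real) + np.einsum(
        "ij,ij->j", z.imag, z.imag
    )


def _intensity_blocks(
    spec: SimulationSpec, rng: np.random.Generator
) -> Iterator[np.ndarray]:
    """Yield successive intensity blocks covering the full duration."""
    constants = derive_constants(spec.optics)
    tau_c = _fastest_decorrelation(spec, constants)
    if math.isfinite(tau_c) and spec.field_dt > tau_c / 10.0:
        raise ValueError(
            f"field_dt {spec.field_dt:g} s too coarse: must be <= 1/10 of the "
            f"fastest decorrelation time ({tau_c:g} s)"
        )
    block_dt = spec.block_dt if spec.block_dt is not None else _default_block_dt(spec, tau_c)
    total = int(round(spec.duration / spec.field_dt))
    block_len = max(int(round(block_dt / spec.field_dt)), 16)
    start = 0
    while start < total:
        n = min(block_len, total - start)
        t_mid = (start + n / 2.0) * spec.field_dt
        alpha = spec.flow_profile.alpha_db_at(t_mid)
        yield _speckle_block(constants, alpha, n, spec.field_dt, spec.n_modes, rng)
        start += n


def synthesize_speckle_intensity(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Full intensity trace (arbitrary units, ensemble mean = n_modes).

    Materializes the whole trace (8 bytes/sample at ``field_dt``); for long
    high-rate streams prefer :func:`simulate_photon_stream`, which converts
    block by block.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return np.concatenate(list(_intensity_blocks(spec, rng)))


def _counts_from_intensity(
    intensity: np.ndarray, spec: SimulationSpec, rng: np.random.Generator
) -> np.ndarray:
    """Poisson counts per count bin given an intensity block."""
    if np.any(intensity < 0):
        raise ValueError("intensity must be nonnegative")
    q = int(round(spec.count_bin_width / spec.field_dt))
    n_bins = len(intensity) // q
    lam_field = intensity * (spec.mean_count_rate * spec.field_dt / spec.n_modes)
    lam = lam_field[: n_bins * q].reshape(n_bins, q).sum(axis=1)
    lam += spec.dark_count_rate * spec.count_bin_width
    # independent Poisson(lam_i) drawn as a Poisson total distributed over
    # bins by the inverse CDF of lam -- exact and much faster than per-bin
    # draws at these bin counts
    csum = np.cumsum(lam)
    total = csum[-1]
    if total <= 0:
        return np.zeros(n_bins, dtype=np.int64)
    n_events = rng.poisson(total)
    u = rng.uniform(0.0, total, n_events)
    idx = np.searchsorted(csum, u, side="right")
    return np.bincount(idx, minlength=n_bins).astype(np.int64)


def sample_photon_counts(
    intensity: np.ndarray,
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
) -> PhotonCountSeries:
    """Photon counts from an intensity trace (doubly stochastic sampling).

    Counts in each ``count_bin_width`` bin are Poisson with mean proportional
    to the intensity integrated over the bin, normalized so the ensemble mean
    rate equals ``mean_count_rate`` (the intensity trace has ensemble mean
    ``n_modes``).  Shot noise is uncorrelated between bins and leaves the
    normalized g2 of the underlying intensity intact.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    counts = _counts_from_intensity(np.asarray(intensity, dtype=float), spec, rng)
    return PhotonCountSeries(counts, bin_width=spec.count_bin_width)


def simulate_photon_stream(spec: SimulationSpec) -> PhotonCountSeries:
    """Synthesize the full photon-count stream for a spec (block-wise).

    Deterministic: identical spec + seed give an identical stream.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    q = int(round(spec.count_bin_width / spec.field_dt))
    chunks: List[np.ndarray] = []
    leftover = np.empty(0)
    for block in _intensity_blocks(spec, rng):
        block = np.concatenate([leftover, block]) if len(leftover) else block
        n_full = (len(block) // q) * q
        leftover = block[n_full:]
        if n_full:
            chunks.append(_counts_from_intensity(block[:n_full], spec, rng))
    counts = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.int64)
    return PhotonCountSeries(counts, bin_width=spec.count_bin_width)


# --- scenario presets ----------------------------------------------------

SCENARIO_NAMES = (
    "solid_phantom",
    "liquid_phantom_series",
    "cuff_ischemia",
    "pulsatile",
)

#: Optics of the silicone solid phantom (mu_s' = 17.2 /cm, mu_a = 0.23 /cm).
_SOLID_OPTICS = OpticalConfig.from_nm(mu_a=0.23, mu_s_prime=17.2, rho=1.0)
#: Optics of the Intralipid/ink liquid phantom (mu_s' ~ 20, mu_a ~ 0.14 /cm).
_LIQUID_OPTICS = OpticalConfig.from_nm(mu_a=0.14, mu_s_prime=20.0, rho=1.0)
#: Generic forearm-tissue optics for in-vivo style scenarios.
_TISSUE_OPTICS = OpticalConfig.from_nm(mu_a=0.1, mu_s_prime=10.0, rho=1.0)

#: Liquid-phantom flow series: viscosity increases (methyl-cellulose style)
#: so alpha_Db falls monotonically, spanning one decade.
LIQUID_PHANTOM_ALPHA_DB = (1.25e-9, 5.0e-10, 2.5e-10, 1.25e-10)


def scenario_presets(
    name: str, seed: int = 0, **overrides
) -> Union[SimulationSpec, List[SimulationSpec]]:
    """Fully populated simulation specs for the standard test scenarios.

    * ``solid_phantom``: near-zero flow (alpha_Db = 1e-10 cm^2/s) in the
      solid-phantom optics; 30 s, for use with the 120-delay schedule.
    * ``liquid_phantom_series``: a list of four 30 s specs with strictly
      decreasing alpha_Db (viscosity series), liquid-phantom optics.
    * ``cuff_ischemia``: 10 s baseline, 25 s occlusion, hyperemic overshoot
      and recovery; 60 s total at tissue optics.
    * ``pulsatile``: sinusoidal alpha_Db modulation at 1.45 Hz (a resting
      heart rate), 60 s, higher count rate for fast (50 Hz) windowing.

    ``overrides`` replace any :class:`SimulationSpec` field.
    """
    if name == "solid_phantom":
        spec = SimulationSpec(
            optics=_SOLID_OPTICS,
            flow_profile=ConstantFlow(1e-10),
            duration=30.0,
            seed=seed,
        )
        return replace(spec, **overrides) if overrides else spec
    if name == "liquid_phantom_series":
        specs = [
            SimulationSpec(
                optics=_LIQUID_OPTICS,
                flow_profile=ConstantFlow(alpha),
                duration=30.0,
                seed=seed + i,
            )
            for i, alpha in enumerate(LIQUID_PHANTOM_ALPHA_DB)
        ]
        return [replace(s, **overrides) for s in specs] if overrides else specs
    if name == "cuff_ischemia":
        # the profile changes on >= 5 s timescales, so 0.1 s quasi-static
        # blocks are ample (and phases of constant flow reuse cached spectra)
        spec = SimulationSpec(
            optics=_TISSUE_OPTICS,
            flow_profile=CuffFlow(baseline=1e-8),
            duration=60.0,
            block_dt=0.1,
            seed=seed,
        )
        return replace(spec, **overrides) if overrides else spec
    if name == "pulsatile":
        spec = SimulationSpec(
            optics=_TISSUE_OPTICS,
            flow_profile=SinusoidalFlow(base=1e-8, frequency_hz=1.45),
            duration=60.0,
            mean_count_rate=2e5,
            block_dt=0.02,
            seed=seed,
        )
        return replace(spec, **overrides) if overrides else spec
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
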