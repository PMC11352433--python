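"""Semi-infinite correlation-diffusion model for diffuse correlation spectroscopy.

Coherent light multiply scattered by a turbid medium (tissue) decorrelates as
the scatterers (red blood cells) move.  For a semi-infinite homogeneous medium
probed in reflectance at source-detector separation ``rho``, the normalized
field autocorrelation g1(tau) solves the correlation-diffusion equation with
an extrapolated-zero boundary:

    g1(tau) = [exp(-r1*K(tau))/r1 - exp(-rb*K(tau))/rb] / H
    K(tau)  = sqrt(A + B * alpha_Db * tau)

with fixed geometry/optics constants

    A  = 3 * mu_s' * mu_a                 [cm^-2]
    B  = 6 * mu_s'^2 * k0^2               [cm^-4]
    k0 = 2*pi*n_medium / lambda           [cm^-1]  (wave number in the medium)
    z0 = 1 / mu_s'                        [cm]
    r1 = sqrt(z0^2 + rho^2)               [cm]
    zb = (2/(3*mu_s')) * (1+Reff)/(1-Reff)  [cm]
    rb = sqrt((2*zb + z0)^2 + rho^2)      [cm]
    H  = exp(-r1*sqrt(A))/r1 - exp(-rb*sqrt(A))/rb   [cm^-1]

The measured intensity autocorrelation follows the Siegert relation

    g2(tau) = 1 + beta * g1(tau)^2

with coherence factor ``beta`` (0 < beta <= 1 for ideal detection; set by the
number of detected speckle modes).  The free parameters fitted from data are
``alpha_Db`` -- the blood flow index (BFI), an effective Brownian diffusion
coefficient in cm^2/s -- and ``beta``.

All lengths are in cm, times in s, alpha_Db in cm^2/s.  Wavelengths are
accepted in nm at the interface and stored in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "OpticalConfig",
    "ModelConstants",
    "FlowState",
    "CorrelationCurve",
    "effective_reflection_coefficient",
    "derive_constants",
    "g1_model",
    "g2_model",
    "decorrelation_time",
]

#: nm -> cm conversion factor.
NM_TO_CM = 1e-7


def effective_reflection_coefficient(n_rel: float) -> float:
    """Effective Fresnel reflection coefficient for a refractive-index step.

    Standard diffuse-optics polynomial approximation in the relative index
    ``n_rel = n_medium / n_outside``:

        Reff = -1.440/n_rel^2 + 0.710/n_rel + 0.668 + 0.0636*n_rel

    Accurate for 1 <= n_rel <~ 1.6 (Reff ~ 0.53 for tissue/air, n_rel = 1.4).
    """
    if n_rel <= 0:
        raise ValueError(f"n_rel must be positive, got {n_rel}")
    return -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel


@dataclass(frozen=True)
class OpticalConfig:
    """Optical properties and probe geometry parameterizing the model.

    Parameters
    ----------
    mu_a : absorption coefficient, cm^-1.
    mu_s_prime : reduced scattering coefficient, cm^-1.
    rho : source-detector separation, cm.
    wavelength_cm : laser wavelength, cm (use :meth:`from_nm` for nm input).
    n_medium : refractive index of the medium (tissue ~ 1.4).
    n_outside : refractive index outside the boundary (air = 1.0).
    reff_override : if given, use this effective reflection coefficient
        instead of the polynomial approximation; must lie in [0, 1).
    """

    mu_a: float
    mu_s_prime: float
    rho: float
    wavelength_cm: float = 785.0 * NM_TO_CM
    n_medium: float = 1.4
    n_outside: float = 1.0
    reff_override: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("mu_a", "mu_s_prime", "rho", "wavelength_cm"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive and finite, got {value}")
        if self.n_medium < 1.0:
            raise ValueError(f"n_medium must be >= 1, got {self.n_medium}")
        if self.n_outside <= 0:
            raise ValueError(f"n_outside must be positive, got {self.n_outside}")
        if self.reff_override is not None and not (0.0 <= self.reff_override < 1.0):
            raise ValueError(
                f"reff_override must lie in [0, 1), got {self.reff_override}"
            )

    @classmethod
    def from_nm(
        cls,
        mu_a: float,
        mu_s_prime: float,
        rho: float,
        wavelength_nm: float = 785.0,
        **kwargs,
    ) -> "OpticalConfig":
        """Build a config with the wavelength given in nm."""
        return cls(
            mu_a=mu_a,
            mu_s_prime=mu_s_prime,
            rho=rho,
            wavelength_cm=wavelength_nm * NM_TO_CM,
            **kwargs,
        )

    @property
    def wavelength_nm(self) -> float:
        return self.wavelength_cm / NM_TO_CM

    @property
    def reff(self) -> float:
        """Effective reflection coefficient (override or polynomial)."""
        if self.reff_override is not None:
            return self.reff_override
        return effective_reflection_coefficient(self.n_medium / self.n_outside)


@dataclass(frozen=True)
class ModelConstants:
    """Precomputed fixed quantities of the semi-infinite solution.

    Units: A cm^-2, B cm^-4, r1/rb/zb cm, H cm^-1, k0 cm^-1, reff unitless.
    """

    A: float
    B: float
    r1: float
    rb: float
    zb: float
    H: float
    k0: float
    reff: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "r1", "rb", "zb", "H", "k0"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive and finite, got {value}")
        if self.rb <= self.r1:
            raise ValueError(f"rb ({self.rb}) must exceed r1 ({self.r1})")


@dataclass(frozen=True)
class FlowState:
    """A (alpha_Db, beta) point: blood flow index and coherence factor.

    alpha_db is in cm^2/s and must be >= 0 (0 = static medium); beta must be
    positive (physically <= 1; the fitter may probe slightly above 1).
    """

    alpha_db: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha_db) and self.alpha_db >= 0):
            raise ValueError(f"alpha_db must be >= 0 and finite, got {self.alpha_db}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be positive and finite, got {self.beta}")


@dataclass(frozen=True)
class CorrelationCurve:
    """Lag times and normalized intensity autocorrelation values.

    ``n_samples`` (number of base time bins contributing) and ``mean_rate``
    (counts/s) are populated by the correlator and ``None`` for model curves.
    """

    taus: np.ndarray
    g2: np.ndarray
    n_samples: Optional[int] = None
    mean_rate: Optional[float] = None

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        g2 = np.asarray(self.g2, dtype=float)
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "g2", g2)
        if taus.ndim != 1 or g2.ndim != 1:
            raise ValueError("taus and g2 must be one-dimensional")
        if len(taus) != len(g2):
            raise ValueError(
                f"length mismatch: {len(taus)} taus vs {len(g2)} g2 values"
            )
        if len(taus) == 0:
            raise ValueError("correlation curve must be nonempty")
        if np.any(np.diff(taus) <= 0):
            raise ValueError("taus must be strictly increasing")

    def __len__(self) -> int:
        return len(self.taus)


def derive_constants(optics: OpticalConfig) -> ModelConstants:
    """Derive the fixed model constants from optics and geometry.

    See the module docstring for the formulas.  Raises ``ValueError`` for
    invalid optics (enforced by :class:`OpticalConfig`) or ``reff >= 1``.
    """
    reff = optics.reff
    if not (0.0 <= reff < 1.0):
        raise ValueError(f"effective reflection coefficient must be in [0, 1), got {reff}")
    mu_a = optics.mu_a
    mu_sp = optics.mu_s_prime
    rho = optics.rho
    A = 3.0 * mu_sp * mu_a
    k0 = 2.0 * math.pi * optics.n_medium / optics.wavelength_cm
    B = 6.0 * mu_sp**2 * k0**2
    z0 = 1.0 / mu_sp
    r1 = math.hypot(z0, rho)
    zb = (2.0 / (3.0 * mu_sp)) * (1.0 + reff) / (1.0 - reff)
    rb = math.hypot(2.0 * zb + z0, rho)
    sqrtA = math.sqrt(A)
    H = math.exp(-r1 * sqrtA) / r1 - math.exp(-rb * sqrtA) / rb
    return ModelConstants(A=A, B=B, r1=r1, rb=rb, zb=zb, H=H, k0=k0, reff=reff)


def _as_tau_array(taus: Sequence[float]) -> np.ndarray:
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    if np.any(~np.isfinite(taus)) or np.any(taus < 0):
        raise ValueError("lag times must be finite and nonnegative")
    if len(taus) > 1 and np.any(np.diff(taus) <= 0):
        raise ValueError("lag times must be strictly increasing")
    return taus


def _g1_values(constants: ModelConstants, alpha_db: float, taus: np.ndarray) -> np.ndarray:
    """Unchecked vectorized g1 evaluation (taus may be any shape)."""
    arg = constants.B * alpha_db * np.asarray(taus, dtype=float)
    K = np.sqrt(constants.A + arg)
    bracket = (
        np.exp(-constants.r1 * K) / constants.r1
        - np.exp(-constants.rb * K) / constants.rb
    )
    # floating cancellation at huge tau can leave a tiny negative residue
    g1 = np.clip(bracket / constants.H, 0.0, None)
    # K(0) = sqrt(A) makes the numerator equal H: enforce the identity
    # exactly rather than to the last ulp (covers tau = 0 and alpha_db = 0)
    return np.where(arg == 0.0, 1.0, g1)


def g1_model(
    constants: ModelConstants, flow: FlowState, taus: Sequence[float]
) -> np.ndarray:
    """Normalized field autocorrelation g1 at the given lag times.

    g1(0) = 1 exactly; g1 decays monotonically in tau and, at fixed tau > 0,
    decreases with alpha_db.
    """
    return _g1_values(constants, flow.alpha_db, _as_tau_array(taus))


def g2_model(
    constants: ModelConstants, flow: FlowState, taus: Sequence[float]
) -> CorrelationCurve:
    """Model intensity autocorrelation via the Siegert relation.

    g2(tau) = 1 + beta * g1(tau)^2, so g2(0) = 1 + beta and g2 -> 1 as the
    field decorrelates.
    """
    taus = _as_tau_array(taus)
    g1 = _g1_values(constants, flow.alpha_db, taus)
    return CorrelationCurve(taus=taus, g2=1.0 + flow.beta * g1**2)


def decorrelation_time(constants: ModelConstants, alpha_db: float) -> float:
    """Lag at which g1 falls to 1/e, found by bisection on a log-tau grid.

    Returns ``inf`` for a static medium (alpha_db == 0).
    """
    if alpha_db == 0:
        return math.inf
    # bracket: g1=1/e requires K ~ sqrt(A)+O(1)/r1; scan generously
    taus = np.logspace(-12, 4, 4000)
    g1 = _g1_values(constants, alpha_db, taus)
    below = np.nonzero(g1 <= math.exp(-1))[0]
    if len(below) == 0:
        return math.inf
    i = below[0]
    if i == 0:
        return taus[0]
    # log-linear interpolation between the straddling grid points
    t0, t1 = taus[i - 1], taus[i]
    f0, f1 = g1[i - 1], g1[i]
    w = (f0 - math.exp(-1)) / (f0 - f1)
    return float(t0 * (t1 / t0) ** w)
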