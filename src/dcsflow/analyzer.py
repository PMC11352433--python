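"""Fitting (beta, alpha_Db) to a measured correlation curve.

The blood flow index is extracted by minimizing the mean squared error (MSE)
between the measured g2 curve and the semi-infinite model over all scheduled
lags, using the Nelder-Mead simplex method.  The fit mirrors a hardware
analyzer's decomposition into small steps so each is testable in isolation:

* :func:`mse` - objective evaluation for one (beta, alpha_Db) candidate;
* :func:`sort_simplex` - assign best/good/worst roles by ascending MSE;
* :func:`propose_points` - reflected/expanded/contracted/shrunk candidates;
* :func:`nelder_mead_fit` - the accept/reject iteration with termination on
  relative MSE spread or an iteration cap;
* :func:`validate_curve` - the pre-fit sanity gate on the curve's intercept
  and tail (a curve whose first point is implausible or whose tail has not
  decayed to 1 cannot be fitted meaningfully).

The search operates on internal coordinates (beta, log10 alpha_Db): alpha_Db
spans decades, so simplex geometry is far better conditioned in log space.
Candidates are clipped to box bounds before evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import CorrelationCurve, FlowState, ModelConstants, _g1_values

__all__ = [
    "FitConfig",
    "FitResult",
    "GateBounds",
    "GateResult",
    "Simplex",
    "SimplexVertex",
    "DegenerateSimplexError",
    "mse",
    "sort_simplex",
    "propose_points",
    "nelder_mead_fit",
    "validate_curve",
]

#: Floor for the relative-spread denominator so noiseless fits (MSE -> 0)
#: keep iterating instead of dividing by zero.
_SPREAD_EPS = 1e-30

#: Default initial simplex spanning the physiological/phantom range.
DEFAULT_INITIAL_SIMPLEX = (
    FlowState(alpha_db=1e-9, beta=0.40),
    FlowState(alpha_db=1e-8, beta=0.55),
    FlowState(alpha_db=5e-8, beta=0.45),
)


class DegenerateSimplexError(ValueError):
    """The simplex has (numerically) zero area and cannot make progress."""


@dataclass(frozen=True)
class FitConfig:
    """Nelder-Mead configuration.

    Coefficients default to the classical choice (reflection 1, expansion 2,
    contraction 0.5, shrink 0.5).  Termination: relative spread
    |MSE(worst) - MSE(best)| / max(MSE(best), eps) < convergence_threshold,
    or max_iterations reached.  Bounds are box constraints; candidates are
    clipped (alpha_db bounds must be positive for the log parameterization).
    """

    initial_simplex: Tuple[FlowState, FlowState, FlowState] = DEFAULT_INITIAL_SIMPLEX
    reflect: float = 1.0
    expand: float = 2.0
    contract: float = 0.5
    shrink: float = 0.5
    convergence_threshold: float = 1e-4
    max_iterations: int = 100
    beta_bounds: Tuple[float, float] = (1e-6, 1.2)
    alpha_db_bounds: Tuple[float, float] = (1e-12, 1e-5)

    def __post_init__(self) -> None:
        if len(self.initial_simplex) != 3:
            raise ValueError("initial_simplex must have exactly 3 vertices")
        for name in ("reflect", "expand", "contract", "shrink"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} coefficient must be positive")
        if not (self.expand > 1.0 > self.contract):
            raise ValueError("need expand > 1 > contract")
        if self.convergence_threshold <= 0:
            raise ValueError("convergence_threshold must be positive")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.alpha_db_bounds[0] <= 0 or self.alpha_db_bounds[1] <= self.alpha_db_bounds[0]:
            raise ValueError("alpha_db_bounds must be positive and increasing")
        if self.beta_bounds[0] <= 0 or self.beta_bounds[1] <= self.beta_bounds[0]:
            raise ValueError("beta_bounds must be positive and increasing")


@dataclass(frozen=True)
class SimplexVertex:
    flow: FlowState
    mse: float


@dataclass(frozen=True)
class Simplex:
    """Three (FlowState, MSE) vertices; after sorting, order is best, good,
    worst (ascending MSE)."""

    vertices: Tuple[SimplexVertex, SimplexVertex, SimplexVertex]

    def __post_init__(self) -> None:
        if len(self.vertices) != 3:
            raise ValueError("a simplex has exactly 3 vertices")

    @property
    def best(self) -> SimplexVertex:
        return self.vertices[0]

    @property
    def good(self) -> SimplexVertex:
        return self.vertices[1]

    @property
    def worst(self) -> SimplexVertex:
        return self.vertices[2]


@dataclass(frozen=True)
class GateBounds:
    """Validity gate: expected ranges for the curve's first and last points."""

    first_lo: float = 1.05
    first_hi: float = 2.0
    last_tol: float = 0.1


@dataclass(frozen=True)
class GateResult:
    passed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.passed


@dataclass(frozen=True)
class FitResult:
    """Outcome of a fit: flow is None when the input was rejected."""

    flow: Optional[FlowState]
    mse: float
    iterations: int
    converged: bool
    termination_reason: str  # "tolerance" | "max_iterations" | "invalid_input"


def mse(
    measured: CorrelationCurve, constants: ModelConstants, candidate: FlowState
) -> float:
    """Mean squared error between measured g2 and the model at the candidate.

    Every lag of the curve contributes; non-finite measured values are
    rejected.
    """
    g2m = measured.g2
    if np.any(~np.isfinite(g2m)):
        raise ValueError("measured curve contains non-finite g2 values")
    g1 = _g1_values(constants, candidate.alpha_db, measured.taus)
    resid = g2m - (1.0 + candidate.beta * g1**2)
    return float(np.mean(resid**2))


def sort_simplex(simplex: Simplex) -> Simplex:
    """Assign best/good/worst by ascending MSE.

    Ties are broken deterministically by favoring the smaller alpha_db, then
    the smaller beta.
    """
    ordered = sorted(
        simplex.vertices, key=lambda v: (v.mse, v.flow.alpha_db, v.flow.beta)
    )
    return Simplex(vertices=tuple(ordered))


# --- internal (beta, log10 alpha_db) coordinates -------------------------


def _to_xy(flow: FlowState) -> np.ndarray:
    if flow.alpha_db <= 0:
        raise ValueError("alpha_db must be positive for the log-space search")
    return np.array([flow.beta, math.log10(flow.alpha_db)])


def _from_xy(xy: np.ndarray, config: FitConfig) -> FlowState:
    beta = float(np.clip(xy[0], *config.beta_bounds))
    log_lo = math.log10(config.alpha_db_bounds[0])
    log_hi = math.log10(config.alpha_db_bounds[1])
    alpha = 10.0 ** float(np.clip(xy[1], log_lo, log_hi))
    return FlowState(alpha_db=alpha, beta=beta)


def _simplex_area(points: np.ndarray) -> float:
    (x0, y0), (x1, y1), (x2, y2) = points
    return 0.5 * abs((x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0))


def propose_points(simplex: Simplex, config: FitConfig) -> Dict[str, object]:
    """Candidate points of one Nelder-Mead step from a sorted simplex.

    Returns the reflected, expanded, contracted (toward the worst vertex,
    i.e. inside), contracted_outside (toward the reflected point) and shrunk
    candidates, all computed in (beta, log10 alpha_db) space from the
    centroid of the best and good vertices and clipped to the bounds:

        reflected          = c + reflect * (c - worst)
        expanded           = c + expand * (reflected - c)
        contracted         = c + contract * (worst - c)
        contracted_outside = c + contract * (reflected - c)
        shrunk             = [best + shrink * (v - best) for v in (good, worst)]
    """
    pts = np.array([_to_xy(v.flow) for v in simplex.vertices])
    scale = max(1.0, float(np.abs(pts).max()))
    if _simplex_area(pts) <= 1e-14 * scale**2:
        raise DegenerateSimplexError(
            "simplex has zero area in (beta, log10 alpha_db) space"
        )
    best, good, worst = pts
    centroid = (best + good) / 2.0
    reflected = centroid + config.reflect * (centroid - worst)
    expanded = centroid + config.expand * (reflected - centroid)
    contracted = centroid + config.contract * (worst - centroid)
    contracted_outside = centroid + config.contract * (reflected - centroid)
    shrunk = [best + config.shrink * (v - best) for v in (good, worst)]
    return {
        "reflected": _from_xy(reflected, config),
        "expanded": _from_xy(expanded, config),
        "contracted": _from_xy(contracted, config),
        "contracted_outside": _from_xy(contracted_outside, config),
        "shrunk": [_from_xy(v, config) for v in shrunk],
    }


def validate_curve(
    measured: CorrelationCurve, gate: GateBounds = GateBounds()
) -> GateResult:
    """Sanity gate on a measured curve before fitting.

    Pass iff the first point lies in (first_lo, first_hi) - a plausible
    1 + beta intercept - and the last point has decayed to within last_tol
    of 1.  Non-finite values fail outright.
    """
    g2 = measured.g2
    if np.any(~np.isfinite(g2)):
        return GateResult(False, "non-finite correlation values")
    first, last = float(g2[0]), float(g2[-1])
    if first <= gate.first_lo:
        return GateResult(False, "intercept below range")
    if first >= gate.first_hi:
        return GateResult(False, "intercept above range")
    if abs(last - 1.0) >= gate.last_tol:
        return GateResult(False, "tail not decayed")
    return GateResult(True, "")


def _invalid_result(reason: str = "invalid_input") -> FitResult:
    return FitResult(
        flow=None, mse=math.nan, iterations=0, converged=False,
        termination_reason=reason,
    )


def nelder_mead_fit(
    measured: CorrelationCurve,
    constants: ModelConstants,
    config: FitConfig = FitConfig(),
    gate: Optional[GateBounds] = None,
) -> FitResult:
    """Fit (beta, alpha_Db) by Nelder-Mead minimization of the MSE.

    If ``gate`` is given the curve is first checked with
    :func:`validate_curve`; a failing curve yields ``invalid_input`` without
    fitting (callers that have already gated pass ``gate=None``).

    Standard decision rules per iteration (on the sorted simplex): accept the
    reflected point if it lies between best and good; try expansion if it
    beats the best (keeping the better of reflected/expanded); otherwise
    contract outside/inside, and shrink toward the best vertex if the
    contraction fails.  MSE(best) is nonincreasing across iterations.
    """
    if gate is not None:
        check = validate_curve(measured, gate)
        if not check:
            return _invalid_result()
    if np.any(~np.isfinite(measured.g2)):
        return _invalid_result()

    def objective(flow: FlowState) -> float:
        return mse(measured, constants, flow)

    try:
        vertices = tuple(
            SimplexVertex(flow=f, mse=objective(f)) for f in config.initial_simplex
        )
        simplex = sort_simplex(Simplex(vertices=vertices))
        # reject a degenerate starting simplex up front
        propose_points(simplex, config)
    except DegenerateSimplexError:
        return _invalid_result()

    iterations = 0
    converged = False
    reason = "max_iterations"
    while iterations < config.max_iterations:
        simplex = sort_simplex(simplex)
        f_best, f_worst = simplex.best.mse, simplex.worst.mse
        spread = abs(f_worst - f_best) / max(f_best, _SPREAD_EPS)
        if spread < config.convergence_threshold:
            converged = True
            reason = "tolerance"
            break
        try:
            cand = propose_points(simplex, config)
        except DegenerateSimplexError:
            # bounds clipping collapsed the simplex; treat as converged here
            converged = True
            reason = "tolerance"
            break
        f_good = simplex.good.mse
        refl = SimplexVertex(cand["reflected"], objective(cand["reflected"]))
        new_vertices: List[SimplexVertex]
        if refl.mse < f_best:
            expd = SimplexVertex(cand["expanded"], objective(cand["expanded"]))
            winner = expd if expd.mse < refl.mse else refl
            new_vertices = [simplex.best, simplex.good, winner]
        elif refl.mse < f_good:
            new_vertices = [simplex.best, simplex.good, refl]
        else:
            if refl.mse < f_worst:
                contr = SimplexVertex(
                    cand["contracted_outside"], objective(cand["contracted_outside"])
                )
                fallback = refl.mse
            else:
                contr = SimplexVertex(cand["contracted"], objective(cand["contracted"]))
                fallback = f_worst
            if contr.mse <= fallback:
                new_vertices = [simplex.best, simplex.good, contr]
            else:
                shr = [
                    SimplexVertex(f, objective(f)) for f in cand["shrunk"]
                ]
                new_vertices = [simplex.best] + shr
        simplex = Simplex(vertices=tuple(new_vertices))
        iterations += 1

    simplex = sort_simplex(simplex)
    best = simplex.best
    return FitResult(
        flow=best.flow,
        mse=best.mse,
        iterations=iterations,
        converged=converged,
        termination_reason=reason,
    )
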