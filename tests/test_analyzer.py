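"""Unit and property tests for the Nelder-Mead flow-index fitter."""

import math

import numpy as np
import pytest

from dcsflow import (
    CorrelationCurve,
    FitConfig,
    FlowState,
    GateBounds,
    Simplex,
    SimplexVertex,
    g2_model,
    mse,
    nelder_mead_fit,
    propose_points,
    sort_simplex,
    validate_curve,
)
from dcsflow.analyzer import DegenerateSimplexError


def _vertex(beta, log_alpha, value):
    return SimplexVertex(FlowState(alpha_db=10.0**log_alpha, beta=beta), mse=value)


WIDE = FitConfig(beta_bounds=(1e-6, 10.0), alpha_db_bounds=(1e-12, 1e5))


class TestMse:
    def test_zero_at_truth(self, tissue_constants, schedule80):
        flow = FlowState(1e-8, 0.5)
        curve = g2_model(tissue_constants, flow, schedule80)
        assert mse(curve, tissue_constants, flow) == 0.0

    def test_constant_offset_gives_c_squared(self, tissue_constants, schedule80):
        flow = FlowState(1e-8, 0.5)
        model = g2_model(tissue_constants, flow, schedule80)
        shifted = CorrelationCurve(taus=model.taus, g2=model.g2 + 0.03)
        assert mse(shifted, tissue_constants, flow) == pytest.approx(0.03**2, rel=1e-12)

    def test_matches_direct_summation(self, tissue_constants, schedule80):
        # independent brute-force evaluation of the objective
        truth = FlowState(1e-8, 0.5)
        candidate = FlowState(2e-8, 0.5)
        measured = g2_model(tissue_constants, truth, schedule80)
        total = 0.0
        for tau, g2m in zip(measured.taus, measured.g2):
            K = math.sqrt(tissue_constants.A + tissue_constants.B * candidate.alpha_db * tau)
            g1 = (
                math.exp(-tissue_constants.r1 * K) / tissue_constants.r1
                - math.exp(-tissue_constants.rb * K) / tissue_constants.rb
            ) / tissue_constants.H
            total += (g2m - (1.0 + candidate.beta * g1**2)) ** 2
        expected = total / len(measured.taus)
        assert mse(measured, tissue_constants, candidate) == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_rejected(self, tissue_constants, schedule80):
        g2 = np.ones(len(schedule80))
        g2[3] = np.nan
        curve = CorrelationCurve(taus=schedule80, g2=g2)
        with pytest.raises(ValueError, match="non-finite"):
            mse(curve, tissue_constants, FlowState(1e-8, 0.5))


class TestSortSimplex:
    def test_ascending_roles(self):
        simplex = Simplex(vertices=(
            _vertex(0.5, -8, 3.0), _vertex(0.6, -9, 1.0), _vertex(0.7, -7, 2.0),
        ))
        out = sort_simplex(simplex)
        assert [v.mse for v in out.vertices] == [1.0, 2.0, 3.0]

    def test_all_equal_tie_break_by_alpha(self):
        simplex = Simplex(vertices=(
            _vertex(0.5, -7, 1.0), _vertex(0.5, -9, 1.0), _vertex(0.5, -8, 1.0),
        ))
        out = sort_simplex(simplex)
        alphas = [v.flow.alpha_db for v in out.vertices]
        assert alphas == sorted(alphas)
        # deterministic across repeats
        assert sort_simplex(simplex) == out

    def test_partial_tie(self):
        simplex = Simplex(vertices=(
            _vertex(0.5, -7, 0.5), _vertex(0.5, -9, 0.0), _vertex(0.5, -8, 0.5),
        ))
        out = sort_simplex(simplex)
        assert out.best.mse == 0.0
        assert out.good.flow.alpha_db < out.worst.flow.alpha_db


class TestProposePoints:
    # triangle in (beta, log10 alpha) space: best (3,0), good (1,2), worst (1,0)
    SIMPLEX = Simplex(vertices=(
        _vertex(3.0, 0.0, 0.0), _vertex(1.0, 2.0, 1.0), _vertex(1.0, 0.0, 2.0),
    ))

    def test_reflection_through_centroid(self):
        cand = propose_points(self.SIMPLEX, WIDE)
        # centroid (2,1); reflected = (3,2)
        assert cand["reflected"].beta == pytest.approx(3.0)
        assert cand["reflected"].alpha_db == pytest.approx(100.0)

    def test_expansion(self):
        cand = propose_points(self.SIMPLEX, WIDE)
        # expanded = c + 2*(r - c) = (4,3)
        assert cand["expanded"].beta == pytest.approx(4.0)
        assert cand["expanded"].alpha_db == pytest.approx(1000.0)

    def test_inside_contraction(self):
        cand = propose_points(self.SIMPLEX, WIDE)
        # contracted = c + 0.5*(w - c) = (1.5, 0.5)
        assert cand["contracted"].beta == pytest.approx(1.5)
        assert cand["contracted"].alpha_db == pytest.approx(10.0**0.5)

    def test_shrink_toward_best(self):
        cand = propose_points(self.SIMPLEX, WIDE)
        shrunk = cand["shrunk"]
        assert shrunk[0].beta == pytest.approx(2.0)      # best + 0.5*(good-best)
        assert shrunk[0].alpha_db == pytest.approx(10.0)
        assert shrunk[1].beta == pytest.approx(2.0)      # best + 0.5*(worst-best)
        assert shrunk[1].alpha_db == pytest.approx(1.0)

    def test_candidates_clipped_to_bounds(self):
        tight = FitConfig(beta_bounds=(1e-6, 1.2), alpha_db_bounds=(1e-12, 1e-5))
        simplex = Simplex(vertices=(
            _vertex(1.0, -6, 0.0), _vertex(0.5, -7, 1.0), _vertex(0.4, -9, 2.0),
        ))
        cand = propose_points(simplex, tight)
        for key in ("reflected", "expanded", "contracted", "contracted_outside"):
            flow = cand[key]
            assert 1e-6 <= flow.beta <= 1.2
            assert 1e-12 <= flow.alpha_db <= 1e-5

    def test_degenerate_simplex_rejected(self):
        collinear = Simplex(vertices=(
            _vertex(0.5, -8, 0.0), _vertex(0.5, -8, 1.0), _vertex(0.5, -8, 2.0),
        ))
        with pytest.raises(DegenerateSimplexError):
            propose_points(collinear, WIDE)


class TestValidateCurve:
    def _curve(self, first, last, n=80):
        taus = np.arange(1, n + 1) * 1e-6
        g2 = np.linspace(first, last, n)
        return CorrelationCurve(taus=taus, g2=g2)

    def test_plausible_curve_passes(self):
        assert validate_curve(self._curve(1.45, 1.003))

    def test_low_intercept_fails(self):
        result = validate_curve(self._curve(0.8, 1.0))
        assert not result and result.reason == "intercept below range"

    def test_high_intercept_fails(self):
        result = validate_curve(self._curve(2.5, 1.0))
        assert not result and result.reason == "intercept above range"

    def test_undecayed_tail_fails(self):
        result = validate_curve(self._curve(1.45, 1.5))
        assert not result and result.reason == "tail not decayed"

    def test_nonfinite_fails(self):
        curve = self._curve(1.45, 1.0)
        g2 = curve.g2.copy()
        g2[5] = np.inf
        result = validate_curve(CorrelationCurve(taus=curve.taus, g2=g2))
        assert not result

    def test_custom_gate(self):
        gate = GateBounds(first_lo=1.0, first_hi=3.0, last_tol=0.5)
        assert validate_curve(self._curve(2.5, 1.4), gate)


class TestNelderMeadFit:
    def test_noiseless_recovery(self, tissue_constants, schedule80):
        for beta, alpha in [(0.5, 1e-9), (0.5, 5e-8), (1.0, 1e-8)]:
            curve = g2_model(tissue_constants, FlowState(alpha, beta), schedule80)
            result = nelder_mead_fit(curve, tissue_constants)
            assert result.flow.alpha_db == pytest.approx(alpha, rel=1e-3)
            assert result.flow.beta == pytest.approx(beta, rel=1e-3)
            assert result.converged

    def test_best_mse_nonincreasing_in_iterations(self, tissue_constants, schedule80):
        rng = np.random.default_rng(12)
        model = g2_model(tissue_constants, FlowState(8e-9, 0.5), schedule80)
        noisy = CorrelationCurve(
            taus=model.taus, g2=model.g2 + rng.normal(0, 0.01, len(model))
        )
        previous = np.inf
        for cap in range(0, 60, 3):
            config = FitConfig(max_iterations=cap)
            result = nelder_mead_fit(noisy, tissue_constants, config)
            assert result.mse <= previous + 1e-18
            previous = result.mse

    def test_plateau_curve_recovers_beta_only(self, tissue_constants):
        # lags far above the decay: g2 = 1 + beta at every lag carries no
        # alpha_db information; the fit pins beta while alpha_db stays
        # unconstrained (it depends on where the simplex started)
        taus = np.arange(1, 81) * 1e-12
        curve = CorrelationCurve(taus=taus, g2=np.full(80, 1.62))
        result = nelder_mead_fit(curve, tissue_constants)
        assert result.flow.beta == pytest.approx(0.62, rel=1e-3)
        other_start = FitConfig(
            initial_simplex=(
                FlowState(2e-11, 0.9), FlowState(1e-10, 0.7), FlowState(6e-10, 0.8),
            )
        )
        other = nelder_mead_fit(curve, tissue_constants, other_start)
        assert other.flow.beta == pytest.approx(0.62, rel=1e-3)
        # alpha_db is not identified: the fit slides it to the insensitive
        # region at the lower bound, far below any starting vertex
        for fit in (result, other):
            assert fit.flow.alpha_db < 1e-11

    def test_zero_iterations_returns_best_initial_vertex(
        self, tissue_constants, schedule80
    ):
        curve = g2_model(tissue_constants, FlowState(1e-8, 0.5), schedule80)
        config = FitConfig(max_iterations=0)
        result = nelder_mead_fit(curve, tissue_constants, config)
        assert not result.converged
        assert result.iterations == 0
        initial_mses = [
            mse(curve, tissue_constants, f) for f in config.initial_simplex
        ]
        assert result.mse == min(initial_mses)

    def test_gated_curve_returns_invalid_input(self, tissue_constants, schedule80):
        flat = CorrelationCurve(taus=schedule80, g2=np.ones(len(schedule80)))
        result = nelder_mead_fit(flat, tissue_constants, gate=GateBounds())
        assert result.flow is None
        assert result.termination_reason == "invalid_input"

    def test_nonfinite_curve_returns_invalid_input(self, tissue_constants, schedule80):
        g2 = np.ones(len(schedule80)) * 1.4
        g2[-1] = np.nan
        curve = CorrelationCurve(taus=schedule80, g2=g2)
        result = nelder_mead_fit(curve, tissue_constants)
        assert result.flow is None
        assert result.termination_reason == "invalid_input"

    def test_degenerate_initial_simplex(self, tissue_constants, schedule80):
        curve = g2_model(tissue_constants, FlowState(1e-8, 0.5), schedule80)
        config = FitConfig(
            initial_simplex=(
                FlowState(1e-8, 0.5), FlowState(1e-8, 0.5), FlowState(1e-8, 0.5),
            )
        )
        result = nelder_mead_fit(curve, tissue_constants, config)
        assert result.flow is None
        assert result.termination_reason == "invalid_input"

    def test_beats_grid_search_on_noisy_curves(self, tissue_constants, schedule80):
        """The fitted MSE never exceeds the minimum of a dense grid search."""
        from dcsflow.model import _g1_values

        rng = np.random.default_rng(99)
        betas = np.linspace(0.2, 1.1, 120)
        log_alphas = np.linspace(-10, -6.5, 120)
        g1_grid = np.array([
            _g1_values(tissue_constants, 10.0**la, schedule80) for la in log_alphas
        ])  # (n_alpha, n_tau)
        for _ in range(5):
            truth = FlowState(10 ** rng.uniform(-9, -7.5), rng.uniform(0.3, 1.0))
            model = g2_model(tissue_constants, truth, schedule80)
            noisy = CorrelationCurve(
                taus=model.taus, g2=model.g2 + rng.normal(0, 0.005, len(model))
            )
            result = nelder_mead_fit(noisy, tissue_constants)
            resid = (
                noisy.g2[None, None, :]
                - 1.0
                - betas[None, :, None] * g1_grid[:, None, :] ** 2
            )
            grid_min = float((resid**2).mean(axis=2).min())
            assert result.mse <= grid_min * (1 + 1e-9) + 1e-18
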