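"""Both time-stepping schemes against analytic and classical oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.special import gamma

from fracpop import (
    FractionalOrder,
    ModelParams,
    SelectionFunction,
    SolverConfig,
    corrector_weights,
    direct_ml_coefficients,
    initial_right_limit,
    mittag_leffler,
    solve,
    solve_direct_ml,
    solve_pc,
)
from fracpop.popmodel import rhs
from fracpop.solvers import StepError, _config_hash


def linear_params(lam: float) -> ModelParams:
    """V(t, N) = -lam*N realized as a=0, p=1, b=lam."""
    return ModelParams(a=0.0, b=lam, p=1.0)


def linear_exact(t, lam, order, n0=1.0):
    """Laplace-transform solution of the linear relaxation problem."""
    a, B = order.alpha, order.b
    scale = B / (B + lam * (1 - a))
    return n0 * scale * mittag_leffler(-lam * a * t**a / (B + lam * (1 - a)), a)


class TestCorrectorWeights:
    @pytest.mark.parametrize("alpha", [0.25, 0.45, 0.5, 0.75, 0.95, 1.0])
    @pytest.mark.parametrize("n", [0, 1, 7, 100])
    def test_terminal_weight_is_one(self, n, alpha):
        assert corrector_weights(n, alpha).weights[-1] == 1.0

    def test_alpha_one_reduces_to_trapezoid_pattern(self):
        w = corrector_weights(6, 1.0).weights
        assert np.allclose(w, [1, 2, 2, 2, 2, 2, 2, 1])

    def test_single_panel_at_alpha_one_is_trapezoid(self):
        w = corrector_weights(0, 1.0)
        assert w.weights[0] == pytest.approx(1.0)  # 0^2 - (-1)*1^1
        # with the h^alpha/(alpha(alpha+1)) prefactor this is h/2 per node
        assert w.prefactor(0.1) == pytest.approx(0.05)

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.75, 0.95])
    @pytest.mark.parametrize("n", [3, 10, 50])
    def test_exact_for_constants(self, n, alpha):
        h = 0.1
        table = corrector_weights(n, alpha)
        t_end = (n + 1) * h
        approx = table.prefactor(h) * table.weights.sum() * 3.0
        exact = 3.0 * t_end**alpha / alpha
        assert approx == pytest.approx(exact, abs=1e-12 * max(1.0, exact))

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.75, 0.95])
    @pytest.mark.parametrize("n", [3, 10, 50])
    def test_exact_for_linear_integrands(self, n, alpha):
        h = 0.1
        table = corrector_weights(n, alpha)
        t = h * np.arange(n + 2)
        t_end = t[-1]
        approx = table.prefactor(h) * float(table.weights @ t)
        exact = t_end ** (alpha + 1) / (alpha * (alpha + 1))
        assert approx == pytest.approx(exact, abs=1e-12 * max(1.0, exact))

    def test_printed_sign_fails_linear_exactness(self):
        """The uncorrected interior-weight sign is demonstrably not a
        degree-1 quadrature (the recorded justification for the fix)."""
        n, alpha, h = 10, 0.5, 0.1
        table = corrector_weights(n, alpha, corrected=False)
        t = h * np.arange(n + 2)
        approx = table.prefactor(h) * float(table.weights @ t)
        exact = t[-1] ** (alpha + 1) / (alpha * (alpha + 1))
        assert abs(approx - exact) > 1e-3
        # nor does it collapse to the trapezoid pattern at alpha=1
        w1 = corrector_weights(4, 1.0, corrected=False).weights
        assert not np.allclose(w1[1:-1], 2.0)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            corrector_weights(5, 1.5)


class TestPredictorAndPC:
    def test_zero_dynamics_stays_at_initial_value(self):
        cfg = SolverConfig(h=0.1, n_steps=50, order=FractionalOrder(0.7))
        tr = solve_pc(ModelParams(a=0.0, b=0.0, p=1.0), 0.3, cfg)
        assert np.all(tr.values == 0.3)

    def test_alpha_one_first_step_is_forward_euler(self):
        """At alpha=1 (B=1) the predictor weight collapses to h and the
        local term vanishes."""
        lam = 0.8
        params = linear_params(lam)
        cfg = SolverConfig(h=0.1, n_steps=1, order=FractionalOrder(1.0))
        from fracpop.solvers import predictor_step

        v0 = rhs(0.0, 1.0, params)
        pred = predictor_step(np.array([0.0]), np.array([v0]), 1.0, params, cfg)
        assert pred == pytest.approx(1.0 + 0.1 * v0, abs=1e-14)

    def test_predictor_tracks_linear_closed_form(self):
        lam, alpha = 1.0, 0.5
        o = FractionalOrder(alpha)
        cfg = SolverConfig(h=0.01, n_steps=100, order=o)
        tr = solve_pc(linear_params(lam), 1.0, cfg)
        exact = np.array([linear_exact(t, lam, o) for t in tr.times])
        rel = np.abs(tr.values[1:] - exact[1:]) / np.abs(exact[1:])
        assert rel.max() < 0.05

    def test_equilibrium_is_fixed_point(self):
        params = ModelParams(a=0.02, b=0.01, p=0.6, v=SelectionFunction.constant(0.01))
        nstar = params.b / params.net_growth(0.0)
        cfg = SolverConfig(h=0.5, n_steps=100, order=FractionalOrder(0.8))
        tr = solve_pc(params, nstar, cfg)
        assert np.abs(tr.values - nstar).max() < 1e-8

    def test_volterra_initial_right_limit(self):
        """The Volterra form jumps at t=0 when V(0,N0) != 0; the computed
        right limit solves x = N0 + (1-a)/B * V(0, x)."""
        lam, alpha = 0.5, 0.6
        o = FractionalOrder(alpha)
        x = initial_right_limit(linear_params(lam), 1.0, o)
        assert x == pytest.approx(o.b / (o.b + lam * (1 - alpha)), abs=1e-14)
        # no jump at equilibrium or at alpha=1
        assert initial_right_limit(linear_params(lam), 0.0, o) == 0.0
        assert initial_right_limit(linear_params(lam), 1.0, FractionalOrder(1.0)) == 1.0

    def test_linear_oracle_convergence_and_order(self):
        lam, alpha = 0.5, 0.6
        o = FractionalOrder(alpha)
        params = linear_params(lam)
        errs = []
        for k in (6, 7, 8):
            h = 2.0**-k
            cfg = SolverConfig(
                h=h, n_steps=int(round(1 / h)), order=o, corrector_mode="fixed-point"
            )
            tr = solve_pc(params, 1.0, cfg)
            exact = np.array([linear_exact(t, lam, o) for t in tr.times])
            # values[0] is pinned to the datum N0 while the Volterra solution
            # jumps at 0+; compare on the computed nodes t > 0
            errs.append(np.abs(tr.values[1:] - exact[1:]).max())
        assert errs[0] > errs[1] > errs[2]
        order = math.log2(errs[0] / errs[2]) / 2
        assert order >= 1.0

    def test_fixed_point_mode_nonconvergence_raises(self):
        cfg = SolverConfig(
            h=0.5, n_steps=5, order=FractionalOrder(0.5),
            corrector_mode="fixed-point", fp_tol=1e-16, fp_max_iter=1,
        )
        with pytest.raises(StepError, match="step 1"):
            solve_pc(ModelParams(a=0.2, b=0.1, p=1.0), 1.0, cfg)


class TestDirectML:
    def test_coefficient_index_error(self):
        with pytest.raises(IndexError):
            direct_ml_coefficients(3, 5, FractionalOrder(0.5), 0.1)

    def test_terminal_coefficient_value(self):
        """The newest-panel coefficient is h*E_{a,2}(-lam h^a) -> h as h->0."""
        o = FractionalOrder(0.5)
        h = 0.01
        got = direct_ml_coefficients(7, 7, o, h)
        expected = h * mittag_leffler(-o.ml_rate * h**0.5, 0.5, 2.0)
        assert got == pytest.approx(expected, abs=1e-15)
        assert got == pytest.approx(h, rel=0.1)

    @pytest.mark.parametrize("alpha", [0.25, 0.45, 0.75, 0.95])
    def test_coefficients_finite(self, alpha):
        o = FractionalOrder(alpha)
        vals = [direct_ml_coefficients(10_000, k, o, 0.01) for k in (0, 1, 5000, 9999, 10_000)]
        assert all(math.isfinite(v) for v in vals)

    def test_classical_limit_of_kernel_sum(self):
        """The beta-weighted sum applied to N = c*t reproduces the classical
        derivative c within 2% near alpha = 1."""
        c, h = 3.0, 0.01
        o = FractionalOrder(0.999)
        n = 100  # t_{n+1} = 1.01
        # increments of N = c*t are c*h, so each ratio (N_{k+1}-N_k)/h = c
        beta_sum = sum(direct_ml_coefficients(n, k, o, h) for k in range(n + 1))
        t_end = (n + 1) * h
        # the coefficients telescope to the full kernel integral
        assert beta_sum == pytest.approx(
            t_end * mittag_leffler(-o.ml_rate * t_end**0.999, 0.999, 2.0), rel=1e-10
        )
        approx = o.b / (1 - o.alpha) * c * beta_sum
        assert abs(approx - c) / c < 0.02

    def test_zero_dynamics(self):
        cfg = SolverConfig(h=0.1, n_steps=30, order=FractionalOrder(0.6), scheme="direct-ml")
        tr = solve_direct_ml(ModelParams(a=0.0, b=0.0, p=1.0), 0.7, cfg)
        assert np.all(tr.values == 0.7)

    def test_equilibrium_is_fixed_point(self):
        params = ModelParams(a=0.02, b=0.01, p=0.6, v=SelectionFunction.constant(0.01))
        nstar = params.b / params.net_growth(0.0)
        cfg = SolverConfig(h=0.5, n_steps=100, order=FractionalOrder(0.8), scheme="direct-ml")
        tr = solve_direct_ml(params, nstar, cfg)
        assert np.abs(tr.values - nstar).max() < 1e-6

    def test_alpha_one_rejected(self):
        cfg = SolverConfig(h=0.1, n_steps=5, order=FractionalOrder(1.0), scheme="direct-ml")
        with pytest.raises(ValueError):
            solve_direct_ml(linear_params(0.1), 1.0, cfg)


class TestSchemeAgreement:
    def test_cross_scheme_consistency(self):
        """Two independent discretizations of the same model must agree."""
        params = ModelParams(a=0.02, b=0.01, p=0.6, v=SelectionFunction.constant(0.01))
        o = FractionalOrder(0.75)
        pc = solve_pc(params, 0.1, SolverConfig(h=0.05, n_steps=2000, order=o))
        dml = solve_direct_ml(
            params, 0.1, SolverConfig(h=0.05, n_steps=2000, order=o, scheme="direct-ml")
        )
        dev = np.abs(pc.values - dml.values).max() / np.abs(pc.values).max()
        assert dev < 0.05

    def test_classical_limit_both_schemes(self):
        params = ModelParams(a=0.02, b=0.01, p=1.0)
        ref = solve_ivp(
            lambda t, y: rhs(t, y[0], params), [0, 50], [0.1],
            rtol=1e-10, atol=1e-13, dense_output=True,
        )
        o = FractionalOrder(0.999)
        for scheme, solver in [("pc", solve_pc), ("direct-ml", solve_direct_ml)]:
            cfg = SolverConfig(h=0.05, n_steps=1000, order=o, scheme=scheme)
            tr = solver(params, 0.1, cfg)
            exact = ref.sol(tr.times)[0]
            rel = np.abs(tr.values - exact).max() / np.abs(exact).max()
            assert rel < 1e-2, scheme


class TestTrajectoryPlumbing:
    def test_determinism_same_hash_same_values(self, figure_params):
        cfg = SolverConfig(h=0.1, n_steps=100, order=FractionalOrder(0.75))
        t1 = solve(figure_params, 0.1, cfg)
        t2 = solve(figure_params, 0.1, cfg)
        assert t1.config_hash == t2.config_hash
        assert np.array_equal(t1.values, t2.values)

    def test_hash_distinguishes_configs(self, figure_params):
        c1 = SolverConfig(h=0.1, n_steps=10, order=FractionalOrder(0.75))
        c2 = SolverConfig(h=0.1, n_steps=10, order=FractionalOrder(0.7))
        assert _config_hash(figure_params, 0.1, c1) != _config_hash(figure_params, 0.1, c2)

    def test_csv_roundtrip_bitwise(self, figure_params, tmp_path):
        import pandas as pd

        cfg = SolverConfig(h=0.5, n_steps=20, order=FractionalOrder(0.5))
        tr = solve(figure_params, 0.1, cfg)
        path = tr.to_csv(tmp_path / "traj.csv")
        df = pd.read_csv(path, float_precision="round_trip")
        assert list(df.columns) == ["t", "N"]
        assert np.array_equal(df["N"].to_numpy(), tr.values)
        assert (tmp_path / "traj.csv.meta.json").exists()

    def test_fate_consistent_increment_signs(self):
        """Discrete increments follow the sign of the rhs: decreasing toward
        extinction below the unstable positive equilibrium."""
        params = ModelParams(a=0.01, b=0.02, p=0.0, v=SelectionFunction.constant(0.03))
        assert params.net_growth(0.0) < 0  # extinction regime
        cfg = SolverConfig(h=0.2, n_steps=200, order=FractionalOrder(0.7))
        tr = solve_pc(params, 0.4, cfg)
        assert np.all(np.diff(tr.values) < 0)
        assert tr.values[-1] > -1e-12  # decays toward 0, not below

        surv = ModelParams(a=0.02, b=0.01, p=0.9, v=SelectionFunction.constant(0.01))
        nstar = surv.b / surv.net_growth(0.0)
        assert all(rhs(0.0, n, surv) < 0 for n in np.linspace(0.01, nstar - 0.01, 25))
        trs = solve_pc(surv, 0.1, SolverConfig(h=0.2, n_steps=200, order=FractionalOrder(0.7)))
        assert np.all(np.diff(trs.values) < 0)
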