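"""Sigmoid rates, ODE right-hand sides and solver correctness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bcellfate as bf
from bcellfate.errors import ConfigurationError, DomainError
from bcellfate.params import ModelSpec, RateParameters


@pytest.mark.parametrize(
    "scale, nu, t, expected",
    [
        (1.0, 0.05, 4.0, 0.5),           # exponent 0 at the anchor
        (1.0, 0.0, 100.0, 0.5),          # nu=0: constant at scale/2
        (0.8, 0.02, 14.0, 0.09536233761769404),  # 0.8/(1+e^2), high-precision
    ],
)
def test_sigmoid_rate_values(scale, nu, t, expected):
    assert bf.eval_sigmoid_rate(scale, nu, t, t0=4.0) == pytest.approx(expected, rel=1e-12)


def test_sigmoid_rate_domain_and_overflow():
    with pytest.raises(DomainError):
        bf.eval_sigmoid_rate(-1.0, 0.1, 5.0, 4.0)
    with pytest.raises(DomainError):
        bf.eval_sigmoid_rate(1.0, -0.1, 5.0, 4.0)
    # huge exponent underflows the ratio to 0, never NaN
    val = bf.eval_sigmoid_rate(1.0, 10.0, 1e4, 4.0)
    assert val == 0.0 and not np.isnan(val)


@settings(derandomize=True, max_examples=50)
@given(scale=st.floats(0.0, 10.0), nu=st.floats(0.0, 1.0),
       x=st.floats(0.0, 50.0))
def test_sigmoid_rate_even_and_monotone(scale, nu, x):
    left = bf.eval_sigmoid_rate(scale, nu, 4.0 - x, 4.0)
    right = bf.eval_sigmoid_rate(scale, nu, 4.0 + x, 4.0)
    # equality up to the 1-ulp rounding of (4.0 +/- x)
    assert left == pytest.approx(right, rel=1e-9, abs=1e-300)
    assert right <= bf.eval_sigmoid_rate(scale, nu, 4.0, 4.0) * (1 + 1e-12) + 1e-15


def test_rhs_hand_computed_branched(constant_sources):
    # constant rates; beta-term = beta0 * Mneg = 5e-5 * 1e6 = 50 cells/day
    spec = ModelSpec(topology="branched")
    params = RateParameters(alpha0=1e-4, beta0=5e-5, delta0=0.2, mu=7e-5,
                            lambda_ctrl=0.49, lambda_n2ko=0.9)
    dG, dM, dMn2 = bf.rhs(spec, params, constant_sources, 5.0, (1e4, 1e3, 100.0))
    assert dG == pytest.approx(1e-4 * 1e7 - 0.2 * 1e4)      # 1000 - 2000
    assert dM == pytest.approx(7e-5 * 1e7 + 50.0 - 0.49 * 1e3)  # 700 + 50 - 490
    assert dMn2 == pytest.approx(50.0 - 0.9 * 100.0)


def test_rhs_zero_rates_and_null_ignores_mu(constant_sources):
    zero = RateParameters()
    assert bf.rhs(ModelSpec("branched"), zero, constant_sources, 5.0,
                  (1e4, 1e3, 1e2)) == (0.0, 0.0, 0.0)
    p_mu = RateParameters(beta0=1e-4, lambda_ctrl=0.3, mu=0.01)
    p_no = RateParameters(beta0=1e-4, lambda_ctrl=0.3, mu=0.0)
    state = (1e4, 1e3, 1e2)
    d_mu = bf.rhs(ModelSpec("null"), p_mu, constant_sources, 6.0, state)
    d_no = bf.rhs(ModelSpec("null"), p_no, constant_sources, 6.0, state)
    assert d_mu == d_no


def _null_closed_form(B, lam, M0, t, t0=4.0):
    return B / lam + (M0 - B / lam) * np.exp(-lam * (t - t0))


@pytest.mark.parametrize("method", ["lsoda", "grid"])
def test_null_model_closed_form(constant_sources, method):
    spec = ModelSpec("null")
    params = RateParameters(beta0=3e-3, lambda_ctrl=0.5, lambda_n2ko=1.1,
                            M0=2e4, M0_n2=2e4)
    times = np.linspace(4.0, 30.0, 40)
    traj = bf.solve(spec, params, constant_sources, times, method=method)
    B = 3e-3 * 1e6
    np.testing.assert_allclose(traj.M, _null_closed_form(B, 0.5, 2e4, times),
                               rtol=1e-6)
    np.testing.assert_allclose(traj.M_n2, _null_closed_form(B, 1.1, 2e4, times),
                               rtol=1e-6)


def test_all_rates_zero_constant_trajectory(constant_sources):
    params = RateParameters(G0=5e3, M0=2e4, M0_n2=1e3)
    times = np.linspace(4.0, 30.0, 10)
    traj = bf.solve(ModelSpec("branched"), params, constant_sources, times)
    np.testing.assert_allclose(traj.G, 5e3, rtol=1e-9)
    np.testing.assert_allclose(traj.M, 2e4, rtol=1e-9)
    np.testing.assert_allclose(traj.M_n2, 1e3, rtol=1e-9)


def test_branched_linear_degenerate_at_mu_zero(truth_sources, study_truth):
    _, params = study_truth
    from dataclasses import replace
    params = replace(params, mu=0.0)
    times = np.linspace(4.0, 30.0, 27)
    tb = bf.solve(ModelSpec("branched", influx_time_varying=True), params,
                  truth_sources, times)
    tl = bf.solve(ModelSpec("linear", influx_time_varying=True), params,
                  truth_sources, times)
    np.testing.assert_allclose(tb.M, tl.M, rtol=1e-9)


def _rk4(spec, params, sources, t_end, dt):
    t = params.t0
    y = np.array([params.G0, params.M0, params.M0_n2])
    ts = [t]
    ys = [y.copy()]
    f = lambda tt, yy: np.array(bf.rhs(spec, params, sources, tt, yy))
    n = int(round((t_end - t) / dt))
    for _ in range(n):
        k1 = f(t, y)
        k2 = f(t + dt / 2, y + dt / 2 * k1)
        k3 = f(t + dt / 2, y + dt / 2 * k2)
        k4 = f(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        ts.append(t)
        ys.append(y.copy())
    return np.array(ts), np.array(ys)


@pytest.mark.parametrize("name", [s.name for s in bf.enumerate_model_family()])
def test_solver_matches_rk4_oracle(name, truth_sources, study_truth):
    """Both solver paths agree with an independent fixed-step RK4 integration
    on every family member for one reference parameter set."""
    _, params = study_truth
    spec = ModelSpec.from_name(name)
    ts, ys = _rk4(spec, params, truth_sources, 12.0, 0.005)
    times = ts[::400]  # every 2 days
    ref = ys[::400]
    for method in ("lsoda", "grid"):
        traj = bf.solve(spec, params, truth_sources, times, method=method)
        for got, exp in ((traj.G, ref[:, 0]), (traj.M, ref[:, 1]),
                         (traj.M_n2, ref[:, 2])):
            np.testing.assert_allclose(got, exp, rtol=1e-4)


def test_solver_refinement_stable(truth_sources, study_truth):
    spec, params = study_truth
    times = np.linspace(4.0, 30.0, 14)
    a = bf.solve(spec, params, truth_sources, times, rtol=1e-8, atol=1e-10)
    b = bf.solve(spec, params, truth_sources, times, rtol=5e-9, atol=5e-11)
    np.testing.assert_allclose(a.M, b.M, rtol=1e-5)
    np.testing.assert_allclose(a.G, b.G, rtol=1e-5)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(alpha0=st.floats(0, 1e-2), beta0=st.floats(0, 1e-2),
       delta0=st.floats(0, 2), lam=st.floats(0, 2), mu=st.floats(0, 1e-3))
def test_nonnegativity_preserved(alpha0, beta0, delta0, lam, mu,
                                 constant_sources):
    params = RateParameters(alpha0=alpha0, beta0=beta0, delta0=delta0, mu=mu,
                            lambda_ctrl=lam, lambda_n2ko=lam, G0=1e3, M0=1e3,
                            M0_n2=1e3)
    traj = bf.solve(ModelSpec("branched"), params, constant_sources,
                    np.linspace(4, 30, 10), method="grid")
    assert (traj.G >= 0).all() and (traj.M >= 0).all() and (traj.M_n2 >= 0).all()


def test_solve_input_validation(constant_sources):
    params = RateParameters(M0=1.0)
    with pytest.raises(DomainError):
        bf.solve(ModelSpec("null"), params, constant_sources, [5.0, 4.5])
    with pytest.raises(DomainError):
        bf.solve(ModelSpec("null"), params, constant_sources, [2.0, 5.0])
    with pytest.raises(DomainError):
        bf.solve(ModelSpec("null"), params, constant_sources, [5.0],
                 method="unknown")


class TestModelFamily:
    def test_family_has_ten_distinct_members(self):
        family = bf.enumerate_model_family()
        assert len(family) == 10
        assert len(set(family)) == 10

    def test_reference_model_unique(self):
        family = bf.enumerate_model_family()
        ref = [s for s in family if s.topology == "branched"
               and s.influx_time_varying and not s.mu_time_varying]
        assert len(ref) == 1

    def test_variants_are_alternatives(self):
        assert not any(s.influx_time_varying and s.loss_time_varying
                       for s in bf.enumerate_model_family())

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("branched", influx_time_varying=True, loss_time_varying=True)
        with pytest.raises(ConfigurationError):
            ModelSpec("null", influx_time_varying=True, mu_time_varying=True)
        with pytest.raises(ConfigurationError):
            ModelSpec("gcb_only")
        with pytest.raises(ConfigurationError):
            ModelSpec("branched", mu_time_varying=True)  # needs TVI

    def test_name_round_trip(self):
        for spec in bf.enumerate_model_family():
            assert ModelSpec.from_name(spec.name) == spec


def test_rate_parameters_reject_negative():
    with pytest.raises(DomainError):
        RateParameters(alpha0=-1.0)
    with pytest.raises(DomainError):
        RateParameters(nu3=-0.1)
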