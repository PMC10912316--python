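"""Likelihood, priors, clonal half-life and Bayesian fitting behaviour."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bcellfate as bf
from bcellfate.data import cohort_from_records
from bcellfate.errors import DomainError
from bcellfate.inference import PriorSpec, default_priors
from bcellfate.params import ModelSpec, RateParameters

_LN2PI = np.log(2 * np.pi)


class TestClonalHalfLife:
    def test_reference_values(self):
        assert bf.clonal_half_life(np.log(2)) == pytest.approx(1.0, rel=1e-12)
        assert bf.clonal_half_life(0.49) == pytest.approx(np.log(2) / 0.49)
        assert bf.clonal_half_life(0.49) == pytest.approx(1.4146, abs=1e-3)
        assert bf.clonal_half_life(0.94) == pytest.approx(0.7374, abs=1e-3)

    def test_invalid_rates_rejected(self):
        for bad in (0.0, -1.0, np.inf):
            with pytest.raises(DomainError):
                bf.clonal_half_life(bad)

    def test_array_propagation_is_antitone(self):
        rates = np.linspace(0.1, 2.0, 25)
        half = bf.clonal_half_life(rates)
        assert (np.diff(half) < 0).all()


def _null_cohort(days_counts):
    recs = [(f"m{i}", "control", d, "MZB_CARpos", c)
            for i, (d, c) in enumerate(days_counts)]
    return cohort_from_records(recs)


class TestLogLikelihood:
    def test_zero_residual_unit_sigma(self, constant_sources):
        spec = ModelSpec("null")
        params = RateParameters(beta0=3e-3, lambda_ctrl=0.5, M0=2e4)
        traj = bf.solve(spec, params, constant_sources, [9.0])
        data = _null_cohort([(9, float(traj.M[0]))])
        total, pointwise, _ = bf.log_likelihood(spec, params, constant_sources,
                                                data, sigma=1.0)
        assert pointwise[0] == pytest.approx(-0.5 * _LN2PI, abs=1e-10)

    def test_doubling_sigma_costs_log2_per_obs(self, constant_sources):
        spec = ModelSpec("null")
        params = RateParameters(beta0=3e-3, lambda_ctrl=0.5, M0=2e4)
        traj = bf.solve(spec, params, constant_sources, [9.0, 14.0])
        data = _null_cohort([(9, float(traj.M[0])), (14, float(traj.M[1]))])
        t1, _, _ = bf.log_likelihood(spec, params, constant_sources, data, 1.0)
        t2, _, _ = bf.log_likelihood(spec, params, constant_sources, data, 2.0)
        assert t1 - t2 == pytest.approx(2 * np.log(2), abs=1e-10)

    def test_three_observation_hand_oracle(self, constant_sources):
        # closed-form null trajectory, hand-computed Normal log densities
        beta0, lam, M0, sigma = 3e-3, 0.5, 2e4, 0.4
        spec = ModelSpec("null")
        params = RateParameters(beta0=beta0, lambda_ctrl=lam, M0=M0)
        days = np.array([7.0, 14.0, 26.0])
        counts = np.array([2.1e4, 9.0e3, 6.5e3])
        B = beta0 * 1e6
        model = B / lam + (M0 - B / lam) * np.exp(-lam * (days - 4.0))
        expected = sum(stats.norm.logpdf(np.log(c), np.log(m), sigma)
                       for c, m in zip(counts, model))
        data = _null_cohort(list(zip(days, counts)))
        total, _, _ = bf.log_likelihood(spec, params, constant_sources, data,
                                        sigma)
        assert total == pytest.approx(expected, abs=1e-6)

    def test_observation_order_invariance(self, constant_sources):
        spec = ModelSpec("null")
        params = RateParameters(beta0=3e-3, lambda_ctrl=0.5, M0=2e4)
        rng = np.random.default_rng(0)
        recs = [(f"m{i}", "control", d, "MZB_CARpos",
                 float(2e4 * rng.lognormal(0, 0.3)))
                for i, d in enumerate([7, 9, 14, 22, 30])]
        base = cohort_from_records(recs)
        shuffled = cohort_from_records([recs[i] for i in (3, 0, 4, 2, 1)])
        t1, _, _ = bf.log_likelihood(spec, params, constant_sources, base, 0.5)
        t2, _, _ = bf.log_likelihood(spec, params, constant_sources, shuffled, 0.5)
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_zero_counts_replaced_with_warning(self, constant_sources, caplog):
        spec = ModelSpec("null")
        params = RateParameters(beta0=3e-3, lambda_ctrl=0.5, M0=2e4)
        data = _null_cohort([(9, 0.0), (14, 1000.0), (22, 800.0)])
        with caplog.at_level("WARNING", logger="bcellfate.inference"):
            total, pointwise, table = bf.log_likelihood(
                spec, params, constant_sources, data, 0.5)
        assert np.isfinite(total)
        assert (table["count"] > 0).all()
        assert table["count"].min() == pytest.approx(400.0)  # half of 800


class TestPriors:
    def test_lognormal_theta_density_matches_scipy(self):
        p = PriorSpec("lognormal", loc=np.log(0.3), scale=1.5)
        for theta in (-3.0, -1.2, 0.4):
            assert p.logpdf_theta(theta) == pytest.approx(
                stats.norm.logpdf(theta, np.log(0.3), 1.5), abs=1e-12)

    def test_halfnormal_theta_density_includes_jacobian(self):
        p = PriorSpec("halfnormal", scale=0.1)
        for theta in (-6.0, -4.0, -2.0):
            x = np.exp(theta)
            expected = stats.halfnorm.logpdf(x, scale=0.1) + theta
            assert p.logpdf_theta(theta) == pytest.approx(expected, abs=1e-12)

    def test_prior_predictive_trajectories_are_sane(self, smoke_fit):
        lp = smoke_fit.logprob_
        rng = np.random.default_rng(4)
        for _ in range(20):
            theta = np.array([
                rng.normal(p.loc, p.scale) if p.dist == "lognormal"
                else np.log(max(abs(rng.normal(0, p.scale)), 1e-12))
                for p in lp.priors])
            theta = np.clip(theta, -24, 24)
            G, M, M_n2 = lp._trajectory_arrays(theta)
            for arr in (G, M, M_n2):
                assert np.all(np.isfinite(arr)) and np.all(arr >= 0)


class TestFit:
    def test_smoke_fit_summary_contract(self, smoke_fit, study_truth):
        _, params = study_truth
        summary = smoke_fit.summary_
        free = smoke_fit.logprob_.names
        assert set(free) <= set(summary["parameter"])
        assert summary["rhat"].notna().all()
        assert (summary["ci_low"] <= summary["median"]).all()
        assert (summary["median"] <= summary["ci_high"]).all()
        # reduced-draw fit still lands in the right decade
        med = summary.set_index("parameter")["median"]
        assert med["lambda_ctrl"] == pytest.approx(params.lambda_ctrl, rel=1.5)
        assert med["M0"] == pytest.approx(params.M0, rel=1.0)

    def test_envelope_contract(self, smoke_fit):
        times = np.linspace(4, 30, 14)
        env = smoke_fit.trajectory_envelope(times, "control", "MZB_CARpos")
        assert (env["ci_low"] >= 0).all()
        assert (env["ci_low"] <= env["median"]).all()
        assert (env["median"] <= env["ci_high"]).all()

    def test_same_seed_reproducible(self, cohort, truth_sources):
        data, _ = cohort
        kw = dict(model="branched_tvi", seed=42, draws=150, tune=150)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = bf.BCellFateModel(**kw).fit(data, sources=truth_sources)
            b = bf.BCellFateModel(**kw).fit(data, sources=truth_sources)
        pd.testing.assert_frame_equal(a.summary_, b.summary_)
        np.testing.assert_array_equal(a.loglik_matrix_, b.loglik_matrix_)

    def test_zero_noise_tight_priors_recover_truth(self, truth_sources,
                                                   study_truth):
        spec, params = study_truth
        design = bf.CohortDesign(
            seed=2, sigma={k: 0.0 for k in ("GCB_CARpos", "MZB_CARpos",
                                            "MZB_CARneg", "FoB_total")})
        data, _ = bf.generate(design)
        overrides = {name: PriorSpec("lognormal", np.log(getattr(params, name)),
                                     0.02)
                     for name in spec.free_parameter_names()}
        for series in ("control_GCB_CARpos", "control_MZB_CARpos",
                       "n2ko_GCB_CARpos", "n2ko_MZB_CARpos"):
            overrides[f"sigma_{series}"] = PriorSpec("lognormal",
                                                     np.log(0.05), 0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = bf.BCellFateModel(model="branched_tvi", seed=9, draws=200,
                                    tune=200, priors=overrides)
            est.fit(data, sources=truth_sources)
        med = est.summary_.set_index("parameter")["median"]
        for name in spec.free_parameter_names():
            assert med[name] == pytest.approx(getattr(params, name), rel=0.05)

    def test_posterior_contracts_with_sample_size(self, truth_sources):
        """Posterior uncertainty narrows (on average over seeds) as the cohort
        grows ~20 -> ~66 -> ~200 mice.

        Contraction is measured on quantities the sampling design identifies:
        the quasi-steady influx/loss ratio mu/lambda (which sets the late
        CAR+ MZB level) and the observation noise sigma.  The marginal of
        lambda alone is ridge-identified (only mu/lambda is pinned by the
        data) so its width is prior-limited at every n.
        """
        ratio_widths, sigma_widths = [], []
        for factor in (0.3, 1.0, 3.0):
            per_ratio, per_sigma = [], []
            for seed in (31, 32):
                ctrl = {d: max(1, round(n * factor))
                        for d, n in bf.cohort.CONTROL_DESIGN.items()}
                n2 = {d: max(1, round(n * factor))
                      for d, n in bf.cohort.N2KO_DESIGN.items()}
                data, _ = bf.generate(bf.CohortDesign(
                    seed=seed, control_days=ctrl, n2ko_days=n2))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est = bf.BCellFateModel(seed=seed, draws=800, tune=800)
                    est.fit(data, sources=truth_sources)
                df = est.draws_frame()
                r = np.log(df["mu"] / df["lambda_ctrl"])
                lo, hi = np.quantile(r, [0.025, 0.975])
                per_ratio.append(hi - lo)
                lo, hi = df["sigma_control_MZB_CARpos"].quantile([0.025, 0.975])
                per_sigma.append(np.log(hi) - np.log(lo))
            ratio_widths.append(np.mean(per_ratio))
            sigma_widths.append(np.mean(per_sigma))
        assert ratio_widths[0] > ratio_widths[2]
        assert sigma_widths[0] > sigma_widths[1] > sigma_widths[2]
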