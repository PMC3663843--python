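"""MCMC sampler: determinism, conjugate oracle, prior sampling,
summaries and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spiv.mcmc import (
    McmcConfig,
    Trace,
    diagnose,
    effective_sample_size,
    posterior_summary,
    potential_scale_reduction,
    run_chain,
    sample_posterior,
)
from spiv.structures import PriorSettings, structure_from_label


def _linear_gaussian_problem(n=200, p=3, seed=0):
    """Biomarker-layer-only data with known coefficients."""
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n, p))
    u_true = np.array([0.5, -0.3, 0.2])
    b_true = 1.0
    x = b_true + G @ u_true + rng.normal(0, 1.0, n)
    xt = x + rng.normal(0, 1.0, n)
    y = rng.integers(0, 2, n)  # ignored: outcome layer disabled
    return G, xt, y, u_true, b_true


class TestDeterminism:
    def test_same_seed_identical_traces(self, small_model_data):
        structure = structure_from_label("M7")
        priors = PriorSettings.from_preset("Setting3")
        cfg = McmcConfig(n_iterations=300, burn_in=100, thin=2, seed=11)
        t1 = run_chain(small_model_data, structure, priors, cfg)
        t2 = run_chain(small_model_data, structure, priors, cfg)
        np.testing.assert_array_equal(t1.deviance, t2.deviance)
        for name in t1.samples:
            np.testing.assert_array_equal(t1.samples[name], t2.samples[name])

    def test_chains_differ_across_spawned_seeds(self, small_model_data):
        structure = structure_from_label("M7")
        priors = PriorSettings.from_preset("Setting3")
        cfg = McmcConfig(n_iterations=200, burn_in=100, n_chains=2, seed=4)
        traces = sample_posterior(small_model_data, structure, priors, cfg)
        assert len(traces) == 2
        assert not np.array_equal(
            traces[0].samples["w"], traces[1].samples["w"]
        )


class TestConjugateOracle:
    def test_posterior_mean_matches_closed_form(self):
        # Gaussian-only sub-model: no outcome layer, Gaussian coefficient
        # priors, fixed precisions -> u has a closed-form posterior after
        # marginalising the latent x (total noise var 1/precx + 1/precxt).
        G, xt, y, u_true, _ = _linear_gaussian_problem()
        structure = structure_from_label("M2")
        sd0 = 1.0
        priors = PriorSettings(precx=1.0, precxt=1.0, precy=1.0)
        cfg = McmcConfig(
            n_iterations=6000, burn_in=1000, thin=1, seed=3,
            outcome_layer=False, gaussian_coefficient_sd=sd0,
        )
        trace = run_chain((G, xt, y), structure, priors, cfg)

        X = np.column_stack([np.ones(len(xt)), G])
        noise_var = 1.0 / priors.precx + 1.0 / priors.precxt
        P = np.diag([1.0 / priors.intercept_sd**2] + [1.0 / sd0**2] * 3)
        A = X.T @ X / noise_var + P
        post_mean = np.linalg.solve(A, X.T @ xt / noise_var)

        u_samples = trace.samples["u"]
        for j in range(3):
            mcse = u_samples[:, j].std(ddof=1) / np.sqrt(
                effective_sample_size(u_samples[:, j])
            )
            assert u_samples[:, j].mean() == pytest.approx(
                post_mean[j + 1], abs=3 * mcse
            )
        b_samples = trace.samples["b_x"]
        mcse = b_samples.std(ddof=1) / np.sqrt(effective_sample_size(b_samples))
        assert b_samples.mean() == pytest.approx(post_mean[0], abs=3 * mcse)


class TestPriorSampling:
    def test_w_marginal_matches_laplace_prior(self):
        # likelihood disabled: the chain must sample w from Laplace(gam1)
        rng = np.random.default_rng(0)
        n, p = 20, 2
        G = rng.standard_normal((n, p))
        xt = rng.standard_normal(n)
        y = rng.integers(0, 2, n)
        gam1 = 1.0
        structure = structure_from_label("M7")
        priors = PriorSettings(gam1=gam1, precx=1, precxt=1, precy=1)
        cfg = McmcConfig(
            n_iterations=110_000, burn_in=10_000, thin=20, seed=8,
            use_likelihood=False, align_confounder_sign=False,
        )
        trace = run_chain((G, xt, y), structure, priors, cfg)
        w = trace.samples["w"]
        assert w.size == 5000
        ks = stats.kstest(w, stats.laplace(scale=1.0 / gam1).cdf)
        assert ks.pvalue > 0.01


class TestPosteriorSummary:
    def _toy_trace(self, samples_w):
        S = {
            "u": np.zeros((len(samples_w), 1)),
            "wg": np.zeros((len(samples_w), 1)),
            "w": np.asarray(samples_w, dtype=float),
            "wr": np.zeros(len(samples_w)),
            "v": np.linspace(0, 1, len(samples_w)),
            "wz": np.zeros(len(samples_w)),
            "b_x": np.zeros(len(samples_w)),
            "b_0": np.zeros(len(samples_w)),
        }
        return Trace(
            samples=S,
            deviance=np.zeros(len(samples_w)),
            latent_means={k: np.zeros(2) for k in ("x", "z", "e")},
            accept_rates={},
            config=McmcConfig(n_iterations=10, burn_in=0, thin=1, seed=0),
            structure=structure_from_label("M7"),
            priors=PriorSettings(),
            predictor_names=["g1"],
        )

    def test_symmetric_samples_have_zero_mean(self):
        t = self._toy_trace([-2.0, 2.0] * 5)
        assert posterior_summary(t).loc["w", "mean"] == pytest.approx(0.0)

    def test_summaries_equal_manual_averages(self):
        vals = [0.1, 0.4, 0.2, 0.9, 0.6, 0.3, 0.8, 0.5, 0.7, 1.0]
        summ = posterior_summary(self._toy_trace(vals)).loc["w"]
        assert summ["mean"] == pytest.approx(np.mean(vals))
        assert summ["sd"] == pytest.approx(np.std(vals, ddof=1))
        assert summ["median"] == pytest.approx(np.percentile(vals, 50))

    def test_percentiles_monotone(self):
        summ = posterior_summary(self._toy_trace(list(range(10))))
        assert (summ["q2_5"] <= summ["median"]).all()
        assert (summ["median"] <= summ["q97_5"]).all()

    def test_empty_trace_rejected(self):
        t = self._toy_trace([])
        t.deviance = np.zeros(0)
        with pytest.raises(ValueError, match="empty"):
            posterior_summary(t)


class TestDiagnostics:
    def test_identical_chains_scale_reduction_is_one(self):
        base = np.random.default_rng(1).standard_normal(500)
        chain = np.concatenate([base, base])  # halves identical too
        rhat = potential_scale_reduction(np.vstack([chain, chain]))
        assert rhat == 1.0

    def test_iid_ess_close_to_sample_size(self):
        n = 4000
        x = np.random.default_rng(7).standard_normal(n)
        ess = effective_sample_size(x)
        # estimator spread on iid input: ~3 sd plus small negative bias
        assert abs(ess - n) < 0.15 * n

    def test_trending_chain_flagged(self):
        rng = np.random.default_rng(2)
        trend = np.linspace(0.0, 3.0, 1000) + 0.1 * rng.standard_normal(1000)
        assert potential_scale_reduction(trend[None, :]) > 1.1

    def test_report_on_fitted_traces(self, small_model_data):
        structure = structure_from_label("M6")
        priors = PriorSettings.from_preset("Setting3")
        cfg = McmcConfig(n_iterations=360, burn_in=200, thin=2, n_chains=2, seed=5)
        traces = sample_posterior(small_model_data, structure, priors, cfg)
        report = diagnose(traces)
        assert {"ess", "rhat"} <= set(report.table.columns)
        assert "v" in report.table.index
        assert len(report.dbar_per_chain) == 2
        assert "short chain" in " ".join(report.warnings)

    def test_single_short_chain_warns_not_fails(self, small_model_data):
        structure = structure_from_label("M6")
        priors = PriorSettings.from_preset("Setting3")
        cfg = McmcConfig(n_iterations=120, burn_in=60, thin=2, seed=5)
        trace = run_chain(small_model_data, structure, priors, cfg)
        report = diagnose(trace)
        assert any("single chain" in w for w in report.warnings)


class TestTracePersistence:
    def test_round_trip_preserves_samples_and_dbar(self, small_model_data,
                                                   tmp_path):
        structure = structure_from_label("M7")
        priors = PriorSettings.from_preset("Setting3")
        cfg = McmcConfig(n_iterations=200, burn_in=100, thin=2, seed=6)
        trace = run_chain(small_model_data, structure, priors, cfg)
        path = tmp_path / "trace.parquet"
        trace.save(path)
        loaded = Trace.load(path)
        np.testing.assert_allclose(loaded.deviance, trace.deviance)
        np.testing.assert_allclose(loaded.samples["w"], trace.samples["w"])
        np.testing.assert_allclose(loaded.samples["u"], trace.samples["u"])
        assert loaded.predictor_names == list(trace.predictor_names)
        assert loaded.structure == trace.structure
        assert loaded.dbar == pytest.approx(trace.dbar)


class TestPermutationInvariance:
    def test_row_exchange_leaves_summaries_within_mc_error(self):
        G, xt, y, *_ = _linear_gaussian_problem(n=150, seed=9)
        structure = structure_from_label("M2")
        priors = PriorSettings(precx=1.0, precxt=1.0, precy=1.0)
        cfg = McmcConfig(
            n_iterations=3000, burn_in=500, thin=1, seed=12,
            outcome_layer=False, gaussian_coefficient_sd=1.0,
        )
        t_orig = run_chain((G, xt, y), structure, priors, cfg)
        perm = np.arange(len(y))
        perm[[0, 1]] = perm[[1, 0]]
        t_swap = run_chain((G[perm], xt[perm], y[perm]), structure, priors, cfg)
        for trace_pair in [(t_orig, t_swap)]:
            a = trace_pair[0].samples["u"][:, 0]
            b = trace_pair[1].samples["u"][:, 0]
            mcse = np.hypot(
                a.std(ddof=1) / np.sqrt(effective_sample_size(a)),
                b.std(ddof=1) / np.sqrt(effective_sample_size(b)),
            )
            assert a.mean() == pytest.approx(b.mean(), abs=4 * mcse)


class TestShrinkage:
    def test_posterior_w_magnitude_non_increasing_in_gam1(self):
        # sparsity: stronger Laplace concentration prunes the direct link
        import spiv
        from spiv.preprocess import prepare_model_data

        table, _ = spiv.simulate_cohort(
            spiv.GeneratorConfig(n_cases=170, n_controls=230, seed=31)
        )
        data = prepare_model_data(table, standardize_biomarker=True)
        means = []
        for gam1 in (0.025, 1.0, 10.0):
            vals = []
            for seed in (0, 1, 2):
                priors = PriorSettings.from_preset("Setting3", gam1=gam1)
                cfg = McmcConfig(
                    n_iterations=2000, burn_in=1000, thin=2, seed=seed
                )
                trace = run_chain(
                    data, structure_from_label("M7"), priors, cfg
                )
                vals.append(np.abs(trace.samples["w"]).mean())
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]
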