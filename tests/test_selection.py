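"""DIC arithmetic, verdicts, published comparison values, grids."""

import numpy as np
import pytest

from spiv import published
from spiv.mcmc import McmcConfig, run_chain, sample_posterior
from spiv.selection import (
    DicResult,
    ExperimentGrid,
    compare_dbar,
    compute_dic,
    dic_difference,
    interpret_difference,
    mean_dic,
    run_experiment,
)
from spiv.structures import PriorSettings, structure_from_label


def _toy_trace(deviances, **kwargs):
    from spiv.mcmc import Trace

    n = len(deviances)
    S = {
        nm: np.zeros(n)
        for nm in ("w", "wr", "v", "wz", "b_x", "b_0")
    }
    S["u"] = np.zeros((n, 1))
    S["wg"] = np.zeros((n, 1))
    return Trace(
        samples=S,
        deviance=np.asarray(deviances, dtype=float),
        latent_means={k: np.zeros(1) for k in ("x", "z", "e")},
        accept_rates={},
        config=McmcConfig(n_iterations=max(n, 2), burn_in=0, thin=1, seed=0),
        structure=structure_from_label("M7"),
        priors=PriorSettings(),
        predictor_names=["g1"],
    )


class TestDicIdentities:
    def test_constant_deviance_gives_zero_complexity(self, small_model_data):
        structure = structure_from_label("M6")
        priors = PriorSettings.from_preset("Setting3")
        cfg = McmcConfig(n_iterations=300, burn_in=150, thin=3, seed=2)
        trace = run_chain(small_model_data, structure, priors, cfg)
        trace.deviance[:] = trace.deviance[0]  # degenerate series
        # force Dhat equal to the constant by aligning the mean state
        res = DicResult(dbar=float(trace.deviance[0]), dhat=float(trace.deviance[0]))
        assert res.pD == 0.0
        assert res.dic == res.dbar

    def test_identities_hold_exactly_on_real_fit(self, small_model_data):
        structure = structure_from_label("M6")
        priors = PriorSettings.from_preset("Setting3")
        cfg = McmcConfig(n_iterations=500, burn_in=250, thin=2, seed=3)
        trace = run_chain(small_model_data, structure, priors, cfg)
        res = compute_dic(trace, small_model_data, structure, priors)
        assert res.dic == res.dbar + res.pD  # exact identity
        assert res.pD == res.dbar - res.dhat

    def test_normal_mean_toy_model_complexity_near_one(self):
        # Normal-mean model, known unit variance, effectively flat
        # prior: exact posterior draws of the mean mu ~ N(xbar, 1/n)
        # mapped onto the measurement layer (x_i = mu for all i).
        # Effective number of parameters pD should be ~ 1.
        from spiv.mcmc import Trace

        rng = np.random.default_rng(4)
        n, S = 100, 4000
        xt = rng.normal(5.0, 1.0, n)
        y = np.zeros(n, dtype=int)
        G = rng.standard_normal((n, 2))
        mu = rng.normal(xt.mean(), np.sqrt(1.0 / n), S)
        dev = n * np.log(2 * np.pi) + np.array(
            [np.sum((xt - m) ** 2) for m in mu]
        )
        samples = {nm: np.zeros(S) for nm in ("w", "wr", "v", "wz", "b_0")}
        samples["b_x"] = mu
        samples["u"] = np.zeros((S, 2))
        samples["wg"] = np.zeros((S, 2))
        trace = Trace(
            samples=samples,
            deviance=dev,
            latent_means={
                "x": np.full(n, mu.mean()),
                "z": np.zeros(n),
                "e": np.zeros(n),
            },
            accept_rates={},
            config=McmcConfig(n_iterations=S, burn_in=0, thin=1, seed=0,
                              outcome_layer=False),
            structure=structure_from_label("M2"),
            priors=PriorSettings(precx=1.0, precxt=1.0, precy=1.0),
            predictor_names=["g1", "g2"],
        )
        res = compute_dic(
            trace, (G, xt, y), structure_from_label("M2"),
            PriorSettings(precx=1.0, precxt=1.0, precy=1.0),
        )
        assert res.pD == pytest.approx(1.0, abs=0.2)

    def test_missing_deviance_series_rejected(self, small_model_data):
        trace = _toy_trace([])
        with pytest.raises(ValueError, match="deviance"):
            compute_dic(trace, small_model_data, structure_from_label("M7"))


class TestDicDifference:
    def test_published_confounder_free_comparison(self):
        # causal vs reverse models without confounders, first setting
        e1 = published.EXPERIMENT1_DIC["Setting1"]
        delta = dic_difference(e1["M2"], e1["M3"])
        assert delta == -221.0  # reverse favoured by 221 units

    def test_published_confounder_advantage(self):
        e1 = published.EXPERIMENT1_DIC["Setting1"]
        assert dic_difference(e1["M1"], e1["M2"]) == 45_929.0

    def test_identical_results_give_zero(self):
        r = DicResult(dbar=10.0, dhat=8.0)
        assert dic_difference(r, r) == 0.0


class TestVerdicts:
    @pytest.mark.parametrize(
        "delta,verdict",
        [
            (221.0, "decisive"),
            (45_929.0, "decisive"),
            (9.7, "substantial"),
            (5.2, "substantial"),
            (3.2, "inconclusive"),
            (-221.0, "decisive"),
            (5.0, "substantial"),
            (10.0, "substantial"),
            (10.000001, "decisive"),
            (0.0, "inconclusive"),
        ],
    )
    def test_thresholds(self, delta, verdict):
        assert interpret_difference(delta) == verdict


class TestCompareDbar:
    def test_identical_traces_give_zero(self):
        t = _toy_trace([4.0, 6.0])
        assert compare_dbar(t, t) == 0.0

    def test_toy_hand_arithmetic(self):
        assert compare_dbar(_toy_trace([10, 12]), _toy_trace([20, 22])) == 10.0

    def test_causal_fit_has_lower_dbar_on_causal_data(self):
        import spiv
        from spiv.preprocess import prepare_model_data

        wins = 0
        priors = PriorSettings.from_preset("Setting3")
        for seed in (101, 102, 103):
            table, _ = spiv.simulate_cohort(
                spiv.GeneratorConfig(
                    n_cases=250, n_controls=350, mode="causal", seed=seed
                )
            )
            data = prepare_model_data(table, standardize_biomarker=True)
            cfg = McmcConfig(n_iterations=1500, burn_in=750, thin=2, seed=seed)
            t7 = run_chain(data, structure_from_label("M7"), priors, cfg)
            t8 = run_chain(data, structure_from_label("M8"), priors, cfg)
            wins += compare_dbar(t7, t8) > 0  # Dbar_8 - Dbar_7 > 0
        assert wins >= 2


class TestMeanDic:
    def test_published_exploratory_row(self):
        grid = published.EXPLORATORY_GRID_DIC
        dics = list(grid[0.025]["causal"]) + list(grid[0.025]["reverse"])
        assert len(dics) == 12
        assert round(mean_dic(dics), 2) == -2801.12

    def test_all_published_row_means(self):
        # printed mean-DIC column of the exploratory grid, 1 d.p.
        expected = {0.025: -2801.1, 0.1: -1816.5, 0.25: -1598.6,
                    1.0: -1571.3, 10.0: -1557.5}
        grid = published.EXPLORATORY_GRID_DIC
        for gam1, want in expected.items():
            dics = list(grid[gam1]["causal"]) + list(grid[gam1]["reverse"])
            assert round(mean_dic(dics), 1) == want

    def test_published_final_phase_group(self):
        s1 = published.FINAL_COMPARISON_DIC["S1"]
        got = mean_dic([s1["M7"], s1["M8"]])
        assert got == -7320.5
        assert round(got) == -7320 or round(got, 0) == -7320.0

    def test_single_element_group(self):
        assert mean_dic([42.0]) == 42.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_dic([])


class TestRunExperiment:
    def test_single_cell_grid_equals_direct_computation(self, small_model_data):
        settings = {"Setting3": PriorSettings.from_preset("Setting3")}
        cfg = McmcConfig(n_iterations=200, burn_in=100, thin=2,
                         n_chains=1, seed=77)
        grid = run_experiment("1", small_model_data, settings, cfg,
                              repeats=1, structures=("M1",))
        assert len(grid.rows) == 1
        structure = structure_from_label("M1")
        traces = sample_posterior(
            small_model_data, structure, settings["Setting3"], cfg
        )
        direct = compute_dic(traces, small_model_data, structure,
                             settings["Setting3"])
        assert grid.rows[0]["dic"] == pytest.approx(direct.dic, abs=1e-9)

    def test_experiment1_grid_layout(self, small_model_data):
        settings = {
            name: PriorSettings.from_preset(name)
            for name in ("Setting1", "Setting3")
        }
        cfg = McmcConfig(n_iterations=80, burn_in=40, thin=2,
                         n_chains=1, seed=5)
        grid = run_experiment("1", small_model_data, settings, cfg)
        df = grid.to_frame()
        assert sorted(df["model"].unique()) == ["M1", "M2", "M3"]
        assert len(df) == 6  # 3 models x 2 settings
        assert grid.pivot().shape == (3, 2)

    def test_exploratory_grid_dimensions(self, small_cohort):
        # 5 gam1 x 6 gam2 prior settings -> 30 causal-reverse comparisons
        from spiv.preprocess import prepare_model_data

        table, _ = small_cohort
        data = prepare_model_data(table)
        settings = {
            f"g1={g1}/g2={g2}": PriorSettings.from_preset(
                "Setting3", gam1=g1, gam2=g2
            )
            for g1 in (0.025, 0.1, 0.25, 1.0, 10.0)
            for g2 in (0.1, 0.5, 1.0, 3.0, 10.0, 20.0)
        }
        assert len(settings) == 30
        cfg = McmcConfig(n_iterations=20, burn_in=10, thin=1,
                         n_chains=1, seed=9)
        grid = run_experiment("3-explore", data, settings, cfg,
                              subsample=(300, 300))
        df = grid.to_frame()
        assert len(df) == 60  # M7 and M8 per setting
        piv = df.pivot_table(index="setting", columns="model", values="dic")
        diffs = piv["M8"] - piv["M7"]
        assert len(diffs) == 30

    def test_unknown_experiment_rejected(self, small_model_data):
        with pytest.raises(ValueError, match="unknown experiment"):
            run_experiment("4", small_model_data, {}, McmcConfig(seed=1))


class TestExperimentGrid:
    def test_tsv_round_trip(self, tmp_path):
        grid = ExperimentGrid()
        grid.add("M1", "Setting1", 0, DicResult(dbar=5.0, dhat=3.0))
        path = tmp_path / "grid.tsv"
        grid.to_tsv(path)
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        assert df.loc[0, "dic"] == 7.0
        assert df.loc[0, "pD"] == 2.0
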