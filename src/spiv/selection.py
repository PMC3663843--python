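"""DIC computation, model comparison, and experiment grids.

The deviance information criterion is DIC = Dbar + pD where Dbar is the
posterior mean of the conditional deviance, Dhat the deviance at the
posterior means of the focused quantities (coefficients *and* latents),
and pD = Dbar - Dhat the effective number of parameters.  Lower DIC is
better; |difference| > 10 units rules out the higher-DIC model, 5-10 is
substantial, below 5 inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import deviance as _deviance
from .mcmc import McmcConfig, Trace, sample_posterior
from .structures import (
    ModelStructure,
    PriorSettings,
    structure_from_label,
    validate_structure,
)

__all__ = [
    "DicResult",
    "ComparisonResult",
    "ExperimentGrid",
    "compute_dic",
    "dic_difference",
    "interpret_difference",
    "compare_dbar",
    "mean_dic",
    "run_experiment",
]


@dataclass
class DicResult:
    dbar: float
    dhat: float
    model_label: str = ""
    settings_label: str = ""
    seed: int | None = None

    @property
    def pD(self) -> float:
        return self.dbar - self.dhat

    @property
    def dic(self) -> float:
        return self.dbar + self.pD

    def __repr__(self):
        return (
            f"DicResult({self.model_label or 'model'}: DIC={self.dic:.2f}, "
            f"Dbar={self.dbar:.2f}, pD={self.pD:.2f})"
        )


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    dic_difference: float  # DIC_b - DIC_a; positive favours a... see note
    verdict: str
    dbar_difference: float = float("nan")


def compute_dic(traces, data, structure: ModelStructure,
                priors: PriorSettings | None = None, **labels) -> DicResult:
    """DIC from one or more chains of the same model.

    Dbar pools the per-sample deviances; Dhat plugs the pooled posterior
    means of coefficients and latents into the deviance.
    """
    if isinstance(traces, Trace):
        traces = [traces]
    if not traces or traces[0].deviance.size == 0:
        raise ValueError("trace carries no deviance series")
    priors = priors if priors is not None else traces[0].priors
    dbar = float(np.mean(np.concatenate([t.deviance for t in traces])))
    # pooled posterior-mean state
    states = [t.posterior_mean_state() for t in traces]
    mean_state = states[0]
    if len(states) > 1:
        for nm in ("u", "wg", "z", "x", "e"):
            setattr(
                mean_state, nm,
                np.mean([getattr(s, nm) for s in states], axis=0),
            )
        for nm in ("w", "wr", "v", "wz", "b_x", "b_0"):
            setattr(
                mean_state, nm,
                float(np.mean([getattr(s, nm) for s in states])),
            )
        for nm in ("precx", "precxt", "precy"):
            vals = [getattr(s, nm) for s in states]
            if vals[0] is not None:
                setattr(mean_state, nm, float(np.mean(vals)))
    data = _as_tuple(data)
    dhat = _deviance(
        mean_state, data, structure, priors,
        include_outcome=traces[0].config.outcome_layer,
    )
    return DicResult(dbar=dbar, dhat=dhat, **labels)


def _dic_value(r) -> float:
    return r.dic if isinstance(r, DicResult) else float(r)


def dic_difference(result_a, result_b) -> float:
    """DIC_b - DIC_a (positive means model a has the lower DIC)."""
    return _dic_value(result_b) - _dic_value(result_a)


def interpret_difference(delta: float) -> str:
    """Verdict from |delta|: >10 decisive, [5, 10] substantial, <5
    inconclusive."""
    a = abs(delta)
    if a > 10.0:
        return "decisive"
    if a >= 5.0:
        return "substantial"
    return "inconclusive"


def compare(result_a: DicResult, result_b: DicResult) -> ComparisonResult:
    delta = dic_difference(result_a, result_b)
    return ComparisonResult(
        model_a=result_a.model_label,
        model_b=result_b.model_label,
        dic_difference=delta,
        verdict=interpret_difference(delta),
        dbar_difference=result_b.dbar - result_a.dbar,
    )


def compare_dbar(trace_a, trace_b) -> float:
    """Dbar_b - Dbar_a in natural log-deviance units."""
    return _dbar_of(trace_b) - _dbar_of(trace_a)


def _dbar_of(t) -> float:
    if isinstance(t, Trace):
        return t.dbar
    if isinstance(t, DicResult):
        return t.dbar
    devs = np.concatenate([c.deviance for c in t])
    if devs.size == 0:
        raise ValueError("trace carries no deviance series")
    return float(devs.mean())


@dataclass
class ExperimentGrid:
    """Factorial grid of DIC results over structures x settings x repeats."""

    rows: list = field(default_factory=list)

    def add(self, model_label, settings_label, repeat, result: DicResult):
        self.rows.append(
            dict(
                model=model_label,
                setting=settings_label,
                repeat=repeat,
                dbar=result.dbar,
                dhat=result.dhat,
                pD=result.pD,
                dic=result.dic,
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def pivot(self) -> pd.DataFrame:
        """Mean DIC per model (rows) x setting (columns), repeats averaged."""
        df = self.to_frame()
        return df.pivot_table(index="model", columns="setting", values="dic")


def mean_dic(grid, group_key=None):
    """Arithmetic mean DIC over the causal and reverse models per group.

    ``grid`` may be an ExperimentGrid/DataFrame (grouped by
    ``group_key``, default 'setting') or a plain sequence of DIC values
    (mean of the sequence).
    """
    if isinstance(grid, ExperimentGrid):
        grid = grid.to_frame()
    if isinstance(grid, pd.DataFrame):
        if grid.empty:
            raise ValueError("empty grid")
        group_key = group_key or "setting"
        sub = grid[grid["model"].isin(_DIRECTIONAL)] if "model" in grid else grid
        if sub.empty:
            raise ValueError("no causal or reverse rows in grid")
        return sub.groupby(group_key)["dic"].mean()
    vals = np.asarray(
        [_dic_value(v) for v in np.atleast_1d(np.asarray(grid, dtype=object))],
        dtype=float,
    )
    if vals.size == 0:
        raise ValueError("empty group")
    return float(vals.mean())


_DIRECTIONAL = {"M1", "M2", "M3", "M4", "M5", "M7", "M8", "causal", "reverse"}

_EXPERIMENT_MODELS = {
    "1": ("M1", "M2", "M3"),
    "2": ("M4", "M5", "M6"),
    "3-explore": ("M7", "M8"),
    "3-final": ("M7", "M8"),
}


def run_experiment(
    experiment_id,
    data,
    settings,
    config: McmcConfig,
    repeats: int = 1,
    structures=None,
    subsample=(500, 500),
) -> ExperimentGrid:
    """Fit every structure of the requested experiment under every
    prior setting with ``repeats`` seeds; return the filled grid.

    ``settings`` is a mapping label -> PriorSettings.  For experiment
    '3-explore' a seeded subsample of ``subsample`` cases and controls
    is drawn from the data first.  ``structures`` restricts the model
    list (default: the experiment's own models).  Chain failures are
    recorded as NaN rows so the grid always completes.
    """
    experiment_id = str(experiment_id)
    if experiment_id not in _EXPERIMENT_MODELS:
        raise ValueError(
            f"unknown experiment {experiment_id!r}; "
            f"choose from {sorted(_EXPERIMENT_MODELS)}"
        )
    g, xt, y = _as_tuple(data)
    if experiment_id == "3-explore":
        g, xt, y = _subsample_cases_controls(
            g, xt, y, subsample[0], subsample[1], config.seed
        )
    data = (g, xt, y)

    grid = ExperimentGrid()
    base_seed = config.seed
    labels = structures or _EXPERIMENT_MODELS[experiment_id]
    for m_idx, label in enumerate(labels):
        structure = validate_structure(structure_from_label(label))
        for set_label, priors in settings.items():
            for rep in range(repeats):
                cfg = McmcConfig(
                    n_iterations=config.n_iterations,
                    burn_in=config.burn_in,
                    thin=config.thin,
                    n_chains=config.n_chains,
                    seed=(base_seed + 10_000 * rep + 101 * m_idx) % (2**31 - 1),
                    proposal_scale=config.proposal_scale,
                    adapt=config.adapt,
                )
                try:
                    traces = sample_posterior(data, structure, priors, cfg)
                    res = compute_dic(
                        traces, data, structure, priors,
                        model_label=label, settings_label=set_label, seed=cfg.seed,
                    )
                    grid.add(label, set_label, rep, res)
                except Exception as err:  # record and continue
                    grid.rows.append(
                        dict(model=label, setting=set_label, repeat=rep,
                             dbar=np.nan, dhat=np.nan, pD=np.nan, dic=np.nan,
                             error=str(err))
                    )
    return grid


def _subsample_cases_controls(g, xt, y, n_cases, n_controls, seed):
    gv = np.asarray(getattr(g, "values", g), dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if cases.size < n_cases or controls.size < n_controls:
        raise ValueError(
            f"need >= {n_cases} cases and {n_controls} controls; have "
            f"{cases.size} and {controls.size}"
        )
    idx = np.sort(
        np.concatenate(
            [
                rng.choice(cases, n_cases, replace=False),
                rng.choice(controls, n_controls, replace=False),
            ]
        )
    )
    return gv[idx], np.asarray(xt, float)[idx], y[idx]


def _as_tuple(data):
    if hasattr(data, "g") and hasattr(data, "xt"):
        return (data.g, data.xt, data.y)
    return data
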