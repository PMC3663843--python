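"""Model/Results front end for the sparse-IV causal-direction analysis.

``CausalDirectionModel`` wraps one graphical structure (M1-M8) applied
to a preprocessed cohort; ``fit`` runs the MCMC and returns
``SpivResults`` carrying posterior summaries, diagnostics and the DIC.

Example
-------
>>> from spiv import cohort, preprocess
>>> from spiv.model import CausalDirectionModel
>>> table, truth = cohort.simulate_cohort(cohort.GeneratorConfig(seed=1))
>>> data = preprocess.prepare_model_data(table)
>>> model = CausalDirectionModel.from_label("M7", data)
>>> res = model.fit(n_iterations=4000, burn_in=2000, seed=1)
>>> print(res.summary())                            # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mcmc as _mcmc
from . import preprocess as _pre
from .selection import DicResult, compute_dic
from .structures import (
    ModelStructure,
    PriorSettings,
    structure_from_label,
    validate_structure,
)

__all__ = ["CausalDirectionModel", "SpivResults"]


class CausalDirectionModel:
    """A sparse-IV graphical model bound to one cohort.

    Parameters
    ----------
    data : ModelData or (g, xt, y) tuple
        Preprocessed inputs: scaled predictor matrix, May-adjusted
        biomarker, binary outcome.
    structure : ModelStructure
        Which links exist (direction, confounder, pleiotropy).
    priors : PriorSettings, optional
        Laplace concentrations and noise precisions (default preset
        gam1 = 0.025, precx = precxt = 200, precy = 100).
    """

    def __init__(self, data, structure: ModelStructure,
                 priors: PriorSettings | None = None):
        self.data = data
        self.structure = validate_structure(structure)
        self.priors = priors if priors is not None else PriorSettings()

    @classmethod
    def from_label(cls, label: str, data, priors=None) -> "CausalDirectionModel":
        return cls(data, structure_from_label(label), priors)

    @classmethod
    def from_cohort(cls, cohort_table: pd.DataFrame, label: str = "M7",
                    priors=None, n_pcs: int = 6,
                    standardize_biomarker: bool = False) -> "CausalDirectionModel":
        """Build directly from a raw cohort table (runs preprocessing)."""
        data = _pre.prepare_model_data(
            cohort_table, n_pcs=n_pcs, standardize_biomarker=standardize_biomarker
        )
        return cls.from_label(label, data, priors)

    def fit(self, n_iterations: int = 20_000, burn_in: int | None = None,
            thin: int = 5, n_chains: int = 2, seed: int = 0,
            **kwargs) -> "SpivResults":
        burn_in = n_iterations // 2 if burn_in is None else burn_in
        config = _mcmc.McmcConfig(
            n_iterations=n_iterations, burn_in=burn_in, thin=thin,
            n_chains=n_chains, seed=seed, **kwargs,
        )
        traces = _mcmc.sample_posterior(self.data, self.structure,
                                        self.priors, config)
        return SpivResults(self, traces)


class SpivResults:
    """Posterior results of a fitted CausalDirectionModel."""

    def __init__(self, model: CausalDirectionModel, traces):
        self.model = model
        self.traces = traces
        self._posterior = None
        self._dic = None

    @property
    def posterior(self) -> pd.DataFrame:
        if self._posterior is None:
            self._posterior = _mcmc.posterior_summary(self.traces)
        return self._posterior

    def dic(self) -> DicResult:
        if self._dic is None:
            self._dic = compute_dic(
                self.traces, self.model.data, self.model.structure,
                self.model.priors, model_label=self.model.structure.label,
            )
        return self._dic

    @property
    def dbar(self) -> float:
        return float(
            np.mean(np.concatenate([t.deviance for t in self.traces]))
        )

    def diagnostics(self) -> _mcmc.DiagnosticsReport:
        return _mcmc.diagnose(self.traces)

    def params(self) -> pd.Series:
        """Posterior means of the structural coefficients."""
        return self.posterior["mean"]

    def credible_interval(self, name: str) -> tuple[float, float]:
        row = self.posterior.loc[name]
        return float(row["q2_5"]), float(row["q97_5"])

    def summary(self) -> str:
        st = self.model.structure
        d = self.dic()
        n_samp = sum(t.n_samples for t in self.traces)
        head = [
            "          Sparse-IV causal direction model",
            "=" * 58,
            f"Structure:        {st.label} (direction={st.direction}, "
            f"confounder={st.include_confounder}, "
            f"pleiotropy={st.include_pleiotropy})",
            f"Chains/samples:   {len(self.traces)} / {n_samp}",
            f"gam1/gam2:        {self.model.priors.gam1} / {self.model.priors.gam2}",
            f"precx/precxt/precy: {self.model.priors.precx} / "
            f"{self.model.priors.precxt} / {self.model.priors.precy}",
            f"Dbar:             {d.dbar:12.2f}",
            f"pD:               {d.pD:12.2f}",
            f"DIC:              {d.dic:12.2f}",
            "-" * 58,
        ]
        core = self.posterior
        scalars = [
            p for p in ("w", "wr", "v", "wz", "b_x", "b_0") if p in core.index
        ]
        body = core.loc[scalars].round(4).to_string()
        return "\n".join(head) + "\n" + body + "\n" + "=" * 58

    def __repr__(self):
        return (
            f"<SpivResults {self.model.structure.label}: "
            f"{len(self.traces)} chain(s)>"
        )
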