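"""Synthetic case-control cohort generation.

Generates cohorts with the statistical structure the sparse-IV analysis
assumes: ~20 SNP dosages in Hardy-Weinberg proportions, environmental
covariates matching the SOCCS study marginals, a latent standard-normal
confounder ``z``, a linear-Gaussian biomarker (true level ``x``, noisy
seasonal measurement ``xt``), and a logistic disease outcome ``y``.  Four
generative structures are supported:

``causal``
    x -> y: the biomarker shifts disease risk (coefficient ``w``).
``reverse``
    y -> x: disease status shifts the biomarker (coefficient ``wr``).
``confounder_only``
    no direct x-y link; association is driven entirely by ``z``.
``null``
    no x-y link and no confounding.

Case-control ascertainment is emulated by oversampling a source
population and subsampling exact case/control quotas; the generative
model itself is a prospective population model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSpec",
    "GeneratorConfig",
    "GroundTruth",
    "simulate_genotypes",
    "inject_seasonality",
    "simulate_cohort",
    "DEFAULT_COVARIATES",
    "DEFAULT_MAFS",
    "COVARIATE_NAMES",
    "SNP_COLUMNS",
]

N_SNPS = 20
SNP_COLUMNS = tuple(f"snp{i:02d}" for i in range(1, N_SNPS + 1))

#: Allele frequencies for the 16 CRC-associated and 4 25-OHD-associated
#: loci the generator emulates (common GWAS variants, MAF 0.09-0.48).
DEFAULT_MAFS = (
    0.35, 0.20, 0.24, 0.09, 0.37, 0.33, 0.29, 0.35,
    0.28, 0.46, 0.19, 0.29, 0.48, 0.10, 0.37, 0.31,
    0.28, 0.25, 0.40, 0.18,
)


@dataclass(frozen=True)
class CovariateSpec:
    """One environmental covariate: name, distribution family, parameters.

    Families: ``normal(mean, sd)``, ``bernoulli(p)``,
    ``categorical(p_0..p_{k-1})`` (integer-coded 0..k-1),
    ``lognormal(meanlog, sdlog)``.
    """

    name: str
    family: str
    params: tuple

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "normal":
            mean, sd = self.params
            return rng.normal(mean, sd, size=n)
        if self.family == "bernoulli":
            (p,) = self.params
            return rng.binomial(1, p, size=n).astype(float)
        if self.family == "categorical":
            p = np.asarray(self.params, dtype=float)
            p = p / p.sum()
            return rng.choice(len(p), size=n, p=p).astype(float)
        if self.family == "lognormal":
            meanlog, sdlog = self.params
            return rng.lognormal(meanlog, sdlog, size=n)
        raise ValueError(f"unknown covariate family {self.family!r}")


# Marginals follow the published SOCCS cohort description (means/SDs for
# continuous variables, category frequencies for ordinal ones).
DEFAULT_COVARIATES: tuple[CovariateSpec, ...] = (
    CovariateSpec("age", "normal", (62.8, 10.3)),
    CovariateSpec("sex", "bernoulli", (0.42,)),
    CovariateSpec("bmi", "normal", (26.69, 4.50)),
    CovariateSpec("physical_activity", "categorical", (0.556, 0.255, 0.117, 0.068)),
    CovariateSpec("family_history", "categorical", (0.934, 0.060, 0.006)),
    CovariateSpec("nsaids", "bernoulli", (0.340,)),
    CovariateSpec(
        "deprivation", "categorical",
        (0.096, 0.219, 0.276, 0.233, 0.097, 0.056, 0.023),
    ),
    CovariateSpec("energy", "normal", (2575.0, 982.0)),
    CovariateSpec("alcohol", "lognormal", (2.07, 1.20)),
    CovariateSpec("smoking", "categorical", (0.437, 0.401, 0.162)),
    CovariateSpec("red_meat", "lognormal", (0.215, 0.55)),
    CovariateSpec("dietary_vitd", "lognormal", (1.45, 0.45)),
    CovariateSpec("supplement_vitd", "categorical", (0.812, 0.131, 0.057)),
)

COVARIATE_NAMES = tuple(c.name for c in DEFAULT_COVARIATES)

# Default generating effects, chosen once for epidemiological realism on
# the raw covariate scales (biomarker in ng/ml, outcome on the log-odds
# scale); see docs/methods.md for the rationale.
_DEFAULT_U = {
    "age": -0.02,
    "sex": 0.5,
    "bmi": -0.15,
    "physical_activity": 0.6,
    "smoking": -0.3,
    "dietary_vitd": 0.35,
    "supplement_vitd": 1.5,
    "snp17": -0.9,
    "snp18": -0.7,
    "snp19": -0.5,
    "snp20": -0.4,
}

_DEFAULT_WG = {
    "age": 0.02,
    "bmi": 0.02,
    "physical_activity": -0.1,
    "family_history": 1.2,
    "nsaids": -0.3,
    "red_meat": 0.1,
    **{
        f"snp{i:02d}": c
        for i, c in zip(
            range(1, 17),
            (0.10, 0.08, 0.09, 0.12, 0.11, 0.09, 0.10, 0.08,
             0.09, 0.10, 0.12, 0.08, 0.09, 0.11, 0.13, 0.10),
        )
    },
}

_MODES = ("causal", "reverse", "confounder_only", "null")


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic cohort.

    Effects ``true_u`` (predictors -> biomarker) and ``true_wg``
    (predictors -> outcome) are dictionaries keyed by covariate/SNP
    column name; unnamed predictors have zero effect.  Precisions are
    inverse variances of the respective Gaussian noise terms.
    """

    n_cases: int = 1057
    n_controls: int = 1588
    mode: str = "causal"
    snp_mafs: Sequence[float] = DEFAULT_MAFS
    covariate_spec: Sequence[CovariateSpec] = DEFAULT_COVARIATES
    true_u: dict = field(default_factory=lambda: dict(_DEFAULT_U))
    true_w: float = -0.15
    true_wr: float = -0.8
    true_wg: dict = field(default_factory=lambda: dict(_DEFAULT_WG))
    # confounding reinforces the inverse biomarker-outcome association
    # (e.g. adiposity/inactivity: higher 25-OHD, lower CRC risk)
    true_v: float = 2.0
    true_wz: float = -0.4
    true_precx: float = 100.0
    true_precxt: float = 100.0
    true_precy: float = 100.0
    seasonal_amplitude: float = 3.5
    seasonal_phase_month: int = 7
    intercept_x: float = 16.7
    intercept_y: float = -2.5
    seed: int = 0
    max_oversample: float = 60.0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        mafs = np.asarray(self.snp_mafs, dtype=float)
        if np.any(mafs < 0) or np.any(mafs > 1):
            raise ValueError("snp_mafs must lie in [0, 1]")
        for prec in (self.true_precx, self.true_precxt, self.true_precy):
            if prec <= 0:
                raise ValueError("precisions must be strictly positive")
        if not 1 <= self.seasonal_phase_month <= 12:
            raise ValueError("seasonal_phase_month must be in 1..12")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        # Structural zeroes implied by the generative mode.
        if self.mode == "null":
            self.true_w = 0.0
            self.true_wr = 0.0
            self.true_v = 0.0
            self.true_wz = 0.0
        elif self.mode == "confounder_only":
            self.true_w = 0.0
            self.true_wr = 0.0
        elif self.mode == "causal":
            self.true_wr = 0.0
        elif self.mode == "reverse":
            self.true_w = 0.0


@dataclass
class GroundTruth:
    """Everything needed to regenerate a cohort bit-exactly."""

    mode: str
    seed: int
    true_u: dict
    true_w: float
    true_wr: float
    true_wg: dict
    true_v: float
    true_wz: float
    true_precx: float
    true_precxt: float
    true_precy: float
    seasonal_amplitude: float
    seasonal_phase_month: int
    intercept_x: float
    intercept_y: float
    n_cases: int
    n_controls: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_genotypes(n: int, mafs: Sequence[float], seed=None) -> np.ndarray:
    """Draw an ``n x len(mafs)`` dosage matrix under Hardy-Weinberg.

    Entry (i, j) is Binomial(2, mafs[j]); loci are independent (no LD).
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs < 0) or np.any(mafs > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int64)


def inject_seasonality(
    x_values: np.ndarray,
    months: np.ndarray,
    amplitude: float,
    phase_month: int,
) -> np.ndarray:
    """Add a single cosine harmonic peaking at ``phase_month``.

    Returns ``x + amplitude * cos(2*pi*(month - phase_month)/12)``.
    """
    months = np.asarray(months)
    if np.any((months < 1) | (months > 12)):
        raise ValueError("months must lie in 1..12")
    if not 1 <= phase_month <= 12:
        raise ValueError("phase_month must be in 1..12")
    x_values = np.asarray(x_values, dtype=float)
    return x_values + amplitude * np.cos(2.0 * np.pi * (months - phase_month) / 12.0)


def _effect_vector(effects: dict, columns: Sequence[str]) -> np.ndarray:
    unknown = set(effects) - set(columns)
    if unknown:
        raise ValueError(f"effects refer to unknown columns: {sorted(unknown)}")
    return np.array([effects.get(c, 0.0) for c in columns])


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _simulate_population(config: GeneratorConfig, n: int,
                         rng: np.random.Generator, return_latents: bool = False):
    """One prospective draw of n individuals under the generative model."""
    cov_names = [c.name for c in config.covariate_spec]
    cov = np.column_stack([c.sample(n, rng) for c in config.covariate_spec])
    geno = simulate_genotypes(n, config.snp_mafs, rng)
    columns = list(cov_names) + list(SNP_COLUMNS[: geno.shape[1]])
    g = np.column_stack([cov, geno.astype(float)])

    u = _effect_vector(config.true_u, columns)
    wg = _effect_vector(config.true_wg, columns)

    z = rng.standard_normal(n)
    e = rng.normal(0.0, 1.0 / np.sqrt(config.true_precy), size=n)
    months = rng.integers(1, 13, size=n)

    x_mean = config.intercept_x + g @ u + config.true_v * z
    if config.mode == "reverse":
        eta = config.intercept_y + g @ wg + config.true_wz * z + e
        y = rng.random(n) < _sigmoid(eta)
        x = x_mean + config.true_wr * y + rng.normal(
            0.0, 1.0 / np.sqrt(config.true_precx), size=n
        )
    else:
        x = x_mean + rng.normal(0.0, 1.0 / np.sqrt(config.true_precx), size=n)
        eta = (
            config.intercept_y
            + config.true_w * x
            + g @ wg
            + config.true_wz * z
            + e
        )
        y = rng.random(n) < _sigmoid(eta)

    xt_noise = rng.normal(0.0, 1.0 / np.sqrt(config.true_precxt), size=n)
    xt_raw = inject_seasonality(
        x + xt_noise, months, config.seasonal_amplitude, config.seasonal_phase_month
    )

    table = pd.DataFrame(g, columns=columns)
    table.insert(0, "month", months)
    table.insert(0, "xt_raw", xt_raw)
    table.insert(0, "y", y.astype(int))
    for snp in SNP_COLUMNS[: geno.shape[1]]:
        table[snp] = table[snp].astype(int)
    if return_latents:
        return table, {"z": z, "x": x, "e": e, "eta": eta}
    return table


def simulate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a case-control cohort with exact case/control quotas.

    A source population is drawn in batches from the prospective model
    and cases/controls are subsampled without replacement until the
    requested ``(n_cases, n_controls)`` are reached.  Raises a
    ``RuntimeError`` naming the achieved case fraction if the quota
    cannot be met within ``config.max_oversample`` times the target size.
    """
    rng = np.random.default_rng(config.seed)
    target = config.n_cases + config.n_controls
    batch = max(4 * target, 2000)
    cases: list[pd.DataFrame] = []
    controls: list[pd.DataFrame] = []
    n_cases_seen = n_controls_seen = n_drawn = 0

    while (
        n_cases_seen < config.n_cases or n_controls_seen < config.n_controls
    ):
        if n_drawn >= config.max_oversample * target:
            frac = n_cases_seen / max(n_drawn, 1)
            raise RuntimeError(
                f"could not reach {config.n_cases} cases / "
                f"{config.n_controls} controls after sampling {n_drawn} "
                f"individuals (achieved case fraction {frac:.4f}); "
                "adjust intercept_y or max_oversample"
            )
        pop = _simulate_population(config, batch, rng)
        n_drawn += batch
        is_case = pop["y"].to_numpy() == 1
        if n_cases_seen < config.n_cases:
            cases.append(pop.loc[is_case])
            n_cases_seen += int(is_case.sum())
        if n_controls_seen < config.n_controls:
            controls.append(pop.loc[~is_case])
            n_controls_seen += int((~is_case).sum())

    case_pool = pd.concat(cases, ignore_index=True)
    control_pool = pd.concat(controls, ignore_index=True)
    case_idx = rng.choice(len(case_pool), size=config.n_cases, replace=False)
    control_idx = rng.choice(len(control_pool), size=config.n_controls, replace=False)
    cohort = pd.concat(
        [case_pool.iloc[np.sort(case_idx)], control_pool.iloc[np.sort(control_idx)]],
        ignore_index=True,
    )
    cohort.insert(0, "id", np.arange(len(cohort)))

    truth = GroundTruth(
        mode=config.mode,
        seed=config.seed,
        true_u=dict(config.true_u),
        true_w=config.true_w,
        true_wr=config.true_wr,
        true_wg=dict(config.true_wg),
        true_v=config.true_v,
        true_wz=config.true_wz,
        true_precx=config.true_precx,
        true_precxt=config.true_precxt,
        true_precy=config.true_precy,
        seasonal_amplitude=config.seasonal_amplitude,
        seasonal_phase_month=config.seasonal_phase_month,
        intercept_x=config.intercept_x,
        intercept_y=config.intercept_y,
        n_cases=config.n_cases,
        n_controls=config.n_controls,
    )
    return cohort, truth
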