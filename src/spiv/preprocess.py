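"""Cohort preprocessing: scaling, genotype PCA, seasonal adjustment.

Turns a raw cohort table into the analysis-ready inputs of the
graphical models: a predictor matrix ``g`` (scaled environmental
covariates plus genotype principal-component scores, all mean 0 / SD 1)
and a May-standardised biomarker ``xt``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .cohort import COVARIATE_NAMES, SNP_COLUMNS

__all__ = [
    "ScalingParams",
    "PredictorMatrix",
    "StandardizedBiomarker",
    "scale_columns",
    "genotype_pcs",
    "deseasonalize_to_may",
    "assemble_predictors",
    "univariate_association",
    "prepare_model_data",
    "ModelData",
]


@dataclass
class ScalingParams:
    columns: list
    means: np.ndarray
    sds: np.ndarray


@dataclass
class PredictorMatrix:
    """Scaled predictor matrix g (n x p) with column names and the
    centering/scaling parameters used, retained for reproducibility."""

    values: np.ndarray
    columns: list
    scaling: ScalingParams

    @property
    def shape(self):
        return self.values.shape


@dataclass
class StandardizedBiomarker:
    """May-adjusted biomarker: seasonal residual plus the fitted value at
    month 5, with the fitted cosine-harmonic coefficients."""

    xt: np.ndarray
    intercept: float
    cos_coef: float
    sin_coef: float

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.cos_coef, self.sin_coef))


def scale_columns(matrix, columns=None):
    """Center each column by its mean and divide by its sample SD (n-1).

    Accepts a DataFrame or 2-D array; returns ``(scaled_array, ScalingParams)``.
    Raises on zero-variance columns, naming the offender.
    """
    if isinstance(matrix, pd.DataFrame):
        columns = list(matrix.columns)
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if columns is None:
            columns = [f"col{i}" for i in range(values.shape[1])]
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance column(s): {[columns[i] for i in bad]}"
        )
    scaled = (values - means) / sds
    return scaled, ScalingParams(list(columns), means, sds)


def genotype_pcs(genotypes, k: int = 6) -> np.ndarray:
    """Principal-component scores of the column-centered dosage matrix.

    Columns are ordered by non-increasing explained variance; each
    component's sign is fixed so its largest-magnitude loading is
    positive.  Constant dosage columns are dropped with a warning before
    the decomposition.  Dosages are centered but not standardised: all
    loci share the 0/1/2 scale.
    """
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    keep = G.std(axis=0) > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} constant genotype column(s) "
            "before PCA",
            stacklevel=2,
        )
        G = G[:, keep]
        m = G.shape[1]
    if k > m:
        raise ValueError(f"k={k} exceeds the {m} usable genotype columns")
    if n <= k:
        raise ValueError("need more individuals than components")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(G)
    # sign convention: largest-|loading| entry of each PC positive
    for j in range(k):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            scores[:, j] *= -1.0
    return scores


def deseasonalize_to_may(values, months) -> StandardizedBiomarker:
    """Remove the seasonal oscillation and report May-adjusted values.

    Fits ``value ~ a + b cos(2 pi m / 12) + c sin(2 pi m / 12)`` by least
    squares and returns the residual plus the fitted value at month 5.
    """
    values = np.asarray(values, dtype=float)
    months = np.asarray(months)
    if np.any((months < 1) | (months > 12)):
        raise ValueError("months must lie in 1..12")
    if values.size < 24:
        raise ValueError("need at least 24 observations for a seasonal fit")
    if np.unique(months).size < 3:
        raise ValueError(
            "seasonal fit is singular: observations cover fewer than 3 months"
        )
    ang = 2.0 * np.pi * months / 12.0
    X = np.column_stack([np.ones_like(values), np.cos(ang), np.sin(ang)])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    a, b, c = coef
    resid = values - X @ coef
    ang_may = 2.0 * np.pi * 5.0 / 12.0
    pred_may = a + b * np.cos(ang_may) + c * np.sin(ang_may)
    return StandardizedBiomarker(resid + pred_may, float(a), float(b), float(c))


def assemble_predictors(covariates, pc_scores=None) -> PredictorMatrix:
    """Concatenate covariates and PC scores, then scale every column.

    Ordinal covariates are assumed already integer-coded (the cohort
    dialect stores category indices); each final column has mean 0 and
    sample SD 1.
    """
    if isinstance(covariates, pd.DataFrame):
        cov_names = list(covariates.columns)
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.asarray(covariates, dtype=float)
        cov_names = [f"cov{i}" for i in range(cov.shape[1])]
    blocks = [cov]
    names = list(cov_names)
    if pc_scores is not None and np.size(pc_scores):
        pcs = np.asarray(pc_scores, dtype=float)
        if pcs.shape[0] != cov.shape[0]:
            raise ValueError(
                f"row mismatch: {cov.shape[0]} covariate rows vs "
                f"{pcs.shape[0]} PC rows"
            )
        blocks.append(pcs)
        names += [f"pc{j + 1}" for j in range(pcs.shape[1])]
    full = np.hstack(blocks)
    scaled, params = scale_columns(full, names)
    return PredictorMatrix(scaled, names, params)


def univariate_association(y, predictor, adjusters=None):
    """Logistic regression of a binary outcome on one predictor.

    Returns ``(log_odds_coef, se, p_value)`` for the predictor, from a
    maximum-likelihood fit with an intercept and optional adjusters.
    Raises on constant inputs or (quasi-)separation.
    """
    y = np.asarray(y, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    if np.all(y == y[0]):
        raise ValueError("outcome is constant")
    if np.ptp(predictor) == 0:
        raise ValueError("predictor has zero variance")
    X = [np.ones_like(predictor), predictor]
    if adjusters is not None:
        adj = np.asarray(adjusters, dtype=float)
        if adj.ndim == 1:
            adj = adj[:, None]
        X.extend(adj.T)
    X = np.column_stack(X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
        ) as err:
            raise ValueError(f"perfect separation in logistic fit: {err}") from None
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


@dataclass
class ModelData:
    """Analysis-ready inputs: outcome, May-adjusted biomarker, predictors."""

    y: np.ndarray
    xt: np.ndarray
    g: PredictorMatrix
    seasonal: StandardizedBiomarker

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.g.values.shape[1]


def prepare_model_data(
    cohort: pd.DataFrame,
    n_pcs: int = 6,
    standardize_biomarker: bool = False,
    genotype_representation: str = "pcs",
) -> ModelData:
    """Full preprocessing pipeline from a cohort table.

    Deseasonalises ``xt_raw`` to its May-adjusted value, reduces the
    genotypes to ``n_pcs`` principal components (or keeps them as raw
    scaled dosage columns with ``genotype_representation='raw'``), and
    assembles the scaled predictor matrix.  By default the biomarker
    stays on its concentration scale (precision settings are
    interpreted on that scale); ``standardize_biomarker=True`` z-scores
    it instead.
    """
    cov_cols = [c for c in COVARIATE_NAMES if c in cohort.columns]
    snp_cols = [c for c in SNP_COLUMNS if c in cohort.columns]
    seasonal = deseasonalize_to_may(
        cohort["xt_raw"].to_numpy(float), cohort["month"].to_numpy()
    )
    xt = seasonal.xt
    if standardize_biomarker:
        xt = (xt - xt.mean()) / xt.std(ddof=1)
    if genotype_representation == "raw":
        g = assemble_predictors(cohort[cov_cols + snp_cols])
    elif genotype_representation == "pcs":
        pcs = (
            genotype_pcs(cohort[snp_cols].to_numpy(), n_pcs)
            if (n_pcs and snp_cols)
            else None
        )
        g = assemble_predictors(cohort[cov_cols], pcs)
    else:
        raise ValueError("genotype_representation must be 'pcs' or 'raw'")
    return ModelData(cohort["y"].to_numpy(int), xt, g, seasonal)
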