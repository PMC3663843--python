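"""Exact log-density and deviance of the sparse-IV graphical models.

The joint density over one cohort factorises per individual i as

    N(x_i | b_x + u.g_i + v z_i [+ wr y_i], 1/precx)
  * N(xt_i | x_i, 1/precxt)
  * N(z_i | 0, 1/precz)
  * N(e_i | 0, 1/precy)
  * Bernoulli(y_i | sigmoid(b_0 + w x_i + wg.g_i + wz z_i + e_i))

times Laplace priors on the structural coefficients (concentration
gam1; gam2 for the confounder links v, wz), broad Gaussian priors on
the intercepts, and Gamma priors on sampled precisions.  The deviance
keeps only the observed-data terms (xt and y), conditioning on the
latents as parameters in focus.
"""

from __future__ import annotations

import numpy as np

from .structures import ModelStructure, ParameterState, PriorSettings

__all__ = [
    "laplace_log_density",
    "log_joint",
    "deviance",
    "biomarker_logpdf",
    "measurement_logpdf",
    "latent_logpdf",
    "outcome_logpmf",
    "prior_log_density",
    "linear_predictor",
    "biomarker_mean",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def laplace_log_density(theta, gam):
    """log of the Laplace(0, 1/gam) density: log(gam/2) - gam|theta|.

    Larger ``gam`` concentrates mass at zero (stronger shrinkage).
    Accepts scalars or arrays.
    """
    if gam <= 0:
        raise ValueError("gam must be strictly positive")
    theta = np.asarray(theta, dtype=float)
    out = np.log(gam / 2.0) - gam * np.abs(theta)
    return float(out) if out.ndim == 0 else out


def _norm_logpdf(x, mean, prec):
    return 0.5 * (np.log(prec) - _LOG_2PI) - 0.5 * prec * (x - mean) ** 2


def _effective_precisions(state: ParameterState, priors: PriorSettings):
    precx = state.precx if state.precx is not None else priors.precx
    precxt = state.precxt if state.precxt is not None else priors.precxt
    precy = state.precy if state.precy is not None else priors.precy
    return precx, precxt, precy


def biomarker_mean(state: ParameterState, g, y, structure: ModelStructure):
    """Conditional mean of the true biomarker x."""
    m = state.b_x + g @ state.u
    if structure.has_confounder:
        m = m + state.v * state.z
    if structure.has_wr:
        m = m + state.wr * np.asarray(y, dtype=float)
    return m


def linear_predictor(state: ParameterState, g, structure: ModelStructure):
    """Logistic-layer linear predictor eta (including liability noise e)."""
    eta = state.b_0 + g @ state.wg + state.e
    if structure.has_w:
        eta = eta + state.w * state.x
    if structure.has_confounder:
        eta = eta + state.wz * state.z
    return eta


def biomarker_logpdf(state, g, y, structure, priors):
    precx, _, _ = _effective_precisions(state, priors)
    m = biomarker_mean(state, g, y, structure)
    return float(np.sum(_norm_logpdf(state.x, m, precx)))


def measurement_logpdf(state, xt, priors):
    _, precxt, _ = _effective_precisions(state, priors)
    return float(np.sum(_norm_logpdf(np.asarray(xt, float), state.x, precxt)))


def latent_logpdf(state, structure, priors):
    """Log density of the per-subject latents z (if present) and e."""
    _, _, precy = _effective_precisions(state, priors)
    total = float(np.sum(_norm_logpdf(state.e, 0.0, precy)))
    if structure.has_confounder:
        total += float(np.sum(_norm_logpdf(state.z, 0.0, priors.precz)))
    return total


def outcome_logpmf(state, g, y, structure):
    eta = linear_predictor(state, g, structure)
    y = np.asarray(y, dtype=float)
    # log Bern(y|sigmoid(eta)) = y*eta - log(1 + exp(eta)), stable form
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def prior_log_density(state: ParameterState, structure, priors: PriorSettings):
    """Coefficient priors: Laplace (direct links with gam1, confounder
    links with gam2), Gaussian intercepts, Gamma terms for sampled
    precisions."""
    total = 0.0
    if structure.has_u:
        total += float(np.sum(laplace_log_density(state.u, priors.gam1)))
    if structure.has_wg:
        total += float(np.sum(laplace_log_density(state.wg, priors.gam1)))
    if structure.has_w:
        total += laplace_log_density(state.w, priors.gam1)
    if structure.has_wr:
        total += laplace_log_density(state.wr, priors.gam1)
    if structure.has_confounder:
        total += laplace_log_density(state.v, priors.gam2)
        total += laplace_log_density(state.wz, priors.gam2)
    prec_b = 1.0 / priors.intercept_sd**2
    total += float(_norm_logpdf(state.b_x, 0.0, prec_b))
    total += float(_norm_logpdf(state.b_0, 0.0, prec_b))
    if priors.precision_mode == "gamma":
        a, b = priors.gamma_shape, priors.gamma_rate
        from scipy.stats import gamma as _gamma

        for prec in _effective_precisions(state, priors):
            total += float(_gamma.logpdf(prec, a, scale=1.0 / b))
    return total


def log_joint(state: ParameterState, data, structure: ModelStructure,
              priors: PriorSettings) -> float:
    """Log of the full joint density (data, latents, priors).

    ``data`` is ``(g, xt, y)`` with g the scaled predictor matrix (or a
    ``PredictorMatrix``).  Raises on non-finite results, naming the
    offending block.
    """
    g, xt, y = _unpack(data)
    terms = {
        "biomarker": biomarker_logpdf(state, g, y, structure, priors),
        "measurement": measurement_logpdf(state, xt, priors),
        "latents": latent_logpdf(state, structure, priors),
        "outcome": outcome_logpmf(state, g, y, structure),
        "priors": prior_log_density(state, structure, priors),
    }
    for name, val in terms.items():
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite log-joint term: {name}")
    return float(sum(terms.values()))


def deviance(state: ParameterState, data, structure: ModelStructure,
             priors: PriorSettings, include_outcome: bool = True) -> float:
    """-2 x observed-data log likelihood, latents conditioned on.

    Only the measurement term p(xt | x) and the outcome term p(y | ...)
    enter; latent and prior densities are excluded.  This is the
    conditional deviance whose posterior mean is Dbar.
    ``include_outcome=False`` restricts to the measurement layer (for
    linear-Gaussian sub-models).
    """
    g, xt, y = _unpack(data)
    ll = measurement_logpdf(state, xt, priors)
    if include_outcome:
        ll += outcome_logpmf(state, g, y, structure)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite deviance")
    return -2.0 * ll


def _unpack(data):
    g, xt, y = data
    g = getattr(g, "values", g)
    return np.asarray(g, float), np.asarray(xt, float), np.asarray(y)
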