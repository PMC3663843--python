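"""MCMC inference for the sparse-IV graphical models.

The sampler is a Gibbs-within-Metropolis scheme:

* linear-Gaussian blocks (intercept b_x, predictor effects u, confounder
  loading v, reverse effect wr) are drawn exactly from their Gaussian
  full conditionals, using the exponential scale-mixture representation
  of the Laplace prior (Bayesian-lasso style auxiliary variances tau);
* logistic-layer coefficients (b_0, w, wg, wz) use adaptive per-block
  random-walk Metropolis with the Laplace prior evaluated directly;
* per-subject latents (true biomarker x, confounder z, liability noise
  e) are updated jointly across subjects: x and z by independence
  proposals from their Gaussian conditional parts accepted against the
  logistic factor, e by an adaptive random walk;
* precisions are drawn conjugately when the Gamma precision mode is on.

Proposal-scale adaptation runs during burn-in only, so retained samples
come from a fixed transition kernel.  Given an identical seed and
configuration the trace is bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import ModelStructure, ParameterState, PriorSettings

__all__ = [
    "McmcConfig",
    "Trace",
    "run_chain",
    "sample_posterior",
    "posterior_summary",
    "diagnose",
    "DiagnosticsReport",
    "effective_sample_size",
    "potential_scale_reduction",
]


@dataclass
class McmcConfig:
    n_iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    n_chains: int = 2
    seed: int = 0
    proposal_scale: float = 0.1
    adapt: bool = True
    store_latents: bool = False
    align_confounder_sign: bool = True
    #: disable data terms to sample from the prior (testing hook)
    use_likelihood: bool = True
    #: replace Laplace priors on linear-block coefficients by fixed
    #: Gaussian priors with this SD (testing hook; None = Laplace)
    gaussian_coefficient_sd: float | None = None
    #: drop the logistic outcome layer entirely (linear-Gaussian sub-model)
    outcome_layer: bool = True

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass
class Trace:
    """Retained samples from one chain.

    ``samples`` maps parameter names (``u``, ``wg`` arrays of shape
    (S, p); ``w``, ``wr``, ``v``, ``wz``, ``b_x``, ``b_0`` of shape
    (S,)) to sample arrays; ``deviance`` is the per-sample conditional
    deviance; ``latent_means`` holds posterior means of x, z, e over the
    retained samples (full latent samples only when requested).
    """

    samples: dict
    deviance: np.ndarray
    latent_means: dict
    accept_rates: dict
    config: McmcConfig
    structure: ModelStructure
    priors: PriorSettings
    predictor_names: list = field(default_factory=list)
    latent_samples: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.deviance.size)

    @property
    def dbar(self) -> float:
        return float(self.deviance.mean())

    def save(self, path) -> None:
        """Persist retained samples in a columnar file (parquet) with a
        JSON sidecar echoing config, structure and priors."""
        import dataclasses
        import json
        from pathlib import Path

        path = Path(path)
        cols = {}
        for nm, arr in self.samples.items():
            if arr.ndim == 1:
                cols[nm] = arr
            else:
                for j in range(arr.shape[1]):
                    label = (
                        self.predictor_names[j]
                        if j < len(self.predictor_names) else j
                    )
                    cols[f"{nm}[{label}]"] = arr[:, j]
        cols["deviance"] = self.deviance
        pd.DataFrame(cols).to_parquet(path)
        sidecar = {
            "config": dataclasses.asdict(self.config),
            "structure": dataclasses.asdict(self.structure),
            "priors": dataclasses.asdict(self.priors),
            "accept_rates": self.accept_rates,
            "latent_means": {k: v.tolist() for k, v in self.latent_means.items()},
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def load(cls, path) -> "Trace":
        import json
        from pathlib import Path

        path = Path(path)
        frame = pd.read_parquet(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        names = [c[2:-1] for c in frame.columns if c.startswith("u[")]
        samples = {
            "u": frame[[f"u[{nm}]" for nm in names]].to_numpy(),
            "wg": frame[[f"wg[{nm}]" for nm in names]].to_numpy(),
        }
        for nm in ("w", "wr", "v", "wz", "b_x", "b_0", "precx", "precxt", "precy"):
            if nm in frame.columns:
                samples[nm] = frame[nm].to_numpy()
        return cls(
            samples=samples,
            deviance=frame["deviance"].to_numpy(),
            latent_means={
                k: np.asarray(v) for k, v in meta["latent_means"].items()
            },
            accept_rates=meta["accept_rates"],
            config=McmcConfig(**meta["config"]),
            structure=ModelStructure(**meta["structure"]),
            priors=PriorSettings(**meta["priors"]),
            predictor_names=names,
        )

    def posterior_mean_state(self) -> ParameterState:
        """ParameterState at posterior means of coefficients and latents."""
        s = self.samples
        return ParameterState(
            u=s["u"].mean(axis=0),
            wg=s["wg"].mean(axis=0),
            w=float(s["w"].mean()),
            wr=float(s["wr"].mean()),
            v=float(s["v"].mean()),
            wz=float(s["wz"].mean()),
            b_x=float(s["b_x"].mean()),
            b_0=float(s["b_0"].mean()),
            z=self.latent_means["z"].copy(),
            x=self.latent_means["x"].copy(),
            e=self.latent_means["e"].copy(),
            precx=float(s["precx"].mean()) if "precx" in s else None,
            precxt=float(s["precxt"].mean()) if "precxt" in s else None,
            precy=float(s["precy"].mean()) if "precy" in s else None,
        )


def _sample_inverse_gaussian(rng, mu, lam):
    """Vectorised inverse-Gaussian(mu, lam) draws (Michael et al.)."""
    mu = np.asarray(mu, dtype=float)
    nu = rng.standard_normal(mu.shape)
    ysq = nu * nu
    x = mu + mu * mu * ysq / (2.0 * lam) - (
        mu / (2.0 * lam)
    ) * np.sqrt(4.0 * mu * lam * ysq + (mu * ysq) ** 2)
    x = np.maximum(x, 1e-300)
    u = rng.random(mu.shape)
    out = np.where(u <= mu / (mu + x), x, mu * mu / x)
    return out


def _bernoulli_loglik_terms(y, eta):
    return y * eta - np.logaddexp(0.0, eta)


class _Sampler:
    """One chain of the Gibbs-within-Metropolis sampler."""

    def __init__(self, data, structure, priors, config, rng):
        g, xt, y = data
        self.G = np.asarray(getattr(g, "values", g), dtype=float)
        self.names = list(getattr(g, "columns", range(self.G.shape[1])))
        self.xt = np.asarray(xt, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.n, self.p = self.G.shape
        self.structure = structure
        self.priors = priors
        self.cfg = config
        self.rng = rng

        self.precx = priors.precx
        self.precxt = priors.precxt
        self.precy = priors.precy
        self.sample_precisions = priors.precision_mode == "gamma"

        # state
        self.u = np.zeros(self.p)
        self.wg = np.zeros(self.p)
        self.w = 0.0
        self.wr = 0.0
        self.v = 0.0
        self.wz = 0.0
        self.b_x = 0.0
        self.b_0 = 0.0
        self.x = self.xt.copy()
        self.z = np.zeros(self.n)
        self.e = np.zeros(self.n)
        # The logistic layer is sampled with x centered at the mean
        # measurement (b_0 internal = reported b_0 + w * x_center): this
        # decorrelates w from the intercept.  Recorded samples are
        # converted back to the uncentered parametrization.
        self.x_center = float(self.xt.mean()) if config.use_likelihood else 0.0
        self._init_state()

        # Laplace scale-mixture variances for the linear block
        self.tau_u = np.ones(self.p)
        self.tau_v = 1.0
        self.tau_wr = 1.0

        # adaptive proposal scales for the logistic layer and e
        s0 = config.proposal_scale
        self.scale_b0 = s0
        self.scale_w = s0
        self.scale_wg = np.full(self.p, s0)
        self.scale_wz = s0
        self.scale_ridge = 0.5
        self.scale_e = 2.4 / np.sqrt(self.precy + 0.25)
        self._acc = {}
        self._tries = {}

        self.eta = self._full_eta()
        self._ll = _bernoulli_loglik_terms(self.y, self.eta)

    def _set_eta(self, eta, ll=None):
        self.eta = eta
        self._ll = _bernoulli_loglik_terms(self.y, eta) if ll is None else ll

    # ------------------------------------------------------------------
    def _init_state(self):
        """Overdispersed data-informed start: coefficients near zero,
        x at the measurement, latents from their priors."""
        rng, st = self.rng, self.structure
        if st.has_u:
            self.u = 0.2 * rng.standard_normal(self.p)
        if st.has_wg:
            self.wg = 0.2 * rng.standard_normal(self.p)
        if st.has_w:
            self.w = 0.2 * rng.standard_normal()
        if st.has_wr:
            self.wr = 0.5 * rng.standard_normal()
        if st.has_confounder:
            self.v = 0.5 * rng.standard_normal()
            self.wz = 0.5 * rng.standard_normal()
            self.z = rng.standard_normal(self.n)
        self.b_x = float(self.xt.mean() + rng.standard_normal())
        pbar = min(max(self.y.mean(), 1e-3), 1 - 1e-3)
        self.b_0 = float(np.log(pbar / (1 - pbar)) + 0.5 * rng.standard_normal())
        self.x = self.xt + rng.standard_normal(self.n) / np.sqrt(self.precxt)
        self.e = rng.standard_normal(self.n) / np.sqrt(max(self.precy, 1.0))

    def _full_eta(self):
        eta = self.b_0 + self.G @ self.wg + self.e
        if self.structure.has_w:
            eta = eta + self.w * (self.x - self.x_center)
        if self.structure.has_confounder:
            eta = eta + self.wz * self.z
        return eta

    # ------------------------------------------------------------------
    # linear-Gaussian block
    def _linear_block(self):
        st, cfg = self.structure, self.cfg
        cols = [np.ones(self.n)]
        prior_prec = [1.0 / self.priors.intercept_sd**2]
        tags = ["b_x"]
        if st.has_u:
            cols.append(self.G)
            if cfg.gaussian_coefficient_sd is not None:
                prior_prec.extend([1.0 / cfg.gaussian_coefficient_sd**2] * self.p)
            else:
                prior_prec.extend(1.0 / self.tau_u)
            tags.extend(["u"] * self.p)
        if st.has_confounder:
            cols.append(self.z[:, None])
            prior_prec.append(
                1.0 / cfg.gaussian_coefficient_sd**2
                if cfg.gaussian_coefficient_sd is not None
                else 1.0 / self.tau_v
            )
            tags.append("v")
        if st.has_wr:
            cols.append(self.y[:, None])
            prior_prec.append(
                1.0 / cfg.gaussian_coefficient_sd**2
                if cfg.gaussian_coefficient_sd is not None
                else 1.0 / self.tau_wr
            )
            tags.append("wr")
        X = np.column_stack(cols)
        d = np.asarray(prior_prec)
        if cfg.use_likelihood:
            A = self.precx * (X.T @ X) + np.diag(d)
            rhs = self.precx * (X.T @ self.x)
        else:
            A = np.diag(d)
            rhs = np.zeros(d.size)
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, rhs)
        beta = mean + np.linalg.solve(
            L.T, self.rng.standard_normal(d.size)
        )
        i = 0
        self.b_x = float(beta[i]); i += 1
        if st.has_u:
            self.u = beta[i : i + self.p].copy(); i += self.p
        if st.has_confounder:
            self.v = float(beta[i]); i += 1
        if st.has_wr:
            self.wr = float(beta[i]); i += 1

    def _update_taus(self):
        if self.cfg.gaussian_coefficient_sd is not None:
            return
        gam1, gam2 = self.priors.gam1, self.priors.gam2
        st = self.structure
        if st.has_u:
            mu = np.minimum(gam1 / np.maximum(np.abs(self.u), 1e-12), 1e8)
            self.tau_u = 1.0 / _sample_inverse_gaussian(self.rng, mu, gam1**2)
        if st.has_confounder:
            mu = min(gam2 / max(abs(self.v), 1e-12), 1e8)
            self.tau_v = float(
                1.0 / _sample_inverse_gaussian(self.rng, np.array(mu), gam2**2)
            )
        if st.has_wr:
            mu = min(gam1 / max(abs(self.wr), 1e-12), 1e8)
            self.tau_wr = float(
                1.0 / _sample_inverse_gaussian(self.rng, np.array(mu), gam1**2)
            )

    # ------------------------------------------------------------------
    # logistic layer
    def _laplace_lp(self, theta, gam):
        return -gam * abs(theta)

    def _mh_scalar(self, name, value, col, scale, gam=None, gaussian_sd=None):
        """One random-walk update of a logistic-layer coefficient."""
        prop = value + scale * self.rng.standard_normal()
        ll_new = None
        eta_new = None
        if self.cfg.use_likelihood and self.cfg.outcome_layer:
            eta_new = self.eta + (prop - value) * col
            ll_new = _bernoulli_loglik_terms(self.y, eta_new)
            d_ll = float(ll_new.sum() - self._ll.sum())
        else:
            d_ll = 0.0
        if gaussian_sd is not None:
            d_lp = -0.5 * (prop**2 - value**2) / gaussian_sd**2
        else:
            d_lp = self._laplace_lp(prop, gam) - self._laplace_lp(value, gam)
        self._tries[name] = self._tries.get(name, 0) + 1
        if np.log(self.rng.random()) < d_ll + d_lp:
            self._acc[name] = self._acc.get(name, 0) + 1
            if eta_new is not None:
                self._set_eta(eta_new, ll_new)
            return prop
        return value

    def _logistic_block(self):
        st, pr = self.structure, self.priors
        self.b_0 = self._mh_scalar(
            "b_0", self.b_0, 1.0, self.scale_b0, gaussian_sd=pr.intercept_sd
        )
        if st.has_w:
            self.w = self._mh_scalar(
                "w", self.w, self.x - self.x_center, self.scale_w, gam=pr.gam1
            )
        if st.has_wg:
            for j in range(self.p):
                new = self._mh_scalar(
                    f"wg{j}", self.wg[j], self.G[:, j], self.scale_wg[j], gam=pr.gam1
                )
                self.wg[j] = new
        if st.has_confounder:
            self.wz = self._mh_scalar(
                "wz", self.wz, self.z, self.scale_wz, gam=pr.gam2
            )
        if st.has_w and (st.has_wg or st.has_confounder):
            self._ridge_move()

    def _ridge_move(self):
        """Joint move along the near-flat likelihood ridge of causal
        models with pleiotropy/confounding.

        Because x ~= b_x + u.g + v z (+ wr y) up to a small residual,
        the direct link w is exchangeable with the indirect paths:
        w -> w + delta compensated by wg -> wg - delta u,
        wz -> wz - delta v and an intercept shift changes eta only by
        delta times the biomarker residual.  The move is a linear shear
        (unit Jacobian); acceptance is dominated by the priors, which is
        exactly what identifies the decomposition.
        """
        if not (self.cfg.use_likelihood and self.cfg.outcome_layer):
            return
        st, pr = self.structure, self.priors
        delta = self.scale_ridge * self.rng.standard_normal()
        resid = self.x - self.b_x
        if st.has_u and st.has_wg:
            resid = resid - self.G @ self.u
            wg_new = self.wg - delta * self.u
        else:
            wg_new = None
        if st.has_confounder:
            resid = resid - self.v * self.z
        eta_new = self.eta + delta * resid
        ll_new = _bernoulli_loglik_terms(self.y, eta_new)
        d_lp = -pr.gam1 * (abs(self.w + delta) - abs(self.w))
        if wg_new is not None:
            d_lp += -pr.gam1 * float(np.sum(np.abs(wg_new) - np.abs(self.wg)))
        if st.has_confounder:
            wz_new = self.wz - delta * self.v
            d_lp += -pr.gam2 * (abs(wz_new) - abs(self.wz))
        b0_new = self.b_0 - delta * (self.b_x - self.x_center)
        d_lp += -0.5 * (b0_new**2 - self.b_0**2) / pr.intercept_sd**2
        d_ll = float(ll_new.sum() - self._ll.sum())
        self._tries["ridge"] = self._tries.get("ridge", 0) + 1
        if np.log(self.rng.random()) < d_ll + d_lp:
            self._acc["ridge"] = self._acc.get("ridge", 0) + 1
            self.w += delta
            if wg_new is not None:
                self.wg = wg_new
            if st.has_confounder:
                self.wz = wz_new
            self.b_0 = b0_new
            self._set_eta(eta_new, ll_new)

    # ------------------------------------------------------------------
    # per-subject latents (vectorised across i)
    def _biomarker_mean(self):
        m = self.b_x + self.G @ self.u
        if self.structure.has_confounder:
            m = m + self.v * self.z
        if self.structure.has_wr:
            m = m + self.wr * self.y
        return m

    def _update_x(self):
        st = self.structure
        m = self._biomarker_mean()
        if not self.cfg.use_likelihood:
            self.x = m + self.rng.standard_normal(self.n) / np.sqrt(self.precx)
            return
        prec = self.precx + self.precxt
        mean = (self.precx * m + self.precxt * self.xt) / prec
        prop = mean + self.rng.standard_normal(self.n) / np.sqrt(prec)
        if st.has_w and self.cfg.outcome_layer:
            eta_new = self.eta + self.w * (prop - self.x)
            ll_new = _bernoulli_loglik_terms(self.y, eta_new)
            acc = np.log(self.rng.random(self.n)) < ll_new - self._ll
            self.x = np.where(acc, prop, self.x)
            self._set_eta(np.where(acc, eta_new, self.eta),
                          np.where(acc, ll_new, self._ll))
            self._track("x", acc)
        else:
            self.x = prop

    def _update_z(self):
        if not self.structure.has_confounder:
            return
        r = self.x - self.b_x - self.G @ self.u
        if self.structure.has_wr:
            r = r - self.wr * self.y
        lik_prec = self.v**2 * self.precx if self.cfg.use_likelihood else 0.0
        prec = self.priors.precz + lik_prec
        mean = (self.v * self.precx * r) / prec if self.cfg.use_likelihood else 0.0
        prop = mean + self.rng.standard_normal(self.n) / np.sqrt(prec)
        if self.cfg.use_likelihood and self.cfg.outcome_layer:
            eta_new = self.eta + self.wz * (prop - self.z)
            ll_new = _bernoulli_loglik_terms(self.y, eta_new)
            acc = np.log(self.rng.random(self.n)) < ll_new - self._ll
            self.z = np.where(acc, prop, self.z)
            self._set_eta(np.where(acc, eta_new, self.eta),
                          np.where(acc, ll_new, self._ll))
            self._track("z", acc)
        else:
            self.z = prop

    def _update_e(self):
        if not (self.cfg.use_likelihood and self.cfg.outcome_layer):
            self.e = self.rng.standard_normal(self.n) / np.sqrt(self.precy)
            return
        prop = self.e + self.scale_e * self.rng.standard_normal(self.n)
        eta_new = self.eta + (prop - self.e)
        ll_new = _bernoulli_loglik_terms(self.y, eta_new)
        logr = ll_new - self._ll - 0.5 * self.precy * (prop**2 - self.e**2)
        acc = np.log(self.rng.random(self.n)) < logr
        self.e = np.where(acc, prop, self.e)
        self._set_eta(np.where(acc, eta_new, self.eta),
                      np.where(acc, ll_new, self._ll))
        self._track("e", acc)

    def _track(self, name, acc_mask):
        self._acc[name] = self._acc.get(name, 0) + int(acc_mask.sum())
        self._tries[name] = self._tries.get(name, 0) + acc_mask.size

    # ------------------------------------------------------------------
    def _update_precisions(self):
        if not (self.sample_precisions and self.cfg.use_likelihood):
            return
        a0, b0 = self.priors.gamma_shape, self.priors.gamma_rate
        rng = self.rng
        ss_x = float(np.sum((self.x - self._biomarker_mean()) ** 2))
        self.precx = rng.gamma(a0 + 0.5 * self.n, 1.0 / (b0 + 0.5 * ss_x))
        ss_xt = float(np.sum((self.xt - self.x) ** 2))
        self.precxt = rng.gamma(a0 + 0.5 * self.n, 1.0 / (b0 + 0.5 * ss_xt))
        ss_e = float(np.sum(self.e**2))
        self.precy = rng.gamma(a0 + 0.5 * self.n, 1.0 / (b0 + 0.5 * ss_e))

    def _adapt(self, it):
        if not self.cfg.adapt or it >= self.cfg.burn_in or it == 0 or it % 50:
            return
        step = min(0.5, 5.0 / np.sqrt(it))

        def tune(scale, name):
            tries = self._tries.get(name, 0)
            if not tries:
                return scale
            rate = self._acc.get(name, 0) / tries
            return float(scale * np.exp(step * (rate - 0.44)))

        self.scale_b0 = tune(self.scale_b0, "b_0")
        self.scale_w = tune(self.scale_w, "w")
        self.scale_wz = tune(self.scale_wz, "wz")
        self.scale_ridge = tune(self.scale_ridge, "ridge")
        self.scale_e = tune(self.scale_e, "e")
        for j in range(self.p):
            self.scale_wg[j] = tune(self.scale_wg[j], f"wg{j}")
        self._acc.clear()
        self._tries.clear()

    # ------------------------------------------------------------------
    def _deviance(self):
        ll = 0.5 * self.n * (np.log(self.precxt) - np.log(2 * np.pi)) - \
            0.5 * self.precxt * float(np.sum((self.xt - self.x) ** 2))
        if self.cfg.outcome_layer:
            ll += float(self._ll.sum())
        return -2.0 * ll

    def run(self) -> Trace:
        cfg = self.cfg
        n_keep = (cfg.n_iterations - cfg.burn_in) // cfg.thin
        S = {
            "u": np.empty((n_keep, self.p)),
            "wg": np.empty((n_keep, self.p)),
            "w": np.empty(n_keep),
            "wr": np.empty(n_keep),
            "v": np.empty(n_keep),
            "wz": np.empty(n_keep),
            "b_x": np.empty(n_keep),
            "b_0": np.empty(n_keep),
        }
        if self.sample_precisions:
            for nm in ("precx", "precxt", "precy"):
                S[nm] = np.empty(n_keep)
        dev = np.empty(n_keep)
        lat_sum = {k: np.zeros(self.n) for k in ("x", "z", "e")}
        lat_store = (
            {k: np.empty((n_keep, self.n)) for k in ("x", "z", "e")}
            if cfg.store_latents
            else {}
        )

        k = 0
        for it in range(cfg.n_iterations):
            self._linear_block()
            self._update_taus()
            if cfg.outcome_layer:
                self._logistic_block()
            self._update_x()
            self._update_z()
            self._update_e()
            self._update_precisions()
            if cfg.outcome_layer:
                self._set_eta(self._full_eta())  # guard against FP drift
            self._adapt(it)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and k < n_keep:
                d = self._deviance()
                if not np.isfinite(d):
                    raise RuntimeError(
                        f"divergent chain: non-finite deviance at iteration {it}"
                    )
                dev[k] = d
                for nm in ("w", "wr", "v", "wz", "b_x"):
                    S[nm][k] = getattr(self, nm)
                S["b_0"][k] = self.b_0 - self.w * self.x_center
                S["u"][k] = self.u
                S["wg"][k] = self.wg
                if self.sample_precisions:
                    S["precx"][k] = self.precx
                    S["precxt"][k] = self.precxt
                    S["precy"][k] = self.precy
                for nm in ("x", "z", "e"):
                    lat_sum[nm] += getattr(self, nm)
                    if cfg.store_latents:
                        lat_store[nm][k] = getattr(self, nm)
                k += 1

        lat_mean = {nm: lat_sum[nm] / max(k, 1) for nm in lat_sum}
        rates = {
            nm: self._acc.get(nm, 0) / t
            for nm, t in self._tries.items()
            if t
        }
        for nm, r in rates.items():
            # x and z use independence proposals from their exact Gaussian
            # conditional parts: acceptance near 1 is ideal there, so only
            # the lower bound applies.
            upper = 2.0 if nm in ("x", "z") else 0.95
            if not 0.05 <= r <= upper:
                warnings.warn(
                    f"acceptance rate for {nm} is {r:.3f} after burn-in",
                    stacklevel=3,
                )

        trace = Trace(
            samples=S,
            deviance=dev[:k],
            latent_means=lat_mean,
            accept_rates=rates,
            config=cfg,
            structure=self.structure,
            priors=self.priors,
            predictor_names=self.names,
            latent_samples=lat_store,
        )
        if cfg.align_confounder_sign and self.structure.has_confounder:
            _align_sign(trace)
        return trace


def _align_sign(trace: Trace) -> None:
    """Resolve the (v, wz, z) -> (-v, -wz, -z) reflection by flipping the
    whole chain so the posterior mean of v is non-negative."""
    if trace.samples["v"].size and trace.samples["v"].mean() < 0:
        trace.samples["v"] *= -1.0
        trace.samples["wz"] *= -1.0
        trace.latent_means["z"] *= -1.0
        if "z" in trace.latent_samples:
            trace.latent_samples["z"] *= -1.0


def run_chain(data, structure: ModelStructure, priors: PriorSettings,
              config: McmcConfig) -> Trace:
    """Run a single MCMC chain and return its Trace.

    ``data`` is ``(g, xt, y)`` (g may be a PredictorMatrix) or a
    ``ModelData``.  Reproducible bit-exactly from ``config.seed``.
    """
    data = _as_tuple(data)
    rng = np.random.default_rng(config.seed)
    return _Sampler(data, structure, priors, config, rng).run()


def sample_posterior(data, structure, priors, config: McmcConfig) -> list[Trace]:
    """Run ``config.n_chains`` chains with seeds spawned from config.seed."""
    data = _as_tuple(data)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_chains)
    traces = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(int(seeds[c]))
        cfg = config
        traces.append(_Sampler(data, structure, priors, cfg, rng).run())
    return traces


def _as_tuple(data):
    if hasattr(data, "g") and hasattr(data, "xt"):
        return (data.g, data.xt, data.y)
    return data


# ---------------------------------------------------------------------------
# summaries and diagnostics

def _scalar_series(trace: Trace) -> dict:
    """Flatten a trace into named scalar sample series."""
    out = {}
    names = trace.predictor_names
    for j in range(trace.samples["u"].shape[1]):
        nm = names[j] if j < len(names) else j
        out[f"u[{nm}]"] = trace.samples["u"][:, j]
        out[f"wg[{nm}]"] = trace.samples["wg"][:, j]
    for nm in ("w", "wr", "v", "wz", "b_x", "b_0", "precx", "precxt", "precy"):
        if nm in trace.samples:
            out[nm] = trace.samples[nm]
    return out


def _active_params(trace: Trace) -> list:
    st = trace.structure
    keep = ["b_x", "b_0"]
    names = trace.predictor_names
    if st.has_u:
        keep += [f"u[{nm}]" for nm in names]
    if st.has_wg:
        keep += [f"wg[{nm}]" for nm in names]
    if st.has_w:
        keep.append("w")
    if st.has_wr:
        keep.append("wr")
    if st.has_confounder:
        keep += ["v", "wz"]
    for nm in ("precx", "precxt", "precy"):
        if nm in trace.samples:
            keep.append(nm)
    return keep


def posterior_summary(traces) -> pd.DataFrame:
    """Pooled posterior summaries (mean, sd, 2.5/50/97.5 percentiles).

    Accepts one Trace or a list of Traces (chains pooled after burn-in).
    """
    if isinstance(traces, Trace):
        traces = [traces]
    if not traces or traces[0].n_samples == 0:
        raise ValueError("empty trace")
    keep = _active_params(traces[0])
    series = {}
    for t in traces:
        for nm, vals in _scalar_series(t).items():
            if nm in keep:
                series.setdefault(nm, []).append(vals)
    rows = []
    for nm in keep:
        pooled = np.concatenate(series[nm])
        q = np.percentile(pooled, [2.5, 50.0, 97.5])
        rows.append(
            dict(parameter=nm, mean=pooled.mean(), sd=pooled.std(ddof=1),
                 q2_5=q[0], median=q[1], q97_5=q[2])
        )
    return pd.DataFrame(rows).set_index("parameter")


def potential_scale_reduction(chains: np.ndarray, split: bool = True) -> float:
    """Classic (split-chain) potential scale reduction R-hat.

    ``chains`` is (n_chains, n_draws).  Chains are split in half by
    default; identical within-half behaviour across chains gives 1.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if split:
        half = chains.shape[1] // 2
        chains = np.vstack([chains[:, :half], chains[:, half : 2 * half]])
    m, n = chains.shape
    if n < 2:
        return np.nan
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    B_over_n = means.var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B_over_n
    # floored at 1: values below 1 are estimation noise, not evidence
    return float(max(1.0, np.sqrt(var_plus / W)))


def effective_sample_size(chains: np.ndarray) -> float:
    """ESS from autocorrelations with Geyer's initial monotone sequence."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if n < 4:
        return float(m * n)
    acov = np.zeros(n)
    for c in range(m):
        x = chains[c] - chains[c].mean()
        f = np.fft.rfft(x, 2 * n)
        ac = np.fft.irfft(f * np.conj(f))[:n] / n
        acov += ac / m
    if acov[0] == 0:
        return float(m * n)
    rho = acov / acov[0]
    # Geyer: sum pairs rho[2k]+rho[2k+1] while positive and non-increasing
    pair_sums = []
    k = 1
    while k + 1 < n:
        s = rho[k] + rho[k + 1]
        if s <= 0:
            break
        pair_sums.append(s)
        k += 2
    # enforce monotone non-increasing
    for i in range(1, len(pair_sums)):
        pair_sums[i] = min(pair_sums[i], pair_sums[i - 1])
    tau = 1.0 + 2.0 * sum(pair_sums)
    return float(m * n / max(tau, 1e-12))


@dataclass
class DiagnosticsReport:
    table: pd.DataFrame
    dbar_per_chain: list
    warnings: list

    def __str__(self):
        lines = [self.table.to_string()]
        lines.append(f"Dbar per chain: {np.round(self.dbar_per_chain, 2)}")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)


def diagnose(traces) -> DiagnosticsReport:
    """Per-parameter ESS and split-chain R-hat, plus per-chain Dbar."""
    if isinstance(traces, Trace):
        traces = [traces]
    if not traces:
        raise ValueError("need at least one trace")
    keep = _active_params(traces[0])
    per_chain = [_scalar_series(t) for t in traces]
    notes = []
    if len(traces) == 1:
        notes.append("single chain: R-hat uses split halves only")
    if traces[0].n_samples < 100:
        notes.append("short chain: diagnostics are unreliable")
    rows = []
    for nm in keep:
        arr = np.vstack([pc[nm] for pc in per_chain])
        rhat = potential_scale_reduction(arr)
        ess = effective_sample_size(arr)
        if np.isfinite(rhat) and rhat > 1.1:
            notes.append(f"{nm}: R-hat {rhat:.3f} > 1.1")
        rows.append(dict(parameter=nm, ess=ess, rhat=rhat))
    table = pd.DataFrame(rows).set_index("parameter")
    return DiagnosticsReport(table, [t.dbar for t in traces], notes)
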