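"""Nonlinear mixed-effects estimation of the bi-exponential growth model.

Lesion-level parameters carry lognormal / logit-normal random effects,

    ln Kg_j    = ln theta_Kg  + eta_Kg_j
    ln Kd_j    = ln theta_Kd  + eta_Kd_j
    logit F_j  = logit theta_F + eta_F_j,      eta ~ N(0, diag(omega^2)),

observations carry proportional error y = f (1 + eps), eps ~ N(0, sigma^2),
and volumes below the quantification limit enter the likelihood through
their censored probability Phi((LOQ - f) / (sigma f)) — the M3 method.
Baseline volume V0 is a lesion-level nuisance with a weak lognormal prior
centred at the first observed volume (optionally pinned to it).

Estimation is stochastic-approximation EM (SAEM): a Metropolis kernel
refreshes the latent lesion parameters, sufficient statistics are averaged
with a decreasing gain, and the residual SD is updated by a one-dimensional
numeric M-step (the censored terms break the closed form).  A Laplace
evaluator provides the marginal log-likelihood independently of the SAEM
path, and empirical-Bayes modes give per-lesion parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit, log_ndtr, logit
from sklearn.base import BaseEstimator

from .growth import GrowthParams

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationEstimate",
    "EstimationError",
    "lesion_loglik",
    "fit_population",
    "empirical_bayes",
    "TumorGrowthMixedModel",
]

_LOG_2PI = math.log(2.0 * math.pi)
_OMEGA_FLOOR = 1e-3
_SIGMA_FLOOR = 1e-4
_EXP_CAP = 500.0


class EstimationError(RuntimeError):
    """Population fit could not be carried out on the given data."""


@dataclass
class PopulationEstimate:
    """Population-level estimate: typical values, random-effect SDs, error SD."""

    theta_kg: float = 0.01  # 1/day (also the conventional initial value)
    theta_kd: float = 0.01  # 1/day
    theta_f: float = 0.1  # fraction
    omega: tuple = (0.5, 0.5, 0.5)  # SDs of eta on (ln Kg, ln Kd, logit F)
    sigma: float = 0.3  # proportional error SD
    loglik: float = float("nan")
    convergence: dict = field(default_factory=dict)

    def mu(self) -> np.ndarray:
        return np.array([math.log(self.theta_kg), math.log(self.theta_kd), logit(self.theta_f)])

    def validate(self) -> None:
        if not (self.theta_kg > 0 and self.theta_kd > 0 and 0 < self.theta_f < 1):
            raise ValueError("theta out of domain")
        if any(w < 0 for w in self.omega) or self.sigma < 0:
            raise ValueError("omega and sigma must be non-negative")


# ---------------------------------------------------------------------------
# data marshalling


@dataclass
class _LesionData:
    """Flattened observation arrays sorted by (patient_id, lesion_id, time)."""

    lesion_ids: np.ndarray  # (J,)
    patient_ids: np.ndarray  # (J,)
    starts: np.ndarray  # (J,) offsets into the obs arrays
    t: np.ndarray  # (N,)
    y: np.ndarray  # (N,) NaN where censored
    cens: np.ndarray  # (N,) bool
    m0: np.ndarray  # (J,) prior centre for ln V0
    n_obs: np.ndarray  # (J,)


def _prepare(measurements: pd.DataFrame, loq: float) -> tuple[_LesionData, int]:
    df = measurements[measurements["lesion_class"] == "target"].copy()
    df = df.sort_values(["patient_id", "lesion_id", "time"], kind="mergesort")
    usable = df["volume"].notna() | df["below_loq"]
    df = df[usable]
    if df.empty:
        raise EstimationError("no usable target observations")
    grp = df.groupby(["patient_id", "lesion_id"], sort=True)
    all_blq = grp["below_loq"].transform("all")
    n_excluded = df.loc[all_blq, ["patient_id", "lesion_id"]].drop_duplicates().shape[0]
    if n_excluded:
        logger.info("excluding %d lesions with all measurements below LOQ", n_excluded)
    df = df[~all_blq]
    if df.empty:
        raise EstimationError("all lesions fully below LOQ; nothing to fit")

    keys = df[["patient_id", "lesion_id"]].drop_duplicates()
    sizes = df.groupby(["patient_id", "lesion_id"], sort=True).size()
    starts = np.concatenate([[0], np.cumsum(sizes.to_numpy())[:-1]])
    first_quant = (
        df[~df["below_loq"]].groupby(["patient_id", "lesion_id"], sort=True)["volume"].first()
    )
    m0 = np.log(np.maximum(first_quant.reindex(sizes.index).fillna(loq / 2.0).to_numpy(), 1e-3))
    data = _LesionData(
        lesion_ids=keys["lesion_id"].to_numpy(),
        patient_ids=keys["patient_id"].to_numpy(),
        starts=starts,
        t=df["time"].to_numpy(float),
        y=df["volume"].to_numpy(float),
        cens=df["below_loq"].to_numpy(bool),
        m0=m0,
        n_obs=sizes.to_numpy(),
    )
    return data, n_excluded


# ---------------------------------------------------------------------------
# likelihood kernels (vectorized over lesions)


def _predict_f(x: np.ndarray, t: np.ndarray, obs2les: np.ndarray) -> np.ndarray:
    """Model prediction per observation for latent matrix x = (J, 4)."""
    kg = np.exp(x[obs2les, 0])
    kd = np.exp(x[obs2les, 1])
    f = expit(x[obs2les, 2])
    v0 = np.exp(np.clip(x[obs2les, 3], -20.0, 30.0))
    grow = np.exp(np.clip(kg * t, -_EXP_CAP, _EXP_CAP))
    decay = np.exp(np.clip(-kd * t, -_EXP_CAP, _EXP_CAP))
    return v0 * (f * grow + (1.0 - f) * decay)


def _obs_loglik_terms(fpred, y, cens, sigma, loq):
    """Per-observation log-likelihood: proportional-error normal + M3 censored."""
    sf = np.maximum(sigma * fpred, 1e-300)
    out = np.empty_like(fpred)
    unc = ~cens
    out[unc] = -0.5 * _LOG_2PI - np.log(sf[unc]) - 0.5 * ((y[unc] - fpred[unc]) / sf[unc]) ** 2
    if cens.any():
        out[cens] = log_ndtr((loq - fpred[cens]) / sf[cens])
    return out


def _complete_loglik(x, data: _LesionData, obs2les, mu, omega, sigma, loq, tau, pin_v0):
    """Per-lesion complete-data log-likelihood (obs terms + latent priors)."""
    fpred = _predict_f(x, data.t, obs2les)
    terms = _obs_loglik_terms(fpred, data.y, data.cens, sigma, loq)
    ll = np.add.reduceat(terms, data.starts)
    om = np.maximum(omega, _OMEGA_FLOOR)
    pri = -0.5 * _LOG_2PI * 3 - np.sum(np.log(om)) - 0.5 * np.sum(
        ((x[:, :3] - mu) / om) ** 2, axis=1
    )
    if not pin_v0:
        pri = pri - 0.5 * _LOG_2PI - math.log(tau) - 0.5 * ((x[:, 3] - data.m0) / tau) ** 2
    return ll + pri


def lesion_loglik(
    pop: PopulationEstimate,
    etas,
    lesion_data: pd.DataFrame,
    loq: float = 200.0,
    v0: float | None = None,
) -> float:
    """Joint log-density of one lesion's observations and its random effects.

    Uncensored rows contribute a normal density with mean f = V(t) and SD
    sigma*f; below-LOQ rows contribute log Phi((loq - f)/(sigma*f)); the
    eta vector contributes its N(0, diag(omega^2)) log-density.  ``v0``
    defaults to the first quantified volume of the lesion.
    """
    pop.validate()
    etas = np.asarray(etas, float)
    df = lesion_data.sort_values("time")
    y = df["volume"].to_numpy(float)
    cens = df["below_loq"].to_numpy(bool) if "below_loq" in df else np.zeros(len(df), bool)
    if pop.sigma == 0 and cens.any():
        raise ValueError("sigma = 0 makes censored probabilities degenerate")
    if v0 is None:
        quant = y[~cens]
        v0 = float(quant[0]) if len(quant) else loq / 2.0
    mu = pop.mu()
    x = np.array([[mu[0] + etas[0], mu[1] + etas[1], mu[2] + etas[2], math.log(v0)]])
    fpred = _predict_f(x, df["time"].to_numpy(float), np.zeros(len(df), int))
    terms = _obs_loglik_terms(fpred, y, cens, max(pop.sigma, _SIGMA_FLOOR), loq)
    om = np.maximum(np.asarray(pop.omega, float), _OMEGA_FLOOR)
    prior = float(np.sum(-0.5 * _LOG_2PI - np.log(om) - 0.5 * (etas / om) ** 2))
    return float(np.sum(terms) + prior)


# ---------------------------------------------------------------------------
# empirical-Bayes modes and Laplace marginal likelihood


def _eb_grad(x, data, obs2les, mu, omega, sigma, loq, tau, pin_v0):
    """Analytic gradient of the complete-data log-likelihood wrt x (J, 4)."""
    t, y, cens = data.t, data.y, data.cens
    kg = np.exp(x[obs2les, 0])
    kd = np.exp(x[obs2les, 1])
    fr = expit(x[obs2les, 2])
    v0 = np.exp(np.clip(x[obs2les, 3], -20.0, 30.0))
    a = np.exp(np.clip(kg * t, -_EXP_CAP, _EXP_CAP))
    b = np.exp(np.clip(-kd * t, -_EXP_CAP, _EXP_CAP))
    f = v0 * (fr * a + (1 - fr) * b)
    sf = np.maximum(sigma * f, 1e-300)

    dL_df = np.empty_like(f)
    unc = ~cens
    r = y[unc] / f[unc] - 1.0
    dL_df[unc] = -1.0 / f[unc] + r * y[unc] / (sigma**2 * f[unc] ** 2)
    if cens.any():
        z = (loq - f[cens]) / sf[cens]
        lpdf = -0.5 * _LOG_2PI - 0.5 * z**2
        ratio = np.exp(lpdf - log_ndtr(z))
        dL_df[cens] = ratio * (-loq / (sigma * f[cens] ** 2))

    df_dx = np.stack(
        [
            v0 * fr * a * t * kg,
            -v0 * (1 - fr) * b * t * kd,
            v0 * (a - b) * fr * (1 - fr),
            f,
        ],
        axis=1,
    )
    g_obs = dL_df[:, None] * df_dx
    g = np.add.reduceat(g_obs, data.starts, axis=0)
    om = np.maximum(omega, _OMEGA_FLOOR)
    g[:, :3] -= (x[:, :3] - mu) / om**2
    if pin_v0:
        g[:, 3] = 0.0
    else:
        g[:, 3] -= (x[:, 3] - data.m0) / tau**2
    return g


def _eb_hessian(x, args, dims):
    """Batched 4x4 Hessians by central differences of the analytic gradient."""
    h = 1e-4
    H = np.zeros((x.shape[0], 4, 4))
    for k in range(dims):
        dx = np.zeros_like(x)
        dx[:, k] = h
        H[:, :, k] = (_eb_grad(x + dx, *args) - _eb_grad(x - dx, *args)) / (2 * h)
    H = 0.5 * (H + np.transpose(H, (0, 2, 1)))
    if dims == 3:  # pinned V0: decouple the fourth coordinate
        H[:, 3, :], H[:, :, 3] = 0.0, 0.0
        H[:, 3, 3] = -1.0
    return H


def _eb_modes(x0, data, obs2les, mu, omega, sigma, loq, tau, pin_v0, max_iter=100):
    """Vectorized Levenberg-Marquardt ascent to per-lesion posterior modes.

    Solves (-H + lam I) step = g per lesion with per-lesion adaptive
    damping, so progress is guaranteed even far from the mode where the
    complete-data log-likelihood is not concave.
    """
    x = x0.copy()
    args = (data, obs2les, mu, omega, sigma, loq, tau, pin_v0)
    ll = _complete_loglik(x, *args)
    dims = 3 if pin_v0 else 4
    J = x.shape[0]
    lam = np.full(J, 1e-3)
    eye = np.eye(4)
    for _ in range(max_iter):
        g = _eb_grad(x, *args)
        if np.max(np.abs(g[:, :dims])) < 1e-6:
            break
        H = _eb_hessian(x, args, dims)
        active = np.ones(J, bool)
        for _ in range(10):
            A = -H[active] + lam[active, None, None] * eye
            try:
                step = np.linalg.solve(A, g[active, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                step = g[active] / (1.0 + lam[active, None])
            bad = ~np.isfinite(step).all(axis=1)
            step[bad] = g[active][bad] / (1.0 + lam[active][bad, None])
            trial = x.copy()
            trial[active] = x[active] + np.clip(step, -3.0, 3.0)
            ll_t = _complete_loglik(trial, *args)
            gain = np.isfinite(ll_t) & (ll_t > ll)
            upd = active & gain
            x[upd] = trial[upd]
            ll = np.where(upd, ll_t, ll)
            lam = np.where(upd, np.maximum(lam * 0.3, 1e-6), lam)
            lam = np.where(active & ~gain, np.minimum(lam * 8.0, 1e10), lam)
            active = active & ~gain
            if not active.any():
                break
    return x, ll, args


def _laplace_loglik(x_modes, ll_modes, args, pin_v0):
    """Marginal log-likelihood by a per-lesion Laplace approximation."""
    data, obs2les = args[0], args[1]
    dims = 3 if pin_v0 else 4
    h = 1e-4
    H = np.zeros((x_modes.shape[0], dims, dims))
    for k in range(dims):
        dx = np.zeros_like(x_modes)
        dx[:, k] = h
        gk = (_eb_grad(x_modes + dx, *args) - _eb_grad(x_modes - dx, *args)) / (2 * h)
        H[:, :, k] = gk[:, :dims]
    H = 0.5 * (H + np.transpose(H, (0, 2, 1)))
    sign, logdet = np.linalg.slogdet(-H)
    logdet = np.where(sign > 0, logdet, np.inf)  # non-concave mode: drop via -inf contribution guard
    contrib = ll_modes + 0.5 * dims * _LOG_2PI - 0.5 * logdet
    return float(np.sum(np.where(np.isfinite(contrib), contrib, ll_modes)))


# ---------------------------------------------------------------------------
# SAEM


class TumorGrowthMixedModel(BaseEstimator):
    """SAEM estimator for the population growth model (sklearn-style).

    Parameters
    ----------
    loq : float
        Quantification limit (mm^3) for the M3 censored likelihood.
    n_explore, n_smooth : int
        SAEM exploratory (gain 1) and smoothing (decreasing gain) iterations.
    n_chains : int
        Parallel Metropolis chains averaged in the stochastic E-step.
    seed : int
        RNG seed; fits are deterministic given data and seed.
    pin_v0 : bool
        Pin each lesion's V0 to its first quantified volume instead of
        estimating it under a weak prior.
    v0_prior_sd : float
        SD (log scale) of the weak V0 prior.
    init : PopulationEstimate, optional
        Starting values; defaults to the conventional Kg=Kd=0.01/day, F=0.1.
    compute_loglik : bool
        Evaluate the Laplace marginal log-likelihood after fitting.

    Attributes
    ----------
    theta_kg_, theta_kd_, theta_f_, omega_, sigma_ : fitted population values
    loglik_ : Laplace marginal log-likelihood (NaN unless requested)
    lesion_params_ : DataFrame of empirical-Bayes lesion parameters
    convergence_ : dict of diagnostics
    """

    def __init__(
        self,
        loq: float = 200.0,
        n_explore: int = 300,
        n_smooth: int = 200,
        n_chains: int = 2,
        seed: int = 0,
        pin_v0: bool = False,
        v0_prior_sd: float = 1.0,
        init: PopulationEstimate | None = None,
        compute_loglik: bool = True,
    ):
        self.loq = loq
        self.n_explore = n_explore
        self.n_smooth = n_smooth
        self.n_chains = n_chains
        self.seed = seed
        self.pin_v0 = pin_v0
        self.v0_prior_sd = v0_prior_sd
        self.init = init
        self.compute_loglik = compute_loglik

    # -- core ---------------------------------------------------------------

    def fit(self, measurements: pd.DataFrame, y=None):
        init = self.init or PopulationEstimate()
        init.validate()
        data, n_excluded = _prepare(measurements, self.loq)
        J = len(data.lesion_ids)
        rich = int(np.sum(data.n_obs >= 3))
        if rich < 50:
            logger.warning("only %d lesions with >= 3 observations; estimates may be unstable", rich)
        obs2les = np.repeat(np.arange(J), data.n_obs)
        rng = np.random.default_rng(self.seed)
        tau = self.v0_prior_sd

        mu = init.mu()
        omega = np.asarray(init.omega, float).copy()
        sigma = float(init.sigma)
        if sigma <= 0 and data.cens.any():
            raise EstimationError("initial sigma = 0 with censored rows present")

        x = np.tile(np.concatenate([mu, [0.0]]), (self.n_chains, J, 1))
        x[:, :, 3] = data.m0
        x += 0.1 * rng.standard_normal(x.shape)
        if self.pin_v0:
            x[:, :, 3] = data.m0

        ll0 = _complete_loglik(x[0], data, obs2les, mu, omega, sigma, self.loq, tau, self.pin_v0)
        if not np.isfinite(ll0).all():
            raise EstimationError(
                f"non-finite likelihood at initial values theta=({init.theta_kg}, "
                f"{init.theta_kd}, {init.theta_f}), sigma={sigma}"
            )

        steps = np.full(4, 0.4)
        dims = 3 if self.pin_v0 else 4
        s1 = np.zeros(3)
        s2 = np.zeros(3)
        sig2_acc = sigma**2
        ll_cur = np.stack(
            [
                _complete_loglik(x[c], data, obs2les, mu, omega, sigma, self.loq, tau, self.pin_v0)
                for c in range(self.n_chains)
            ]
        )
        n_iter = self.n_explore + self.n_smooth
        acc_hist = np.zeros(4)
        for it in range(1, n_iter + 1):
            gamma = 1.0 if it <= self.n_explore else 1.0 / (it - self.n_explore)
            # --- stochastic E-step: coordinate Metropolis over chains ------
            for c in range(self.n_chains):
                for k in range(dims):
                    prop = x[c].copy()
                    prop[:, k] += steps[k] * rng.standard_normal(J)
                    ll_prop = _complete_loglik(
                        prop, data, obs2les, mu, omega, sigma, self.loq, tau, self.pin_v0
                    )
                    accept = np.log(rng.random(J)) < (ll_prop - ll_cur[c])
                    x[c][accept] = prop[accept]
                    ll_cur[c] = np.where(accept, ll_prop, ll_cur[c])
                    rate = accept.mean()
                    acc_hist[k] = 0.9 * acc_hist[k] + 0.1 * rate
                    if it <= self.n_explore:
                        steps[k] *= math.exp(0.999 ** it * (rate - 0.35))
                        steps[k] = min(max(steps[k], 1e-3), 3.0)

            # --- sufficient statistics with stochastic averaging -----------
            phi = x[:, :, :3].reshape(-1, 3)
            S1 = phi.mean(axis=0) * J  # sum over lesions, averaged over chains
            S2 = (phi**2).mean(axis=0) * J
            s1 = s1 + gamma * (S1 - s1)
            s2 = s2 + gamma * (S2 - s2)
            mu = s1 / J
            omega = np.sqrt(np.maximum(s2 / J - mu**2, _OMEGA_FLOOR**2))

            # --- sigma: 1-d numeric M-step on the pooled chains ------------
            fpool = np.concatenate([_predict_f(x[c], data.t, obs2les) for c in range(self.n_chains)])
            ypool = np.tile(data.y, self.n_chains)
            cpool = np.tile(data.cens, self.n_chains)
            unc = ~cpool
            if cpool.any():
                res2 = ((ypool[unc] - fpool[unc]) / fpool[unc]) ** 2

                def _neg(sig):
                    sig = max(sig, _SIGMA_FLOOR)
                    val = -len(res2) * math.log(sig) - res2.sum() / (2 * sig**2)
                    z = (self.loq - fpool[cpool]) / (sig * fpool[cpool])
                    return -(val + log_ndtr(z).sum())

                sig_hat = minimize_scalar(_neg, bounds=(1e-3, 2.0), method="bounded").x
            else:
                sig_hat = math.sqrt(np.mean(((ypool[unc] - fpool[unc]) / fpool[unc]) ** 2))
            sig2_acc = sig2_acc + gamma * (sig_hat**2 - sig2_acc)
            sigma = max(math.sqrt(sig2_acc), _SIGMA_FLOOR)
            # likelihood cache is stale after parameter updates
            for c in range(self.n_chains):
                ll_cur[c] = _complete_loglik(
                    x[c], data, obs2les, mu, omega, sigma, self.loq, tau, self.pin_v0
                )

        self.theta_kg_ = float(np.exp(mu[0]))
        self.theta_kd_ = float(np.exp(mu[1]))
        self.theta_f_ = float(expit(mu[2]))
        self.omega_ = tuple(float(w) for w in omega)
        self.sigma_ = float(sigma)
        self._data = data
        self._obs2les = obs2les
        self._mu = mu
        self._tau = tau
        self.convergence_ = {
            "n_iter": n_iter,
            "n_lesions": J,
            "n_obs": len(data.t),
            "n_excluded_all_blq": n_excluded,
            "acceptance": acc_hist.round(3).tolist(),
            "steps": steps.round(4).tolist(),
        }

        # empirical-Bayes modes from the warm chain state
        x_warm = x.mean(axis=0)
        modes, ll_modes, args = _eb_modes(
            x_warm, data, obs2les, mu, omega, sigma, self.loq, tau, self.pin_v0
        )
        self._modes = modes
        self._mode_args = args
        self.lesion_params_ = self._modes_frame(modes, omega)
        self.loglik_ = (
            _laplace_loglik(modes, ll_modes, args, self.pin_v0) if self.compute_loglik else float("nan")
        )
        return self

    def _modes_frame(self, modes, omega):
        data = self._data
        post_sd = self._posterior_sds(modes)
        om = np.maximum(np.asarray(omega), _OMEGA_FLOOR)
        shrink = np.clip(1.0 - (post_sd[:, :3] ** 2) / om**2, 0.0, 1.0).mean(axis=1)
        full = data.n_obs <= 1
        return pd.DataFrame(
            {
                "patient_id": data.patient_ids,
                "lesion_id": data.lesion_ids,
                "v0": np.exp(modes[:, 3]),
                "f": expit(modes[:, 2]),
                "kg": np.exp(modes[:, 0]),
                "kd": np.exp(modes[:, 1]),
                "eta_kg": modes[:, 0] - self._mu[0],
                "eta_kd": modes[:, 1] - self._mu[1],
                "eta_f": modes[:, 2] - self._mu[2],
                "n_obs": data.n_obs,
                "shrinkage": shrink,
                "full_shrinkage": full,
            }
        )

    def _posterior_sds(self, modes):
        args = self._mode_args
        h = 1e-4
        J = modes.shape[0]
        H = np.zeros((J, 4, 4))
        for k in range(4):
            dx = np.zeros_like(modes)
            dx[:, k] = h
            H[:, :, k] = (_eb_grad(modes + dx, *args) - _eb_grad(modes - dx, *args)) / (2 * h)
        H = 0.5 * (H + np.transpose(H, (0, 2, 1)))
        sds = np.full((J, 4), np.inf)
        for j in range(J):
            try:
                cov = np.linalg.inv(-H[j])
                d = np.diag(cov)
                if (d > 0).all():
                    sds[j] = np.sqrt(d)
            except np.linalg.LinAlgError:
                pass
        return sds

    # -- views --------------------------------------------------------------

    def population_estimate(self) -> PopulationEstimate:
        return PopulationEstimate(
            theta_kg=self.theta_kg_,
            theta_kd=self.theta_kd_,
            theta_f=self.theta_f_,
            omega=self.omega_,
            sigma=self.sigma_,
            loglik=self.loglik_,
            convergence=dict(self.convergence_),
        )

    def marginal_loglik(self, pop: PopulationEstimate | None = None) -> float:
        """Laplace marginal log-likelihood of the fitted data at ``pop``.

        Independent of the SAEM trajectory: per-lesion modes are re-found
        from the prior centre, not from the chain state.
        """
        if not hasattr(self, "_data"):
            raise EstimationError("model is not fitted")
        pop = pop or self.population_estimate()
        mu = pop.mu()
        omega = np.asarray(pop.omega, float)
        J = len(self._data.lesion_ids)
        x0 = np.tile(np.concatenate([mu, [0.0]]), (J, 1))
        x0[:, 3] = self._data.m0
        modes, ll_modes, args = _eb_modes(
            x0, self._data, self._obs2les, mu, omega, max(pop.sigma, _SIGMA_FLOOR),
            self.loq, self._tau, self.pin_v0,
        )
        return _laplace_loglik(modes, ll_modes, args, self.pin_v0)

    def lesion_growth_params(self) -> dict:
        """Empirical-Bayes :class:`GrowthParams` keyed by lesion_id."""
        return {
            r.lesion_id: GrowthParams(v0=r.v0, f=r.f, kg=r.kg, kd=r.kd)
            for r in self.lesion_params_.itertuples()
        }


# ---------------------------------------------------------------------------
# functional wrappers


def fit_population(
    data: pd.DataFrame,
    init: PopulationEstimate | None = None,
    **options,
) -> PopulationEstimate:
    """Fit the population model on target-lesion measurements; see
    :class:`TumorGrowthMixedModel` for options."""
    model = TumorGrowthMixedModel(init=init, **options)
    model.fit(data)
    est = model.population_estimate()
    est.convergence["model"] = model
    return est


def empirical_bayes(pop: PopulationEstimate, lesion_data: pd.DataFrame, **options) -> pd.DataFrame:
    """Per-lesion posterior-mode parameters under a fixed population estimate.

    Lesions with a single observation shrink fully to the population
    typical values (flagged ``full_shrinkage``).
    """
    model = options.pop("model", None)
    if model is None:
        model = TumorGrowthMixedModel(
            init=pop, n_explore=0, n_smooth=0, compute_loglik=False, **options
        )
        data, _ = _prepare(lesion_data, model.loq)
        J = len(data.lesion_ids)
        obs2les = np.repeat(np.arange(J), data.n_obs)
        mu = pop.mu()
        omega = np.asarray(pop.omega, float)
        x0 = np.tile(np.concatenate([mu, [0.0]]), (J, 1))
        x0[:, 3] = data.m0
        modes, _, args = _eb_modes(
            x0, data, obs2les, mu, omega, max(pop.sigma, _SIGMA_FLOOR),
            model.loq, model.v0_prior_sd, model.pin_v0,
        )
        model._data, model._obs2les, model._mu, model._tau = data, obs2les, mu, model.v0_prior_sd
        model._modes, model._mode_args = modes, args
        return model._modes_frame(modes, omega)
    return model.lesion_params_
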