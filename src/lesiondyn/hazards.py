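"""Organ-level response/progression hazards via shared-frailty Cox models.

Lesions from one patient are correlated; a Gaussian random intercept per
patient (log-normal frailty) absorbs that correlation.  Fitting follows
the penalized-partial-likelihood approach: for a fixed frailty variance
theta the joint mode of (beta, b) maximizes the Efron partial
log-likelihood minus b'b/(2 theta); theta itself maximizes the
Laplace-integrated likelihood

    L(theta) = l_part(b_hat) - b_hat'b_hat/(2 theta)
               - 1/2 log det(K) - q/2 log theta,          K = H_bb + I/theta,

where H_bb is the negative Hessian of the partial likelihood in b.
Hazard ratios are reported per organ against a declared reference organ
(abdomen by default), with Wald confidence intervals from the penalized
information and optional likelihood-ratio p-values.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "FrailtyCoxPH",
    "fit_frailty_cox",
    "select_covariates",
    "classify_phenotypes",
    "stratified_hazards",
]


# ---------------------------------------------------------------------------
# Efron partial likelihood kernels


class _EfronData:
    """Pre-sorted arrays and tie-group indexing for one dataset."""

    def __init__(self, durations, events, Z):
        order = np.argsort(durations, kind="mergesort")
        self.t = np.asarray(durations, float)[order]
        self.e = np.asarray(events, bool)[order]
        self.Z = np.asarray(Z, float)[order]
        self.n, self.m = self.Z.shape
        dt = self.t[self.e]
        self.ut = np.unique(dt)
        self.gidx = np.searchsorted(self.t, self.ut, side="left")
        self.dstart = np.searchsorted(dt, self.ut, side="left")
        counts = np.diff(np.append(self.dstart, len(dt)))
        self.dcount = counts
        self.group_of_death = np.repeat(np.arange(len(self.ut)), counts)
        self.frac = np.concatenate([np.arange(d) / d for d in counts]) if len(counts) else np.empty(0)
        self.dZ = self.Z[self.e]
        # per-observation group position for the cumulative-weight trick
        self.pos = np.searchsorted(self.gidx, np.arange(self.n), side="right")

    def loglik_grad_hess(self, beta, want_hess=True):
        lp = np.clip(self.Z @ beta, -200.0, 200.0)
        r = np.exp(lp)
        S0 = np.cumsum(r[::-1])[::-1]
        S0g = S0[self.gidx]
        dr = r[self.e]
        s0k = np.add.reduceat(dr, self.dstart) if len(self.ut) else np.empty(0)
        g = self.group_of_death
        denom = S0g[g] - self.frac * s0k[g]
        loglik = float(lp[self.e].sum() - np.log(denom).sum())

        inv = 1.0 / denom
        w_k = np.add.reduceat(inv, self.dstart)
        v_flat = self.frac * inv
        v_k = np.add.reduceat(v_flat, self.dstart)
        cumw = np.cumsum(w_k)
        cw = np.where(self.pos > 0, cumw[np.minimum(self.pos, len(cumw)) - 1], 0.0)

        rw = r * cw
        drv = dr * v_k[g]
        grad = self.dZ.sum(axis=0) - (self.Z.T @ rw) + (self.dZ.T @ drv)
        if not want_hess:
            return loglik, grad, None

        S1 = np.cumsum((r[:, None] * self.Z)[::-1], axis=0)[::-1]
        S1g = S1[self.gidx]
        s1k = np.add.reduceat(dr[:, None] * self.dZ, self.dstart, axis=0)
        M = (S1g[g] - self.frac[:, None] * s1k[g]) * inv[:, None]
        Hn = (self.Z.T * rw) @ self.Z - (self.dZ.T * drv) @ self.dZ - M.T @ M
        return loglik, grad, Hn


def _efron_loglik_naive(durations, events, Z, beta):
    """O(n^2) reference Efron partial log-likelihood (used by the tests)."""
    t = np.asarray(durations, float)
    e = np.asarray(events, bool)
    lp = np.asarray(Z, float) @ beta
    r = np.exp(lp)
    ll = 0.0
    for tk in np.unique(t[e]):
        D = e & (t == tk)
        R = t >= tk
        d = int(D.sum())
        ll += lp[D].sum()
        for l in range(d):
            ll -= math.log(r[R].sum() - (l / d) * r[D].sum())
    return ll


# ---------------------------------------------------------------------------
# estimator


class FrailtyCoxPH(BaseEstimator):
    """Cox proportional hazards with a Gaussian patient-level random effect.

    Parameters
    ----------
    theta : float or None
        Frailty variance.  None (default) estimates it by maximizing the
        Laplace-integrated likelihood; 0 fits a plain Cox model.
    theta_bounds : tuple
        Search bounds for the variance (log-scale Brent).
    max_newton : int
        Inner Newton iteration cap.

    Attributes
    ----------
    coef_, se_ : fixed-effect estimates and Wald SEs
    frailty_var_ : estimated (or fixed) frailty variance
    frailty_ : per-cluster random effects (pd.Series)
    integrated_loglik_ : Laplace-integrated log-likelihood at the optimum
    partial_loglik_ : Efron partial log-likelihood at the joint mode
    summary_ : DataFrame with coef/HR/CI/p per term
    """

    def __init__(self, theta=None, theta_bounds=(1e-4, 4.0), max_newton=50, tol=1e-8):
        self.theta = theta
        self.theta_bounds = theta_bounds
        self.max_newton = max_newton
        self.tol = tol

    # -- internals ----------------------------------------------------------

    def _inner_fit(self, data, p, q, theta, beta0):
        """Newton on (beta, b) for fixed frailty variance."""
        beta = beta0.copy()
        pen_idx = slice(p, p + q)

        def pen_ll(b_all, ll):
            b = b_all[pen_idx]
            return ll - (b @ b) / (2 * theta) if q else ll

        ll, grad, Hn = data.loglik_grad_hess(beta)
        cur = pen_ll(beta, ll)
        for _ in range(self.max_newton):
            gp = grad.copy()
            if q:
                gp[pen_idx] -= beta[pen_idx] / theta
                Hn = Hn.copy()
                Hn[np.arange(p, p + q), np.arange(p, p + q)] += 1.0 / theta
            Hn[np.arange(len(beta)), np.arange(len(beta))] += 1e-10
            try:
                step = np.linalg.solve(Hn, gp)
            except np.linalg.LinAlgError:
                step = gp * 1e-3
            if not np.isfinite(step).all():
                step = gp * 1e-3
            scale = 1.0
            accepted = False
            for _ in range(30):
                trial = beta + scale * step
                ll_t, grad_t, Hn_t = data.loglik_grad_hess(trial)
                if np.isfinite(ll_t) and pen_ll(trial, ll_t) >= cur - 1e-12:
                    accepted = True
                    break
                scale *= 0.5
            if not accepted:
                break
            new = pen_ll(trial, ll_t)
            improved = new - cur
            beta, ll, grad, Hn = trial, ll_t, grad_t, Hn_t
            cur = new
            if abs(improved) < self.tol and np.max(np.abs(gp)) < 1e-4 * max(1, data.n):
                break
        return beta, ll, grad, Hn, cur

    def _integrated(self, data, p, q, theta, beta0):
        beta, ll, grad, Hn, cur = self._inner_fit(data, p, q, theta, beta0)
        if q == 0 or theta <= 0:
            return ll, beta, ll, Hn
        b = beta[p:]
        K = Hn[p:, p:].copy()
        K[np.arange(q), np.arange(q)] += 1.0 / theta
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            logdet = np.inf
        lint = ll - (b @ b) / (2 * theta) - 0.5 * logdet - 0.5 * q * math.log(theta)
        return lint, beta, ll, Hn

    # -- API ----------------------------------------------------------------

    def fit(self, X: pd.DataFrame, durations, events, groups=None):
        """Fit on a numeric design matrix X; ``groups`` defines the clusters."""
        X = pd.DataFrame(X)
        self.feature_names_ = list(X.columns)
        p = X.shape[1]
        if groups is not None:
            codes, uniques = pd.factorize(np.asarray(groups))
            q = len(uniques)
            G = np.zeros((len(X), q))
            G[np.arange(len(X)), codes] = 1.0
            Z = np.hstack([X.to_numpy(float), G])
            self.cluster_labels_ = list(uniques)
        else:
            q = 0
            Z = X.to_numpy(float)
            self.cluster_labels_ = []
        durations = np.maximum(np.asarray(durations, float), 1e-8)
        events = np.asarray(events, bool)
        if events.sum() == 0:
            raise ValueError("no events in the data")
        data = _EfronData(durations, events, Z)
        beta0 = np.zeros(p + q)

        if q == 0 or (self.theta is not None and self.theta == 0):
            if q:
                data = _EfronData(durations, events, Z[:, :p])
                q = 0
            beta, ll, grad, Hn, _ = self._inner_fit(data, p, 0, 1.0, np.zeros(p))
            theta_hat = 0.0
            lint = ll
        elif self.theta is not None:
            theta_hat = float(self.theta)
            lint, beta, ll, Hn = self._integrated(data, p, q, theta_hat, beta0)
        else:
            lo, hi = self.theta_bounds
            warm = {"beta": beta0}

            def neg(log_th):
                lint, b_hat, _, _ = self._integrated(data, p, q, math.exp(log_th), warm["beta"])
                warm["beta"] = b_hat
                return -lint

            res = minimize_scalar(
                neg, bounds=(math.log(lo), math.log(hi)), method="bounded",
                options={"xatol": 0.02},
            )
            theta_hat = math.exp(res.x)
            # profile likelihood is flat near zero: snap tiny variances
            lint0, *_ = self._integrated(data, p, q, lo, warm["beta"])
            if -res.fun < lint0 + 1e-6:
                theta_hat = lo
            lint, beta, ll, Hn = self._integrated(data, p, q, theta_hat, warm["beta"])

        Hp = Hn.copy()
        if q:
            Hp[np.arange(p, p + q), np.arange(p, p + q)] += 1.0 / theta_hat
        Hp[np.arange(p + q), np.arange(p + q)] += 1e-10
        try:
            cov = np.linalg.inv(Hp)
        except np.linalg.LinAlgError:
            cov = np.full((p + q, p + q), np.nan)
        self.coef_ = pd.Series(beta[:p], index=self.feature_names_)
        self.se_ = pd.Series(np.sqrt(np.maximum(np.diag(cov)[:p], 0.0)), index=self.feature_names_)
        self.frailty_var_ = theta_hat
        self.frailty_ = pd.Series(beta[p:], index=self.cluster_labels_) if q else pd.Series(dtype=float)
        self.partial_loglik_ = ll
        self.integrated_loglik_ = lint
        self.n_events_ = int(events.sum())
        self._fit_ctx = (data, p, q, theta_hat, beta)

        z = self.coef_ / self.se_.replace(0, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pw = 2 * stats.norm.sf(np.abs(z))
        self.summary_ = pd.DataFrame(
            {
                "coef": self.coef_,
                "se": self.se_,
                "hr": np.exp(self.coef_),
                "ci_low": np.exp(self.coef_ - 1.96 * self.se_),
                "ci_high": np.exp(self.coef_ + 1.96 * self.se_),
                "p": pw,
            }
        )
        return self

    def lrt_pvalues(self, columns=None) -> pd.Series:
        """Likelihood-ratio p-values: refit dropping each column at the
        estimated frailty variance (profile LRT)."""
        data, p, q, theta, beta = self._fit_ctx
        if columns is None:
            columns = self.feature_names_
        full = self.integrated_loglik_
        out = {}
        for col in columns:
            j = self.feature_names_.index(col)
            keep = [k for k in range(p + q) if k != j]
            sub = _EfronData(data.t, data.e, data.Z[:, keep])
            if q and theta > 0:
                lred, *_ = self._integrated(sub, p - 1, q, theta, np.delete(beta, j))
            else:
                lred = self._inner_fit(sub, p - 1, 0, 1.0, np.delete(beta, j))[1]
            lr = max(2.0 * (full - lred), 0.0)
            out[col] = float(stats.chi2.sf(lr, df=1))
        return pd.Series(out)


# ---------------------------------------------------------------------------
# design-matrix helpers and module-level operations


def _build_design(df: pd.DataFrame, reference_organ: str, covariates: list | None):
    """Organ factor (reference dropped) + optional covariate columns."""
    organs = sorted(df["organ"].unique())
    if reference_organ not in organs:
        raise ValueError(f"reference organ {reference_organ!r} absent from data")
    cols = {}
    for o in organs:
        if o != reference_organ:
            cols[f"organ[{o}]"] = (df["organ"] == o).astype(float)
    X = pd.DataFrame(cols, index=df.index)
    for cov in covariates or []:
        s = df[cov]
        if s.dtype == object or s.dtype == bool or str(s.dtype) == "category":
            d = pd.get_dummies(s.astype(str), prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, d], axis=1)
        else:
            X[cov] = s.astype(float).fillna(s.astype(float).mean())
    return X, organs


def _endpoint_frame(events: pd.DataFrame, patients: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    if endpoint not in ("response", "progression"):
        raise ValueError("endpoint must be 'response' or 'progression'")
    df = events.copy()
    if endpoint == "response":
        # new lesions enter the progression analysis only
        df = df[df["lesion_class"] != "new"]
        df = df[df["response_time"].notna()]
        df = df.rename(columns={"response_time": "duration", "response_event": "event"})
    else:
        df = df[df["progression_time"].notna()]
        df = df.rename(columns={"progression_time": "duration", "progression_event": "event"})
    keep = [c for c in patients.columns if c not in df.columns or c == "patient_id"]
    return df.merge(patients[keep], on="patient_id", how="left")


def fit_frailty_cox(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    endpoint: str,
    covariates: list | None = None,
    reference_organ: str = "abdomen",
    compute_lrt: bool = False,
    theta=None,
) -> FrailtyCoxPH:
    """Frailty Cox fit for one endpoint; attaches ``organ_hazards_``.

    Organs with zero events are dropped with a warning.  The reference
    organ has hazard ratio 1 with a degenerate CI by construction.
    """
    df = _endpoint_frame(events, patients, endpoint)
    ev_per_organ = df.groupby("organ")["event"].sum()
    dead = ev_per_organ[ev_per_organ == 0].index.tolist()
    if dead:
        logger.warning("dropping organs with zero %s events: %s", endpoint, dead)
        df = df[~df["organ"].isin(dead)]
    if df["organ"].nunique() < 2:
        raise ValueError("need >= 2 organs with events to contrast hazards")
    X, organs = _build_design(df, reference_organ, covariates)
    model = FrailtyCoxPH(theta=theta)
    model.fit(X, df["duration"], df["event"], groups=df["patient_id"])
    lrt = model.lrt_pvalues([c for c in X.columns if c.startswith("organ[")]) if compute_lrt else None

    rows = [
        dict(organ=reference_organ, endpoint=endpoint, hr=1.0, ci_low=1.0, ci_high=1.0, p=np.nan)
    ]
    for o in organs:
        if o == reference_organ:
            continue
        key = f"organ[{o}]"
        s = model.summary_.loc[key]
        rows.append(
            dict(
                organ=o,
                endpoint=endpoint,
                hr=s["hr"],
                ci_low=s["ci_low"],
                ci_high=s["ci_high"],
                p=lrt[key] if lrt is not None else s["p"],
            )
        )
    model.organ_hazards_ = pd.DataFrame(rows)
    model.endpoint_ = endpoint
    return model


def select_covariates(
    candidates: list,
    events: pd.DataFrame,
    patients: pd.DataFrame,
    endpoint: str,
    alpha: float = 0.05,
    reference_organ: str = "abdomen",
) -> list:
    """Univariable-addition likelihood-ratio screening at level ``alpha``.

    Each candidate is added singly to the organ-only frailty model; those
    improving it at p < alpha are selected (logged with their p-values).
    """
    if not candidates:
        return []
    df = _endpoint_frame(events, patients, endpoint)
    ev_per_organ = df.groupby("organ")["event"].sum()
    df = df[~df["organ"].isin(ev_per_organ[ev_per_organ == 0].index)]
    X0, _ = _build_design(df, reference_organ, None)
    base = FrailtyCoxPH().fit(X0, df["duration"], df["event"], groups=df["patient_id"])
    theta = base.frailty_var_
    selected = []
    for cov in candidates:
        Xc, _ = _build_design(df, reference_organ, [cov])
        m = FrailtyCoxPH(theta=theta if theta > 0 else 0).fit(
            Xc, df["duration"], df["event"], groups=df["patient_id"]
        )
        df_added = Xc.shape[1] - X0.shape[1]
        lr = max(2.0 * (m.integrated_loglik_ - base.integrated_loglik_), 0.0)
        pval = float(stats.chi2.sf(lr, df=max(df_added, 1)))
        logger.info("covariate screen %s on %s: LR=%.2f df=%d p=%.4f", cov, endpoint, lr, df_added, pval)
        if pval < alpha:
            selected.append(cov)
    return selected


def classify_phenotypes(response_hazards: pd.DataFrame, progression_hazards: pd.DataFrame) -> pd.DataFrame:
    """Assign each organ a response x progression phenotype.

    Non-reference organs are 'high' on an axis when their HR exceeds 1
    against the reference; the reference organ itself is labelled by
    comparing 1 to the median HR of the other organs.
    """
    r = response_hazards.set_index("organ")["hr"]
    g = progression_hazards.set_index("organ")["hr"]
    common = r.index.intersection(g.index)
    missing = r.index.symmetric_difference(g.index)
    if len(missing):
        logger.warning("organs missing from one endpoint excluded: %s", sorted(missing))

    def axis_label(hrs, organ):
        if hrs[organ] != 1.0 or (hrs != 1.0).sum() == 0:
            return hrs[organ] > 1.0
        others = hrs[hrs.index != organ]
        return 1.0 > others.median()

    rows = []
    for organ in common:
        hi_r = axis_label(r, organ)
        hi_g = axis_label(g, organ)
        label = f"{'high' if hi_r else 'low'}-{'high' if hi_g else 'low'}"
        rows.append(dict(organ=organ, phenotype=label))
    return pd.DataFrame(rows)


def stratified_hazards(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    endpoint: str,
    stratum_col: str = "treatment_group",
    **fit_kwargs,
) -> pd.DataFrame:
    """Separate organ-hazard fits per stratum (e.g. treatment group)."""
    df = events.merge(patients[["patient_id", stratum_col]], on="patient_id", how="left")
    out = []
    for level, sub_events in df.groupby(stratum_col):
        sub = sub_events.drop(columns=[stratum_col])
        try:
            m = fit_frailty_cox(sub, patients, endpoint, **fit_kwargs)
        except ValueError as err:
            logger.warning("stratum %s skipped: %s", level, err)
            continue
        haz = m.organ_hazards_.copy()
        haz["stratum"] = level
        out.append(haz)
    if not out:
        raise ValueError("no stratum could be fitted")
    return pd.concat(out, ignore_index=True)
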