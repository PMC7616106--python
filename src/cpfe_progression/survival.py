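"""Survival analysis: Kaplan-Meier/log-rank, adjusted Cox models with a
centre random intercept, concordance and proportional-hazards diagnostics.

The centre random intercept is a log-normal shared frailty: centre effects
enter the Cox linear predictor as coefficients penalised by a Gaussian prior
with variance theta, maximised by penalized partial likelihood (Efron ties);
theta itself maximises the Laplace-approximate marginal likelihood.  Models
without centre structure go through lifelines' Cox fitter.  The
proportional-hazards diagnostic is the Grambsch-Therneau scaled-Schoenfeld
score test against the rank transform of event time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats
from scipy.optimize import minimize_scalar

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ADJUSTERS = (
    "age",
    "male",
    "smoking_ever",
    "antifibrotic_ever",
    "dlco_pp_baseline",
)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


@dataclass
class KMResult:
    curves: dict  # group label -> DataFrame(time, at_risk, survival)
    chi2: float
    df: int
    p_value: float


def km_logrank(times, events, groups) -> KMResult:
    """Product-limit curves per group and the k-sample log-rank test."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("log-rank comparison requires at least two groups")
    curves = {}
    for g in labels:
        m = groups == g
        kmf = KaplanMeierFitter().fit(times[m], events[m])
        tab = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "at_risk": tab["at_risk"].to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            }
        )
    res = multivariate_logrank_test(times, groups, events)
    return KMResult(
        curves=curves,
        chi2=float(res.test_statistic),
        df=int(len(labels) - 1),
        p_value=float(res.p_value),
    )


# ---------------------------------------------------------------------------
# events-per-covariate rule and concordance


def events_per_covariate_check(
    n_events: int, n_covariates: int, min_events_per_covariate: int = 8
) -> bool:
    """Minimum-8-outcome-events-per-predictor eligibility rule."""
    if n_events < 0 or n_covariates < 0:
        raise ValidationError("counts must be non-negative")
    return n_events >= min_events_per_covariate * n_covariates


def c_index(times, events, risk_scores) -> float:
    """Harrell's concordance of a risk score (higher score = earlier death).

    Comparable pairs follow the usual censoring rules; tied scores count 1/2.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    scores = np.asarray(risk_scores, dtype=float)
    try:
        return float(concordance_index(times, -scores, events))
    except ZeroDivisionError as exc:
        raise ValidationError("concordance undefined: no permissible pairs") from exc


# ---------------------------------------------------------------------------
# Efron partial likelihood (own implementation, used by the frailty model)


def _efron_ll_grad_hess(X, time, event, beta):
    """Efron-tie log partial likelihood with gradient and Hessian."""
    n, p = X.shape
    order = np.argsort(-time, kind="stable")  # descending: risk sets are prefixes
    Xs, ts, es = X[order], time[order], event[order]
    lp = Xs @ beta
    lp_stab = lp - lp.max()
    w = np.exp(lp_stab)
    cw0 = np.cumsum(w)
    cw1 = np.cumsum(w[:, None] * Xs, axis=0)
    xxw = np.einsum("ni,nj->nij", Xs, Xs) * w[:, None, None]
    cw2 = np.cumsum(xxw, axis=0)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    neg_ts = -ts
    for t in np.unique(ts[es == 1]):
        last = np.searchsorted(neg_ts, -t, side="right") - 1
        S0, S1, S2 = cw0[last], cw1[last], cw2[last]
        D = np.nonzero((ts == t) & (es == 1))[0]
        d = len(D)
        wD = w[D]
        s0d = wD.sum()
        s1d = (wD[:, None] * Xs[D]).sum(axis=0)
        s2d = xxw[D].sum(axis=0)
        ll += lp_stab[D].sum()
        grad += Xs[D].sum(axis=0)
        for l in range(d):
            frac = l / d
            denom = S0 - frac * s0d
            u = (S1 - frac * s1d) / denom
            V = (S2 - frac * s2d) / denom
            ll -= math.log(denom)
            grad -= u
            hess -= V - np.outer(u, u)
    return ll, grad, hess


def _newton_cox(X, time, event, penalty_diag=None, beta0=None, tol=1e-9, max_iter=50):
    """Newton-Raphson maximiser of the (optionally ridge-penalised) Efron
    partial likelihood.  Returns (beta, unpenalised ll, unpenalised Hessian,
    converged flag)."""
    n, p = X.shape
    P = np.zeros(p) if penalty_diag is None else np.asarray(penalty_diag, dtype=float)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll, grad, hess = _efron_ll_grad_hess(X, time, event, beta)
    pll = ll - 0.5 * float(P @ beta**2)
    converged = False
    for _ in range(max_iter):
        g = grad - P * beta
        H = hess - np.diag(P)
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, g, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_c, grad_c, hess_c = _efron_ll_grad_hess(X, time, event, cand)
            pll_c = ll_c - 0.5 * float(P @ cand**2)
            if pll_c >= pll - 1e-12:
                break
            scale *= 0.5
        improvement = pll_c - pll
        beta, ll, grad, hess, pll = cand, ll_c, grad_c, hess_c, pll_c
        if abs(improvement) < tol:
            converged = True
            break
    return beta, ll, hess, converged


@dataclass
class FrailtyCoxFit:
    """Penalized-partial-likelihood Cox fit with a Gaussian centre intercept."""

    covariates: list
    beta: np.ndarray
    se: np.ndarray
    centre_labels: list
    centre_effects: np.ndarray
    theta: float  # frailty variance (variance of the log-hazard intercepts)
    log_likelihood: float
    linear_predictor: np.ndarray
    info_covariates: np.ndarray  # unpenalised information, covariate block
    converged: bool


def fit_frailty_cox(
    df: pd.DataFrame,
    covariates: list,
    duration_col: str,
    event_col: str,
    centre_col: str,
    theta: float | None = None,
    theta_bounds: tuple[float, float] = (1e-4, 4.0),
) -> FrailtyCoxFit:
    """Cox model with a log-normal shared frailty (random intercept) per centre.

    Centre effects are ridge-penalised coefficients with penalty 1/theta;
    theta maximises the Laplace approximation to the marginal likelihood
    unless given explicitly.
    """
    X = df[covariates].to_numpy(dtype=float)
    time = df[duration_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=int)
    centres = pd.Categorical(df[centre_col])
    labels = list(centres.categories)
    q = len(labels)
    Z = np.eye(q)[centres.codes]
    XZ = np.hstack([X, Z])
    p = X.shape[1]

    state = {"beta": None}

    def profile(log_theta: float) -> float:
        th = math.exp(log_theta)
        pen = np.concatenate([np.zeros(p), np.full(q, 1.0 / th)])
        beta, ll, hess, _ = _newton_cox(XZ, time, event, pen, beta0=state["beta"])
        state["beta"] = beta
        b = beta[p:]
        H_bb = -hess[p:, p:]
        sign, logdet = np.linalg.slogdet(H_bb + np.eye(q) / th)
        if sign <= 0:
            return 1e12
        marg = ll - float(b @ b) / (2 * th) - 0.5 * q * math.log(th) - 0.5 * logdet
        return -marg

    if theta is None:
        res = minimize_scalar(
            profile,
            bounds=(math.log(theta_bounds[0]), math.log(theta_bounds[1])),
            method="bounded",
            options={"xatol": 1e-3},
        )
        theta = math.exp(res.x)
    pen = np.concatenate([np.zeros(p), np.full(q, 1.0 / theta)])
    beta_full, ll, hess, converged = _newton_cox(XZ, time, event, pen, beta0=state["beta"])
    H_pen = -(hess - np.diag(pen))
    try:
        cov = np.linalg.inv(H_pen)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H_pen)
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
    lp = XZ @ beta_full
    return FrailtyCoxFit(
        covariates=list(covariates),
        beta=beta_full[:p],
        se=se,
        centre_labels=labels,
        centre_effects=beta_full[p:],
        theta=float(theta),
        log_likelihood=float(ll),
        linear_predictor=lp,
        info_covariates=-hess[:p, :p],
        converged=bool(converged),
    )


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic (Grambsch-Therneau)


def schoenfeld_test(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    linear_predictor: np.ndarray,
    covariate_names: list | None = None,
    info: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Scaled-Schoenfeld score test of proportional hazards against time rank.

    Returns (per-covariate table with chi2/p, global p).  ``info`` is the
    covariate information matrix of the fit; if omitted it is computed from
    the supplied linear predictor (Breslow form).
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lp = np.asarray(linear_predictor, dtype=float)
    if event.sum() == 0:
        raise ValidationError("Schoenfeld test undefined with zero events")
    n, p = X.shape
    order = np.argsort(-time, kind="stable")
    Xs, ts, es, lps = X[order], time[order], event[order], lp[order]
    w = np.exp(lps - lps.max())
    cw0 = np.cumsum(w)
    cw1 = np.cumsum(w[:, None] * Xs, axis=0)
    xxw = np.einsum("ni,nj->nij", Xs, Xs) * w[:, None, None]
    cw2 = np.cumsum(xxw, axis=0)
    neg_ts = -ts
    resid, ev_times, info_acc = [], [], np.zeros((p, p))
    for t in np.unique(ts[es == 1]):
        last = np.searchsorted(neg_ts, -t, side="right") - 1
        S0, S1, S2 = cw0[last], cw1[last], cw2[last]
        xbar = S1 / S0
        V = S2 / S0 - np.outer(xbar, xbar)
        for i in np.nonzero((ts == t) & (es == 1))[0]:
            resid.append(Xs[i] - xbar)
            ev_times.append(t)
            info_acc += V
    resid = np.asarray(resid)
    ev_times = np.asarray(ev_times)
    d = len(ev_times)
    if info is None:
        info = info_acc
    g = stats.rankdata(ev_times)
    gc = g - g.mean()
    gss = float(gc @ gc)
    u = resid.T @ gc
    A = np.linalg.pinv(info)
    Au = A @ u
    global_stat = d * float(u @ Au) / gss
    global_p = float(stats.chi2.sf(global_stat, df=p))
    names = covariate_names or [f"x{i}" for i in range(p)]
    per = []
    for j in range(p):
        stat_j = d * Au[j] ** 2 / (A[j, j] * gss)
        per.append(
            {"covariate": names[j], "chi2": stat_j, "p": float(stats.chi2.sf(stat_j, 1))}
        )
    return pd.DataFrame(per), global_p


def schoenfeld_test_from_lifelines(cph: CoxPHFitter, df: pd.DataFrame,
                                   duration_col: str, event_col: str):
    """Run the diagnostic on a lifelines fit (keeps one code path for the test)."""
    covs = list(cph.params_.index)
    X = df[covs].to_numpy(dtype=float)
    lp = X @ cph.params_.to_numpy()
    return schoenfeld_test(
        X,
        df[duration_col].to_numpy(float),
        df[event_col].to_numpy(int),
        lp,
        covariate_names=covs,
    )


# ---------------------------------------------------------------------------
# adjusted Cox models


@dataclass
class CoxResult:
    subgroup: str
    covariate: str
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    c_index: float
    schoenfeld_global_p: float
    n_subjects: int
    n_events: int
    frailty_variance: float | None
    converged: bool
    eligible: bool = True

    def as_row(self) -> dict:
        return {
            "subgroup": self.subgroup,
            "covariate": self.covariate,
            "c_index": self.c_index,
            "p_value": self.p_value,
            "hazard_ratio": self.hazard_ratio,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "schoenfeld_global_p": self.schoenfeld_global_p,
            "n_subjects": self.n_subjects,
            "n_events": self.n_events,
            "frailty_variance": self.frailty_variance,
            "converged": self.converged,
            "eligible": self.eligible,
        }


def ineligible_result(subgroup: str, covariate: str, n: int, n_events: int) -> CoxResult:
    return CoxResult(
        subgroup, covariate, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
        n, n_events, None, False, eligible=False,
    )


def fit_adjusted_cox(
    df: pd.DataFrame,
    decline_covariate: str,
    duration_col: str = "survival_years",
    event_col: str = "death",
    adjusters: tuple = DEFAULT_ADJUSTERS,
    centre_col: str | None = "centre_id",
    subgroup: str = "all",
    min_events_per_covariate: int = 8,
) -> CoxResult:
    """Multivariable Cox model of one decline covariate plus the adjusters.

    Adjusted for age, sex, smoking history, antifibrotic use and baseline
    percent-predicted DLco; centre heterogeneity enters as a log-normal
    shared frailty when ``centre_col`` identifies more than one centre.
    Hazard ratios are per unit of the decline covariate (per 1% of annual
    decline for continuous covariates, per group for binary flags) with Wald
    CIs on the log scale.
    """
    covs = list(adjusters) + [decline_covariate]
    cols = covs + [duration_col, event_col]
    if centre_col is not None and centre_col in df.columns:
        cols.append(centre_col)
    data = df[cols].dropna().copy()
    for c in covs:
        data[c] = data[c].astype(float)
    n, n_events = len(data), int(data[event_col].sum())
    if not events_per_covariate_check(n_events, len(covs), min_events_per_covariate):
        raise ValidationError(
            f"events-per-covariate rule failed: {n_events} events for {len(covs)} covariates"
        )
    use_frailty = (
        centre_col is not None
        and centre_col in data.columns
        and data[centre_col].nunique() > 1
    )
    time = data[duration_col].to_numpy(float)
    event = data[event_col].to_numpy(int)
    X = data[covs].to_numpy(float)
    if use_frailty:
        fit = fit_frailty_cox(data, covs, duration_col, event_col, centre_col)
        j = covs.index(decline_covariate)
        coef, se = fit.beta[j], fit.se[j]
        lp = fit.linear_predictor
        converged = fit.converged
        frailty_var = fit.theta
        info = fit.info_covariates
    else:
        cph = CoxPHFitter().fit(
            data.drop(columns=[centre_col], errors="ignore"), duration_col, event_col
        )
        coef = float(cph.params_[decline_covariate])
        se = float(cph.standard_errors_[decline_covariate])
        lp = X @ cph.params_[covs].to_numpy()
        converged = True
        frailty_var = None
        info = None
    z = coef / se if se > 0 else np.nan
    p_value = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    ci_lo, ci_hi = math.exp(coef - 1.96 * se), math.exp(coef + 1.96 * se)
    cidx = c_index(time, event, lp)
    try:
        _, global_p = schoenfeld_test(
            X, time, event, lp, covariate_names=covs, info=info
        )
    except ValidationError:
        global_p = np.nan
    return CoxResult(
        subgroup=subgroup,
        covariate=decline_covariate,
        hazard_ratio=math.exp(coef),
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p_value=p_value,
        c_index=cidx,
        schoenfeld_global_p=global_p,
        n_subjects=n,
        n_events=n_events,
        frailty_variance=frailty_var,
        converged=converged,
    )
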