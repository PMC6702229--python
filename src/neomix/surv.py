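"""Survival modelling: Kaplan-Meier, Cox PH, elastic-net Cox, maxstat cutpoints.

Cox proportional-hazards fits use the Efron tie correction (Breslow
available), with Wald tests of each level against a reference and a global
logrank test.  Gene selection for survival uses an elastic-net-penalised
Cox model along a log-spaced lambda path with leave-one-out
cross-validated partial-likelihood deviance (Verweij & Van Houwelingen)
and the one-standard-error rule.  Expression cutpoints are maximally
selected standardized logrank statistics with a minimum group proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


@dataclass
class SurvivalFit:
    reference: str
    hazard_ratios: pd.DataFrame      # level -> HR, CI low/high, Wald z, p
    logrank_p: float
    n_per_group: pd.Series
    flagged: bool = False
    diagnostics: str = ""


@dataclass
class CutpointResult:
    gene: str
    cutpoint: float
    statistic: float        # standardized logrank statistic at the cutpoint
    n_low: int
    n_high: int
    logrank_p: float


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve as a (time, survival) step table."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter().fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def _cox_nll_grad_hess(beta, x, times, events, ties="efron"):
    """Negative log partial likelihood with gradient and Hessian.

    Efron's tie correction by default (Breslow via ``ties="breslow"``); the
    Hessian is the observed information used for Wald statistics.
    """
    eta = x @ beta
    w = np.exp(eta)
    p = x.shape[1]
    nll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        at_risk = times >= t
        d = int(dead.sum())
        s0_r = w[at_risk].sum()
        s1_r = x[at_risk].T @ w[at_risk]
        s2_r = (x[at_risk].T * w[at_risk]) @ x[at_risk]
        s0_d = w[dead].sum()
        s1_d = x[dead].T @ w[dead]
        s2_d = (x[dead].T * w[dead]) @ x[dead]
        nll -= eta[dead].sum()
        grad -= x[dead].sum(axis=0)
        steps = range(d) if ties == "efron" else [0] * d
        for j in steps:
            frac = j / d if ties == "efron" else 0.0
            s0 = s0_r - frac * s0_d
            s1 = s1_r - frac * s1_d
            s2 = s2_r - frac * s2_d
            nll += np.log(s0)
            grad += s1 / s0
            hess += s2 / s0 - np.outer(s1, s1) / s0**2
    return nll, grad, hess


def _newton_cox(x, times, events, ties="efron", max_iter=100, gtol=1e-9):
    """Newton-Raphson maximisation of the partial likelihood with step halving."""
    beta = np.zeros(x.shape[1])
    nll, grad, hess = _cox_nll_grad_hess(beta, x, times, events, ties)
    # step acceptance must tolerate the floating-point resolution of the
    # objective, which is ~1e-13 relative near the optimum
    f_tol = 1e-10 * (1.0 + abs(nll))
    for _ in range(max_iter):
        if np.abs(grad).max() < gtol:
            break
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            candidate = beta - scale * step
            new_nll, new_grad, new_hess = _cox_nll_grad_hess(candidate, x, times, events, ties)
            if new_nll <= nll + f_tol:
                beta, nll, grad, hess = candidate, new_nll, new_grad, new_hess
                break
            scale /= 2
        else:
            break  # no admissible step: the objective is flat to machine precision
    # "converged" means the score is numerically zero at the returned point
    converged = np.abs(grad).max() < 1e-5 * (1.0 + abs(nll))
    return beta, hess, converged


def cox_fit(
    times, events, group: pd.Series, reference: str,
    covariables: pd.DataFrame | None = None, ties: str = "efron",
) -> SurvivalFit:
    """Cox PH of group (vs reference) with optional covariables.

    Newton-Raphson on the Efron-corrected partial likelihood; hazard ratios,
    95% Wald CIs and p-values per non-reference level from the observed
    information; the global p is the logrank test over the groups.
    Monotone-likelihood / separation cases are returned flagged, not raised.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    g = pd.Series(group).astype(str).reset_index(drop=True)
    if reference not in set(g):
        raise ValueError(f"reference level {reference!r} not present")
    levels = [l for l in sorted(g.unique()) if l != reference]
    cols = [(g == lev).astype(float).to_numpy() for lev in levels]
    names = list(levels)
    if covariables is not None:
        cov = pd.get_dummies(covariables.reset_index(drop=True), drop_first=True, dtype=float)
        cov = cov.loc[:, cov.std(axis=0) > 0]
        cols.extend(cov.to_numpy().T)
        names.extend(cov.columns)
    x = np.column_stack(cols)

    beta, hess, converged = _newton_cox(x, times, events, ties=ties)
    flagged = not converged or np.abs(beta).max() > 15
    diagnostics = ""
    if not converged:
        diagnostics = "Newton iterations did not converge (possible monotone likelihood)"
    elif np.abs(beta).max() > 15:
        diagnostics = "extreme coefficient: complete or quasi-complete separation"
    with np.errstate(all="ignore"):
        try:
            cov_beta = np.linalg.inv(hess)
            se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(beta), np.nan)
            flagged = True
            diagnostics = diagnostics or "singular information matrix"
    zcrit = stats.norm.ppf(0.975)
    rows = {}
    for i, lev in enumerate(levels):
        z = beta[i] / se[i] if se[i] > 0 else np.nan
        rows[lev] = {
            "hr": float(np.exp(beta[i])),
            "ci_low": float(np.exp(beta[i] - zcrit * se[i])),
            "ci_high": float(np.exp(beta[i] + zcrit * se[i])),
            "z": float(z),
            "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        }
    lr = multivariate_logrank_test(times, g.to_numpy(), events)
    return SurvivalFit(
        reference=reference,
        hazard_ratios=pd.DataFrame(rows).T,
        logrank_p=float(lr.p_value),
        n_per_group=g.value_counts(),
        flagged=flagged,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# elastic-net Cox with LOO deviance and the one-SE rule
# ---------------------------------------------------------------------------

def _breslow_loglik(beta: np.ndarray, x: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    eta = x @ beta
    order = np.argsort(-times, kind="stable")  # decreasing time: cumulative risk sets
    eta_o = eta[order]
    t_o = times[order]
    e_o = events[order]
    log_cum = np.logaddexp.accumulate(eta_o)
    # ties: risk set includes everyone with time >= t; extend cumsum over equal times
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j + 1 < n and t_o[j + 1] == t_o[i]:
            j += 1
        denom = log_cum[j]
        for k in range(i, j + 1):
            if e_o[k] == 1:
                ll += eta_o[k] - denom
        i = j + 1
    return ll


@dataclass
class CoxnetSelection:
    selected: list
    coefficients: pd.Series
    lambda_path: np.ndarray
    cv_deviance: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    flagged: bool = False


def coxnet_select(
    times, events, X: pd.DataFrame, alpha: float = 0.5,
    n_lambda: int = 100, lambda_min_ratio: float = 1e-4, seed: int = 0,
) -> CoxnetSelection:
    """Elastic-net Cox gene selection with LOO CV and the one-SE rule.

    ``X`` is a samples x genes matrix, already centred and scaled.  The
    lambda path spans four decades below the smallest lambda giving the null
    model; held-out deviance per lambda follows Verweij & Van Houwelingen:
    ``dev_i = -2 (loglik_full(beta_-i) - loglik_-i(beta_-i))``.  The chosen
    lambda is the largest with mean CV deviance within one standard error of
    the minimum; genes with nonzero coefficients there are returned.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    x = X.to_numpy(dtype=float)
    n = len(times)

    if alpha == 0:
        # ridge keeps every coefficient nonzero; fit a single L2-penalised Cox
        df = pd.DataFrame(x, columns=X.columns)
        df["T"] = times
        df["E"] = events
        cph = CoxPHFitter(penalizer=1.0, l1_ratio=0.0)
        cph.fit(df, duration_col="T", event_col="E")
        coef = cph.params_.reindex(X.columns)
        return CoxnetSelection(
            selected=list(X.columns), coefficients=coef,
            lambda_path=np.array([1.0]), cv_deviance=np.array([np.nan]),
            cv_se=np.array([np.nan]), lambda_min=1.0, lambda_1se=1.0,
        )

    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(event=events.astype(bool), time=times)
    base = CoxnetSurvivalAnalysis(
        l1_ratio=alpha, n_alphas=n_lambda, alpha_min_ratio=lambda_min_ratio,
        fit_baseline_model=False, normalize=False,
    )
    base.fit(x, y)
    path = np.asarray(base.alphas_)

    dev = np.zeros((n, len(path)))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if events[keep].sum() == 0:
            continue
        est = CoxnetSurvivalAnalysis(
            l1_ratio=alpha, alphas=list(path), fit_baseline_model=False, normalize=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(x[keep], y[keep])
        coefs = est.coef_  # genes x lambdas
        fitted_alphas = np.asarray(est.alphas_)
        for j, lam in enumerate(path):
            jj = int(np.argmin(np.abs(fitted_alphas - lam)))
            beta = coefs[:, jj]
            ll_full = _breslow_loglik(beta, x, times, events)
            ll_fold = _breslow_loglik(beta, x[keep], times[keep], events[keep])
            dev[i, j] = -2.0 * (ll_full - ll_fold)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n)
    j_min = int(np.argmin(mean_dev))
    threshold = mean_dev[j_min] + se_dev[j_min]
    candidates = np.flatnonzero(mean_dev <= threshold)
    # path is decreasing in lambda; the largest qualifying lambda is the first
    j_1se = int(candidates.min()) if len(candidates) else j_min
    lam_1se = float(path[j_1se])

    coef = pd.Series(base.coef_[:, j_1se], index=X.columns)
    selected = list(coef.index[coef != 0.0])
    return CoxnetSelection(
        selected=selected,
        coefficients=coef,
        lambda_path=path,
        cv_deviance=mean_dev,
        cv_se=se_dev,
        lambda_min=float(path[j_min]),
        lambda_1se=lam_1se,
        flagged=len(selected) == 0,
    )


# ---------------------------------------------------------------------------
# maximally selected rank statistics
# ---------------------------------------------------------------------------

def standardized_logrank(times, events, in_low: np.ndarray) -> float:
    """Standardized logrank statistic (O - E)/sqrt(V) for a two-group split."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    in_low = np.asarray(in_low, dtype=bool)
    event_times = np.unique(times[events == 1])
    o = e = v = 0.0
    for t in event_times:
        at_risk = times >= t
        n_t = at_risk.sum()
        n1_t = (at_risk & in_low).sum()
        d_t = ((times == t) & (events == 1)).sum()
        d1_t = ((times == t) & (events == 1) & in_low).sum()
        o += d1_t
        e += d_t * n1_t / n_t
        if n_t > 1:
            v += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    if v == 0:
        return 0.0
    return (o - e) / np.sqrt(v)


def maxstat_cutpoint(times, events, x, minprop: float = 0.1) -> CutpointResult:
    """Cutpoint maximising |standardized logrank| over admissible splits.

    Candidate cutpoints are midpoints between consecutive distinct values of
    ``x``; a split is admissible if both sides keep at least ``minprop`` of
    the samples.  The reported p-value is the unadjusted logrank p of the
    chosen split.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    n = len(x)
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError("x must take at least two distinct values")
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    min_n = minprop * n
    best = None
    for c in cuts:
        low = x <= c
        if low.sum() < min_n or (~low).sum() < min_n:
            continue
        z = standardized_logrank(times, events, low)
        if best is None or abs(z) > abs(best[1]):
            best = (c, z, int(low.sum()))
    if best is None:
        raise ValueError(f"no admissible cutpoint with minprop={minprop}")
    c, z, n_low = best
    p = float(stats.chi2.sf(z * z, 1))
    return CutpointResult(
        gene="", cutpoint=float(c), statistic=float(z),
        n_low=n_low, n_high=n - n_low, logrank_p=p,
    )
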