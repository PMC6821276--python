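"""Survival endpoints: Kaplan–Meier, log-rank, Cox proportional hazards.

The covariance SEM cannot represent a right-censored outcome, so edges that
point into a survival node are estimated by a Cox proportional-hazards model
whose covariates are ALL graph parents of that node fitted simultaneously
(latent parents enter as factor scores).  This hybrid preserves the usual
multivariable-adjustment semantics: adding a mediator or confounder parent
attenuates the direct edge's z-score exactly as in an adjusted Cox model.
Positive coefficients mean higher hazard, i.e. worse outcome.

Kaplan–Meier estimation and the log-rank test delegate to lifelines; the Cox
partial likelihood uses the Breslow tie convention and is maximized by
Newton iterations here (lifelines implements the Efron correction only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .cohort import Cohort
from .model_graph import ModelGraph
from .sem_engine import (FitResult, ParameterEstimate, SemError, compile_graph,
                         factor_scores)


class SurvivalError(ValueError):
    pass


@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    times: np.ndarray          # sorted event times
    survival: np.ndarray       # S(t) just after each time
    at_risk: np.ndarray        # risk-set size just before each time
    group: str = "all"

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "at_risk": self.at_risk, "group": self.group}
        )


@dataclass
class CoxResult:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: bool
    n: int
    n_events: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"covariate": self.names, "beta": self.beta, "se": self.se,
             "z": self.z, "p": self.p}
        )


def _clean(times, events, X=None):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    keep = ~(np.isnan(times) | np.isnan(events))
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        keep &= ~np.isnan(X).any(axis=1)
        return times[keep], events[keep], X[keep]
    return times[keep], events[keep]


def km_estimate(times, events, groups=None) -> list[KMCurve]:
    """Kaplan–Meier product-limit curves, one per group.

    Ŝ(t) = prod over event times t_i <= t of (1 - d_i/n_i).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if groups is None:
        groups = np.array(["all"] * len(times), dtype=object)
    else:
        groups = np.asarray(groups, dtype=object)
    curves = []
    for g in pd.unique(groups):
        sel = groups == g
        t, e = _clean(times[sel], events[sel])
        if t.size == 0:
            raise SurvivalError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e)
        ev_times = np.sort(np.unique(t[e == 1]))
        if ev_times.size:
            surv = kmf.survival_function_at_times(ev_times).to_numpy()
            at_risk = np.array([(t >= et).sum() for et in ev_times], dtype=float)
        else:
            surv = np.array([])
            at_risk = np.array([])
        curves.append(KMCurve(ev_times, surv, at_risk, group=str(g)))
    return curves


def logrank_test(times, events, groups) -> tuple[float, float]:
    """k-sample log-rank test; chi-square statistic with k-1 df."""
    times, events = np.asarray(times, float), np.asarray(events, float)
    groups = np.asarray(groups, dtype=object)
    t, e = _clean(times, events)
    keep = ~(np.isnan(times) | np.isnan(events))
    g = groups[keep]
    labels = pd.unique(g)
    if len(labels) < 2:
        raise SurvivalError("log-rank test needs >= 2 groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards, Breslow ties
# ---------------------------------------------------------------------------

def _cox_loglik(beta, times, events, X):
    """Breslow partial log-likelihood, gradient and information matrix."""
    eta = X @ beta
    # center the linear predictor for numerical stability; the centering
    # cancels exactly in the partial likelihood when applied consistently
    eta = eta - eta.mean()
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # decreasing time
    ts, es, Xs, ws, etas = times[order], events[order], X[order], w[order], eta[order]
    n, q = Xs.shape
    ll = 0.0
    grad = np.zeros(q)
    info = np.zeros((q, q))
    s0 = 0.0
    s1 = np.zeros(q)
    s2 = np.zeros((q, q))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        for k in range(i, j):  # extend risk set with everyone at this time
            s0 += ws[k]
            s1 += ws[k] * Xs[k]
            s2 += ws[k] * np.outer(Xs[k], Xs[k])
        d_idx = [k for k in range(i, j) if es[k] == 1]
        d = len(d_idx)
        if d:
            xbar = s1 / s0
            ll += float(etas[d_idx].sum()) - d * np.log(s0)
            grad += Xs[d_idx].sum(axis=0) - d * xbar
            info += d * (s2 / s0 - np.outer(xbar, xbar))
        i = j
    return ll, grad, info


def cox_fit(times, events, covariates, names=None, max_iter: int = 100,
            tol: float = 1e-9) -> CoxResult:
    """Cox PH by Newton–Raphson on the Breslow partial likelihood.

    Returns per-covariate beta, SE (inverse information), Wald z and
    two-sided normal p.  Non-convergence or separation flags the result.
    """
    times, events, X = _clean(times, events, covariates)
    n, q = X.shape
    if names is None:
        names = [f"x{k}" for k in range(q)]
    if events.sum() < 1:
        raise SurvivalError("Cox model needs at least one event")
    beta = np.zeros(q)
    converged = False
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, grad, info = _cox_loglik(beta, times, events, X)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving to keep the likelihood ascending
        scale = 1.0
        for _ in range(20):
            cand = beta + scale * step
            ll_new, _, _ = _cox_loglik(cand, times, events, X)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(grad)) < tol or abs(ll - ll_old) < tol * (abs(ll) + 1):
            converged = True
            break
        ll_old = ll
    _, _, info = _cox_loglik(beta, times, events, X)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(q, np.nan)
        converged = False
    if np.max(np.abs(beta)) > 15:  # hallmark of complete separation
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return CoxResult(list(names), beta, se, z, p, converged, n, int(events.sum()))


# ---------------------------------------------------------------------------
# graph integration
# ---------------------------------------------------------------------------

def survival_link_estimates(graph: ModelGraph, cohort: Cohort,
                            fit: FitResult | None = None) -> list[ParameterEstimate]:
    """Estimate all graph edges that point into survival nodes.

    One Cox model per survival node with all its parents as simultaneous
    covariates; latent parents are represented by their factor scores from
    the SEM ``fit``.  Returned estimates merge into the unified parameter
    table (op ``"~"``, lhs = the survival node)."""
    estimates: list[ParameterEstimate] = []
    ram = fit.ram if fit is not None else None
    for node in graph.nodes.values():
        if node.kind != "observed" or node.var_id not in cohort:
            continue
        if cohort.variable(node.var_id).dtype != "survival":
            continue
        parents = graph.parents(node.id)
        if not parents:
            continue
        surv = cohort.survival_frame(node.var_id)
        cols = {}
        for par in parents:
            pnode = graph.nodes[par]
            if pnode.kind == "latent":
                if fit is None or not fit.converged:
                    raise SemError(
                        f"latent parent {par!r} of {node.id!r} needs a converged SEM fit"
                    )
                ram_here, data = compile_graph(graph, cohort)
                scores = factor_scores(fit, data)
                cols[par] = scores[par].reindex(surv.index)
            else:
                cols[par] = pd.Series(cohort.values(pnode.var_id),
                                      index=cohort.sample_ids).reindex(surv.index)
        X = pd.DataFrame(cols)
        res = cox_fit(surv["time"].to_numpy(), surv["event"].to_numpy(),
                      X.to_numpy(), names=list(X.columns))
        for k, par in enumerate(res.names):
            estimates.append(
                ParameterEstimate(node.id, "~", par, float(res.beta[k]),
                                  float(res.se[k]), float(res.z[k]), float(res.p[k]))
            )
    return estimates


def median_split(values, labels=("low", "high")) -> np.ndarray:
    """Split at the median: <= median -> low, > median -> high (object array,
    missing stays None)."""
    values = np.asarray(values, dtype=float)
    obs = values[~np.isnan(values)]
    if np.unique(obs).size < 2:
        raise SurvivalError("median_split needs >= 2 distinct values")
    med = np.median(obs)
    out = np.full(values.shape, None, dtype=object)
    lo, hi = labels
    for i, v in enumerate(values):
        if not np.isnan(v):
            out[i] = hi if v > med else lo
    return out
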