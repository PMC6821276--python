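"""Covariance structural equation modeling in the RAM parameterization.

A model graph compiles to three matrices over the ordered variables
(observed first, then latent): ``A`` holds directed-path coefficients
(``A[i, j]`` = coefficient on the edge j→i), ``S`` holds symmetric
(co)variances, and ``F`` filters out the latent rows.  The model-implied
covariance is

    Sigma = F (I - A)^-1 S (I - A)^-T F^T

and parameters are estimated by minimizing the normal-theory maximum
likelihood discrepancy

    F_ML = ln|Sigma| + tr(S_obs Sigma^-1) - ln|S_obs| - p

with a quasi-Newton optimizer and an analytic gradient.  Standard errors come
from the observed information (Hessian of F_ML scaled by 2/(n-1)),
z = estimate/SE with two-sided normal p-values.  chi^2 = (n-1) F_ML at the
optimum feeds the comparative (TLI, CFI) and absolute (RMSEA, SRMR) fit
indices; the chi-square p-value itself is deliberately not reported, being
overly sensitive to cohort size.

Binary and ordinal variables are numerically coded (0/1 and integer codes)
and enter the covariance; this linear treatment is a documented
approximation.  Survival nodes are excluded here and handled by the hybrid
Cox stage in :mod:`graphsem.survival`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import Cohort
from .model_graph import COVARIANCE, LOADING, REGRESSION, GraphError, ModelGraph

__all__ = [
    "RAMSpec", "ParameterEstimate", "FitIndices", "FitResult",
    "compile_graph", "implied_covariance", "ml_discrepancy", "fit_sem",
    "fit_indices", "baseline_chisq", "effect_decomposition", "factor_scores",
    "fit_multi_cohort",
]


class SemError(ValueError):
    pass


@dataclass(frozen=True)
class FreeParam:
    """One free entry of A or S.  ``lhs op rhs`` follows the text syntax
    (op "~" path, "=~" loading, "~~" variance/covariance)."""

    matrix: str  # "A" or "S"
    i: int
    j: int
    lhs: str
    op: str
    rhs: str
    start: float


@dataclass
class RAMSpec:
    """Compiled matrix form of a model graph."""

    var_order: list[str]          # observed modeled columns first, latents last
    n_observed: int
    A_fixed: np.ndarray
    S_fixed: np.ndarray
    free: list[FreeParam]
    latent_ids: list[str]
    survival_nodes: list[str]     # excluded sinks, handled by the Cox stage
    column_of: dict[str, str]     # node id -> data column (observed nodes)

    @property
    def n_free(self) -> int:
        return len(self.free)

    @property
    def F(self) -> np.ndarray:
        m = len(self.var_order)
        return np.eye(m)[: self.n_observed]

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = self.A_fixed.copy()
        S = self.S_fixed.copy()
        for val, par in zip(theta, self.free):
            if par.matrix == "A":
                A[par.i, par.j] = val
            else:
                S[par.i, par.j] = val
                S[par.j, par.i] = val
        return A, S

    def df(self, include_means: bool = False) -> int:
        p = self.n_observed
        return p * (p + 1) // 2 - self.n_free


@dataclass(frozen=True)
class ParameterEstimate:
    lhs: str
    op: str
    rhs: str
    estimate: float
    se: float
    z: float
    p: float
    std_estimate: float | None = None

    @property
    def label(self) -> str:
        return f"{self.lhs} {self.op} {self.rhs}"


@dataclass
class FitIndices:
    chisq: float
    df: int
    tli: float | None
    cfi: float | None
    rmsea: float | None
    srmr: float
    n_samples: int
    converged: bool
    n_iterations: int


@dataclass
class FitResult:
    estimates: list[ParameterEstimate]
    indices: FitIndices | None
    implied_cov: np.ndarray | None
    sample_cov: np.ndarray
    ram: RAMSpec
    theta: np.ndarray
    cohort_name: str = ""
    converged: bool = True
    stable: bool | None = None  # spectral radius < 1 for cyclic models

    def estimate(self, lhs: str, op: str, rhs: str) -> ParameterEstimate:
        for est in self.estimates:
            if (est.lhs, est.op, est.rhs) == (lhs, op, rhs):
                return est
        raise KeyError(f"no parameter {lhs} {op} {rhs}")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cohort": self.cohort_name, "lhs": e.lhs, "op": e.op, "rhs": e.rhs,
                    "estimate": e.estimate, "se": e.se, "z": e.z, "p": e.p,
                    "std_estimate": e.std_estimate,
                }
                for e in self.estimates
            ]
        )


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def _numeric_columns(cohort: Cohort, node_var: str) -> list[str]:
    """Data columns encoding one observed node (k-1 dummies for categorical)."""
    var = cohort.variable(node_var)
    if var.dtype in ("continuous", "binary", "ordinal"):
        return [node_var]
    if var.dtype == "categorical":
        k = len(var.labels or ())
        if k < 2:
            raise SemError(f"categorical {node_var!r} needs >=2 labels")
        if k == 2:
            return [node_var]  # single 0/1 dummy, baseline = first label
        return [f"{node_var}={lab}" for lab in var.labels[1:]]
    raise SemError(f"variable {node_var!r} of dtype {var.dtype} cannot enter the SEM")


def _encode_data(cohort: Cohort, node_vars: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for nv in node_vars:
        var = cohort.variable(nv)
        vals = cohort.values(nv)
        if var.dtype == "categorical" and var.labels and len(var.labels) > 2:
            for j, lab in enumerate(var.labels[1:], start=1):
                cols[f"{nv}={lab}"] = np.where(np.isnan(vals), np.nan,
                                               (vals == j).astype(float))
        else:
            cols[nv] = vals
    return pd.DataFrame(cols, index=cohort.sample_ids)


def compile_graph(graph: ModelGraph, cohort: Cohort) -> tuple[RAMSpec, pd.DataFrame]:
    """Compile a validated graph against a cohort.

    Returns the RAM specification and the listwise-complete data matrix over
    the modeled observed columns.  Survival nodes are recorded but excluded
    from the covariance model; the latent scale is identified by fixing each
    factor's first loading to 1.  By default, free covariances are added
    among all pairs of exogenous observed variables (standard SEM
    convention), unless the graph opts out.
    """
    survival_nodes = []
    modeled_nodes = []
    for node in graph.nodes.values():
        if node.kind == "observed" and node.var_id in cohort \
                and cohort.variable(node.var_id).dtype == "survival":
            survival_nodes.append(node.id)
        else:
            modeled_nodes.append(node)
    for e in graph.regressions():
        if e.src in survival_nodes:
            raise GraphError(f"survival node {e.src!r} may only be a sink")

    obs_nodes = [n for n in modeled_nodes if n.kind == "observed"]
    latent_ids = [n.id for n in modeled_nodes if n.kind == "latent"]
    if not obs_nodes:
        # survival-only model: nothing for the covariance stage
        ram = RAMSpec([], 0, np.zeros((0, 0)), np.zeros((0, 0)), [], [],
                      survival_nodes, {})
        return ram, pd.DataFrame(index=cohort.sample_ids)

    # expand observed nodes to data columns; categorical => k-1 dummies
    column_of: dict[str, str] = {}
    obs_cols: list[str] = []
    node_of_col: dict[str, str] = {}
    for n in obs_nodes:
        cols = _numeric_columns(cohort, n.var_id)
        if len(cols) == 1:
            column_of[n.id] = n.var_id
        else:
            column_of[n.id] = cols[0]  # representative; edges expand below
        for c in cols:
            obs_cols.append(c)
            node_of_col[c] = n.id
    cols_of_node = {}
    for n in obs_nodes:
        cols_of_node[n.id] = _numeric_columns(cohort, n.var_id)

    var_order = obs_cols + latent_ids
    idx = {v: i for i, v in enumerate(var_order)}
    m = len(var_order)
    p = len(obs_cols)

    data = _encode_data(cohort, [n.var_id for n in obs_nodes])
    data = data[obs_cols].dropna(axis=0, how="any")
    if len(data) < 3:
        raise SemError(f"only {len(data)} complete samples; need >= 3")
    samp_var = data.var(ddof=1)

    def expand(node_id: str) -> list[str]:
        """Matrix-row names for a node (data columns, or the latent itself)."""
        return cols_of_node.get(node_id, [node_id])

    A_fixed = np.zeros((m, m))
    S_fixed = np.zeros((m, m))
    free: list[FreeParam] = []

    def var_start(name: str) -> float:
        if name in samp_var.index:
            return max(0.5 * float(samp_var[name]), 0.05)
        return 0.5  # latent

    # regression paths
    for e in graph.regressions():
        if e.dst in survival_nodes:
            continue
        for src_col in expand(e.src):
            for dst_col in expand(e.dst):
                i, j = idx[dst_col], idx[src_col]
                if e.fixed_value is not None:
                    A_fixed[i, j] = e.fixed_value
                else:
                    free.append(FreeParam("A", i, j, dst_col, "~", src_col, 0.1))

    # factor loadings: first fixed to 1
    for latent in latent_ids:
        loads = graph.loadings(latent)
        for k, e in enumerate(loads):
            for dst_col in expand(e.dst):
                i, j = idx[dst_col], idx[latent]
                if e.fixed_value is not None:
                    A_fixed[i, j] = e.fixed_value
                elif k == 0:
                    A_fixed[i, j] = 1.0
                else:
                    free.append(FreeParam("A", i, j, latent, "=~", dst_col, 1.0))

    # endogenous = any incoming path/loading; everything gets a (residual) variance
    has_parent = {v: False for v in var_order}
    for par in free:
        if par.matrix == "A":
            has_parent[par.lhs if par.op == "~" else par.rhs] = True
    nz = np.argwhere(A_fixed != 0)
    for i, j in nz:
        has_parent[var_order[i]] = True
    for v in var_order:
        i = idx[v]
        free.append(FreeParam("S", i, i, v, "~~", v, var_start(v)))

    # explicit covariance edges
    for e in graph.covariances():
        for a in expand(e.src):
            for b in expand(e.dst):
                i, j = idx[a], idx[b]
                if e.fixed_value is not None:
                    S_fixed[i, j] = S_fixed[j, i] = e.fixed_value
                else:
                    free.append(FreeParam("S", i, j, a, "~~", b, 0.0))

    # default covariances among exogenous observed columns
    if graph.auto_covary_exogenous:
        explicit = {(par.i, par.j) for par in free if par.matrix == "S"}
        explicit |= {(j, i) for i, j in explicit}
        exo = [c for c in obs_cols if not has_parent[c]]
        for a_i in range(len(exo)):
            for b_i in range(a_i + 1, len(exo)):
                i, j = idx[exo[a_i]], idx[exo[b_i]]
                if (i, j) not in explicit and S_fixed[i, j] == 0:
                    free.append(FreeParam("S", i, j, exo[a_i], "~~", exo[b_i], 0.0))

    ram = RAMSpec(var_order, p, A_fixed, S_fixed, free, latent_ids,
                  survival_nodes, column_of)
    if ram.df() < 0:
        raise SemError(f"model not identified: df = {ram.df()} < 0")
    return ram, data


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def implied_covariance(ram: RAMSpec, theta: np.ndarray) -> np.ndarray:
    """Sigma = F (I-A)^-1 S (I-A)^-T F^T over the observed variables."""
    A, S = ram.matrices(np.asarray(theta, dtype=float))
    m = A.shape[0]
    eye = np.eye(m)
    try:
        B = np.linalg.solve(eye - A, eye)
    except np.linalg.LinAlgError:
        raise SemError("non-invertible path structure (I - A singular)") from None
    full = B @ S @ B.T
    return full[: ram.n_observed, : ram.n_observed]


def ml_discrepancy(s_obs: np.ndarray, sigma: np.ndarray) -> float:
    """Normal-theory ML fit function; >= 0, zero iff Sigma = S_obs."""
    s_obs = np.asarray(s_obs, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    p = s_obs.shape[0]
    if s_obs.shape != sigma.shape:
        raise SemError("covariance order mismatch")
    sign_s, logdet_s = np.linalg.slogdet(s_obs)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise SemError("covariance matrices must be positive definite")
    return float(logdet_m + np.trace(s_obs @ np.linalg.inv(sigma)) - logdet_s - p)


def _fml_and_grad(ram: RAMSpec, theta: np.ndarray, s_obs: np.ndarray):
    """F_ML and its analytic gradient.

    dF/dtheta_k = tr[(Sigma^-1 - Sigma^-1 S_obs Sigma^-1) dSigma/dtheta_k],
    with dSigma assembled from dA (paths) or dS (variances) via the RAM
    identity.
    """
    A, S = ram.matrices(theta)
    m = A.shape[0]
    p = ram.n_observed
    eye = np.eye(m)
    try:
        B = np.linalg.solve(eye - A, eye)  # (I-A)^-1
    except np.linalg.LinAlgError:
        return np.inf, np.full(ram.n_free, np.nan)
    full = B @ S @ B.T
    sigma = full[:p, :p]
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_m <= 0:
        return np.inf, np.full(ram.n_free, np.nan)
    sigma_inv = np.linalg.inv(sigma)
    sign_s, logdet_s = np.linalg.slogdet(s_obs)
    fml = logdet_m + float(np.trace(s_obs @ sigma_inv)) - logdet_s - p

    # W = dF/dSigma (observed block), lifted to the full order with F^T W F
    W = sigma_inv - sigma_inv @ s_obs @ sigma_inv
    W_full = np.zeros((m, m))
    W_full[:p, :p] = W
    # For theta_k in A: dSigma_full = B dA B S B^T + transpose
    # tr(W dSigma) = 2 * (B^T W_full B S B^T)[i, j] for dA = E_ij
    BSBt = B @ S @ B.T
    M_A = 2.0 * (B.T @ W_full @ BSBt)          # index [i, j]
    M_S = B.T @ W_full @ B                      # for dS = E_ij + E_ji (i != j)
    grad = np.empty(ram.n_free)
    for k, par in enumerate(ram.free):
        if par.matrix == "A":
            grad[k] = M_A[par.i, par.j]
        elif par.i == par.j:
            grad[k] = M_S[par.i, par.i]
        else:
            grad[k] = 2.0 * M_S[par.i, par.j]
    return fml, grad


def _hessian_fd(fun_grad, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    q = theta.size
    H = np.zeros((q, q))
    for k in range(q):
        step = eps * max(1.0, abs(theta[k]))
        tp = theta.copy(); tp[k] += step
        tm = theta.copy(); tm[k] -= step
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        H[:, k] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


def baseline_chisq(s_obs: np.ndarray, n: int) -> tuple[float, int]:
    """Independence-baseline chi-square for the comparative indices.

    The baseline frees only the p variances, so its ML discrepancy has the
    closed form F_b = -ln|R| with R the sample correlation matrix;
    chi^2_b = (n-1) F_b, df_b = p(p-1)/2.
    """
    s_obs = np.asarray(s_obs, dtype=float)
    p = s_obs.shape[0]
    if p < 2:
        raise SemError("baseline needs >= 2 variables")
    d = np.sqrt(np.diag(s_obs))
    R = s_obs / np.outer(d, d)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise SemError("singular sample correlation matrix")
    return float(-(n - 1) * logdet), p * (p - 1) // 2


def fit_indices(chisq_m: float, df_m: int, chisq_b: float, df_b: int, n: int,
                s_obs: np.ndarray, sigma_hat: np.ndarray) -> tuple:
    """TLI, CFI, RMSEA, SRMR from model and baseline chi-squares.

    TLI is reported unclipped; with df_m = 0 (saturated) TLI and RMSEA are
    not applicable and returned as None.
    """
    if df_b <= 0:
        raise SemError("baseline df must be positive")
    if df_m > 0:
        ratio_b = chisq_b / df_b
        ratio_m = chisq_m / df_m
        tli = (ratio_b - ratio_m) / (ratio_b - 1.0) if ratio_b != 1.0 else None
        rmsea = float(np.sqrt(max(chisq_m - df_m, 0.0) / (df_m * (n - 1))))
    else:
        tli = None
        rmsea = None
    denom = max(chisq_b - df_b, chisq_m - df_m, 0.0)
    cfi = 1.0 - max(chisq_m - df_m, 0.0) / denom if denom > 0 else 1.0
    d = np.sqrt(np.diag(s_obs))
    resid = (s_obs - sigma_hat) / np.outer(d, d)
    iu = np.triu_indices(s_obs.shape[0])
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return tli, cfi, rmsea, srmr


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _standardized(ram: RAMSpec, theta: np.ndarray) -> dict[int, float]:
    """Standardized path/loading estimates: b * sd(src)/sd(dst) on the
    model-implied metric."""
    A, S = ram.matrices(theta)
    m = A.shape[0]
    eye = np.eye(m)
    try:
        B = np.linalg.solve(eye - A, eye)
    except np.linalg.LinAlgError:
        return {}
    full = B @ S @ B.T
    sd = np.sqrt(np.clip(np.diag(full), 0, None))
    out = {}
    for k, par in enumerate(ram.free):
        if par.matrix == "A":
            if sd[par.i] > 0:
                out[k] = theta[k] * sd[par.j] / sd[par.i]
        else:
            if sd[par.i] > 0 and sd[par.j] > 0:
                out[k] = theta[k] / (sd[par.i] * sd[par.j])
    return out


def fit_sem(ram: RAMSpec, data: pd.DataFrame, cohort_name: str = "",
            max_iter: int = 500) -> FitResult:
    """Fit a compiled RAM model by quasi-Newton ML.

    Convergence: gradient max-norm < 1e-6 or relative F_ML change < 1e-10.
    SEs from the observed information; chi^2 = (n-1) F_ML at the optimum.
    """
    n = len(data)
    p = ram.n_observed
    if p == 0:
        raise SemError("nothing to fit: model has no non-survival observed variables")
    if n <= p:
        raise SemError(f"need n > p complete samples (n={n}, p={p})")
    X = data[ram.var_order[:p]].to_numpy(dtype=float)
    s_obs = np.cov(X, rowvar=False, ddof=1)
    s_obs = np.atleast_2d(s_obs)

    theta0 = np.array([par.start for par in ram.free], dtype=float)
    fun_grad = lambda th: _fml_and_grad(ram, th, s_obs)

    res = optimize.minimize(
        fun_grad, theta0, jac=True, method="BFGS",
        options={"gtol": 1e-6, "maxiter": max_iter},
    )
    # one Newton-ish polish via L-BFGS-B if BFGS stalled above tolerance
    if not res.success and np.max(np.abs(res.jac)) > 1e-4:
        res2 = optimize.minimize(
            fun_grad, res.x, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-8},
        )
        if res2.fun <= res.fun:
            res = res2
    theta = res.x
    fml, grad = fun_grad(theta)
    converged = bool(np.isfinite(fml)) and (
        res.success or np.max(np.abs(grad)) < 1e-4 or fml < 1e-10
    )

    A, _ = ram.matrices(theta)
    radius = float(np.max(np.abs(np.linalg.eigvals(A)))) if A.size else 0.0
    stable = radius < 1.0

    # standard errors from the observed information
    se = np.full(ram.n_free, np.nan)
    if converged:
        H = _hessian_fd(fun_grad, theta)
        info = H * (n - 1) / 2.0
        try:
            cov_theta = np.linalg.inv(info)
            diag = np.diag(cov_theta).copy()
            diag[diag < 0] = np.nan
            se = np.sqrt(diag)
        except np.linalg.LinAlgError:
            warnings.warn("singular information matrix; SEs unavailable", stacklevel=2)

    std = _standardized(ram, theta) if converged else {}
    estimates = []
    for k, par in enumerate(ram.free):
        est = float(theta[k])
        sk = float(se[k]) if np.isfinite(se[k]) else np.nan
        z = est / sk if sk and np.isfinite(sk) and sk > 0 else np.nan
        pval = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        estimates.append(ParameterEstimate(par.lhs, par.op, par.rhs, est, sk, z,
                                           pval, std.get(k)))

    indices = None
    sigma_hat = None
    if converged:
        sigma_hat = implied_covariance(ram, theta)
        chisq = max((n - 1) * fml, 0.0)
        dfm = ram.df()
        if p >= 2:
            chisq_b, df_b = baseline_chisq(s_obs, n)
            tli, cfi, rmsea, srmr = fit_indices(chisq, dfm, chisq_b, df_b, n,
                                                s_obs, sigma_hat)
        else:
            tli = cfi = rmsea = None
            srmr = float(abs(s_obs[0, 0] - sigma_hat[0, 0]) / s_obs[0, 0])
        indices = FitIndices(chisq, dfm, tli, cfi, rmsea, srmr, n,
                             True, int(res.nit))
    return FitResult(estimates, indices, sigma_hat, s_obs, ram, theta,
                     cohort_name=cohort_name, converged=converged, stable=stable)


def fit_graph(graph: ModelGraph, cohort: Cohort) -> FitResult:
    """Convenience: compile and fit in one step."""
    ram, data = compile_graph(graph, cohort)
    return fit_sem(ram, data, cohort_name=cohort.name)


# ---------------------------------------------------------------------------
# effects, scores, multi-cohort
# ---------------------------------------------------------------------------

def effect_decomposition(ram: RAMSpec, theta: np.ndarray, source: str,
                         target: str) -> tuple[float, float, float]:
    """Direct, indirect and total effect of ``source`` on ``target``.

    total = ((I-A)^-1 - I)[target, source]; direct = A[target, source];
    indirect = total - direct.  Requires a stable path matrix
    (spectral radius of A below 1)."""
    A, _ = ram.matrices(np.asarray(theta, dtype=float))
    order = {v: i for i, v in enumerate(ram.var_order)}
    for name in (source, target):
        if name not in order:
            raise SemError(f"{name!r} is not a modeled variable")
    radius = float(np.max(np.abs(np.linalg.eigvals(A)))) if A.size else 0.0
    if radius >= 1.0:
        raise SemError(f"unstable cycle: spectral radius {radius:.3f} >= 1")
    m = A.shape[0]
    total_mat = np.linalg.solve(np.eye(m) - A, np.eye(m)) - np.eye(m)
    i, j = order[target], order[source]
    direct = float(A[i, j])
    total = float(total_mat[i, j])
    return direct, total - direct, total


def factor_scores(fit: FitResult, data: pd.DataFrame) -> pd.DataFrame:
    """Regression-method factor scores for each latent.

    score = Psi_f Lambda^T Sigma^-1 (y - ybar), where Lambda is the observed
    ×latent block of total effects of the latents on the indicators and
    Psi_f the model-implied latent covariance.  Linear in the data; mean 0
    over the fitting samples."""
    if not fit.converged:
        raise SemError("cannot score a non-converged fit")
    ram = fit.ram
    if not ram.latent_ids:
        raise SemError("model has no latent variables")
    A, S = ram.matrices(fit.theta)
    m = A.shape[0]
    p = ram.n_observed
    B = np.linalg.solve(np.eye(m) - A, np.eye(m))
    full = B @ S @ B.T
    lat_idx = [ram.var_order.index(l) for l in ram.latent_ids]
    sigma = full[:p, :p]
    # Lambda: covariance-based loading block cov(y, f) = full[obs, latent]
    cov_yf = full[np.ix_(range(p), lat_idx)]
    weights = np.linalg.solve(sigma, cov_yf)          # p × m_latent
    X = data[ram.var_order[:p]].to_numpy(dtype=float)
    centered = X - X.mean(axis=0)
    scores = centered @ weights
    return pd.DataFrame(scores, index=data.index, columns=ram.latent_ids)


def fit_multi_cohort(graph: ModelGraph, cohorts: Sequence[Cohort]) -> pd.DataFrame:
    """Fit one graph across several cohorts.

    Returns a long-format table (cohort, lhs, op, rhs, estimate, se, z, p);
    cohorts lacking a modeled variable are skipped with a warning, and
    per-cohort failures are recorded rather than fatal."""
    rows = []
    for cohort in cohorts:
        missing = [
            n.var_id for n in graph.nodes.values()
            if n.kind == "observed" and n.var_id not in cohort
            and n.var_id not in {d.get("id") for d in graph.derived}
        ]
        if missing:
            warnings.warn(f"cohort {cohort.name!r} lacks {missing}; skipped", stacklevel=2)
            continue
        try:
            result = fit_graph(graph, cohort)
        except (SemError, GraphError) as exc:
            warnings.warn(f"cohort {cohort.name!r} failed: {exc}", stacklevel=2)
            continue
        rows.append(result.table())
    if not rows:
        return pd.DataFrame(columns=["cohort", "lhs", "op", "rhs", "estimate",
                                     "se", "z", "p", "std_estimate"])
    return pd.concat(rows, ignore_index=True)
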