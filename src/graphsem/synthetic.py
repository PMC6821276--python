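"""Synthetic multi-omics cohorts from a known ground-truth structural model.

Every other module is testable without downloads: a :class:`SimSpec` fixes a
linear structural model with Gaussian disturbances (optionally with latent
factors and stable cycles), Bernoulli mutation indicators (marginal or
logistic on parents), GISTIC-style ordinal copy-number codes obtained by
quantile-thresholding a Gaussian copy signal, and right-censored exponential
survival times whose log-hazard is linear in specified parents.  The same
seed always yields the same cohort, and :func:`write_fixture_files` emits a
file bundle that round-trips exactly through :mod:`graphsem.cohort_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort, Variable
from . import cohort_io


class SimError(ValueError):
    pass


@dataclass
class SimSpec:
    """Ground truth for one simulated cohort.

    binary:     id -> {"prevalence": p} or {"parents": {pid: beta}, "intercept": a}
                (logistic); ids conventionally end in ".Mut".
    structural: id -> {"parents": {pid: coef}, "noise_sd": sd,
                "latent": bool, "source": "mRNA"}; parents may be binary,
                continuous or latent; cycles allowed while stable.
    cnv:        id -> {"freqs": {code: frequency}} over codes -2..2.
    survival:   {"id": ..., "baseline_hazard": h0, "betas": {pid: beta},
                "censoring_rate": r} or None.
    """

    n_samples: int = 500
    seed: int = 0
    name: str = "SIM"
    binary: Mapping[str, Mapping] = field(default_factory=dict)
    structural: Mapping[str, Mapping] = field(default_factory=dict)
    cnv: Mapping[str, Mapping] = field(default_factory=dict)
    survival: Mapping | None = None


def _source_for(var_id: str, entry: Mapping) -> str:
    if "source" in entry:
        return entry["source"]
    if var_id.endswith(".RNA"):
        return "mRNA"
    if var_id.endswith(".RPPA"):
        return "RPPA"
    if var_id.endswith(".miRNA"):
        return "miRNA"
    return "Clinical"


def _structural_order_matrix(spec: SimSpec) -> tuple[list[str], np.ndarray]:
    ids = list(spec.structural)
    index = {v: i for i, v in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)))
    for vid, entry in spec.structural.items():
        for pid, coef in entry.get("parents", {}).items():
            if pid in index:
                A[index[vid], index[pid]] = coef
    if A.size:
        radius = float(np.max(np.abs(np.linalg.eigvals(A))))
        if radius >= 1.0:
            raise SimError(f"unstable structural cycle (spectral radius {radius:.3f})")
    return ids, A


def implied_truth_cov(spec: SimSpec) -> tuple[list[str], np.ndarray]:
    """Ground-truth covariance over (binary + structural) variables.

    Binary variables are treated as independent exogenous inputs with
    variance p(1-p) (exact for marginal Bernoulli specs)."""
    bin_ids = list(spec.binary)
    str_ids, A_ss = _structural_order_matrix(spec)
    nb, ns = len(bin_ids), len(str_ids)
    order = bin_ids + str_ids
    A = np.zeros((nb + ns, nb + ns))
    A[nb:, nb:] = A_ss
    for vid, entry in spec.structural.items():
        i = nb + str_ids.index(vid)
        for pid, coef in entry.get("parents", {}).items():
            if pid in bin_ids:
                A[i, bin_ids.index(pid)] = coef
    S = np.zeros((nb + ns, nb + ns))
    for j, bid in enumerate(bin_ids):
        prev = spec.binary[bid].get("prevalence")
        if prev is None:
            raise SimError(f"implied covariance needs marginal prevalence for {bid!r}")
        S[j, j] = prev * (1 - prev)
    for j, sid in enumerate(str_ids):
        sd = spec.structural[sid].get("noise_sd", 1.0)
        S[nb + j, nb + j] = sd ** 2
    m = nb + ns
    B = np.linalg.solve(np.eye(m) - A, np.eye(m))
    return order, B @ S @ B.T


def simulate_cohort(spec: SimSpec) -> tuple[Cohort, dict]:
    """Draw one cohort; returns (cohort, ground-truth record)."""
    for bid, entry in spec.binary.items():
        prev = entry.get("prevalence")
        if prev is not None and not (0 < prev < 1):
            raise SimError(f"prevalence of {bid!r} must be in (0,1)")
    if spec.survival is not None:
        r = spec.survival.get("censoring_rate", 0.0)
        if not (0 <= r < 1):
            raise SimError("censoring_rate must be in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = [f"S{i:05d}" for i in range(n)]
    columns: dict[str, np.ndarray] = {}

    # binary nodes (marginal first, then logistic on already-drawn parents)
    marginal = {k: v for k, v in spec.binary.items() if "prevalence" in v}
    logistic = {k: v for k, v in spec.binary.items() if "prevalence" not in v}
    for bid, entry in marginal.items():
        columns[bid] = (rng.random(n) < entry["prevalence"]).astype(float)
    for bid, entry in logistic.items():
        eta = np.full(n, float(entry.get("intercept", 0.0)))
        for pid, beta in entry.get("parents", {}).items():
            if pid not in columns:
                raise SimError(f"logistic parent {pid!r} of {bid!r} not yet generated")
            eta = eta + beta * columns[pid]
        prob = 1.0 / (1.0 + np.exp(-eta))
        columns[bid] = (rng.random(n) < prob).astype(float)

    # structural system, solved jointly (supports stable cycles)
    str_ids, A_ss = _structural_order_matrix(spec)
    if str_ids:
        E = np.zeros((n, len(str_ids)))
        for j, sid in enumerate(str_ids):
            entry = spec.structural[sid]
            sd = float(entry.get("noise_sd", 1.0))
            eps = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
            for pid, coef in entry.get("parents", {}).items():
                if pid in columns:  # binary (or previously fixed) exogenous input
                    eps = eps + coef * columns[pid]
                elif pid not in str_ids:
                    raise SimError(f"unknown parent {pid!r} of {sid!r}")
            E[:, j] = eps
        Y = np.linalg.solve(np.eye(len(str_ids)) - A_ss, E.T).T
        for j, sid in enumerate(str_ids):
            columns[sid] = Y[:, j]

    # ordinal copy-number codes by quantile-thresholding a Gaussian signal
    for cid, entry in spec.cnv.items():
        freqs = dict(entry.get("freqs", {0: 1.0}))
        total = sum(freqs.values())
        if not np.isclose(total, 1.0):
            raise SimError(f"CNV frequencies for {cid!r} must sum to 1")
        signal = rng.normal(size=n)
        codes = sorted(freqs)  # ascending -2..2
        cuts = np.cumsum([freqs[c] for c in codes])[:-1]
        thresholds = np.quantile(signal, cuts)
        columns[cid] = np.array(
            [codes[int(np.searchsorted(thresholds, s, side="right"))] for s in signal],
            dtype=float,
        )

    variables: list[Variable] = []
    data: dict[str, np.ndarray] = {}
    for bid in spec.binary:
        variables.append(Variable(bid, "Mutation", "binary"))
        data[bid] = columns[bid]
    for sid, entry in spec.structural.items():
        if entry.get("latent"):
            continue  # latent ground truth is returned but not observed
        variables.append(Variable(sid, _source_for(sid, entry), "continuous"))
        data[sid] = columns[sid]
    for cid in spec.cnv:
        variables.append(Variable(cid, "CNV", "ordinal"))
        data[cid] = columns[cid]

    truth: dict = {"columns": {k: v.copy() for k, v in columns.items()},
                   "spec": spec}
    if all("prevalence" in v for v in spec.binary.values()):
        order, cov = implied_truth_cov(spec)
        truth["implied_order"] = order
        truth["implied_cov"] = cov

    if spec.survival is not None:
        sv = spec.survival
        sid = sv.get("id", "OS.Survival")
        h0 = float(sv.get("baseline_hazard", 0.01))
        eta = np.zeros(n)
        for pid, beta in sv.get("betas", {}).items():
            if pid not in columns:
                raise SimError(f"survival parent {pid!r} not generated")
            eta = eta + beta * columns[pid]
        hazard = h0 * np.exp(eta)
        T = rng.exponential(1.0 / hazard)
        rate = float(sv.get("censoring_rate", 0.0))
        if rate > 0:
            cmax = _censoring_horizon(T, rate)
            C = rng.uniform(0, cmax, size=n)
            times = np.minimum(T, C)
            events = (T <= C).astype(float)
        else:
            times, events = T, np.ones(n)
        variables.append(Variable(sid, "Survival", "survival"))
        data[f"{sid}__time"] = times
        data[f"{sid}__event"] = events
        truth["survival_latent_times"] = T

    cohort = Cohort.from_columns(spec.name, samples, data, variables)
    return cohort, truth


def _censoring_horizon(T: np.ndarray, rate: float) -> float:
    """Uniform-horizon upper bound giving the target expected censored
    fraction on the drawn event times (bisection)."""
    lo, hi = 1e-9, float(T.max()) * 100
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(np.minimum(T / mid, 1.0)))  # P(C < T | T)
        if frac > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

def write_fixture_files(cohort: Cohort, out_dir,
                        time_col: str = "OS_time", event_col: str = "OS_event") -> dict:
    """Write a cohort as the standard file bundle.

    expression.tsv / cnv.tsv (gene × sample), mutations.maf, clinical.tsv —
    each exactly loadable by :mod:`graphsem.cohort_io`; float values are
    written at shortest round-trip precision so write→load is the identity.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = cohort.sample_ids
    paths: dict[str, Path] = {}

    expr_rows = {}
    for var in cohort.variables.values():
        if var.source in ("mRNA", "miRNA", "RPPA") and var.dtype == "continuous":
            gene = var.id.rsplit(".", 1)[0]
            expr_rows[gene] = cohort.values(var.id)
    if expr_rows:
        frame = pd.DataFrame(expr_rows, index=samples).T
        frame.index.name = "gene"
        paths["expression"] = out / "expression.tsv"
        frame.to_csv(paths["expression"], sep="\t", float_format="%.17g")

    mut_vars = [v for v in cohort.variables.values() if v.source == "Mutation"]
    if mut_vars:
        rows = []
        for var in mut_vars:
            gene = var.id.rsplit(".", 1)[0]
            vals = cohort.values(var.id)
            for s, v in zip(samples, vals):
                if v == 1.0:
                    rows.append((gene, s, "Missense_Mutation"))
        maf = pd.DataFrame(rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                                          "Variant_Classification"])
        paths["maf"] = out / "mutations.maf"
        maf.to_csv(paths["maf"], sep="\t", index=False)

    cnv_rows = {}
    for var in cohort.variables.values():
        if var.source == "CNV":
            gene = var.id.rsplit(".", 1)[0]
            cnv_rows[gene] = cohort.values(var.id).astype(int)
    if cnv_rows:
        frame = pd.DataFrame(cnv_rows, index=samples).T
        frame.index.name = "gene"
        paths["cnv"] = out / "cnv.tsv"
        frame.to_csv(paths["cnv"], sep="\t")

    surv_ids = cohort.survival_ids()
    clin = pd.DataFrame(index=pd.Index(samples, name="sample"))
    if surv_ids:
        sf = cohort.survival_frame(surv_ids[0])
        clin[time_col] = sf["time"]
        clin[event_col] = sf["event"].astype(int)
    for var in cohort.variables.values():
        if var.source == "Clinical" and var.dtype == "continuous":
            clin[var.id.rsplit(".", 1)[0]] = cohort.values(var.id)
    if len(clin.columns):
        paths["clinical"] = out / "clinical.tsv"
        clin.to_csv(paths["clinical"], sep="\t", float_format="%.17g")
    return paths


def load_fixture_bundle(paths: Mapping, name: str = "SIM",
                        time_col: str = "OS_time", event_col: str = "OS_event",
                        cohort_samples=None) -> Cohort:
    """Re-assemble a cohort from a write_fixture_files bundle."""
    parts = []
    if "expression" in paths:
        parts.append(cohort_io.load_expression_matrix(paths["expression"], "mRNA"))
    if "clinical" in paths:
        parts.append(cohort_io.load_clinical(paths["clinical"], time_col, event_col))
    if "cnv" in paths:
        parts.append(cohort_io.load_gistic_cnv(paths["cnv"]))
    if "maf" in paths:
        if cohort_samples is None:
            if parts:
                cohort_samples = parts[0].sample_ids
            else:
                raise SimError("MAF-only bundle needs cohort_samples")
        parts.append(cohort_io.load_maf_mutations(paths["maf"], cohort_samples))
    return cohort_io.assemble_cohort(parts, name=name)
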