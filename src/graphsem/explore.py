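"""All-against-all association screening with FDR control.

The screen helps pick variables for a model when prior knowledge is thin:
one seed variable is tested against every candidate of the requested data
types, the statistic dispatching on the dtype pair:

* continuous–continuous: Pearson r, z from t = r*sqrt((n-2)/(1-r^2));
* binary–continuous: point-biserial (pooled two-sample t), signed so that
  positive means higher values in the "1"/mutant group;
* binary–binary: log odds ratio with the Haldane–Anscombe 0.5 correction
  and Woolf SE — positive z is co-occurrence, negative mutual exclusivity;
* anything–survival: Cox Wald z (positive = worse outcome);
* ordinal copy-number codes are treated as numeric.

P-values are Benjamini–Hochberg adjusted within a run; |z| is capped at 38,
beyond which the two-sided normal p underflows double precision.  A screen
can be precomputed into a columnar store and queried for top hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .survival import SurvivalError, cox_fit

Z_CAP = 38.0


class ExploreError(ValueError):
    pass


@dataclass
class AssociationRecord:
    seed: str
    candidate: str
    stat_kind: str
    estimate: float
    z: float
    p: float
    q: float = np.nan
    n_used: int = 0

    def as_dict(self) -> dict:
        return {
            "seed": self.seed, "candidate": self.candidate,
            "stat_kind": self.stat_kind, "estimate": self.estimate,
            "z": self.z, "p": self.p, "q": self.q, "n_used": self.n_used,
        }


def _cap(z: float) -> float:
    if np.isnan(z):
        return z
    return float(np.clip(z, -Z_CAP, Z_CAP))


def _numeric_kind(dtype: str) -> str:
    if dtype in ("continuous", "ordinal"):
        return "numeric"
    if dtype == "binary":
        return "binary"
    if dtype == "categorical":
        return "binary"  # two-level derived variables; multi-level unsupported here
    return dtype


def _pearson(x, y, kind: str) -> tuple[float, float, float, int]:
    n = len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan, np.nan, n
    r, _ = stats.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2 * stats.t.sf(abs(t), df=n - 2)) if np.isfinite(t) else 0.0
    return r, _cap(t), p, n


def _log_odds(x, y) -> tuple[float, float, float, int]:
    n = len(x)
    a = float(np.sum((x == 1) & (y == 1)))
    b = float(np.sum((x == 1) & (y == 0)))
    c = float(np.sum((x == 0) & (y == 1)))
    d = float(np.sum((x == 0) & (y == 0)))
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return np.nan, np.nan, np.nan, n
    a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = float(2 * stats.norm.sf(abs(z)))
    return float(log_or), _cap(z), p, n


def pairwise_association(cohort: Cohort, x_id: str, y_id: str) -> AssociationRecord:
    """Association of two cohort variables, dispatched on their dtype pair.

    Survival may appear on either side; a degenerate (zero-variance) side
    yields a record with missing statistics (still counted in the FDR
    denominator downstream)."""
    x_var, y_var = cohort.variable(x_id), cohort.variable(y_id)

    if "survival" in (x_var.dtype, y_var.dtype):
        if x_var.dtype == "survival" and y_var.dtype == "survival":
            raise ExploreError("cannot associate two survival variables")
        surv_id, other_id = (x_id, y_id) if x_var.dtype == "survival" else (y_id, x_id)
        surv = cohort.survival_frame(surv_id)
        vals = cohort.values(other_id)
        keep = (~np.isnan(vals)) & surv["time"].notna().to_numpy() \
            & surv["event"].notna().to_numpy()
        n = int(keep.sum())
        if n < 3 or np.std(vals[keep]) == 0 or surv["event"].to_numpy()[keep].sum() < 1:
            return AssociationRecord(x_id, y_id, "cox_wald", np.nan, np.nan, np.nan,
                                     n_used=n)
        try:
            res = cox_fit(surv["time"].to_numpy()[keep],
                          surv["event"].to_numpy()[keep], vals[keep])
        except SurvivalError:
            return AssociationRecord(x_id, y_id, "cox_wald", np.nan, np.nan, np.nan,
                                     n_used=n)
        return AssociationRecord(x_id, y_id, "cox_wald", float(res.beta[0]),
                                 _cap(float(res.z[0])), float(res.p[0]), n_used=n)

    x = cohort.values(x_id)
    y = cohort.values(y_id)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ExploreError(f"fewer than 3 complete pairs for ({x_id}, {y_id})")
    kx, ky = _numeric_kind(x_var.dtype), _numeric_kind(y_var.dtype)

    if kx == "binary" and ky == "binary":
        est, z, p, n = _log_odds(x, y)
        return AssociationRecord(x_id, y_id, "log_odds_ratio", est, z, p, n_used=n)
    if kx == "binary" or ky == "binary":
        # point-biserial == Pearson on the 0/1 coding; sign follows the group
        est, z, p, n = _pearson(x, y, "point_biserial")
        return AssociationRecord(x_id, y_id, "point_biserial", est, z, p, n_used=n)
    est, z, p, n = _pearson(x, y, "pearson")
    return AssociationRecord(x_id, y_id, "pearson", est, z, p, n_used=n)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (order-preserving; NaN-tolerant).

    NaN entries still count in the test total m (conservative)."""
    p = np.asarray(pvalues, dtype=float)
    obs = ~np.isnan(p)
    if np.any((p[obs] < 0) | (p[obs] > 1)):
        raise ExploreError("p-values must lie in [0, 1]")
    m = p.size
    q = np.full(m, np.nan)
    idx = np.where(obs)[0]
    if idx.size == 0:
        return q
    order = idx[np.argsort(p[idx], kind="stable")]
    ranked = p[order] * m / (np.arange(1, order.size + 1))
    # enforce monotonicity from the largest rank down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q[order] = np.minimum(ranked, 1.0)
    return q


def screen_variable(
    cohort: Cohort,
    seed_id: str,
    types: Sequence[str] | None = None,
    include_survival: bool = False,
    exclude_same_gene: bool = False,
) -> pd.DataFrame:
    """Screen a seed variable against every candidate of the given sources.

    Returns a frame ranked by |z| (ties broken by candidate id) with BH q
    computed over all attempted tests, degenerate candidates included."""
    cohort.variable(seed_id)
    gene = seed_id.split(".")[0]
    candidates = []
    for var in cohort.variables.values():
        if var.id == seed_id:
            continue
        if var.dtype == "survival":
            if include_survival:
                candidates.append(var.id)
            continue
        if types is not None and var.source not in types:
            continue
        if exclude_same_gene and var.id.split(".")[0] == gene:
            continue
        candidates.append(var.id)
    if not candidates:
        raise ExploreError("empty candidate set")
    records = []
    for cand in candidates:
        try:
            records.append(pairwise_association(cohort, seed_id, cand))
        except ExploreError:
            records.append(AssociationRecord(seed_id, cand, "degenerate",
                                             np.nan, np.nan, np.nan))
    q = bh_fdr([r.p for r in records])
    for rec, qi in zip(records, q):
        rec.q = float(qi) if np.isfinite(qi) else np.nan
    frame = pd.DataFrame([r.as_dict() for r in records])
    frame["_absz"] = frame["z"].abs()
    frame = frame.sort_values(["_absz", "candidate"], ascending=[False, True],
                              na_position="last").drop(columns="_absz")
    return frame.reset_index(drop=True)


def compound_screen(
    cohort: Cohort,
    include: Sequence[tuple[str, float]],
    exclude: Sequence[tuple[str, float]] = (),
    types: Sequence[str] | None = None,
    include_survival: bool = False,
) -> pd.DataFrame:
    """Candidates significant for ALL include seeds and none of the excludes.

    ``include``/``exclude`` are (seed id, q threshold) pairs — e.g. genes
    associated with both a driver mutation and overall survival but not with
    a copy-number confounder.  Returns the include-screen rows of the first
    seed restricted to the surviving candidates."""
    if not include:
        raise ExploreError("compound screen needs >= 1 include condition")
    screens = {}
    for seed, _ in list(include) + list(exclude):
        if seed not in screens:
            screens[seed] = screen_variable(
                cohort, seed, types=types, include_survival=include_survival
            ).set_index("candidate")
    keep: set[str] | None = None
    for seed, thresh in include:
        hits = set(screens[seed].index[screens[seed]["q"] < thresh])
        keep = hits if keep is None else keep & hits
    for seed, thresh in exclude:
        bad = set(screens[seed].index[screens[seed]["q"] < thresh])
        keep -= bad
    first = screens[include[0][0]]
    out = first.loc[sorted(keep)].reset_index()
    return out.sort_values(["z", "candidate"], key=lambda s: s.abs() if s.name == "z" else s,
                           ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# precompute / query store
# ---------------------------------------------------------------------------

STORE_VERSION = "graphsem-screen-1"


def precompute_store(cohort: Cohort, path, types: Sequence[str] | None = None,
                     include_survival: bool = True, chunk_size: int = 200) -> int:
    """Precompute all pairwise associations into a columnar Parquet store.

    Pairs are computed in chunks so the same code handles a fixture and a
    full cohort; returns the number of records written."""
    import pyarrow as pa
    import pyarrow.parquet as pq

    var_ids = [
        v.id for v in cohort.variables.values()
        if (types is None or v.source in types or v.dtype == "survival")
        and (include_survival or v.dtype != "survival")
    ]
    pairs = [(a, b) for i, a in enumerate(var_ids) for b in var_ids[i + 1:]
             if not (cohort.variables[a].dtype == "survival"
                     and cohort.variables[b].dtype == "survival")]
    frames = []
    for start in range(0, len(pairs), chunk_size):
        chunk = pairs[start:start + chunk_size]
        rows = []
        for a, b in chunk:
            try:
                rows.append(pairwise_association(cohort, a, b).as_dict())
            except ExploreError:
                rows.append(AssociationRecord(a, b, "degenerate", np.nan, np.nan,
                                              np.nan).as_dict())
        frames.append(pd.DataFrame(rows))
    table_frame = (pd.concat(frames, ignore_index=True) if frames
                   else pd.DataFrame(columns=["seed", "candidate", "stat_kind",
                                              "estimate", "z", "p", "q", "n_used"]))
    table_frame["q"] = bh_fdr(table_frame["p"].to_numpy()) if len(table_frame) else []
    table = pa.Table.from_pandas(table_frame, preserve_index=False)
    table = table.replace_schema_metadata({b"graphsem_store": STORE_VERSION.encode()})
    pq.write_table(table, path)
    return len(table_frame)


def query_top(path, seed_id: str, k: int = 50, q_max: float | None = None,
              stat_kinds: Sequence[str] | None = None) -> pd.DataFrame:
    """Top-k |z| records for a seed from a precomputed store (pure query)."""
    import pyarrow.parquet as pq

    table = pq.read_table(path)
    meta = table.schema.metadata or {}
    if meta.get(b"graphsem_store", b"").decode() != STORE_VERSION:
        raise ExploreError(f"not a graphsem screen store (or version mismatch): {path}")
    frame = table.to_pandas()
    sel = (frame["seed"] == seed_id) | (frame["candidate"] == seed_id)
    frame = frame[sel].copy()
    flip = frame["candidate"] == seed_id
    frame.loc[flip, ["seed", "candidate"]] = frame.loc[flip, ["candidate", "seed"]].values
    # q over the seed's own run, so a query matches an on-the-fly screen
    frame["q"] = bh_fdr(frame["p"].to_numpy())
    if q_max is not None:
        frame = frame[frame["q"] < q_max]
    if stat_kinds is not None:
        frame = frame[frame["stat_kind"].isin(stat_kinds)]
    frame["_absz"] = frame["z"].abs()
    frame = frame.sort_values(["_absz", "candidate"], ascending=[False, True],
                              na_position="last").drop(columns="_absz")
    return frame.head(k).reset_index(drop=True)
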