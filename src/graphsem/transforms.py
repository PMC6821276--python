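"""Custom variable creation: binarization, grouping and row scaling.

These operations derive new analysis variables from existing cohort columns —
e.g. collapsing GISTIC copy-number codes to ``Diploid``/``Copy Gain``, or
pooling the mutation indicators of a pathway (``NF1``, ``KRAS``, ``NRAS``,
``BRAF`` → ``Ras_MAPK``) into a single ``WT``/``Mutant`` variable.  Derived
variables carry their rule as provenance so reports can be reproduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .cohort import Cohort, CohortError, Variable


class TransformError(ValueError):
    pass


@dataclass(frozen=True)
class GroupingRule:
    """Pool binary member variables into one categorical variable.

    mode="any": positive iff any member is 1; mode="all": positive iff all
    members are 1; mode="custom" applies ``custom_map`` to the member tuple.
    """

    member_ids: tuple[str, ...]
    mode: str = "any"
    category_labels: tuple[str, str] = ("WT", "Mutant")
    custom_map: Callable[[tuple], str] | None = None

    def __post_init__(self):
        if self.mode not in ("any", "all", "custom"):
            raise TransformError(f"unknown grouping mode {self.mode!r}")
        if self.mode == "custom" and self.custom_map is None:
            raise TransformError("mode='custom' requires custom_map")


def binarize(
    cohort: Cohort,
    var_id: str,
    new_id: str,
    *,
    threshold: float | None = None,
    value_map: Mapping[float, str] | None = None,
    labels: tuple[str, str] = ("low", "high"),
) -> Variable:
    """Derive a binary/categorical variable from a continuous or ordinal one.

    Either a ``threshold`` (strictly-greater split with ``labels``) or an
    explicit ``value_map`` from codes to category names.  Codes absent from
    the map become missing.  The source variable is untouched.
    """
    if (threshold is None) == (value_map is None):
        raise TransformError("give exactly one of threshold or value_map")
    vals = cohort.values(var_id)
    if value_map is not None:
        cats = sorted(set(value_map.values()))
        code = {lab: float(i) for i, lab in enumerate(cats)}
        out = np.full(vals.shape, np.nan)
        for i, v in enumerate(vals):
            if not np.isnan(v) and v in value_map:
                out[i] = code[value_map[v]]
        var = Variable(
            new_id, "Derived", "categorical", labels=tuple(cats),
            provenance={"op": "binarize", "source": var_id, "map": dict(value_map)},
        )
    else:
        out = np.where(np.isnan(vals), np.nan, (vals > threshold).astype(float))
        var = Variable(
            new_id, "Derived", "categorical", labels=tuple(labels),
            provenance={"op": "binarize", "source": var_id, "threshold": threshold},
        )
    observed = out[~np.isnan(out)]
    if observed.size and np.unique(observed).size < 2:
        warnings.warn(f"binarize({var_id!r}): single non-missing category", stacklevel=2)
    cohort.add_variable(var, out)
    return var


def median_threshold(cohort: Cohort, var_id: str, new_id: str,
                     labels: tuple[str, str] = ("low", "high")) -> Variable:
    """Binarize at the median: values strictly above the median are 'high'."""
    vals = cohort.values(var_id)
    med = float(np.nanmedian(vals))
    return binarize(cohort, var_id, new_id, threshold=med, labels=labels)


def group_variables(cohort: Cohort, rule: GroupingRule, new_id: str) -> Variable:
    """Apply a :class:`GroupingRule` over sample-aligned binary members.

    Missing members: under mode="any" a single observed 1 suffices for the
    positive category even if co-members are missing; the output is missing
    only when every observed member is 0 and at least one member is missing
    (dually for mode="all").
    """
    members = []
    for mid in rule.member_ids:
        if mid not in cohort:
            raise TransformError(f"unknown member variable {mid!r}")
        var = cohort.variable(mid)
        if var.dtype not in ("binary",):
            raise TransformError(f"member {mid!r} must be binary, got {var.dtype}")
        members.append(cohort.values(mid))
    mat = np.column_stack(members)
    neg, pos = rule.category_labels
    n = mat.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        row = mat[i]
        miss = np.isnan(row)
        if rule.mode == "custom":
            if miss.any():
                continue
            lab = rule.custom_map(tuple(int(v) for v in row))
            out[i] = 1.0 if lab == pos else 0.0
        elif rule.mode == "any":
            if np.nansum(row) >= 1:
                out[i] = 1.0
            elif miss.any():
                out[i] = np.nan
            else:
                out[i] = 0.0
        else:  # all
            if (~miss).all() and row.sum() == len(row):
                out[i] = 1.0
            elif np.any(row[~miss] == 0):
                out[i] = 0.0
            else:
                out[i] = np.nan
    var = Variable(
        new_id, "Derived", "categorical", labels=(neg, pos),
        provenance={"op": "group", "members": list(rule.member_ids), "mode": rule.mode},
    )
    cohort.add_variable(var, out)
    return var


def zscale_rows(matrix: np.ndarray) -> np.ndarray:
    """Scale each row to mean 0, sd 1 (sample sd, n−1) over non-missing cells.

    Constant rows are returned as zeros with a warning.
    """
    mat = np.asarray(matrix, dtype=float).copy()
    for i in range(mat.shape[0]):
        row = mat[i]
        obs = ~np.isnan(row)
        if obs.sum() == 0:
            continue
        mu = row[obs].mean()
        sd = row[obs].std(ddof=1) if obs.sum() > 1 else 0.0
        if sd == 0.0:
            warnings.warn(f"zscale_rows: constant row {i}, left at 0", stacklevel=2)
            mat[i, obs] = 0.0
        else:
            mat[i, obs] = (row[obs] - mu) / sd
    return mat


def materialize_derived(cohort: Cohort, spec: Sequence[Mapping]) -> list[Variable]:
    """Apply the ``derived`` section of a model JSON to a cohort.

    Each entry is ``{"op": "binarize"|"group"|"median_split", ...}`` with the
    keyword fields of the corresponding function.  Already-present derived
    variables (same id) are left as-is.
    """
    created = []
    for entry in spec:
        op = entry.get("op")
        new_id = entry.get("id")
        if new_id is None:
            raise TransformError("derived entry missing 'id'")
        if new_id in cohort:
            continue
        if op == "binarize":
            vmap = entry.get("map")
            if vmap is not None:
                vmap = {float(k): v for k, v in vmap.items()}
            created.append(
                binarize(
                    cohort, entry["source"], new_id,
                    threshold=entry.get("threshold"), value_map=vmap,
                    labels=tuple(entry.get("labels", ("low", "high"))),
                )
            )
        elif op == "median_split":
            created.append(
                median_threshold(
                    cohort, entry["source"], new_id,
                    labels=tuple(entry.get("labels", ("low", "high"))),
                )
            )
        elif op == "group":
            rule = GroupingRule(
                member_ids=tuple(entry["members"]),
                mode=entry.get("mode", "any"),
                category_labels=tuple(entry.get("labels", ("WT", "Mutant"))),
            )
            created.append(group_variables(cohort, rule, new_id))
        else:
            raise TransformError(f"unknown derived op {op!r}")
    return created
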