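"""Typed multi-omics cohort container.

A :class:`Cohort` is a sample-aligned registry of typed variables drawn from
several omics sources (expression, mutations, copy number, clinical,
survival).  Values are held in a single float matrix (``NaN`` = missing);
categorical variables are stored as float codes with their labels on the
:class:`Variable` record, and a survival variable is backed by a pair of
hidden columns (time, event) addressed through :meth:`Cohort.survival_frame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Recognized variable sources.
SOURCES = ("mRNA", "miRNA", "RPPA", "Mutation", "CNV", "Clinical", "Survival", "Derived")

#: Recognized measurement types.
DTYPES = ("continuous", "binary", "ordinal", "categorical", "survival")

#: GISTIC thresholded copy-number codes and their conventional labels.
CNV_LABELS = {
    -2: "deep loss",
    -1: "shallow loss",
    0: "no change",
    1: "gain",
    2: "amplification",
}

_DEFAULT_DTYPE = {
    "mRNA": "continuous",
    "miRNA": "continuous",
    "RPPA": "continuous",
    "Mutation": "binary",
    "CNV": "ordinal",
    "Survival": "survival",
}


class CohortError(ValueError):
    """Raised for malformed cohort inputs."""


@dataclass(frozen=True)
class Variable:
    """A single typed variable, e.g. ``TP53.Mut`` or ``ESR1.RNA``."""

    id: str
    source: str
    dtype: str
    labels: tuple[str, ...] | None = None
    provenance: Mapping | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.source not in SOURCES:
            raise CohortError(f"unknown source {self.source!r} for variable {self.id!r}")
        if self.dtype not in DTYPES:
            raise CohortError(f"unknown dtype {self.dtype!r} for variable {self.id!r}")
        default = _DEFAULT_DTYPE.get(self.source)
        if default is not None and self.source != "Derived" and self.dtype != default:
            raise CohortError(
                f"variable {self.id!r}: source {self.source} implies dtype {default}, "
                f"got {self.dtype}"
            )


def _survival_cols(var_id: str) -> tuple[str, str]:
    return f"{var_id}__time", f"{var_id}__event"


class Cohort:
    """Sample-aligned multi-omics variable registry for one cancer type.

    Parameters
    ----------
    name:
        Cohort label, conventionally a cancer-type code such as ``"LAML"``.
    data:
        Sample × column float frame.  Ordinary variables occupy one column
        named by their id; a survival variable ``S`` occupies two columns
        ``S__time`` and ``S__event``.
    variables:
        Registry of :class:`Variable` records, one per variable id.
    """

    def __init__(self, name: str, data: pd.DataFrame, variables: Mapping[str, Variable]):
        self.name = name
        self._data = data.astype(float)
        self.variables: dict[str, Variable] = dict(variables)
        self._check()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_columns(
        cls,
        name: str,
        sample_ids: Sequence[str],
        columns: Mapping[str, np.ndarray],
        variables: Iterable[Variable],
    ) -> "Cohort":
        frame = pd.DataFrame(
            {k: np.asarray(v, dtype=float) for k, v in columns.items()},
            index=pd.Index(sample_ids, name="sample"),
        )
        return cls(name, frame, {v.id: v for v in variables})

    def _check(self) -> None:
        n = len(self._data)
        seen: set[str] = set()
        for vid, var in self.variables.items():
            if vid != var.id:
                raise CohortError(f"registry key {vid!r} != variable id {var.id!r}")
            if vid in seen:
                raise CohortError(f"duplicate variable id {vid!r}")
            seen.add(vid)
            if var.dtype == "survival":
                tcol, ecol = _survival_cols(vid)
                for col in (tcol, ecol):
                    if col not in self._data.columns:
                        raise CohortError(f"survival variable {vid!r} missing column {col!r}")
                t = self._data[tcol].to_numpy()
                e = self._data[ecol].to_numpy()
                obs = ~np.isnan(t)
                if np.any(t[obs] < 0):
                    raise CohortError(f"negative survival time in {vid!r}")
                eobs = e[~np.isnan(e)]
                if not np.all(np.isin(eobs, (0.0, 1.0))):
                    raise CohortError(f"event indicator of {vid!r} not in {{0,1}}")
            else:
                if vid not in self._data.columns:
                    raise CohortError(f"variable {vid!r} has no value column")
                if len(self._data[vid]) != n:
                    raise CohortError(f"length mismatch for {vid!r}")
                if var.dtype == "ordinal" and var.source == "CNV":
                    vals = self._data[vid].dropna().to_numpy()
                    bad = ~np.isin(vals, (-2.0, -1.0, 0.0, 1.0, 2.0))
                    if bad.any():
                        raise CohortError(f"CNV codes outside -2..2 in {vid!r}")
                if var.dtype == "binary":
                    vals = self._data[vid].dropna().to_numpy()
                    if not np.all(np.isin(vals, (0.0, 1.0))):
                        raise CohortError(f"binary variable {vid!r} has non-0/1 values")

    # -- access ---------------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def n_samples(self) -> int:
        return len(self._data)

    def __contains__(self, var_id: str) -> bool:
        return var_id in self.variables

    def variable(self, var_id: str) -> Variable:
        try:
            return self.variables[var_id]
        except KeyError:
            raise CohortError(f"unknown variable {var_id!r} in cohort {self.name!r}") from None

    def values(self, var_id: str) -> np.ndarray:
        """Sample-aligned float vector for a non-survival variable (NaN = missing)."""
        var = self.variable(var_id)
        if var.dtype == "survival":
            raise CohortError(f"{var_id!r} is a survival variable; use survival_frame()")
        return self._data[var_id].to_numpy(copy=True)

    def mask(self, var_id: str) -> np.ndarray:
        """Boolean missing-value mask (True = missing)."""
        return np.isnan(self.values(var_id))

    def survival_frame(self, var_id: str) -> pd.DataFrame:
        """``(time, event)`` frame for a survival variable, indexed by sample."""
        var = self.variable(var_id)
        if var.dtype != "survival":
            raise CohortError(f"{var_id!r} is not a survival variable")
        tcol, ecol = _survival_cols(var_id)
        out = self._data[[tcol, ecol]].copy()
        out.columns = ["time", "event"]
        return out

    def survival_ids(self) -> list[str]:
        return [v.id for v in self.variables.values() if v.dtype == "survival"]

    def frame(self, var_ids: Sequence[str]) -> pd.DataFrame:
        """Sample × variable frame over ordinary (non-survival) variables."""
        for vid in var_ids:
            self.variable(vid)
        return self._data[list(var_ids)].copy()

    def add_variable(self, var: Variable, values: np.ndarray) -> None:
        """Attach a derived variable (sample-aligned float vector)."""
        if var.id in self.variables:
            raise CohortError(f"variable {var.id!r} already exists")
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_samples,):
            raise CohortError(f"values for {var.id!r} have wrong length")
        self._data[var.id] = values
        self.variables[var.id] = var
        self._check()

    def decode(self, var_id: str) -> np.ndarray:
        """Values of a categorical/ordinal variable as label strings (object array)."""
        var = self.variable(var_id)
        vals = self.values(var_id)
        out = np.full(vals.shape, None, dtype=object)
        if var.dtype == "categorical" and var.labels:
            for i, v in enumerate(vals):
                if not np.isnan(v):
                    out[i] = var.labels[int(v)]
        elif var.dtype == "ordinal" and var.source == "CNV":
            for i, v in enumerate(vals):
                if not np.isnan(v):
                    out[i] = CNV_LABELS[int(v)]
        else:
            raise CohortError(f"{var_id!r} has no label decoding")
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Cohort({self.name!r}, n={self.n_samples}, vars={len(self.variables)})"
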