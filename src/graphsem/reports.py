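"""Static analysis outputs: clustered-heatmap orderings, co-occurrence
tables, and reproducible file exports with a manifest."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .transforms import zscale_rows


class ReportError(ValueError):
    pass


@dataclass
class HeatmapOrder:
    row_order: list[int]
    col_order: list[int]
    linkage: str
    scaled: bool


def heatmap_order(matrix: np.ndarray, scale_rows: bool = False) -> HeatmapOrder:
    """Deterministic row/column ordering for a clustered heatmap.

    Average-linkage hierarchical clustering on Euclidean distances, with
    dendrogram leaves ordered deterministically (ties broken by input
    index).  Rows may be z-scaled first, as in expression heatmaps."""
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ReportError("heatmap needs >= 2 rows and >= 2 columns")
    if np.isnan(mat).all(axis=1).any():
        raise ReportError("all-missing row")
    if scale_rows:
        mat = zscale_rows(mat)
    if np.allclose(mat, mat.flat[0]):
        warnings.warn("constant matrix; input order returned", stacklevel=2)
        return HeatmapOrder(list(range(mat.shape[0])), list(range(mat.shape[1])),
                            "average", scale_rows)

    def leaf_order(data: np.ndarray) -> list[int]:
        if data.shape[0] < 2:
            return [0]
        filled = np.where(np.isnan(data), np.nanmean(data, axis=0, keepdims=True), data)
        link = hierarchy.linkage(pdist(filled), method="average")
        return [int(i) for i in hierarchy.leaves_list(link)]

    return HeatmapOrder(leaf_order(mat), leaf_order(mat.T), "average", scale_rows)


def cooccurrence_table(a: np.ndarray, b: np.ndarray,
                       collapse_b_loss: bool = False) -> dict:
    """2×2 co-occurrence of two binary alterations.

    ``collapse_b_loss`` first collapses ordinal copy-number codes in ``b``
    to loss = any code < 0 (the monosomy/shallow-loss convention).  Returns
    counts, the Haldane-corrected log odds ratio and the Fisher exact p;
    degenerate margins leave the statistics flagged as NaN."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if collapse_b_loss:
        b = np.where(np.isnan(b), np.nan, (b < 0).astype(float))
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    counts = np.array([
        [np.sum((a == 1) & (b == 1)), np.sum((a == 1) & (b == 0))],
        [np.sum((a == 0) & (b == 1)), np.sum((a == 0) & (b == 0))],
    ], dtype=float)
    out = {"counts": counts.astype(int)}
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        out.update({"log_odds_ratio": np.nan, "p": np.nan, "degenerate": True})
        return out
    h = counts + 0.5
    out["log_odds_ratio"] = float(np.log(h[0, 0] * h[1, 1] / (h[0, 1] * h[1, 0])))
    _, p = stats.fisher_exact(counts.astype(int))
    out["p"] = float(p)
    out["degenerate"] = False
    return out


def export_results(out_dir, *, tables: Mapping[str, pd.DataFrame] = None,
                   indices: Mapping[str, Mapping] = None,
                   curves: Sequence = (), manifest_extra: Mapping = None) -> Path:
    """Write TSV/JSON outputs plus a manifest of what produced them.

    ``tables``: name -> frame (written as <name>.tsv); ``indices``: name ->
    JSON-serializable dict; ``curves``: KMCurve objects (one km_curves.tsv).
    Returns the manifest path."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ReportError(f"cannot create output dir {out}: {exc}") from exc
    written = []
    for name, frame in (tables or {}).items():
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        written.append(path.name)
    for name, obj in (indices or {}).items():
        path = out / f"{name}.json"
        path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")
        written.append(path.name)
    if curves:
        path = out / "km_curves.tsv"
        pd.concat([c.table() for c in curves], ignore_index=True).to_csv(
            path, sep="\t", index=False)
        written.append(path.name)
    manifest = {"files": sorted(written)}
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=_jsonable, sort_keys=True) + "\n")
    return mpath


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
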