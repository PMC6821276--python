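"""Readers for the standard per-cohort file formats.

Supported inputs (all tab-delimited, optionally gzipped):

* gene × sample expression matrices (first column = gene id, header = samples),
* MAF somatic mutation calls,
* GISTIC thresholded by-gene copy-number matrices (integer codes −2..2),
* clinical tables keyed by sample id, including overall-survival time/event.

Each loader returns a :class:`~graphsem.cohort.Cohort` "part";
:func:`assemble_cohort` aligns parts on their shared samples.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError, Variable

#: Variant_Classification values counted as a mutation.  This is the
#: conventional non-silent set; Silent/UTR/Intron/IGR calls do not flip the
#: indicator.
NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

_SOURCE_SUFFIX = {"mRNA": "RNA", "miRNA": "miRNA", "RPPA": "RPPA"}

_EVENT_SYNONYMS = {
    "0": 0.0, "1": 1.0, "0.0": 0.0, "1.0": 1.0,
    "alive": 0.0, "living": 0.0, "censored": 0.0,
    "dead": 1.0, "deceased": 1.0,
}


def _to_float(series: pd.Series) -> np.ndarray:
    """Parse strings to float with correct rounding (unlike pd.to_numeric,
    which can be one ULP off); non-numeric cells become NaN."""

    def parse(cell):
        if cell is None:
            return np.nan
        try:
            return float(cell)
        except (TypeError, ValueError):
            return np.nan

    return np.array([parse(c) for c in series], dtype=float)


def _read_tsv(path) -> pd.DataFrame:
    # pandas infers gzip from the .gz extension
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        raise CohortError(f"empty file: {path}")
    return df


def load_expression_matrix(path, source_tag: str = "mRNA") -> Cohort:
    """Load a gene × sample matrix of continuous measurements.

    One continuous variable per row is created, named ``<GENE>.<suffix>``
    (suffix ``RNA`` for mRNA, ``miRNA``/``RPPA`` verbatim).  Non-numeric
    cells become missing.
    """
    if source_tag not in _SOURCE_SUFFIX:
        raise CohortError(f"source_tag must be one of {sorted(_SOURCE_SUFFIX)}")
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise CohortError(f"expression matrix needs gene column + samples: {path}")
    genes = df.iloc[:, 0]
    dup = genes[genes.duplicated()]
    if not dup.empty:
        raise CohortError(f"duplicate gene rows: {sorted(dup.unique())}")
    if genes.empty:
        raise CohortError(f"expression matrix has no gene rows: {path}")
    samples = list(df.columns[1:])
    suffix = _SOURCE_SUFFIX[source_tag]
    values = df.iloc[:, 1:].apply(_to_float)
    columns = {}
    variables = []
    for gene, row in zip(genes, values.itertuples(index=False)):
        vid = f"{gene}.{suffix}"
        columns[vid] = np.asarray(row, dtype=float)
        variables.append(Variable(vid, source_tag, "continuous"))
    return Cohort.from_columns("", samples, columns, variables)


def load_maf_mutations(
    path,
    cohort_samples: Sequence[str],
    gene_list: Iterable[str] | None = None,
    retained_classes: frozenset[str] = NONSILENT_CLASSES,
) -> Cohort:
    """Load per-gene binary mutation indicators from a MAF.

    A sample is mutant for a gene if it carries at least one retained
    (non-silent) variant; cohort samples absent from the MAF are wild-type
    (0), since MAFs list only variant-bearing samples.
    """
    df = _read_tsv(path)
    required = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")
    for col in required:
        if col not in df.columns:
            raise CohortError(f"MAF missing mandatory column {col!r}")
    samples = list(cohort_samples)
    sample_pos = {s: i for i, s in enumerate(samples)}
    keep = df[df["Variant_Classification"].isin(retained_classes)]
    genes = sorted(set(keep["Hugo_Symbol"]) if gene_list is None else set(gene_list))
    columns = {f"{g}.Mut": np.zeros(len(samples)) for g in genes}
    for gene, barcode in zip(keep["Hugo_Symbol"], keep["Tumor_Sample_Barcode"]):
        vid = f"{gene}.Mut"
        if vid in columns and barcode in sample_pos:
            columns[vid][sample_pos[barcode]] = 1.0
    variables = [Variable(f"{g}.Mut", "Mutation", "binary") for g in genes]
    return Cohort.from_columns("", samples, columns, variables)


def load_gistic_cnv(path) -> Cohort:
    """Load a gene × sample GISTIC thresholded copy-number matrix.

    Codes follow the usual semantics: −2 deep loss, −1 shallow loss,
    0 no change, 1 gain, 2 amplification.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise CohortError(f"GISTIC matrix needs gene column + samples: {path}")
    genes = df.iloc[:, 0]
    dup = genes[genes.duplicated()]
    if not dup.empty:
        raise CohortError(f"duplicate gene rows: {sorted(dup.unique())}")
    samples = list(df.columns[1:])
    values = df.iloc[:, 1:].apply(_to_float)
    arr = values.to_numpy(dtype=float)
    bad = ~(np.isnan(arr) | np.isin(arr, (-2.0, -1.0, 0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise CohortError(
            f"CNV code outside -2..2 at gene {genes.iloc[i]!r}, sample {samples[j]!r}: "
            f"{values.iat[i, j]}"
        )
    columns = {f"{g}.GISTIC": arr[i] for i, g in enumerate(genes)}
    variables = [Variable(f"{g}.GISTIC", "CNV", "ordinal") for g in genes]
    return Cohort.from_columns("", samples, columns, variables)


def load_clinical(path, time_col: str = "OS_time", event_col: str = "OS_event",
                  survival_id: str = "OS.Survival") -> Cohort:
    """Load a clinical table: numeric columns become continuous variables,
    string columns categorical, and ``(time_col, event_col)`` one survival
    variable.  ``dead``/``alive`` event strings are mapped to 1/0."""
    df = _read_tsv(path)
    id_col = df.columns[0]
    samples = list(df[id_col])
    if len(set(samples)) != len(samples):
        raise CohortError("duplicate sample ids in clinical table")
    for col in (time_col, event_col):
        if col not in df.columns:
            raise CohortError(f"clinical table missing column {col!r}")

    times = _to_float(df[time_col])
    if np.any(times[~np.isnan(times)] < 0):
        raise CohortError("negative survival time")
    events = np.full(len(df), np.nan)
    for i, raw in enumerate(df[event_col]):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw) == "nan":
            continue
        key = str(raw).strip().lower()
        if key not in _EVENT_SYNONYMS:
            raise CohortError(f"event value {raw!r} not in {{0,1,dead,alive}}")
        events[i] = _EVENT_SYNONYMS[key]

    columns = {f"{survival_id}__time": times, f"{survival_id}__event": events}
    variables = [Variable(survival_id, "Survival", "survival")]
    for col in df.columns:
        if col in (id_col, time_col, event_col):
            continue
        numeric = pd.Series(_to_float(df[col]))
        vid = f"{col}.Clinical"
        if numeric.notna().sum() >= max(1, int(0.5 * df[col].notna().sum())):
            columns[vid] = numeric.to_numpy(dtype=float)
            variables.append(Variable(vid, "Clinical", "continuous"))
        else:
            labels = sorted(x for x in df[col].dropna().unique())
            code = {lab: float(k) for k, lab in enumerate(labels)}
            columns[vid] = np.array(
                [code.get(x, np.nan) if isinstance(x, str) else np.nan for x in df[col]]
            )
            variables.append(Variable(vid, "Clinical", "categorical", labels=tuple(labels)))
    return Cohort.from_columns("", samples, columns, variables)


def assemble_cohort(parts: Sequence[Cohort], name: str = "cohort",
                    how: str = "intersection") -> Cohort:
    """Align loaded parts into one cohort.

    Samples are intersected by default (``how="union"`` keeps all samples
    with a missing mask) and sorted for deterministic order.
    """
    if not parts:
        raise CohortError("assemble_cohort needs at least one part")
    if how not in ("intersection", "union"):
        raise CohortError("how must be 'intersection' or 'union'")
    sets = [set(p.sample_ids) for p in parts]
    samples = set.intersection(*sets) if how == "intersection" else set.union(*sets)
    if not samples:
        raise CohortError("no samples shared across parts")
    order = sorted(samples)
    frames = []
    variables: dict[str, Variable] = {}
    for part in parts:
        for vid, var in part.variables.items():
            if vid in variables:
                raise CohortError(f"variable {vid!r} appears in more than one part")
            variables[vid] = var
        frames.append(part._data.reindex(order))
    data = pd.concat(frames, axis=1)
    data.index.name = "sample"
    return Cohort(name, data, variables)
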