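"""Delimited-text readers and writers.

All pipeline inputs and outputs are plain TSV/CSV: qPCR plate tables (one
row per replicate well), MEGAN-style count tables (first column the feature
path, remaining columns counts per timepoint), per-series expression tables
and fit-result tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .decay import DecayFit, ExpressionSeries, fits_to_records
from .errors import ValidationError
from .metat import PRE_LABEL, AnnotatedCounts

__all__ = [
    "read_counts_table",
    "write_counts_table",
    "read_plate_table",
    "write_fits_table",
    "read_series_table",
    "write_series_table",
]

PLATE_COLUMNS = ["sample_id", "gene", "material", "known_copies", "cq"]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts_table(
    path: str | Path, rna_type: str, pre_col: str | None = PRE_LABEL
) -> AnnotatedCounts:
    """Read a feature × timepoint count table (first column = feature key)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return AnnotatedCounts(df, rna_type, pre_col)


def write_counts_table(counts: AnnotatedCounts, path: str | Path) -> None:
    path = Path(path)
    counts.counts.to_csv(path, sep=_sep(path), index_label="feature")


def read_plate_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR plate table with one row per replicate well."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"plate table missing columns: {missing}")
    if len(df) == 0:
        raise ValidationError(f"plate table {path} is empty")
    return df


def write_fits_table(fits: Sequence[DecayFit], path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(fits_to_records(fits)).to_csv(path, sep=_sep(path), index=False)


def write_series_table(series_list: Sequence[ExpressionSeries], path: str | Path) -> None:
    """Write per-series records: one row per entity × timepoint."""
    rows = []
    for s in series_list:
        if s.pre_treatment_value is not None:
            rows.append(
                dict(entity_id=s.entity_id, condition=s.condition, timepoint_min=np.nan,
                     value=s.pre_treatment_value, detected=True, pre_treatment=True)
            )
        for t, v, d in zip(s.timepoints, s.values, s.detected):
            rows.append(
                dict(entity_id=s.entity_id, condition=s.condition, timepoint_min=t,
                     value=v, detected=bool(d), pre_treatment=False)
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def read_series_table(path: str | Path) -> list[ExpressionSeries]:
    """Read per-series records written by :func:`write_series_table`."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    out = []
    for (entity, cond), grp in df.groupby(["entity_id", "condition"], dropna=False, sort=False):
        pre = grp[grp.pre_treatment]
        post = grp[~grp.pre_treatment].sort_values("timepoint_min")
        out.append(
            ExpressionSeries(
                entity_id=str(entity),
                condition="" if pd.isna(cond) else str(cond),
                timepoints=post["timepoint_min"].to_numpy(),
                values=post["value"].to_numpy(),
                detected=post["detected"].to_numpy(dtype=bool),
                pre_treatment_value=float(pre["value"].iloc[0]) if len(pre) else None,
            )
        )
    return out
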