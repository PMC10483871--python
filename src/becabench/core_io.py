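"""Shared data model and TSV readers/writers for expression matrices and sample sheets.

The in-memory containers are thin wrappers around :class:`pandas.DataFrame`:
an :class:`ExpressionMatrix` is a feature × sample numeric grid tagged with a
measurement *scale* and an omics *layer*; a :class:`SampleSheet` records the
experimental design (donor, replicate, batch, processing order, study vs
reference role) for each sample. Missing values are ``NaN`` in memory and
empty cells on disk — never zero, because downstream imputation strategies
differ by correction method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SCALES = ("counts", "normalized", "log2", "ratio_log2")
LAYERS = ("transcriptomics", "proteomics", "metabolomics")

#: canonical Quartet-style donor labels; any unique strings are accepted
DEFAULT_DONORS = ("D5", "D6", "F7", "M8")

SHEET_COLUMNS = ["sample_id", "donor", "replicate", "batch", "batch_order", "role"]


class ValidationError(ValueError):
    """Raised when a matrix or sheet violates its structural invariants."""


@dataclass
class ExpressionMatrix:
    """Feature × sample expression grid with scale and omics-layer tags.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids. ``NaN``
        marks a missing measurement.
    scale
        One of ``counts``, ``normalized``, ``log2``, ``ratio_log2``.
    layer
        One of ``transcriptomics``, ``proteomics``, ``metabolomics``.
    """

    values: pd.DataFrame
    scale: str
    layer: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame (features × samples)")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        self.values = self.values.astype(float)
        arr = self.values.to_numpy()
        if self.scale == "counts":
            with np.errstate(invalid="ignore"):
                if np.any(arr[~np.isnan(arr)] < 0):
                    raise ValidationError("counts matrix contains negative values")
        if self.scale in ("log2", "ratio_log2") and np.isnan(arr).any():
            raise ValidationError(
                f"{self.scale} matrix contains missing values; impute or floor first"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.values.columns)
        if missing:
            raise ValidationError(f"samples not in matrix: {sorted(missing)}")
        return replace(self, values=self.values[ids].copy())

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise ValidationError(f"features not in matrix: {sorted(missing)}")
        return replace(self, values=self.values.loc[ids].copy())

    def copy(self) -> "ExpressionMatrix":
        return replace(self, values=self.values.copy())


@dataclass
class SampleSheet:
    """Per-sample design annotations.

    ``table`` has columns ``sample_id, donor, replicate, batch, batch_order,
    role`` (role ∈ {study, reference}); extra columns (e.g. ``layer``) are
    carried through untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if len(self.table) == 0:
            raise ValidationError("sample sheet is empty")
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in sheet: {dupes}")
        key = self.table[["donor", "replicate", "batch"]]
        if key.duplicated().any():
            raise ValidationError("(donor, replicate, batch) combinations must be unique")
        roles = set(self.table["role"].unique())
        if not roles <= {"study", "reference"}:
            raise ValidationError(f"unknown roles {roles - {'study', 'reference'}}")
        ref_donors = set(self.table.loc[self.table["role"] == "reference", "donor"])
        if len(ref_donors) > 1:
            raise ValidationError(
                f"all reference samples must share one donor; got {sorted(ref_donors)}"
            )
        order = self.table.groupby("batch")["batch_order"].nunique()
        if (order != 1).any():
            raise ValidationError("batch_order must be constant within each batch")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def batches(self) -> list[str]:
        """Batch ids sorted by batch_order (the processing/date order)."""
        t = self.table[["batch", "batch_order"]].drop_duplicates().sort_values("batch_order")
        return list(t["batch"])

    @property
    def donors(self) -> list[str]:
        return sorted(self.table["donor"].unique())

    @property
    def reference_donor(self) -> str | None:
        ref = self.table.loc[self.table["role"] == "reference", "donor"]
        return None if ref.empty else ref.iloc[0]

    @property
    def study_ids(self) -> list[str]:
        return list(self.table.loc[self.table["role"] == "study", "sample_id"])

    @property
    def reference_ids(self) -> list[str]:
        return list(self.table.loc[self.table["role"] == "reference", "sample_id"])

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        ids = list(sample_ids)
        missing = set(ids) - set(self.table["sample_id"])
        if missing:
            raise ValidationError(f"samples not in sheet: {sorted(missing)}")
        sub = self.table.set_index("sample_id").loc[ids].reset_index()
        return SampleSheet(sub)

    def batch_of(self) -> pd.Series:
        """sample_id → batch mapping."""
        return self.table.set_index("sample_id")["batch"]

    def donor_of(self) -> pd.Series:
        """sample_id → donor mapping."""
        return self.table.set_index("sample_id")["donor"]


@dataclass
class DesignSummary:
    n_batches: int
    n_donors: int
    n_samples: int
    replicates: pd.DataFrame  # donor × batch replicate counts
    batches_without_reference: list[str] = field(default_factory=list)

    @property
    def has_reference_gaps(self) -> bool:
        return len(self.batches_without_reference) > 0


# -- I/O ----------------------------------------------------------------------


def read_expression(path: str | Path, scale: str, layer: str) -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix (feature_id first column, sample-id header).

    Blank cells become missing values. Duplicated feature or sample ids and
    non-numeric cells are rejected with an error naming the offender.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: expected a feature-id column plus ≥1 sample column")
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "feature_id"
    values = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            feat = raw.index[bad][0]
            raise ValidationError(
                f"{path}: non-numeric value {raw.loc[feat, col]!r} at feature {feat!r}, sample {col!r}"
            )
        values[col] = converted
    return ExpressionMatrix(values=values, scale=scale, layer=layer)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; missing values become empty cells."""
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "donor": str, "batch": str})
    return SampleSheet(table)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def validate_design(matrix: ExpressionMatrix, sheet: SampleSheet) -> DesignSummary:
    """Cross-check a matrix against its sample sheet.

    Returns batch/donor/replicate counts and flags batches that carry no
    reference replicates (reference-based corrections will fail there).
    """
    missing = set(sheet.sample_ids) - set(matrix.sample_ids)
    if missing:
        raise ValidationError(f"sheet samples absent from matrix: {sorted(missing)}")
    t = sheet.table
    replicates = t.pivot_table(
        index="donor", columns="batch", values="sample_id", aggfunc="count", fill_value=0
    )
    ref_batches = set(t.loc[t["role"] == "reference", "batch"])
    gaps = [b for b in sheet.batches if b not in ref_batches]
    return DesignSummary(
        n_batches=t["batch"].nunique(),
        n_donors=t["donor"].nunique(),
        n_samples=len(t),
        replicates=replicates,
        batches_without_reference=gaps,
    )
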