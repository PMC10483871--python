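"""Batch-effect correction algorithms (BECAs) and the plugin registry.

Three corrections are native:

raw
    no correction (identity), the baseline every method is judged against;
bmc
    per-batch per-feature mean-centering — subtract each feature's within-
    batch mean, forcing every batch mean to zero. Harmless when donors are
    balanced across batches; destroys the biological signal when donors are
    confounded with batches;
ratio
    ratio-based scaling against reference materials — subtract, per feature
    per batch, the mean log2 value of the in-batch reference replicates.
    Because a linear per-batch measurement distortion hits study and
    reference samples alike, it cancels in the ratio, making corrected
    profiles comparable across batches regardless of design.

External methods (ComBat, Harmony, SVA, RUV, ...) plug in through
:func:`register_beca` under the same calling contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, SampleSheet, ValidationError


@dataclass
class CorrectionResult:
    corrected: ExpressionMatrix
    method: str
    parameters: dict = field(default_factory=dict)
    imputation: str | None = None


def _check_log2(matrix: ExpressionMatrix, op: str) -> None:
    if matrix.scale not in ("log2", "ratio_log2"):
        raise ValidationError(f"{op} expects a log2-scale matrix, got {matrix.scale!r}")


def correct_raw(matrix: ExpressionMatrix) -> CorrectionResult:
    """Identity correction: expression profiles without batch correction."""
    _check_log2(matrix, "correct_raw")
    return CorrectionResult(corrected=matrix.copy(), method="raw")


def correct_bmc(matrix: ExpressionMatrix, sheet: SampleSheet) -> CorrectionResult:
    """Per-batch per-feature mean-centering (all samples of the batch)."""
    _check_log2(matrix, "correct_bmc")
    missing = set(matrix.sample_ids) - set(sheet.sample_ids)
    if missing:
        raise ValidationError(f"samples lacking batch annotation: {sorted(missing)}")
    batch_of = sheet.batch_of()
    values = matrix.values.copy()
    for _, ids in values.columns.to_series().groupby(batch_of[values.columns].to_numpy()):
        cols = list(ids)
        values[cols] = values[cols].sub(values[cols].mean(axis=1), axis=0)
    return CorrectionResult(corrected=replace(matrix, values=values), method="bmc")


def correct_ratio(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    n_ref_replicates: int = 3,
    seed: int = 0,
    keep_reference: bool = True,
) -> CorrectionResult:
    """Ratio-based scaling against in-batch reference replicates.

    Every sample's log2 profile is shifted by subtracting the mean log2
    profile of ``n_ref_replicates`` reference replicates of its own batch
    (the arithmetic mean of log2 values — the geometric mean on the linear
    scale). When a batch holds more reference replicates than requested, the
    subset is drawn once per batch with ``seed``. Reference samples are
    corrected by the same denominator and kept by default.
    """
    _check_log2(matrix, "correct_ratio")
    if n_ref_replicates < 1:
        raise ValidationError("n_ref_replicates must be ≥ 1")
    missing = set(matrix.sample_ids) - set(sheet.sample_ids)
    if missing:
        raise ValidationError(f"samples lacking batch annotation: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    t = sheet.table
    values = matrix.values.copy()
    present = set(values.columns)
    for batch in sheet.batches:
        in_batch = [s for s in t.loc[t["batch"] == batch, "sample_id"] if s in present]
        if not in_batch:
            continue
        ref_ids = [
            s
            for s in t.loc[(t["batch"] == batch) & (t["role"] == "reference"), "sample_id"]
            if s in present
        ]
        if len(ref_ids) < n_ref_replicates:
            raise ValidationError(
                f"batch {batch}: {len(ref_ids)} reference replicates present, "
                f"need {n_ref_replicates}"
            )
        if len(ref_ids) > n_ref_replicates:
            ref_ids = list(rng.choice(ref_ids, size=n_ref_replicates, replace=False))
        denom = values[ref_ids].mean(axis=1)
        values[in_batch] = values[in_batch].sub(denom, axis=0)
    if not keep_reference:
        study = [s for s in values.columns if s in set(sheet.study_ids)]
        values = values[study]
    corrected = ExpressionMatrix(values=values, scale="ratio_log2", layer=matrix.layer)
    return CorrectionResult(
        corrected=corrected,
        method="ratio",
        parameters={"n_ref_replicates": n_ref_replicates, "seed": seed},
    )


# -- plugin registry ----------------------------------------------------------

BecaFn = Callable[[ExpressionMatrix, SampleSheet, dict], ExpressionMatrix]

_REGISTRY: dict[str, dict] = {}


def _builtin_raw(matrix, sheet, covariates):
    return correct_raw(matrix).corrected


def _builtin_bmc(matrix, sheet, covariates):
    return correct_bmc(matrix, sheet).corrected


def _builtin_ratio(matrix, sheet, covariates):
    return correct_ratio(
        matrix,
        sheet,
        n_ref_replicates=covariates.get("n_ref_replicates", 3),
        seed=covariates.get("seed", 0),
    ).corrected


def register_beca(
    name: str, fn: BecaFn, imputation: str = "zero", uses_reference: bool = False
) -> str:
    """Register a correction under ``name``.

    ``fn`` maps (matrix, sheet, covariates-dict) → matrix of identical shape;
    ``imputation`` declares whether the method needs plain ``zero`` or
    ``jitter`` imputation upstream. ``uses_reference`` marks reference-
    sample-based methods: only those are handed the reference replicates by
    the evaluation pipeline (non-reference methods see study samples alone,
    mirroring how each method would be used in practice). Returns the name.
    """
    if name in _REGISTRY:
        raise ValidationError(f"BECA {name!r} already registered")
    if imputation not in ("zero", "jitter"):
        raise ValidationError("imputation must be 'zero' or 'jitter'")
    _REGISTRY[name] = {"fn": fn, "imputation": imputation, "uses_reference": uses_reference}
    return name


def unregister_beca(name: str) -> None:
    if name in ("raw", "bmc", "ratio"):
        raise ValidationError(f"cannot unregister built-in BECA {name!r}")
    _REGISTRY.pop(name, None)


def list_becas() -> list[str]:
    return sorted(_REGISTRY)


def beca_imputation(name: str) -> str:
    if name not in _REGISTRY:
        raise ValidationError(f"unknown BECA {name!r}")
    return _REGISTRY[name]["imputation"]


def beca_uses_reference(name: str) -> bool:
    if name not in _REGISTRY:
        raise ValidationError(f"unknown BECA {name!r}")
    return _REGISTRY[name]["uses_reference"]


def apply_beca(
    name: str, matrix: ExpressionMatrix, sheet: SampleSheet, covariates: dict | None = None
) -> CorrectionResult:
    """Run a registered correction by name, enforcing the shape contract."""
    if name not in _REGISTRY:
        raise ValidationError(f"unknown BECA {name!r}; registered: {list_becas()}")
    entry = _REGISTRY[name]
    out = entry["fn"](matrix, sheet, covariates or {})
    if not isinstance(out, ExpressionMatrix):
        raise ValidationError(f"BECA {name!r} returned {type(out).__name__}, not ExpressionMatrix")
    if list(out.feature_ids) != list(matrix.feature_ids) or set(out.sample_ids) != set(
        matrix.sample_ids
    ):
        raise ValidationError(f"BECA {name!r} changed the matrix shape or ids")
    return CorrectionResult(
        corrected=out,
        method=name,
        parameters=dict(covariates or {}),
        imputation=entry["imputation"],
    )


for _name, _fn, _uses_ref in (
    ("raw", _builtin_raw, False),
    ("bmc", _builtin_bmc, False),
    ("ratio", _builtin_ratio, True),
):
    _REGISTRY[_name] = {"fn": _fn, "imputation": "zero", "uses_reference": _uses_ref}
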