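"""Normalization, flooring, imputation, and feature-detection rules.

These are the fixed preprocessing conventions of the benchmark: counts are
CPM-normalized; normalized abundances get a small floor added before log2
(0.01 for transcriptomics/proteomics, 1 for metabolomics); missing
proteomics/metabolomics values are imputed with zero (or a small jitter for
corrections that cannot tolerate within-batch constant features); a feature
counts as detected when it reaches a threshold in strictly more than a
required fraction of libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, ValidationError

#: per-layer floor added before log2 transformation
DEFAULT_FLOORS = {"transcriptomics": 0.01, "proteomics": 0.01, "metabolomics": 1.0}


@dataclass(frozen=True)
class DetectionRule:
    """A feature is detected if value ≥ threshold in > min_fraction of libraries."""

    threshold: float
    min_fraction: float

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("detection threshold must be > 0")
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValidationError("min_fraction must be in (0, 1]")


#: per-layer detection defaults: ≥0.1 in >30% of libraries for
#: transcriptomics/proteomics, ≥1 in >70% for metabolomics
DEFAULT_DETECTION = {
    "transcriptomics": DetectionRule(threshold=0.1, min_fraction=0.30),
    "proteomics": DetectionRule(threshold=0.1, min_fraction=0.30),
    "metabolomics": DetectionRule(threshold=1.0, min_fraction=0.70),
}


def cpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts → counts-per-million: value(g,s) = count(g,s) / total(s) × 1e6."""
    if matrix.scale != "counts":
        raise ValidationError(f"cpm_normalize expects counts, got scale {matrix.scale!r}")
    totals = matrix.values.sum(axis=0, skipna=True)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValidationError(f"zero-total sample(s): {list(zero.index)}")
    values = matrix.values.div(totals, axis=1) * 1e6
    return replace(matrix, values=values, scale="normalized")


def floor_log2(matrix: ExpressionMatrix, floor: float | None = None) -> ExpressionMatrix:
    """value → log2(value + floor); missing values must be imputed first.

    ``floor=None`` takes the layer default (0.01 / 0.01 / 1). ``floor=0`` is
    allowed for strictly positive matrices (exact log2, no flooring).
    """
    if matrix.scale != "normalized":
        raise ValidationError(f"floor_log2 expects normalized scale, got {matrix.scale!r}")
    if floor is None:
        floor = DEFAULT_FLOORS[matrix.layer]
    if floor < 0:
        raise ValidationError("floor must be ≥ 0")
    arr = matrix.values.to_numpy()
    if np.isnan(arr).any():
        raise ValidationError("matrix contains missing values; run impute_missing first")
    shifted = arr + floor
    if np.any(shifted <= 0):
        raise ValidationError("non-positive value after flooring; increase floor")
    values = pd.DataFrame(np.log2(shifted), index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=values, scale="log2")


def impute_missing(
    matrix: ExpressionMatrix,
    strategy: str = "zero",
    sd: float = 0.01,
    seed: int = 0,
) -> ExpressionMatrix:
    """Replace missing cells: ``zero`` sets them to 0; ``jitter`` draws
    Normal(0, sd²) values (near zero, possibly negative — no truncation) so
    that corrections intolerant of within-batch constant features still work.
    """
    if matrix.scale != "normalized":
        raise ValidationError(f"impute_missing expects normalized scale, got {matrix.scale!r}")
    if strategy not in ("zero", "jitter"):
        raise ValidationError(f"unknown imputation strategy {strategy!r}")
    if sd < 0:
        raise ValidationError("jitter sd must be ≥ 0")
    values = matrix.values.copy()
    mask = values.isna()
    if not mask.to_numpy().any():
        return replace(matrix, values=values)
    if strategy == "zero":
        values = values.fillna(0.0)
    else:
        rng = np.random.default_rng(seed)
        fill = rng.normal(0.0, sd, size=values.shape)
        arr = values.to_numpy()
        arr[mask.to_numpy()] = fill[mask.to_numpy()]
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return replace(matrix, values=values)


def filter_detected(matrix: ExpressionMatrix, rule: DetectionRule | None = None) -> list[str]:
    """Feature ids whose passing-library fraction strictly exceeds the rule's
    ``min_fraction`` ("over 30%" is read as a strict inequality). Missing
    values count as not passing. Applied to the un-imputed normalized matrix.
    """
    if matrix.scale != "normalized":
        raise ValidationError(f"filter_detected expects normalized scale, got {matrix.scale!r}")
    if rule is None:
        rule = DEFAULT_DETECTION[matrix.layer]
    arr = matrix.values.to_numpy()
    with np.errstate(invalid="ignore"):
        passing = np.nansum(arr >= rule.threshold, axis=1)
    frac = passing / matrix.shape[1]
    keep = frac > rule.min_fraction
    return [f for f, k in zip(matrix.feature_ids, keep) if k]
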