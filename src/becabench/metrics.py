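"""Quantitative performance metrics for batch-effect correction.

The headline metric is the PCA-based signal-to-noise ratio (SNR): after
feature-wise unit-variance scaling and PCA, the decibel-scaled ratio of the
average squared distance between replicates of *different* donors to the
average squared distance between replicates of the *same* donor, measured in
the plane of the first two components weighted by their explained-variance
fractions:

    SNR = 10 log10( [m C(n,2) / (C(m,2) n n)]
                    * sum_{x<y} sum_{i,j} sum_p W_p (PC_pix - PC_pjy)^2
                    / sum_x sum_{i<j} sum_p W_p (PC_pix - PC_pjx)^2 )

with m donors and n replicates per donor. Higher SNR means biological groups
separate further relative to technical noise.

Differential-expression concordance is scored against the consensus truth
sets with the relative correlation (RC, Pearson r of log2 FCs), the
Matthews correlation coefficient over the DEF confusion, and the Jaccard
index of DEF sets; clustering accuracy with the adjusted Rand index; and
method comparison with a min–max-scaled total score averaged over four
metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .core_io import ExpressionMatrix, ValidationError


# -- PCA ----------------------------------------------------------------------


def pca_scores(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples after per-feature centering and unit-variance scaling.

    Constant features are dropped before scaling. Returns (scores, variance
    fractions): scores is samples × components, variance fractions sum to 1.
    """
    if matrix.scale not in ("log2", "ratio_log2"):
        raise ValidationError(f"pca_scores expects log2-scale data, got {matrix.scale!r}")
    if matrix.shape[1] < 3:
        raise ValidationError("PCA needs ≥3 samples")
    x = matrix.values.to_numpy().T  # samples × features
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValidationError("all features are constant")
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    # SVD of the centered scaled matrix == prcomp-style PCA
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s**2 / (s**2).sum()
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.sample_ids, columns=cols), var


def snr(
    scores: pd.DataFrame,
    weights: np.ndarray,
    donor_labels: pd.Series,
    n_components: int = 2,
) -> float:
    """Decibel SNR of donor separation in the first two weighted PCs.

    ``scores`` rows are samples, ``weights`` the explained-variance fractions
    aligned with the score columns, ``donor_labels`` maps sample id → donor.
    Requires ≥2 donors with ≥2 replicates each; unequal replicate counts use
    per-donor counts in the combinatorial prefactor. Zero within-donor spread
    returns +inf with a warning.
    """
    donors = donor_labels.loc[scores.index]
    groups = {d: scores.loc[donors[donors == d].index].to_numpy()[:, :n_components] for d in donors.unique()}
    m = len(groups)
    if m < 2:
        raise ValidationError("SNR needs ≥2 donors")
    sizes = {d: g.shape[0] for d, g in groups.items()}
    if min(sizes.values()) < 2:
        raise ValidationError("SNR needs ≥2 replicates per donor")
    w = np.asarray(weights[:n_components], dtype=float)

    names = sorted(groups)
    between = 0.0
    n_between_pairs = 0
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            gx, gy = groups[x], groups[y]
            d2 = ((gx[:, None, :] - gy[None, :, :]) ** 2 * w).sum(axis=2)
            between += d2.sum()
            n_between_pairs += d2.size
    within = 0.0
    n_within_pairs = 0
    for x in names:
        g = groups[x]
        d2 = ((g[:, None, :] - g[None, :, :]) ** 2 * w).sum(axis=2)
        iu = np.triu_indices(g.shape[0], k=1)
        within += d2[iu].sum()
        n_within_pairs += len(iu[0])
    if within == 0.0:
        warnings.warn("zero within-donor spread; SNR is +inf", RuntimeWarning, stacklevel=2)
        return math.inf
    # equal-n case reduces to the m*C(n,2) / (C(m,2)*n*n) prefactor
    ratio = (between / n_between_pairs) / (within / n_within_pairs)
    return 10.0 * math.log10(ratio)


def snr_from_matrix(matrix: ExpressionMatrix, donor_labels: pd.Series) -> float:
    """Convenience: PCA then SNR on the matrix's samples."""
    scores, var = pca_scores(matrix)
    return snr(scores, var, donor_labels)


# -- DE concordance -----------------------------------------------------------


def rc(test_fc: pd.Series, reference_fc: pd.Series) -> float:
    """Relative correlation: Pearson r of test vs reference log2 FCs over the
    feature intersection (≥3 overlapping features required)."""
    common = test_fc.index.intersection(reference_fc.index)
    if len(common) < 3:
        raise ValidationError(f"only {len(common)} overlapping features; need ≥3")
    a = test_fc.loc[common].to_numpy(dtype=float)
    b = reference_fc.loc[common].to_numpy(dtype=float)
    return float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(test_labels: pd.Series, reference_labels: pd.Series) -> ConfusionCounts:
    """DEF confusion vs the consensus truth over the feature intersection.

    Positives are reference up/down features. A test call is a TP only when
    its direction matches the reference; a reference-positive called in the
    *wrong* direction counts as FP (it is a spurious call, not a miss), so
    TP+TN+FP+FN always equals the evaluated feature count.
    """
    common = test_labels.index.intersection(reference_labels.index)
    if len(common) == 0:
        raise ValidationError("test and reference feature sets are disjoint")
    t = test_labels.loc[common].to_numpy()
    r = reference_labels.loc[common].to_numpy()
    bad = set(np.unique(r)) - {"up", "down", "non"}
    if bad:
        raise ValidationError(f"unknown reference labels {bad}")
    ref_pos = r != "non"
    test_pos = t != "non"
    tp = int(np.sum(ref_pos & test_pos & (t == r)))
    fp = int(np.sum(test_pos & ~(ref_pos & (t == r))))
    fn = int(np.sum(ref_pos & ~test_pos))
    tn = int(np.sum(~ref_pos & ~test_pos))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    num = c.tp * c.tn - c.fp * c.fn
    den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def sensitivity(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0


def specificity(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0


def precision(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0


def f1(c: ConfusionCounts) -> float:
    p, s = precision(c), sensitivity(c)
    return 2 * p * s / (p + s) if (p + s) else 0.0


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total else 0.0


def npv(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fn) if (c.tn + c.fn) else 0.0


def jaccard(test_set: set, reference_set: set) -> float:
    """|∩| / |∪| of DEF feature sets; 1 when both are empty."""
    union = test_set | reference_set
    if not union:
        return 1.0
    return len(test_set & reference_set) / len(union)


# -- clustering ---------------------------------------------------------------


def ari(partition_a: pd.Series, partition_b: pd.Series) -> float:
    """Adjusted Rand index between two partitions of the same element set.

    Standard pair-counting contingency form (chance-adjusted; 1 for identical
    partitions, ≈0 for independent ones).
    """
    if set(partition_a.index) != set(partition_b.index):
        raise ValidationError("partitions cover different element sets")
    b = partition_b.loc[partition_a.index]
    return float(adjusted_rand_score(partition_a.to_numpy(), b.to_numpy()))


# -- method ranking -----------------------------------------------------------


def total_score(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Min–max scale each metric column to (0,1) across methods, then average.

    ``metric_table`` is indexed by correction method with one column per
    metric (typically SNR, MCC of DEFs, MCC of prediction, ARI). A constant
    column scales to 0.5 for every method. Returns the scaled table plus
    ``total_score`` and descending ``rank`` columns.
    """
    if metric_table.empty:
        raise ValidationError("empty metric table")
    scaled = pd.DataFrame(index=metric_table.index)
    for col in metric_table.columns:
        v = metric_table[col].astype(float)
        lo, hi = v.min(), v.max()
        scaled[col] = 0.5 if hi == lo else (v - lo) / (hi - lo)
    out = scaled.copy()
    out["total_score"] = scaled.mean(axis=1)
    out["rank"] = out["total_score"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("total_score", ascending=False)
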