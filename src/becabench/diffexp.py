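"""Differential expression: intra-batch FCs, consensus truth sets, cross-batch calls.

Fold changes between donor pairs are computed per batch on log2 data:
replicates are averaged first, the log2 FC is the difference of means, and a
two-sample t-test on the replicate values supplies the p value. Consensus
"ground-truth" reference datasets are built from the full design: the
reference FC of a feature is the mean of its intra-batch FCs across all
batches (retained only when the t-test reached p < 0.05 in at least three
batches), and the reference DEF label is the plurality vote over the
per-batch up/down/non calls (plurality ties excluded).

Cross-batch comparisons emulate what a user of a corrected multi-batch
dataset would do: pick replicates spanning batches (3 vs 3) and call DEFs
the same way, to be judged against the consensus truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, SampleSheet, ValidationError
from .scenarios import ScenarioSubset
from .simulate import STUDY_PAIRS, pair_name

#: linear fold-change threshold per layer for DEF calls (down threshold is its
#: reciprocal: 0.5 for transcriptomics/proteomics, 0.667 for metabolomics)
FC_THRESHOLDS = {"transcriptomics": 2.0, "proteomics": 2.0, "metabolomics": 1.5}

_VAR_FLOOR = 1e-12  # pooled-variance floor for zero-variance groups


def _ttest(a: np.ndarray, b: np.ndarray, test: str = "student") -> np.ndarray:
    """Vectorized two-sample t-test p-values over rows (features).

    ``student`` pools variances (the reproduction default); ``welch`` does
    not assume equal variances. Zero-variance groups are handled with a
    variance floor, so identical groups give t = 0, p = 1.
    """
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("t-test needs ≥2 replicates per group")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    if test == "student":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        sp2 = np.maximum(sp2, _VAR_FLOOR)
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(t, n1 + n2 - 2)
    elif test == "welch":
        se1, se2 = np.maximum(v1, _VAR_FLOOR) / n1, np.maximum(v2, _VAR_FLOOR) / n2
        t = (m1 - m2) / np.sqrt(se1 + se2)
        df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    else:
        raise ValidationError(f"unknown test {test!r}; use 'student' or 'welch'")
    return 2.0 * stats.t.sf(np.abs(t), df)


def group_fc(
    matrix: ExpressionMatrix,
    numerator_ids: list[str],
    denominator_ids: list[str],
    test: str = "student",
) -> pd.DataFrame:
    """Per-feature log2 FC (mean difference) and t-test p for two sample groups."""
    if matrix.scale not in ("log2", "ratio_log2"):
        raise ValidationError(f"group_fc expects log2-scale data, got {matrix.scale!r}")
    a = matrix.values[numerator_ids].to_numpy()
    b = matrix.values[denominator_ids].to_numpy()
    return pd.DataFrame(
        {
            "feature": matrix.feature_ids,
            "log2_fc": a.mean(axis=1) - b.mean(axis=1),
            "p_value": _ttest(a, b, test=test),
        }
    )


def intra_batch_fc(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    batch: str,
    pair: tuple[str, str],
    test: str = "student",
) -> pd.DataFrame:
    """FC records for one donor pair within one batch (numerator first)."""
    num, den = pair
    t = sheet.table
    ids_num = [
        s for s in t.loc[(t["batch"] == batch) & (t["donor"] == num), "sample_id"]
        if s in set(matrix.sample_ids)
    ]
    ids_den = [
        s for s in t.loc[(t["batch"] == batch) & (t["donor"] == den), "sample_id"]
        if s in set(matrix.sample_ids)
    ]
    if len(ids_num) < 2 or len(ids_den) < 2:
        raise ValidationError(
            f"batch {batch}, pair {pair_name(num, den)}: need ≥2 replicates per donor"
        )
    out = group_fc(matrix, ids_num, ids_den, test=test)
    out["pair"] = pair_name(num, den)
    out["batch"] = batch
    return out


def intra_batch_all(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    pairs: tuple[tuple[str, str], ...] = STUDY_PAIRS,
    test: str = "student",
) -> pd.DataFrame:
    """All intra-batch FC records over every batch × donor pair."""
    frames = [
        intra_batch_fc(matrix, sheet, batch, pair, test=test)
        for batch in sheet.batches
        for pair in pairs
    ]
    return pd.concat(frames, ignore_index=True)


def call_defs(
    fc_records: pd.DataFrame,
    layer: str,
    p_threshold: float = 0.05,
    adjust: str | None = None,
) -> pd.Series:
    """Label features up/down/non from FC records of a single comparison.

    up: p < 0.05 and linear FC above the layer threshold (2 for
    transcriptomics/proteomics, 1.5 for metabolomics); down: p < 0.05 and FC
    below its reciprocal; non otherwise. ``adjust="bh"`` gates on
    Benjamini–Hochberg-adjusted p instead of raw p (same topology, different
    threshold — the multiple-testing variant).
    """
    if layer not in FC_THRESHOLDS:
        raise ValidationError(f"unknown layer {layer!r}")
    thr = np.log2(FC_THRESHOLDS[layer])
    p = fc_records["p_value"].to_numpy()
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    elif adjust is not None:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    fc = fc_records["log2_fc"].to_numpy()
    sig = p < p_threshold
    label = np.where(sig & (fc > thr), "up", np.where(sig & (fc < -thr), "down", "non"))
    return pd.Series(label, index=pd.Index(fc_records["feature"], name="feature"), name="label")


@dataclass
class ReferenceDataset:
    """Consensus truth per donor pair: reference FCs and DEF labels."""

    fc: pd.DataFrame  # feature, pair, ref_log2_fc, n_significant
    defs: pd.DataFrame  # feature, pair, label (tie-excluded)

    def pair_fc(self, pair: str) -> pd.Series:
        t = self.fc[self.fc["pair"] == pair]
        return t.set_index("feature")["ref_log2_fc"]

    def pair_defs(self, pair: str) -> pd.Series:
        t = self.defs[self.defs["pair"] == pair]
        return t.set_index("feature")["label"]

    def to_table(self) -> pd.DataFrame:
        merged = self.fc.merge(self.defs, on=["feature", "pair"], how="outer")
        return merged[["feature", "pair", "ref_log2_fc", "label", "n_significant"]]


def build_reference_fc(
    records: pd.DataFrame, p_threshold: float = 0.05, min_significant_batches: int = 3
) -> pd.DataFrame:
    """Reference FC = mean of intra-batch log2 FCs over all batches, retained
    only for features with t-test p < 0.05 in ≥ ``min_significant_batches``."""
    if records["batch"].nunique() < min_significant_batches:
        raise ValidationError(
            f"records span {records['batch'].nunique()} batches; "
            f"need ≥ {min_significant_batches}"
        )
    g = records.groupby(["feature", "pair"], sort=True)
    out = g.agg(
        ref_log2_fc=("log2_fc", "mean"),
        n_significant=("p_value", lambda p: int((p < p_threshold).sum())),
    ).reset_index()
    return out[out["n_significant"] >= min_significant_batches].reset_index(drop=True)


def build_reference_defs(labels: pd.DataFrame) -> pd.DataFrame:
    """Plurality vote over per-batch labels; tied pluralities are excluded.

    ``labels`` holds columns feature, pair, batch, label (one vote per batch).
    """
    counts = labels.pivot_table(
        index=["feature", "pair"], columns="label", aggfunc="size", fill_value=0
    )
    top = counts.max(axis=1)
    untied = counts.eq(top, axis=0).sum(axis=1) == 1  # tied plurality — no consensus
    winner = counts.idxmax(axis=1)[untied]
    out = winner.rename("label").reset_index().sort_values(["feature", "pair"])
    return out[["feature", "pair", "label"]].reset_index(drop=True)


def build_reference_dataset(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    pairs: tuple[tuple[str, str], ...] = STUDY_PAIRS,
    test: str = "student",
    p_threshold: float = 0.05,
    min_significant_batches: int = 3,
) -> ReferenceDataset:
    """Full-design consensus truth: intra-batch FCs → reference FCs + DEF votes.

    Computed on the uncorrected (raw log2) full-design matrix; corrected
    matrices only ever feed the cross-batch test side.
    """
    records = intra_batch_all(matrix, sheet, pairs=pairs, test=test)
    fc = build_reference_fc(
        records, p_threshold=p_threshold, min_significant_batches=min_significant_batches
    )
    votes = []
    for (batch, pair), grp in records.groupby(["batch", "pair"], sort=True):
        lab = call_defs(grp, matrix.layer, p_threshold=p_threshold)
        votes.append(
            pd.DataFrame(
                {"feature": lab.index, "pair": pair, "batch": batch, "label": lab.to_numpy()}
            )
        )
    defs = build_reference_defs(pd.concat(votes, ignore_index=True))
    return ReferenceDataset(fc=fc, defs=defs)


def _pair_stream(seed: int, repeat_index: int, pair: tuple[str, str]) -> np.random.Generator:
    tag = zlib.crc32(pair_name(*pair).encode()) % (2**16)
    return np.random.default_rng([seed, repeat_index, tag])


def sample_cross_batch_comparison(
    subset: ScenarioSubset,
    pair: tuple[str, str],
    repeat_index: int = 0,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Seeded 3-vs-3 study-sample selection for one cross-batch comparison.

    Balanced scenario: three batches are drawn and each donor contributes its
    single replicate from each (6 samples, 3 batches). Confounded scenario:
    one batch is drawn per donor and contributes all three replicates
    (6 samples, 2 batches).
    """
    num, den = pair
    rng = _pair_stream(seed, repeat_index, pair)
    t = subset.sheet.table
    study = t[t["role"] == "study"]
    sel: dict[str, list[str]] = {}
    if subset.kind == "balanced":
        batches = sorted(study["batch"].unique())
        if len(batches) < 3:
            raise ValidationError("balanced cross-batch comparison needs ≥3 batches")
        chosen = rng.choice(batches, size=3, replace=False)
        for donor in (num, den):
            ids = study[(study["donor"] == donor) & (study["batch"].isin(chosen))]["sample_id"]
            if len(ids) != 3:
                raise ValidationError(
                    f"donor {donor}: expected 3 samples in chosen batches, got {len(ids)}"
                )
            sel[donor] = list(ids)
    elif subset.kind == "confounded":
        for donor in (num, den):
            donor_batches = sorted(study.loc[study["donor"] == donor, "batch"].unique())
            if not donor_batches:
                raise ValidationError(f"donor {donor} absent from subset")
            batch = rng.choice(donor_batches)
            ids = study[(study["donor"] == donor) & (study["batch"] == batch)]["sample_id"]
            if len(ids) < 3:
                raise ValidationError(f"donor {donor}, batch {batch}: need 3 replicates")
            sel[donor] = list(ids)
    else:
        raise ValidationError(f"unknown scenario kind {subset.kind!r}")
    return sel


def cross_batch_fc(
    matrix: ExpressionMatrix,
    selection: dict[str, list[str]],
    pair: tuple[str, str],
    test: str = "student",
) -> pd.DataFrame:
    """FC records for one sampled cross-batch comparison (batch = 'cross')."""
    num, den = pair
    out = group_fc(matrix, selection[num], selection[den], test=test)
    out["pair"] = pair_name(num, den)
    out["batch"] = "cross"
    return out
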