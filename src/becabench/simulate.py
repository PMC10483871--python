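"""Synthetic multi-omics generator with explicit batch-distortion ground truth.

The measurement model is linear on the log2 scale: a measured intensity I of
feature g in sample s from batch b is

    log2 I(g, s) = a(g, b) + beta(b) * log2 C(g, donor(s)) + eps,

where C is the true abundance, a(g, b) a per-feature per-batch additive
distortion, beta(b) a per-batch gain, and eps ~ Normal(0, sigma_eps^2)
replicate noise. With a = 0, beta = 1, sigma_eps = 0 the measurement is the
identity on log2 C. The additive-offset default (beta = 1) is the regime in
which ratio scaling against in-batch reference replicates cancels the batch
term exactly.

Donor structure emulates a four-member family quartet — two monozygotic
twins (D5, D6; near-identical profiles, D6 conventionally the reference
material) plus father F7 and mother M8 — each profiled in triplicate in
every batch.

Layer realism: the transcriptomics layer exponentiates log2 intensities to
expected counts (library-size scaled) and rounds; proteomics/metabolomics
layers stay on a normalized-abundance scale and apply missing-not-at-random
masking whose probability is logistic in the (negative) log2 intensity, so
low-abundance analytes go missing more often.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import DEFAULT_DONORS, ExpressionMatrix, SampleSheet, ValidationError

#: ordered donor-pair convention: numerator is the donor later in the tuple,
#: written "num/den" (e.g. "F7/D5" means F7 over D5)
STUDY_PAIRS = (("F7", "D5"), ("M8", "D5"), ("M8", "F7"))


def pair_name(numerator: str, denominator: str) -> str:
    return f"{numerator}/{denominator}"


@dataclass
class TrueProfiles:
    """Ground-truth log2 abundances and differential labels.

    ``log2_c`` is a feature × donor grid; ``de`` is a tidy table with one row
    per (feature, donor pair) holding the realized true log2 fold change and
    its label (up/down/non at the configured effect floor).
    """

    log2_c: pd.DataFrame
    de: pd.DataFrame  # columns: feature, pair, true_log2_fc, label
    effect_floor: float
    seed: int

    @property
    def feature_ids(self) -> list[str]:
        return list(self.log2_c.index)

    @property
    def donors(self) -> list[str]:
        return list(self.log2_c.columns)

    def pair_table(self, pair: str) -> pd.DataFrame:
        t = self.de[self.de["pair"] == pair]
        if t.empty:
            raise ValidationError(f"unknown donor pair {pair!r}")
        return t.set_index("feature")


@dataclass
class BatchEffectModel:
    """Per-batch linear distortion of log2 abundances.

    ``offsets`` is a feature × batch grid of additive shifts a(g,b);
    ``gains`` is a per-batch Series (or feature × batch grid) of slopes
    beta(b) > 0; ``noise_sd`` is the replicate-noise SD on the log2 scale.
    Missingness (proteomics/metabolomics layers) is Bernoulli with
    p = sigmoid(miss_intercept + miss_slope * (−log2 I)); ``miss_intercept=None``
    disables it.
    """

    offsets: pd.DataFrame
    gains: pd.Series | pd.DataFrame
    noise_sd: float
    miss_intercept: float | None = None
    miss_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be ≥ 0")
        gains = self.gains.to_numpy() if hasattr(self.gains, "to_numpy") else np.asarray(self.gains)
        if np.any(gains <= 0):
            raise ValidationError("gains must be strictly positive")

    @property
    def batches(self) -> list[str]:
        return list(self.offsets.columns)

    def gain_for(self, batch: str) -> np.ndarray | float:
        if isinstance(self.gains, pd.DataFrame):
            return self.gains[batch].to_numpy()
        return float(self.gains[batch])

    @classmethod
    def identity(cls, features: list[str], batches: list[str]) -> "BatchEffectModel":
        """No distortion: a = 0, beta = 1, sigma_eps = 0, no missingness."""
        offsets = pd.DataFrame(0.0, index=features, columns=batches)
        gains = pd.Series(1.0, index=batches)
        return cls(offsets=offsets, gains=gains, noise_sd=0.0)

    @classmethod
    def sample(
        cls,
        features: list[str],
        batches: list[str],
        offset_sd: float = 1.0,
        gain_log2_sd: float = 0.0,
        noise_sd: float = 0.2,
        miss_intercept: float | None = None,
        miss_slope: float = 1.0,
        seed: int = 0,
    ) -> "BatchEffectModel":
        """Draw a(g,b) ~ Normal(0, offset_sd²) and, optionally, per-batch
        gains beta(b) = 2**Normal(0, gain_log2_sd²) (beta ≡ 1 by default)."""
        rng = np.random.default_rng(seed)
        offsets = pd.DataFrame(
            rng.normal(0.0, offset_sd, size=(len(features), len(batches))),
            index=features,
            columns=batches,
        )
        if gain_log2_sd > 0:
            gains = pd.Series(2.0 ** rng.normal(0.0, gain_log2_sd, size=len(batches)), index=batches)
        else:
            gains = pd.Series(1.0, index=batches)
        return cls(
            offsets=offsets,
            gains=gains,
            noise_sd=noise_sd,
            miss_intercept=miss_intercept,
            miss_slope=miss_slope,
            seed=seed,
        )


def _draw_effects(rng: np.random.Generator, spec: tuple, size: int) -> np.ndarray:
    """Signed effect magnitudes from a ("fixed", m) / ("uniform", lo, hi) /
    ("normal", mu, sd) spec; signs are ± with equal probability."""
    kind = spec[0]
    if kind == "fixed":
        mag = np.full(size, float(spec[1]))
    elif kind == "uniform":
        mag = rng.uniform(float(spec[1]), float(spec[2]), size=size)
    elif kind == "normal":
        mag = np.abs(rng.normal(float(spec[1]), float(spec[2]), size=size))
    else:
        raise ValidationError(f"unknown effect_size_dist kind {kind!r}")
    signs = rng.choice([-1.0, 1.0], size=size)
    return mag * signs


def simulate_truth(
    n_features: int = 2000,
    donors: tuple[str, ...] = DEFAULT_DONORS,
    de_fraction: float = 0.1,
    effect_size_dist: tuple = ("uniform", 1.0, 3.0),
    twins: tuple[str, str] | None = ("D5", "D6"),
    twin_divergence: float = 0.02,
    baseline_mean: float = 3.0,
    baseline_sd: float = 2.0,
    effect_floor: float = 1.0,
    seed: int = 0,
) -> TrueProfiles:
    """Ground-truth donor profiles with donor-specific differential features.

    The first donor carries the baseline profile (log2 abundances ~
    Normal(baseline_mean, baseline_sd²)); each further non-twin donor shifts
    a random ``de_fraction`` of features by draws from ``effect_size_dist``;
    a twin copies its sibling's profile except on a ``twin_divergence``
    fraction of features. Labels (up/down at ``effect_floor``, else non) are
    derived from the realized pairwise log2 fold changes.
    """
    if n_features < 1:
        raise ValidationError("n_features must be ≥ 1")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValidationError(f"de_fraction must be in [0, 1], got {de_fraction}")
    if not 0.0 <= twin_divergence <= 1.0:
        raise ValidationError("twin_divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    features = [f"F{i + 1:05d}" for i in range(n_features)]
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_features)

    twin_of: dict[str, str] = {}
    if twins is not None and twins[0] in donors and twins[1] in donors:
        twin_of[twins[1]] = twins[0]

    shifts = pd.DataFrame(0.0, index=features, columns=list(donors))
    anchor = donors[0]
    for donor in donors[1:]:
        if donor in twin_of:
            continue
        k = int(round(de_fraction * n_features))
        idx = rng.choice(n_features, size=k, replace=False)
        col = np.zeros(n_features)
        col[idx] = _draw_effects(rng, effect_size_dist, k)
        shifts[donor] = col
    for twin, sibling in twin_of.items():
        k = int(round(twin_divergence * n_features))
        idx = rng.choice(n_features, size=k, replace=False)
        col = shifts[sibling].to_numpy().copy()
        col[idx] += _draw_effects(rng, effect_size_dist, k)
        shifts[twin] = col
    _ = anchor  # anchor keeps the unshifted baseline

    log2_c = shifts.add(baseline, axis=0)
    log2_c.index.name = "feature_id"

    rows = []
    order = {d: i for i, d in enumerate(donors)}
    for i, den in enumerate(donors):
        for num in donors[i + 1 :]:
            fc = (log2_c[num] - log2_c[den]).to_numpy()
            label = np.where(fc >= effect_floor, "up", np.where(fc <= -effect_floor, "down", "non"))
            rows.append(
                pd.DataFrame(
                    {
                        "feature": features,
                        "pair": pair_name(num, den),
                        "true_log2_fc": fc,
                        "label": label,
                    }
                )
            )
    _ = order
    de = pd.concat(rows, ignore_index=True)
    return TrueProfiles(log2_c=log2_c, de=de, effect_floor=effect_floor, seed=seed)


def simulate_measurements(
    truth: TrueProfiles,
    model: BatchEffectModel,
    design: SampleSheet,
    layer: str = "transcriptomics",
    library_size: float = 1e6,
    count_noise: str = "round",
    seed: int | None = None,
) -> ExpressionMatrix:
    """Apply the linear batch-distortion model to every sample in a design.

    Transcriptomics output is a count matrix (expected counts =
    2**log2I × library_size/1e6, deterministically rounded by default, or
    Poisson-sampled with ``count_noise="poisson"``); proteomics/metabolomics
    output is a normalized-abundance matrix with MNAR missing values.
    """
    unknown = set(design.table["donor"]) - set(truth.donors)
    if unknown:
        raise ValidationError(f"design donors absent from truth: {sorted(unknown)}")
    missing_batches = set(design.table["batch"]) - set(model.batches)
    if missing_batches:
        raise ValidationError(f"design batches absent from model: {sorted(missing_batches)}")
    if count_noise not in ("round", "poisson"):
        raise ValidationError(f"count_noise must be 'round' or 'poisson', got {count_noise!r}")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    features = truth.feature_ids
    n = len(features)
    cols: dict[str, np.ndarray] = {}
    for row in design.table.itertuples(index=False):
        base = truth.log2_c[row.donor].to_numpy()
        beta = model.gain_for(row.batch)
        log2_i = model.offsets[row.batch].to_numpy() + beta * base
        if model.noise_sd > 0:
            log2_i = log2_i + rng.normal(0.0, model.noise_sd, size=n)
        if layer == "transcriptomics":
            expected = (2.0 ** log2_i) * (library_size / 1e6)
            if count_noise == "poisson":
                vals = rng.poisson(expected).astype(float)
            else:
                vals = np.rint(expected)
        else:
            vals = 2.0 ** log2_i
            if model.miss_intercept is not None:
                logit = model.miss_intercept + model.miss_slope * (-log2_i)
                p_miss = 1.0 / (1.0 + np.exp(-logit))
                vals = np.where(rng.random(n) < p_miss, np.nan, vals)
        cols[row.sample_id] = vals
    values = pd.DataFrame(cols, index=pd.Index(features, name="feature_id"))
    scale = "counts" if layer == "transcriptomics" else "normalized"
    return ExpressionMatrix(values=values, scale=scale, layer=layer)


def inject_reference_noise(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    fold_sd: float,
    seed: int = 0,
    replace: bool = False,
) -> ExpressionMatrix:
    """Degrade reference replicates with scaled per-feature noise.

    For each feature in each batch, zero-mean normal noise with SD equal to
    ``fold_sd`` times the per-feature SD across that batch's reference
    replicates is *added* to each reference replicate (study samples are
    untouched). ``replace=True`` instead substitutes the draw itself for the
    value — the literal "randomly generated with mean zero" reading, which
    discards the reference signal entirely.
    """
    if fold_sd < 0:
        raise ValidationError("fold_sd must be ≥ 0")
    out = matrix.copy()
    if fold_sd == 0 and not replace:
        return out
    rng = np.random.default_rng(seed)
    t = sheet.table
    for batch in sheet.batches:
        ref_ids = t[(t["batch"] == batch) & (t["role"] == "reference")]["sample_id"].tolist()
        if len(ref_ids) < 2:
            raise ValidationError(
                f"batch {batch}: need ≥2 reference replicates to estimate SD, got {len(ref_ids)}"
            )
        block = out.values[ref_ids].to_numpy()
        sd = np.nanstd(block, axis=1, ddof=1)
        noise = rng.normal(0.0, 1.0, size=block.shape) * (fold_sd * sd)[:, None]
        out.values[ref_ids] = noise if replace else block + noise
    return out


def degrade_reference_counts(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    pct_genes: float,
    factor: float,
    seed: int = 0,
) -> ExpressionMatrix:
    """Reduce a random gene subset's counts in each reference replicate.

    Emulates gene-specific RNA degradation in a low-quality reference
    library: per reference replicate *independently*, ``floor(pct_genes × G)``
    features have their counts multiplied by ``factor`` (typically 1/2, 1/4,
    or 1/8) and rounded, so the affected gene sets differ across replicates
    of the same batch. Study samples are untouched.
    """
    if matrix.scale != "counts":
        raise ValidationError(f"degrade_reference_counts needs a counts matrix, got {matrix.scale}")
    if not 0.0 <= pct_genes <= 1.0:
        raise ValidationError("pct_genes must be in [0, 1]")
    if not 0.0 < factor <= 1.0:
        raise ValidationError("factor must be in (0, 1]")
    out = matrix.copy()
    if pct_genes == 0.0 or factor == 1.0:
        return out
    rng = np.random.default_rng(seed)
    n = out.shape[0]
    k = int(np.floor(pct_genes * n))
    for ref_id in sheet.reference_ids:
        if ref_id not in out.values.columns:
            continue
        idx = rng.choice(n, size=k, replace=False)
        col = out.values[ref_id].to_numpy()
        col[idx] = np.rint(col[idx] * factor)
        out.values[ref_id] = col
    return out


# -- convenience: one call per omics layer ------------------------------------

#: per-layer generator defaults; offset SD is largest for metabolomics, where
#: batch effects run highest among the three layers
LAYER_DEFAULTS: dict[str, dict] = {
    "transcriptomics": dict(baseline_mean=3.0, baseline_sd=2.0, offset_sd=1.0,
                            miss_intercept=None, miss_slope=1.0),
    "proteomics": dict(baseline_mean=3.0, baseline_sd=2.0, offset_sd=1.0,
                       miss_intercept=-2.0, miss_slope=1.0),
    "metabolomics": dict(baseline_mean=6.0, baseline_sd=2.0, offset_sd=1.5,
                         miss_intercept=-2.0, miss_slope=0.5),
}


@dataclass
class LayerSimulation:
    """Bundled output of :func:`simulate_layer`."""

    matrix: ExpressionMatrix
    sheet: SampleSheet
    truth: TrueProfiles
    model: BatchEffectModel
    params: dict = field(default_factory=dict)


def simulate_layer(
    layer: str,
    design: SampleSheet,
    n_features: int = 2000,
    de_fraction: float = 0.1,
    noise_sd: float = 0.2,
    offset_sd: float | None = None,
    truth: TrueProfiles | None = None,
    seed: int = 0,
    **overrides,
) -> LayerSimulation:
    """Simulate one omics layer over a design sheet with layer defaults.

    A shared ``truth`` may be passed so all layers of a multi-omics run carry
    the same underlying biology (the matched-material assumption); otherwise
    truth is drawn from ``seed``.
    """
    if layer not in LAYER_DEFAULTS:
        raise ValidationError(f"unknown layer {layer!r}")
    params = dict(LAYER_DEFAULTS[layer])
    params.update(overrides)
    if offset_sd is not None:
        params["offset_sd"] = offset_sd
    if truth is None:
        truth = simulate_truth(
            n_features=n_features,
            de_fraction=de_fraction,
            baseline_mean=params["baseline_mean"],
            baseline_sd=params["baseline_sd"],
            seed=seed,
        )
    batches = design.batches
    model = BatchEffectModel.sample(
        features=truth.feature_ids,
        batches=batches,
        offset_sd=params["offset_sd"],
        noise_sd=noise_sd,
        miss_intercept=params["miss_intercept"],
        miss_slope=params["miss_slope"],
        seed=seed + 1,
    )
    matrix = simulate_measurements(truth, model, design, layer=layer, seed=seed + 2)
    return LayerSimulation(matrix=matrix, sheet=design, truth=truth, model=model, params=params)
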