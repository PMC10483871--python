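"""Cross-batch prediction harness and multi-omics integration clustering.

Prediction emulates the clinical use of multi-batch expression data: models
for donor-level endpoints (sex: the father vs the female donors; age: twin
daughters vs parents) are trained on the chronologically earlier batches
with repeated cross-validation (25 runs of 5-fold by default) and validated
on the later batches, so any residual batch structure inflates or deflates
the external-layer metrics.

Integration clusters matched samples across omics layers. The native
baseline standardizes features per layer, concatenates, and spectrally
clusters; a similarity-network-fusion (SNF) method builds per-layer sample
affinity graphs (scaled exponential kernel), cross-diffuses them, and
clusters the fused graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.cluster import SpectralClustering
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score
from sklearn.neighbors import NearestCentroid
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .core_io import ExpressionMatrix, SampleSheet, ValidationError
from . import metrics as _metrics

#: donor → endpoint label maps: F7 is the male parent; the twins are young
ENDPOINTS: dict[str, dict[str, str]] = {
    "sex": {"D5": "female", "D6": "female", "F7": "male", "M8": "female"},
    "age": {"D5": "young", "D6": "young", "F7": "old", "M8": "old"},
}


def endpoint_labels(sheet: SampleSheet, endpoint: str) -> pd.Series:
    """Per-sample binary endpoint labels inherited from the donor."""
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"unknown endpoint {endpoint!r}; known: {sorted(ENDPOINTS)}")
    mapping = ENDPOINTS[endpoint]
    unknown = set(sheet.table["donor"]) - set(mapping)
    if unknown:
        raise ValidationError(f"donors without {endpoint} label: {sorted(unknown)}")
    return sheet.table.set_index("sample_id")["donor"].map(mapping)


def _make_estimator(classifier, params: dict) -> BaseEstimator:
    if isinstance(classifier, BaseEstimator):
        est = clone(classifier)
        est.set_params(**params)
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if classifier == "nearest_centroid":
        return Pipeline([("scale", StandardScaler()), ("clf", NearestCentroid(**params))])
    if classifier == "logistic":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", LogisticRegression(max_iter=2000, **params))]
        )
    raise ValidationError(f"unknown classifier {classifier!r}")


_DEFAULT_GRIDS: dict[str, list[dict]] = {
    "nearest_centroid": [{}],
    "logistic": [{"C": 0.01}, {"C": 1.0}, {"C": 100.0}],
}


@dataclass
class FittedModel:
    """A refit classifier plus its CV provenance."""

    estimator: BaseEstimator
    feature_ids: list[str]
    classes: list[str]
    cv_score: float
    best_params: dict = field(default_factory=dict)
    classifier: str = "custom"

    @property
    def positive_class(self) -> str:
        # deterministic convention: lexicographically last class is "positive"
        return self.classes[-1]


def cv_train(
    train: ExpressionMatrix,
    labels: pd.Series,
    classifier="nearest_centroid",
    param_grid: list[dict] | None = None,
    n_repeats: int = 25,
    n_folds: int = 5,
    seed: int = 0,
) -> FittedModel:
    """Repeated-CV model selection, then refit on the full training set.

    Hyperparameters are chosen by mean MCC over ``n_repeats`` runs of
    ``n_folds``-fold stratified CV (25×5 by default); the winning setting is
    refit on all training samples. Fold assignment is fully seeded.
    """
    y = labels.loc[train.sample_ids]
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValidationError("training labels contain a single class")
    counts = y.value_counts()
    if counts.min() < n_folds:
        raise ValidationError(
            f"smallest class has {counts.min()} samples; need ≥ n_folds={n_folds}"
        )
    if param_grid is None:
        param_grid = _DEFAULT_GRIDS.get(classifier, [{}]) if isinstance(classifier, str) else [{}]
    x = train.values.to_numpy().T
    cv = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
    best_score, best_params = -np.inf, {}
    import warnings as _warnings

    with _warnings.catch_warnings():
        # batch-centered data can leave within-class-constant features
        _warnings.filterwarnings("ignore", message=".*zero standard deviation.*")
        for params in param_grid:
            est = _make_estimator(classifier, params)
            scores = cross_val_score(
                est, x, y.to_numpy(), cv=cv,
                scoring=lambda e, xx, yy: matthews_corrcoef(yy, e.predict(xx)),
            )
            score = float(np.mean(scores))
            if score > best_score:
                best_score, best_params = score, params
        final = _make_estimator(classifier, best_params)
        final.fit(x, y.to_numpy())
    return FittedModel(
        estimator=final,
        feature_ids=list(train.feature_ids),
        classes=classes,
        cv_score=best_score,
        best_params=best_params,
        classifier=classifier if isinstance(classifier, str) else type(classifier).__name__,
    )


def validate(model: FittedModel, validation: ExpressionMatrix, labels: pd.Series) -> dict[str, float]:
    """External-layer evaluation on held-out samples.

    Returns MCC, F1, sensitivity, specificity, precision, accuracy, and
    positive/negative predictive values computed from the prediction
    confusion (positive class = :attr:`FittedModel.positive_class`).
    """
    if list(validation.feature_ids) != model.feature_ids:
        raise ValidationError("validation features do not match training features")
    y = labels.loc[validation.sample_ids].to_numpy()
    pred = model.estimator.predict(validation.values.to_numpy().T)
    pos = model.positive_class
    c = _metrics.ConfusionCounts(
        tp=int(np.sum((pred == pos) & (y == pos))),
        tn=int(np.sum((pred != pos) & (y != pos))),
        fp=int(np.sum((pred == pos) & (y != pos))),
        fn=int(np.sum((pred != pos) & (y == pos))),
    )
    return {
        "mcc": _metrics.mcc(c),
        "f1": _metrics.f1(c),
        "sensitivity": _metrics.sensitivity(c),
        "specificity": _metrics.specificity(c),
        "precision": _metrics.precision(c),
        "accuracy": _metrics.accuracy(c),
        "ppv": _metrics.precision(c),
        "npv": _metrics.npv(c),
    }


# -- multi-omics integration --------------------------------------------------


def _align_layers(
    matrices: dict[str, ExpressionMatrix],
    sheets: dict[str, SampleSheet],
    sample_ids: dict[str, list[str]],
) -> tuple[dict[str, list[str]], pd.Series]:
    """Order each layer's selection by (donor, batch_order, replicate) and
    align positionally within donor; donor sequences must agree."""
    ordered: dict[str, list[str]] = {}
    donor_seqs: dict[str, list[str]] = {}
    for layer, ids in sample_ids.items():
        t = sheets[layer].table.set_index("sample_id").loc[ids].reset_index()
        t = t.sort_values(["donor", "batch_order", "replicate"])
        missing = set(t["sample_id"]) - set(matrices[layer].sample_ids)
        if missing:
            raise ValidationError(f"layer {layer!r}: samples missing from matrix: {sorted(missing)}")
        ordered[layer] = list(t["sample_id"])
        donor_seqs[layer] = list(t["donor"])
    seqs = list(donor_seqs.values())
    if any(s != seqs[0] for s in seqs[1:]):
        raise ValidationError("layers are unalignable: per-donor sample counts differ")
    first = next(iter(ordered))
    donors = pd.Series(donor_seqs[first], index=ordered[first], name="donor")
    return ordered, donors


def _snf_affinity(x: np.ndarray, k: int, alpha: float) -> np.ndarray:
    """Scaled exponential similarity kernel on euclidean distances."""
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    n = d.shape[0]
    k = min(k, n - 1)
    sorted_d = np.sort(d, axis=1)
    mean_knn = sorted_d[:, 1 : k + 1].mean(axis=1)  # exclude self-distance 0
    eps = (mean_knn[:, None] + mean_knn[None, :] + d) / 3.0 + 1e-12
    w = np.exp(-(d**2) / (2.0 * (alpha * eps) ** 2))
    return (w + w.T) / 2.0


def _snf_fuse(affinities: list[np.ndarray], k: int, t: int) -> np.ndarray:
    """Cross-diffusion of per-layer affinity graphs (similarity network fusion)."""
    n = affinities[0].shape[0]
    k = min(k, n - 1)

    def full_kernel(w: np.ndarray) -> np.ndarray:
        p = w / (2.0 * w.sum(axis=1, keepdims=True))
        np.fill_diagonal(p, 0.5)
        return p

    def sparse_kernel(w: np.ndarray) -> np.ndarray:
        s = np.zeros_like(w)
        for i in range(n):
            nn = np.argsort(w[i])[::-1]
            nn = nn[nn != i][:k]
            s[i, nn] = w[i, nn]
        return s / s.sum(axis=1, keepdims=True)

    ps = [full_kernel(w) for w in affinities]
    ss = [sparse_kernel(w) for w in affinities]
    m = len(ps)
    for _ in range(t):
        nxt = []
        for v in range(m):
            others = [ps[u] for u in range(m) if u != v] or [ps[v]]
            avg = np.mean(others, axis=0)
            p = ss[v] @ avg @ ss[v].T
            nxt.append((p + p.T) / 2.0)
        ps = [full_kernel(p + 1e-12) for p in nxt]
    fused = np.mean(ps, axis=0)
    return (fused + fused.T) / 2.0


def integrate_cluster(
    matrices: dict[str, ExpressionMatrix],
    sheets: dict[str, SampleSheet],
    sample_ids: dict[str, list[str]],
    method: str = "concat_spectral",
    k: int = 3,
    snf_neighbors: int = 12,
    snf_alpha: float = 0.5,
    snf_iterations: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Cluster matched multi-omics samples into ``k`` groups.

    ``concat_spectral`` standardizes features per layer, concatenates, and
    runs spectral clustering; ``snf`` fuses per-layer affinity graphs
    (K=12 neighbors, kernel hyperparameter 0.5, 10 diffusion iterations by
    default) and clusters the fused graph. Returns cluster labels indexed by
    the first layer's sample ids; the partition is invariant (up to
    relabeling) to sample order.
    """
    if k < 1:
        raise ValidationError("k must be ≥ 1")
    ordered, donors = _align_layers(matrices, sheets, sample_ids)
    blocks = []
    for layer, ids in ordered.items():
        x = matrices[layer].values[ids].to_numpy().T  # samples × features
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
        blocks.append(x)
    index = pd.Index(ordered[next(iter(ordered))], name="sample_id")
    if k == 1:
        return pd.Series(0, index=index, name="cluster")
    n = blocks[0].shape[0]
    import warnings as _warnings

    with _warnings.catch_warnings():
        # well-separated groups disconnect the kNN graph; harmless here
        _warnings.filterwarnings("ignore", message="Graph is not fully connected")
        if method == "concat_spectral":
            x = np.hstack(blocks)
            sc = SpectralClustering(
                n_clusters=k,
                affinity="nearest_neighbors",
                n_neighbors=min(12, n - 1),
                assign_labels="kmeans",
                random_state=seed,
            )
            labels = sc.fit_predict(x)
        elif method == "snf":
            affinities = [_snf_affinity(b, k=snf_neighbors, alpha=snf_alpha) for b in blocks]
            fused = _snf_fuse(affinities, k=snf_neighbors, t=snf_iterations)
            sc = SpectralClustering(
                n_clusters=k, affinity="precomputed", assign_labels="kmeans", random_state=seed
            )
            labels = sc.fit_predict(fused)
        else:
            raise ValidationError(f"unknown integration method {method!r}")
    _ = donors
    return pd.Series(labels, index=index, name="cluster")
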