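"""End-to-end benchmark orchestration: simulate → preprocess → correct → evaluate.

:func:`run_benchmark` executes the full evaluation grid — every scenario ×
correction × omics layer — on synthetic data and collects tidy metric
records plus a min–max-scaled total score ranking the corrections.
:func:`run_ref_quality_sweep` measures how ratio-based scaling degrades as
reference-sample quality falls (added reference noise, or count reduction in
random gene subsets).

All randomness fans out from one master seed into named sub-streams
(simulation / scenario / DE sampling / CV folds / integration), so any stage
is independently reproducible and a rerun with the same seed is identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import becas as _becas
from . import diffexp as _de
from . import downstream as _ds
from . import metrics as _metrics
from . import preprocess as _prep
from . import scenarios as _scen
from . import simulate as _sim
from .core_io import DEFAULT_DONORS, ExpressionMatrix, SampleSheet, ValidationError

_ALL_FAMILIES = ("snr", "de", "prediction", "integration")


@dataclass
class RunConfig:
    """Benchmark configuration (defaults are the reference study conditions).

    15 batches × 4 donors × 3 replicates per omics layer; D6 as reference
    material; 2000 features per layer; 10% differential features; additive
    batch offsets (SD 1.0, metabolomics 1.5); replicate noise SD 0.2;
    15 cross-batch DE repeats and 10 integration repeats.
    """

    layers: list[str] = field(default_factory=lambda: list(_sim.LAYER_DEFAULTS))
    n_features: int = 2000
    n_batches: int = 15
    reps: int = 3
    donors: tuple[str, ...] = DEFAULT_DONORS
    reference_donor: str = "D6"
    de_fraction: float = 0.1
    noise_sd: float = 0.2
    offset_sd: dict | None = None  # per-layer override, e.g. {"transcriptomics": 2.0}
    becas: list[str] = field(default_factory=lambda: ["raw", "bmc", "ratio"])
    scenarios: list[str] = field(default_factory=lambda: ["balanced", "confounded"])
    metric_families: tuple[str, ...] = _ALL_FAMILIES
    de_repeats: int = 15
    integration_repeats: int = 10
    integration_samples: int = 36
    integration_batches: int = 12
    integration_method: str = "concat_spectral"
    n_ref_replicates: int = 3
    classifier: str = "nearest_centroid"
    cv_repeats: int = 25
    cv_folds: int = 5
    n_train_batches: int = 9
    endpoints: list[str] = field(default_factory=lambda: ["sex", "age"])
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.becas) - set(_becas.list_becas())
        if unknown:
            raise ValidationError(f"unregistered BECAs: {sorted(unknown)}")
        bad = set(self.metric_families) - set(_ALL_FAMILIES)
        if bad:
            raise ValidationError(f"unknown metric families: {sorted(bad)}")
        if self.de_repeats < 1 or self.integration_repeats < 1:
            raise ValidationError("repeat counts must be ≥ 1")
        self.donors = tuple(self.donors)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _streams(seed: int) -> dict[str, int]:
    """Named 31-bit sub-seeds fanned out from the master seed."""
    state = np.random.SeedSequence(seed).generate_state(8)
    names = ["simulation", "scenario", "de", "cv", "integration", "beca", "sweep", "spare"]
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


@dataclass
class MetricReport:
    """Tidy per-repeat metric records plus the scaled total-score ranking."""

    records: pd.DataFrame  # scenario, beca, layer, repeat, metric, value
    total_scores: pd.DataFrame | None
    provenance: dict

    def summary(self) -> pd.DataFrame:
        """Mean metric value per (scenario, beca, layer, metric)."""
        return (
            self.records.groupby(["scenario", "beca", "layer", "metric"])["value"]
            .mean()
            .reset_index()
        )

    def mean_metric(self, metric: str, **filters) -> float:
        t = self.records[self.records["metric"] == metric]
        for col, val in filters.items():
            t = t[t[col] == val]
        if t.empty:
            raise ValidationError(f"no records for metric {metric!r} with {filters}")
        return float(t["value"].mean())

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "metrics.tsv", sep="\t", index=False)
        payload = {"provenance": self.provenance}
        if self.total_scores is not None:
            self.total_scores.to_csv(out / "total_scores.tsv", sep="\t")
            payload["total_scores"] = self.total_scores.reset_index().to_dict(orient="records")
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


@dataclass
class _LayerState:
    """Per-layer intermediates shared across scenarios and corrections."""

    log2_full: ExpressionMatrix
    full_sheet: SampleSheet
    reference: _de.ReferenceDataset
    subsets: dict[str, _scen.ScenarioSubset]
    corrected: dict[tuple[str, str], ExpressionMatrix] = field(default_factory=dict)


def _prepare_layer(
    layer: str, config: RunConfig, full: SampleSheet, sim_seed: int, scen_seed: int,
    layer_index: int,
) -> _LayerState:
    offset_sd = (config.offset_sd or {}).get(layer)
    sim = _sim.simulate_layer(
        layer,
        full,
        n_features=config.n_features,
        de_fraction=config.de_fraction,
        noise_sd=config.noise_sd,
        offset_sd=offset_sd,
        seed=sim_seed,
    )
    norm = _prep.cpm_normalize(sim.matrix) if sim.matrix.scale == "counts" else sim.matrix

    subsets: dict[str, _scen.ScenarioSubset] = {}
    for kind in config.scenarios:
        builder = _scen.build_balanced if kind == "balanced" else _scen.build_confounded
        subsets[kind] = builder(full, config.reference_donor, seed=scen_seed + layer_index)

    # detection is scenario-aware: keep features detected in every scenario subset
    detected: set[str] | None = None
    for subset in subsets.values():
        ids = [s for s in subset.sheet.sample_ids if s in set(norm.sample_ids)]
        found = set(_prep.filter_detected(norm.subset_samples(ids)))
        detected = found if detected is None else detected & found
    if detected is None:  # no scenarios configured: detect on the full matrix
        detected = set(_prep.filter_detected(norm))
    if len(detected) < 10:
        raise ValidationError(f"layer {layer!r}: only {len(detected)} detected features")
    keep = [f for f in norm.feature_ids if f in detected]

    imputed = _prep.impute_missing(norm, strategy="zero")
    log2_full = _prep.floor_log2(imputed).subset_features(keep)
    reference = _de.build_reference_dataset(log2_full, full)
    return _LayerState(
        log2_full=log2_full, full_sheet=full, reference=reference, subsets=subsets
    )


def _evaluate_de(
    corrected: ExpressionMatrix,
    subset: _scen.ScenarioSubset,
    reference: _de.ReferenceDataset,
    layer: str,
    n_repeats: int,
    seed: int,
) -> list[dict]:
    rows = []
    for repeat in range(n_repeats):
        for pair in _sim.STUDY_PAIRS:
            name = _sim.pair_name(*pair)
            sel = _de.sample_cross_batch_comparison(subset, pair, repeat_index=repeat, seed=seed)
            rec = _de.cross_batch_fc(corrected, sel, pair)
            test_fc = rec.set_index("feature")["log2_fc"]
            ref_fc = reference.pair_fc(name)
            ref_defs = reference.pair_defs(name)
            labels = _de.call_defs(rec, layer)
            common = labels.index.intersection(ref_defs.index)
            conf = _metrics.confusion(labels, ref_defs)
            test_set = set(labels.loc[common][labels.loc[common] != "non"].index)
            ref_set = set(ref_defs.loc[common][ref_defs.loc[common] != "non"].index)
            for metric, value in (
                ("rc", _metrics.rc(test_fc, ref_fc)),
                ("mcc_defs", _metrics.mcc(conf)),
                ("jaccard_defs", _metrics.jaccard(test_set, ref_set)),
            ):
                rows.append({"repeat": repeat, "pair": name, "metric": metric, "value": value})
    return rows


def _evaluate_prediction(
    corrected: ExpressionMatrix,
    subset: _scen.ScenarioSubset,
    config: RunConfig,
    seed: int,
) -> list[dict]:
    train_ids, valid_ids = _scen.chrono_split(subset, n_train_batches=config.n_train_batches)
    rows = []
    for endpoint in config.endpoints:
        labels = _ds.endpoint_labels(subset.sheet, endpoint)
        counts = labels.loc[train_ids].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            continue  # chronological split left a degenerate training set
        model = _ds.cv_train(
            corrected.subset_samples(train_ids),
            labels,
            classifier=config.classifier,
            n_repeats=config.cv_repeats,
            n_folds=min(config.cv_folds, int(counts.min())),
            seed=seed,
        )
        result = _ds.validate(model, corrected.subset_samples(valid_ids), labels)
        rows.append(
            {"repeat": 0, "pair": endpoint, "metric": "mcc_prediction", "value": result["mcc"]}
        )
        rows.append({"repeat": 0, "pair": endpoint, "metric": "f1_prediction", "value": result["f1"]})
    return rows


def run_benchmark(config: RunConfig) -> MetricReport:
    """Execute the full scenario × correction × layer evaluation grid.

    Returns per-repeat metric records (SNR; RC / MCC / Jaccard of DEFs over
    cross-batch repeats; prediction MCC and F1 per endpoint; integration ARI
    per repeat) and, when all four score families were computed, the
    min–max-scaled total-score ranking of the corrections.
    """
    streams = _streams(config.seed)
    full = _scen.build_full_design(
        n_batches=config.n_batches,
        donors=config.donors,
        reps=config.reps,
        reference_donor=config.reference_donor,
    )
    layer_states: dict[str, _LayerState] = {}
    for i, layer in enumerate(config.layers):
        layer_states[layer] = _prepare_layer(
            layer, config, full, sim_seed=streams["simulation"] + i,
            scen_seed=streams["scenario"], layer_index=i,
        )

    rows: list[dict] = []
    for layer, state in layer_states.items():
        for kind in config.scenarios:
            subset = state.subsets[kind]
            sub_matrix = state.log2_full.subset_samples(subset.sheet.sample_ids)
            study_sheet = subset.sheet.subset(subset.study_ids)
            study_matrix = sub_matrix.subset_samples(subset.study_ids)
            for beca in config.becas:
                cov = {"n_ref_replicates": config.n_ref_replicates, "seed": streams["beca"]}
                # only reference-based corrections are handed the reference replicates
                if _becas.beca_uses_reference(beca):
                    corrected = _becas.apply_beca(beca, sub_matrix, subset.sheet, cov).corrected
                else:
                    corrected = _becas.apply_beca(beca, study_matrix, study_sheet, cov).corrected
                state.corrected[(kind, beca)] = corrected
                base = {"scenario": kind, "beca": beca, "layer": layer}
                if "snr" in config.metric_families:
                    study = corrected.subset_samples(subset.study_ids)
                    value = _metrics.snr_from_matrix(study, subset.sheet.donor_of())
                    rows.append({**base, "repeat": 0, "pair": "", "metric": "snr", "value": value})
                if "de" in config.metric_families:
                    for r in _evaluate_de(
                        corrected, subset, state.reference, layer,
                        n_repeats=config.de_repeats, seed=streams["de"],
                    ):
                        rows.append({**base, **r})
                if "prediction" in config.metric_families:
                    for r in _evaluate_prediction(corrected, subset, config, seed=streams["cv"]):
                        rows.append({**base, **r})

    if "integration" in config.metric_families:
        for kind in config.scenarios:
            selections = _scen.integration_subset(
                {layer: layer_states[layer].subsets[kind] for layer in config.layers},
                n_samples=config.integration_samples,
                n_batches=config.integration_batches,
                n_repeats=config.integration_repeats,
                seed=streams["integration"],
            )
            for beca in config.becas:
                matrices = {
                    layer: layer_states[layer].corrected[(kind, beca)]
                    for layer in config.layers
                }
                sheets = {layer: layer_states[layer].subsets[kind].sheet for layer in config.layers}
                for repeat, sel in enumerate(selections):
                    partition = _ds.integrate_cluster(
                        matrices, sheets, sel,
                        method=config.integration_method,
                        k=3, seed=streams["integration"],
                    )
                    first_layer = config.layers[0]
                    donors = sheets[first_layer].donor_of().loc[partition.index]
                    value = _metrics.ari(partition, donors)
                    rows.append(
                        {
                            "scenario": kind, "beca": beca, "layer": "multiomics",
                            "repeat": repeat, "pair": "", "metric": "ari", "value": value,
                        }
                    )

    records = pd.DataFrame(
        rows, columns=["scenario", "beca", "layer", "repeat", "pair", "metric", "value"]
    )

    total = None
    wanted = {"snr": "snr", "mcc_defs": "de", "mcc_prediction": "prediction", "ari": "integration"}
    if all(f in config.metric_families for f in wanted.values()):
        table = pd.DataFrame(
            {
                metric: records[records["metric"] == metric].groupby("beca")["value"].mean()
                for metric in wanted
            }
        ).loc[config.becas]
        total = _metrics.total_score(table)

    provenance = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "streams": _streams(config.seed),
    }
    return MetricReport(records=records, total_scores=total, provenance=provenance)


def run_ref_quality_sweep(
    config: RunConfig,
    fold_sds: list[float] | None = None,
    degradations: list[tuple[float, float]] | None = None,
    layers: list[str] | None = None,
) -> pd.DataFrame:
    """SNR of ratio-scaled data under degrading reference-sample quality.

    ``fold_sds`` adds zero-mean noise to reference replicates with SD equal
    to the given multiples of the in-batch reference SD (on the log2 scale);
    ``degradations`` is a list of (pct_genes, factor) count reductions
    (transcriptomics-style). Each grid row also carries the uncorrected
    (raw) SNR of the same subset for comparison. Returns a tidy frame with
    columns scenario, layer, mode, level, beca, snr.
    """
    if not fold_sds and not degradations:
        raise ValidationError("provide a non-empty fold_sds or degradations grid")
    if "ratio" not in config.becas:
        raise ValidationError("reference-quality sweep requires the ratio BECA")
    layers = layers or [config.layers[0]]
    streams = _streams(config.seed)
    full = _scen.build_full_design(
        n_batches=config.n_batches, donors=config.donors,
        reps=config.reps, reference_donor=config.reference_donor,
    )
    rows: list[dict] = []
    for i, layer in enumerate(layers):
        state = _prepare_layer(
            layer, config, full, sim_seed=streams["simulation"] + i,
            scen_seed=streams["scenario"], layer_index=i,
        )
        for kind, subset in state.subsets.items():
            sub = state.log2_full.subset_samples(subset.sheet.sample_ids)
            donor_of = subset.sheet.donor_of()
            raw_snr = _metrics.snr_from_matrix(sub.subset_samples(subset.study_ids), donor_of)
            for fold in fold_sds or []:
                noisy = _sim.inject_reference_noise(
                    sub, subset.sheet, fold_sd=fold, seed=streams["sweep"]
                )
                corr = _becas.correct_ratio(
                    noisy, subset.sheet, n_ref_replicates=config.n_ref_replicates,
                    seed=streams["beca"],
                ).corrected
                value = _metrics.snr_from_matrix(corr.subset_samples(subset.study_ids), donor_of)
                rows.append(dict(scenario=kind, layer=layer, mode="noise", level=fold,
                                 beca="ratio", snr=value))
                rows.append(dict(scenario=kind, layer=layer, mode="noise", level=fold,
                                 beca="raw", snr=raw_snr))
        if degradations and layer == "transcriptomics":
            sim = _sim.simulate_layer(
                layer, full, n_features=config.n_features, de_fraction=config.de_fraction,
                noise_sd=config.noise_sd, offset_sd=(config.offset_sd or {}).get(layer),
                seed=streams["simulation"] + i,
            )
            for pct, factor in degradations:
                degraded = _sim.degrade_reference_counts(
                    sim.matrix, full, pct_genes=pct, factor=factor, seed=streams["sweep"]
                )
                norm = _prep.cpm_normalize(degraded)
                log2_full = _prep.floor_log2(_prep.impute_missing(norm, strategy="zero"))
                log2_full = log2_full.subset_features(state.log2_full.feature_ids)
                for kind, subset in state.subsets.items():
                    sub = log2_full.subset_samples(subset.sheet.sample_ids)
                    donor_of = subset.sheet.donor_of()
                    corr = _becas.correct_ratio(
                        sub, subset.sheet, n_ref_replicates=config.n_ref_replicates,
                        seed=streams["beca"],
                    ).corrected
                    value = _metrics.snr_from_matrix(
                        corr.subset_samples(subset.study_ids), donor_of
                    )
                    raw_snr = _metrics.snr_from_matrix(
                        sub.subset_samples(subset.study_ids), donor_of
                    )
                    rows.append(dict(scenario=kind, layer=layer, mode="degradation",
                                     level=f"{pct:g}@{factor:g}", beca="ratio", snr=value))
                    rows.append(dict(scenario=kind, layer=layer, mode="degradation",
                                     level=f"{pct:g}@{factor:g}", beca="raw", snr=raw_snr))
    return pd.DataFrame(rows)
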