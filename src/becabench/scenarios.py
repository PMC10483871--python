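"""Construction of the benchmark's experimental designs and sample splits.

The full design mirrors a multi-batch reference-material study: every batch
profiles all four donors in triplicate (12 libraries/batch), with one donor
(default D6, one of the monozygotic twins) serving as the concurrent
reference material. Two evaluation scenarios are carved out of it:

balanced
    every study donor contributes one replicate to every batch, so biology
    and batch are orthogonal;
confounded
    batches are partitioned among the study donors, so each donor's samples
    come entirely from its own batches and biology is inseparable from batch
    without an anchor.

Both scenarios retain all reference replicates of every selected batch and
hold the same study-sample count, so metric differences reflect design, not
sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DEFAULT_DONORS, SampleSheet, ValidationError


@dataclass
class ScenarioSubset:
    """A balanced or confounded slice of the full design."""

    kind: str  # "balanced" | "confounded"
    sheet: SampleSheet  # restricted to the selected samples
    reference_donor: str
    seed: int

    @property
    def study_ids(self) -> list[str]:
        return self.sheet.study_ids

    @property
    def reference_ids(self) -> list[str]:
        return self.sheet.reference_ids


def make_sample_id(donor: str, batch: str, replicate: int) -> str:
    return f"{donor}_{batch}_R{replicate}"


def build_full_design(
    n_batches: int = 15,
    donors: tuple[str, ...] = DEFAULT_DONORS,
    reps: int = 3,
    reference_donor: str = "D6",
) -> SampleSheet:
    """Full design: every donor in triplicate in every batch.

    Defaults give 15 batches × 4 donors × 3 replicates = 180 libraries.
    ``batch_order`` ranks batches by processing date (1..n_batches).
    """
    if n_batches < 1 or reps < 1 or len(donors) < 1:
        raise ValidationError("n_batches, reps, and donor count must all be ≥ 1")
    if reference_donor not in donors:
        raise ValidationError(f"reference donor {reference_donor!r} not among donors {donors}")
    width = len(str(n_batches))
    rows = []
    for b in range(1, n_batches + 1):
        batch = f"B{b:0{width}d}"
        for donor in donors:
            for r in range(1, reps + 1):
                rows.append(
                    {
                        "sample_id": make_sample_id(donor, batch, r),
                        "donor": donor,
                        "replicate": r,
                        "batch": batch,
                        "batch_order": b,
                        "role": "reference" if donor == reference_donor else "study",
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


def build_balanced(full: SampleSheet, reference_donor: str = "D6", seed: int = 0) -> ScenarioSubset:
    """Balanced scenario: one random replicate per study donor per batch.

    All reference replicates of every batch are retained. With the default
    full design this yields 45 study + 45 reference samples.
    """
    rng = np.random.default_rng(seed)
    t = full.table
    study_donors = [d for d in full.donors if d != reference_donor]
    keep: list[str] = []
    for batch in full.batches:
        ref = t[(t["batch"] == batch) & (t["donor"] == reference_donor)]
        if ref.empty:
            raise ValidationError(f"reference donor {reference_donor!r} absent from batch {batch}")
        keep.extend(ref["sample_id"])
        for donor in study_donors:
            cand = t[(t["batch"] == batch) & (t["donor"] == donor)]["sample_id"].tolist()
            if not cand:
                raise ValidationError(f"donor {donor!r} absent from batch {batch}")
            keep.append(cand[rng.integers(len(cand))])
    sub = full.subset(keep)
    # balanced subsets mark only the reference donor's samples as reference
    table = sub.table.copy()
    table["role"] = np.where(table["donor"] == reference_donor, "reference", "study")
    return ScenarioSubset("balanced", SampleSheet(table), reference_donor, seed)


def build_confounded(
    full: SampleSheet, reference_donor: str = "D6", seed: int = 0
) -> ScenarioSubset:
    """Confounded scenario: batches partitioned equally among study donors.

    Each study donor contributes *all* its replicates, but only from its
    randomly assigned batch group; reference replicates from every batch are
    retained. Requires the batch count to divide evenly by the number of
    study donors.
    """
    rng = np.random.default_rng(seed)
    t = full.table
    study_donors = [d for d in full.donors if d != reference_donor]
    batches = full.batches
    if len(batches) % len(study_donors) != 0:
        raise ValidationError(
            f"{len(batches)} batches not divisible by {len(study_donors)} study donors"
        )
    per = len(batches) // len(study_donors)
    shuffled = list(rng.permutation(batches))
    assignment = {
        donor: set(shuffled[i * per : (i + 1) * per]) for i, donor in enumerate(study_donors)
    }
    keep = list(t.loc[t["donor"] == reference_donor, "sample_id"])
    for donor, group in assignment.items():
        keep.extend(t[(t["donor"] == donor) & (t["batch"].isin(group))]["sample_id"])
    sub = full.subset(keep)
    table = sub.table.copy()
    table["role"] = np.where(table["donor"] == reference_donor, "reference", "study")
    return ScenarioSubset("confounded", SampleSheet(table), reference_donor, seed)


def chrono_split(subset: ScenarioSubset, n_train_batches: int = 9) -> tuple[list[str], list[str]]:
    """Chronological train/validation split of the study samples.

    Study samples from the first ``n_train_batches`` batches (by
    ``batch_order``, standing in for data-generation date) form the training
    set; the rest the validation set. Defaults split 45 study samples 27/18.
    """
    batches = subset.sheet.batches
    if n_train_batches >= len(batches):
        raise ValidationError(
            f"n_train_batches={n_train_batches} must be < total batches ({len(batches)})"
        )
    train_batches = set(batches[:n_train_batches])
    t = subset.sheet.table
    study = t[t["role"] == "study"]
    train = list(study.loc[study["batch"].isin(train_batches), "sample_id"])
    valid = list(study.loc[~study["batch"].isin(train_batches), "sample_id"])
    return train, valid


def integration_subset(
    subsets: dict[str, ScenarioSubset],
    n_samples: int = 36,
    n_batches: int = 12,
    n_repeats: int = 10,
    seed: int = 0,
) -> list[dict[str, list[str]]]:
    """Seeded study-sample selections for multi-omics integration.

    For each repeat and each omics layer, selects ``n_samples`` study samples
    spanning ``n_batches`` batches with every study donor represented. When
    each donor's batches are exclusive (confounded design) the batch draw is
    stratified per donor so all layers contribute identical per-donor sample
    counts; in a balanced design any batch holds every donor and batches are
    drawn uniformly.

    Returns one ``{layer: [sample ids]}`` dict per repeat.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be ≥ 1")
    rng = np.random.default_rng(seed)
    out: list[dict[str, list[str]]] = []
    for _ in range(n_repeats):
        per_layer: dict[str, list[str]] = {}
        for layer, subset in subsets.items():
            study = subset.sheet.table[subset.sheet.table["role"] == "study"]
            donors = sorted(study["donor"].unique())
            donor_batches = {d: sorted(study.loc[study["donor"] == d, "batch"].unique()) for d in donors}
            exclusive = all(
                not (set(donor_batches[a]) & set(donor_batches[b]))
                for i, a in enumerate(donors)
                for b in donors[i + 1 :]
            )
            if exclusive:
                if n_batches % len(donors) != 0:
                    raise ValidationError(
                        f"n_batches={n_batches} not divisible by {len(donors)} donors "
                        "for a confounded (donor-exclusive) design"
                    )
                per = n_batches // len(donors)
                chosen: list[str] = []
                for d in donors:
                    if len(donor_batches[d]) < per:
                        raise ValidationError(
                            f"donor {d} spans only {len(donor_batches[d])} batches; need {per}"
                        )
                    chosen.extend(rng.choice(donor_batches[d], size=per, replace=False))
            else:
                all_batches = sorted(study["batch"].unique())
                if len(all_batches) < n_batches:
                    raise ValidationError(
                        f"layer {layer!r} spans {len(all_batches)} batches; need {n_batches}"
                    )
                chosen = list(rng.choice(all_batches, size=n_batches, replace=False))
            picked = study[study["batch"].isin(chosen)].sort_values(
                ["donor", "batch_order", "replicate"]
            )
            if len(picked) != n_samples:
                raise ValidationError(
                    f"layer {layer!r}: selected {len(picked)} study samples from "
                    f"{n_batches} batches, expected {n_samples}"
                )
            if set(picked["donor"].unique()) != set(donors):
                raise ValidationError(f"layer {layer!r}: selection misses a study donor")
            per_layer[layer] = list(picked["sample_id"])
        out.append(per_layer)
    return out


def reference_overhead(n_ref: int = 3, batch_size: int = 96) -> float:
    """Fractional cost of carrying reference replicates in a batch.

    With ``n_ref`` reference libraries in a batch of ``batch_size``, the
    overhead relative to the remaining study libraries is
    ``n_ref / (batch_size − n_ref)`` — e.g. 3/(96−3) ≈ 3.2%.
    """
    if not 0 < n_ref < batch_size:
        raise ValidationError("need 0 < n_ref < batch_size")
    return n_ref / (batch_size - n_ref)
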