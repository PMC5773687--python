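"""TSS-weighted ensemble construction, projection, and binarization.

Each algorithm × pseudo-absence replicate combination whose mean TSS
across split replicates exceeds the retention threshold (default 0.7) is
refit on its full training set and enters the ensemble with its mean TSS
as weight.  The ensemble suitability of a cell is the weighted average of
the member scores (weights normalised at predict time); one binarization
threshold per species is fixed by maximising TSS of the ensemble scores
against the pooled presence/pseudo-absence rows of the current scenario
and re-used unchanged for every future scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import learners
from .errors import EmptyEnsembleError, ProjectionError
from .evaluation import EvaluationRecord, max_tss_threshold, records_to_frame
from .grids import CONTINUOUS, PredictorStack, RasterLayer
from .preprocess import TrainingSet


@dataclass
class EnsembleMember:
    algorithm_id: str
    pa_replicate: int
    fitted: learners.FittedLearner
    weight: float  # mean TSS across split replicates


@dataclass
class EnsembleModel:
    species: str
    members: list[EnsembleMember]
    retention_tss_min: float
    binarization_threshold: float | None = None

    @property
    def weights(self) -> np.ndarray:
        return np.array([m.weight for m in self.members])

    @property
    def schema(self):
        return self.members[0].fitted.schema


@dataclass
class SuitabilityMap:
    layer: RasterLayer
    species: str
    scenario_id: str


@dataclass
class BinaryRangeMap:
    layer: RasterLayer
    threshold: float
    species: str
    scenario_id: str

    @property
    def mask(self) -> np.ndarray:
        return self.layer.values == 1


def build_ensemble(
    records: list[EvaluationRecord],
    training_sets: list[TrainingSet],
    retention_tss_min: float = 0.7,
    seed: int = 0,
) -> EnsembleModel:
    """Retain every algorithm × PA-replicate with mean TSS strictly above
    the threshold, refit it on the full training set, and weight it by
    that mean TSS.  Raises EmptyEnsembleError when nothing survives."""
    df = records_to_frame(records)
    species = df["species"].iloc[0]
    by_ts = {ts.replicate_id: ts for ts in training_sets}
    means = (
        df.groupby(["algorithm", "pa_rep"])["tss"].mean().reset_index()
    )
    members: list[EnsembleMember] = []
    for _, row in means.iterrows():
        if row["tss"] <= retention_tss_min:
            continue
        ts = by_ts[int(row["pa_rep"])]
        fitted = learners.fit(
            row["algorithm"], ts.features, ts.labels, ts.schema, seed=seed
        )
        members.append(
            EnsembleMember(
                algorithm_id=str(row["algorithm"]),
                pa_replicate=int(row["pa_rep"]),
                fitted=fitted,
                weight=float(row["tss"]),
            )
        )
    if not members:
        raise EmptyEnsembleError(retention_tss_min)
    return EnsembleModel(
        species=species, members=members, retention_tss_min=retention_tss_min
    )


def predict_rows(ens: EnsembleModel, features: pd.DataFrame) -> np.ndarray:
    """Weighted average of member scores, weights normalised to sum 1."""
    w = ens.weights
    w = w / w.sum()
    scores = np.zeros(len(features))
    for member, wi in zip(ens.members, w):
        scores = scores + wi * learners.predict(member.fitted, features)
    return scores


def project(ens: EnsembleModel, stack: PredictorStack) -> SuitabilityMap:
    """Per-cell ensemble suitability over a scenario stack; cells with any
    missing schema variable map to the missing sentinel."""
    needed = [name for name, _ in ens.schema]
    missing = set(needed) - set(stack.names)
    if missing:
        raise ProjectionError(
            f"scenario {stack.scenario_id!r} lacks variable(s) {sorted(missing)}"
        )
    grid = stack.grid
    valid = np.ones(grid.shape, dtype=bool)
    for name in needed:
        valid &= np.isfinite(stack.layers[name].values)
    rows, cols = np.nonzero(valid)
    X = pd.DataFrame({n: stack.layers[n].values[rows, cols] for n in needed})
    values = np.full(grid.shape, np.nan)
    if len(X):
        values[rows, cols] = predict_rows(ens, X)
    return SuitabilityMap(
        layer=RasterLayer(grid, f"{ens.species}_suitability", values, CONTINUOUS),
        species=ens.species,
        scenario_id=stack.scenario_id,
    )


def set_binarization_threshold(
    ens: EnsembleModel, training_sets: list[TrainingSet]
) -> EnsembleModel:
    """Fix the species' binarization threshold by maximising TSS of the
    ensemble scores on the pooled rows of all pseudo-absence replicates."""
    X = pd.concat([ts.features for ts in training_sets], ignore_index=True)
    y = np.concatenate([ts.labels for ts in training_sets])
    scores = predict_rows(ens, X)
    ok = np.isfinite(scores)
    t, _ = max_tss_threshold(scores[ok], y[ok])
    return replace(ens, binarization_threshold=float(t))


def binarize(sm: SuitabilityMap, threshold: float) -> BinaryRangeMap:
    """Cellwise score >= threshold; missing cells stay missing."""
    values = np.where(
        np.isfinite(sm.layer.values),
        (sm.layer.values >= threshold).astype(float),
        np.nan,
    )
    return BinaryRangeMap(
        layer=RasterLayer(sm.layer.grid, f"{sm.species}_binary", values, CONTINUOUS),
        threshold=float(threshold),
        species=sm.species,
        scenario_id=sm.scenario_id,
    )
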