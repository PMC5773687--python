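"""End-to-end orchestration: filter → prune → pseudo-absences →
fit/evaluate → ensemble → project → binarize → range change → protected-
area overlay → risk report.

One global seed drives every stochastic stage.  It is expanded with
``numpy.random.SeedSequence([seed, STAGE])`` using fixed stage indices
(0 correlation-sample, 1 pseudo-absences, 2 evaluation splits, 3 refits),
so replicates are statistically independent yet each stage is replayable
in isolation from the manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import learners
from .ensemble import (
    EnsembleModel,
    binarize,
    build_ensemble,
    project,
    set_binarization_threshold,
)
from .errors import ConfigError, PipelineStageError
from .evaluation import (
    EvaluationRecord,
    evaluate_all,
    records_to_frame,
    summarize_by_algorithm,
)
from .grids import OccurrenceSet, PredictorStack, ProtectedAreaSet, write_raster
from .preprocess import (
    FilteredOccurrences,
    PruneResult,
    build_training_sets,
    pearson_prune,
    spatial_filter,
)
from .range_risk import (
    RiskReport,
    assess_pa_threat,
    build_risk_report,
    summarize_range_change,
)

_STAGE_PRUNE, _STAGE_PA, _STAGE_EVAL, _STAGE_REFIT = range(4)


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All knobs of one pipeline run; serialisable to/from YAML."""

    seed: int = 0
    prune_threshold: float = 0.8
    prune_priority: list[str] | None = None
    pa_n: int | None = None            # pseudo-absences per replicate (None = presence count)
    pa_replicates: int = 3
    sre_q: float = 0.025
    learners_enabled: list[str] = field(default_factory=lambda: ["GLM", "SRE"])
    n_splits: int = 5
    split_fraction: float = 0.70
    split_method: str = "shuffle"
    retention_tss_min: float = 0.7
    area_mode: str = "spherical"

    _KEYS = (
        "seed prune_threshold prune_priority pa_n pa_replicates sre_q "
        "learners_enabled n_splits split_fraction split_method "
        "retention_tss_min area_mode"
    ).split()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls._KEYS)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    species: str
    filtered: FilteredOccurrences
    prune: PruneResult
    records: list[EvaluationRecord]
    ensemble: EnsembleModel
    suitability: dict[str, "object"]     # scenario -> SuitabilityMap
    binary: dict[str, "object"]          # scenario -> BinaryRangeMap
    report: RiskReport
    config: RunConfig


def run_pipeline(
    occurrences: OccurrenceSet,
    stacks: dict[str, PredictorStack],
    protected_areas: ProtectedAreaSet | None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the whole modelling chain for one species.

    ``stacks`` must contain a 'current' scenario; every other key is
    treated as a future scenario projected, binarized with the current-
    scenario threshold, and compared against the current range.
    """
    cfg = config or RunConfig()
    if "current" not in stacks:
        raise ConfigError("stacks must include a 'current' scenario")
    current_stack = stacks["current"]
    unknown = set(cfg.learners_enabled) - set(learners.available_algorithms())
    if unknown:
        raise ConfigError(f"unregistered learner(s): {sorted(unknown)}")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            if isinstance(exc, PipelineStageError):
                raise
            raise PipelineStageError(name, exc) from exc

    filtered = stage("spatial_filter", spatial_filter, occurrences,
                     current_stack.grid)
    prune = stage(
        "pearson_prune",
        pearson_prune,
        current_stack,
        threshold=cfg.prune_threshold,
        priority=cfg.prune_priority,
        seed=_stage_seed(cfg.seed, _STAGE_PRUNE),
    )
    training_sets = stage(
        "build_training_sets",
        build_training_sets,
        filtered,
        current_stack,
        prune,
        n_pa=cfg.pa_n,
        n_replicates=cfg.pa_replicates,
        base_seed=_stage_seed(cfg.seed, _STAGE_PA),
        sre_q=cfg.sre_q,
    )
    records = stage(
        "evaluate",
        evaluate_all,
        training_sets,
        algorithms=list(cfg.learners_enabled),
        n_splits=cfg.n_splits,
        fraction=cfg.split_fraction,
        seed=_stage_seed(cfg.seed, _STAGE_EVAL),
        method=cfg.split_method,
    )
    ens = stage(
        "build_ensemble",
        build_ensemble,
        records,
        training_sets,
        retention_tss_min=cfg.retention_tss_min,
        seed=_stage_seed(cfg.seed, _STAGE_REFIT),
    )
    ens = stage("set_binarization_threshold", set_binarization_threshold,
                ens, training_sets)

    suitability = {}
    binary = {}
    for scenario_id, stack in stacks.items():
        sm = stage(f"project[{scenario_id}]", project, ens, stack)
        suitability[scenario_id] = sm
        binary[scenario_id] = binarize(sm, ens.binarization_threshold)

    changes = []
    threats = []
    for scenario_id in stacks:
        if scenario_id == "current":
            continue
        changes.append(
            stage(
                f"rangechange[{scenario_id}]",
                summarize_range_change,
                binary["current"],
                binary[scenario_id],
                area_mode=cfg.area_mode,
            )
        )
        if protected_areas is not None and len(protected_areas):
            threats.extend(
                stage(
                    f"overlay[{scenario_id}]",
                    assess_pa_threat,
                    binary["current"],
                    binary[scenario_id],
                    protected_areas,
                )
            )
    report = build_risk_report(threats, changes)
    return PipelineResult(
        species=occurrences.species,
        filtered=filtered,
        prune=prune,
        records=records,
        ensemble=ens,
        suitability=suitability,
        binary=binary,
        report=report,
        config=cfg,
    )


def write_outputs(result: PipelineResult, directory) -> None:
    """Write evaluation records, summary statistics, maps, report CSVs and
    a manifest sufficient to replay the run."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records_to_frame(result.records).to_csv(
        directory / "evaluation_records.csv", index=False
    )
    summarize_by_algorithm(result.records).to_csv(
        directory / "evaluation_summary.csv", index=False
    )
    species_tag = result.species.replace(" ", "_")
    for scenario_id, sm in result.suitability.items():
        write_raster(sm.layer, directory / f"{species_tag}_{scenario_id}_suit.asc")
    for scenario_id, bm in result.binary.items():
        write_raster(bm.layer, directory / f"{species_tag}_{scenario_id}_bin.asc")
    result.report.write(directory)
    manifest = {
        "species": result.species,
        "config": result.config.to_dict(),
        "n_filtered_occurrences": len(result.filtered),
        "kept_variables": result.prune.all_kept,
        "dropped_variables": [
            {"dropped": d, "partner": p, "r": float(r)}
            for d, p, r in result.prune.dropped
        ],
        "ensemble": {
            "members": [
                {
                    "algorithm": m.algorithm_id,
                    "pa_replicate": m.pa_replicate,
                    "weight": m.weight,
                }
                for m in result.ensemble.members
            ],
            "retention_tss_min": result.ensemble.retention_tss_min,
            "binarization_threshold": result.ensemble.binarization_threshold,
        },
    }
    with open(directory / "manifest.yml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
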