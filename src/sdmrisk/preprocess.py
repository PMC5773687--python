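"""Occurrence thinning, collinearity pruning, and pseudo-absence training sets.

Three standard presence-only preparation steps: (1) spatial filtering that
merges all records falling in one grid cell into a single occurrence, (2)
greedy Pearson pruning that drops one of every pair of predictors
correlated beyond a magnitude threshold, and (3) envelope-exclusion
pseudo-absence sampling — background cells are drawn only from outside the
surface-range-envelope of the presences, replicated to absorb sampling
bias in the absences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    InsufficientBackgroundError,
    InsufficientDataError,
)
from .grids import CONTINUOUS, Grid, OccurrenceSet, PredictorStack, RasterLayer
from .learners import sre_fit, sre_predict

logger = logging.getLogger(__name__)


@dataclass
class FilteredOccurrences:
    """One representative point per occupied grid cell (first encountered)."""

    species: str
    cells: list[tuple[int, int]]
    representative_points: list[tuple[float, float]]
    grid: Grid

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class PruneResult:
    kept: list[str]                       # continuous variables that survived
    dropped: list[tuple[str, str, float]]  # (dropped, retained partner, r)
    threshold: float
    passthrough_categorical: list[str] = field(default_factory=list)

    @property
    def all_kept(self) -> list[str]:
        """Kept continuous variables plus untested categorical layers."""
        return self.kept + self.passthrough_categorical


@dataclass
class TrainingSet:
    """Labelled presence / pseudo-absence rows for one replicate."""

    species: str
    replicate_id: int
    features: pd.DataFrame            # columns = schema variable names
    labels: np.ndarray                # 1 presence, 0 pseudo-absence
    cells: list[tuple[int, int]]
    pa_seed: int
    schema: list[tuple[str, str]]     # (name, kind) in feature-column order

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        assert len(self.features) == len(self.labels) == len(self.cells)


def spatial_filter(occ: OccurrenceSet, grid: Grid) -> FilteredOccurrences:
    """Merge all points sharing a grid cell into one occurrence, keeping
    the first point encountered in input order as the representative.
    Idempotent; empty input yields an empty result."""
    seen: dict[tuple[int, int], tuple[float, float]] = {}
    for lon, lat in occ.points:
        row, col = grid.cell_of(lon, lat)
        key = (int(row), int(col))
        if key not in seen:
            seen[key] = (float(lon), float(lat))
    return FilteredOccurrences(
        species=occ.species,
        cells=list(seen.keys()),
        representative_points=list(seen.values()),
        grid=grid,
    )


def _sample_cells(grid: Grid, n_sample: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    n_cells = grid.n_rows * grid.n_cols
    if n_cells <= n_sample:
        idx = np.arange(n_cells)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_cells, size=n_sample, replace=False)
    return np.divmod(idx, grid.n_cols)


def pearson_prune(
    stack: PredictorStack,
    threshold: float = 0.8,
    priority: list[str] | None = None,
    cells: tuple[np.ndarray, np.ndarray] | None = None,
    n_sample: int = 10_000,
    seed: int = 0,
) -> PruneResult:
    """Greedy priority-ordered collinearity pruning.

    Scanning ``priority`` in order, a variable is kept iff its Pearson |r|
    with every already-kept variable is <= ``threshold``; otherwise it is
    dropped, recording the first offending kept partner.  Correlations are
    computed over a seeded random sample of cells (default at most 10^4),
    using for each pair only the cells where both layers are non-missing.
    Categorical layers pass through untested.
    """
    if not 0 < threshold <= 1:
        raise ConfigError("threshold must lie in (0, 1]")
    continuous = stack.continuous_names()
    categorical = [n for n in stack.names if n not in continuous]
    if priority is None:
        priority = list(continuous)
    else:
        missing = set(continuous) - set(priority)
        if missing:
            raise ConfigError(
                f"priority list does not cover continuous layer(s) {sorted(missing)}"
            )
        priority = [p for p in priority if p in continuous]

    rows, cols = cells if cells is not None else _sample_cells(stack.grid, n_sample, seed)
    samples = {n: stack.layers[n].values[rows, cols] for n in continuous}

    def pair_r(a: str, b: str) -> float:
        xa, xb = samples[a], samples[b]
        ok = np.isfinite(xa) & np.isfinite(xb)
        if ok.sum() < 3:
            raise InsufficientDataError(
                f"fewer than 3 valid cells shared by {a!r} and {b!r}"
            )
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(xa[ok], xb[ok])[0, 1]
        return 0.0 if np.isnan(r) else float(r)

    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for var in priority:
        offender = None
        for k in kept:
            r = pair_r(var, k)
            if abs(r) > threshold:
                offender = (var, k, r)
                break
        if offender is None:
            kept.append(var)
        else:
            dropped.append(offender)
    return PruneResult(
        kept=kept,
        dropped=dropped,
        threshold=threshold,
        passthrough_categorical=categorical,
    )


def sre_envelope_layer(
    stack: PredictorStack, variables: list[str], bounds_env
) -> RasterLayer:
    """Rasterise a fitted surface-range envelope over the stack: 1 inside
    the envelope, 0 outside, NaN where any input variable is missing."""
    grid = stack.grid
    rows, cols = np.indices(grid.shape)
    X = pd.DataFrame(
        {v: stack.layers[v].values[rows.ravel(), cols.ravel()] for v in variables}
    )
    scores = sre_predict(bounds_env, X)
    return RasterLayer(grid, "sre_envelope", scores.reshape(grid.shape))


def sample_pseudo_absences(
    envelope: RasterLayer,
    n: int,
    seed: int,
    exclude: set[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Sample ``n`` distinct cells uniformly without replacement from the
    envelope-0, non-missing cells not in ``exclude``."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    exclude = exclude or set()
    eligible = np.argwhere(envelope.values == 0)
    pool = [tuple(map(int, rc)) for rc in eligible if tuple(map(int, rc)) not in exclude]
    if len(pool) < n:
        raise InsufficientBackgroundError(requested=n, available=len(pool))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def build_training_sets(
    occ: FilteredOccurrences,
    stack: PredictorStack,
    kept: PruneResult,
    n_pa: int | None = None,
    n_replicates: int = 3,
    base_seed: int = 0,
    sre_q: float = 0.025,
) -> list[TrainingSet]:
    """One TrainingSet per pseudo-absence replicate.

    Presence features are extracted at the representative points; rows with
    any missing feature are dropped and logged.  The pseudo-absence pool is
    the complement of the presence surface-range envelope (tail fraction
    ``sre_q``), sampled afresh per replicate with a seed derived
    deterministically from ``base_seed``.  ``n_pa`` defaults to the
    presence count (balance by construction).
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    variables = kept.all_kept
    schema = [(v, stack.layers[v].kind) for v in variables]
    cont_vars = [v for v, k in schema if k == CONTINUOUS]

    rows = np.array([c[0] for c in occ.cells])
    cols = np.array([c[1] for c in occ.cells])
    feat = pd.DataFrame({v: stack.layers[v].values[rows, cols] for v in variables})
    ok = np.isfinite(feat.to_numpy()).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d presence cell(s) with missing features",
            occ.species, n_dropped,
        )
    feat = feat.loc[ok].reset_index(drop=True)
    pres_cells = [c for c, keep in zip(occ.cells, ok) if keep]
    if n_pa is None:
        n_pa = len(pres_cells)

    env = sre_fit(feat[cont_vars], q=sre_q)
    env_layer = sre_envelope_layer(stack, cont_vars, env)
    # cells with any missing schema feature are ineligible as background
    valid = np.ones(stack.grid.shape, dtype=bool)
    for v in variables:
        valid &= np.isfinite(stack.layers[v].values)
    env_values = np.where(valid, env_layer.values, np.nan)
    env_layer = RasterLayer(stack.grid, "sre_envelope", env_values)

    seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)
    out: list[TrainingSet] = []
    for rep, pa_seed in enumerate(seeds):
        pa_cells = sample_pseudo_absences(
            env_layer, n=n_pa, seed=int(pa_seed), exclude=set(pres_cells)
        )
        pa_rows = np.array([c[0] for c in pa_cells])
        pa_cols = np.array([c[1] for c in pa_cells])
        pa_feat = pd.DataFrame(
            {v: stack.layers[v].values[pa_rows, pa_cols] for v in variables}
        )
        features = pd.concat([feat, pa_feat], ignore_index=True)
        labels = np.concatenate([np.ones(len(feat), int), np.zeros(len(pa_feat), int)])
        out.append(
            TrainingSet(
                species=occ.species,
                replicate_id=rep,
                features=features,
                labels=labels,
                cells=pres_cells + pa_cells,
                pa_seed=int(pa_seed),
                schema=schema,
            )
        )
    return out
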