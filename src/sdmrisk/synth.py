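"""Virtual landscape and virtual species generator.

Supplies every input the pipeline needs — a multi-layer climate stack with
warmed future counterparts, presence-only occurrence points drawn from a
known Gaussian niche, and rectangular protected areas with species and
ecosystem attributes — together with exported ground truth (true range
masks, true net range change) so that the full modelling chain can be
scored against a species whose niche is known exactly.

The niche is a product of independent Gaussian responses,

    suitability(x) = prod_v exp(-(x_v - mu_v)^2 / (2 sigma_v^2)),

so the true range (suitability >= threshold) is an analytically tractable
box-like region.  Future scenarios re-use the current scenario's noise
fields and differ only by stated additive deltas: the climate signal is
the only change the pipeline has to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box as shapely_box

from .errors import CannotSampleError, ConfigError, PlacementError
from .grids import (
    CATEGORICAL,
    CONTINUOUS,
    Grid,
    OccurrenceSet,
    PredictorStack,
    ProtectedArea,
    ProtectedAreaSet,
    RasterLayer,
)
from .range_risk import net_change_percent
from .grids import mask_area_km2

# Fixed attribute vocabularies for simulated reserves; synthetic stand-ins
# for real protected-area registries.
PROTECTED_SPECIES_VOCAB = [
    "Taxus chinensis",
    "Ginkgo biloba",
    "Bretschneidera sinensis",
    "Alsophila spinulosa",
    "Davidia involucrata",
    "Cathaya argyrophylla",
    "Metasequoia glyptostroboides",
    "Glyptostrobus pensilis",
    "Cycas panzhihuaensis",
    "Abies ziyuanensis",
    "Manglietia decidua",
    "Parakmeria omeiensis",
]

ECOSYSTEM_VOCAB = [
    "subtropical evergreen broad-leaved forest",
    "mid-subtropical forest",
    "tropical monsoon rainforest",
    "montane mixed conifer forest",
    "karst seasonal rainforest",
    "river-valley sclerophyllous woodland",
]


@dataclass(frozen=True)
class LayerRecipe:
    """Linear climate surface plus smoothed Gaussian noise.

    direction: 'ns' (value varies with latitude) or 'ew' (with longitude);
    slope is per degree along that axis, anchored at the extent's south/west
    edge; smoothing radius is the Gaussian-filter sigma in cells and must be
    positive.  ``n_classes > 0`` makes the layer categorical: the smoothed
    field is quantile-binned into that many integer codes.
    """

    direction: str = "ns"
    slope: float = 0.0
    intercept: float = 0.0
    noise_sd: float = 0.0
    smooth_radius: float = 1.0
    n_classes: int = 0


@dataclass(frozen=True)
class ScenarioConfig:
    grid: Grid
    layer_recipes: dict[str, LayerRecipe]
    future_deltas: dict[str, dict[str, float]]  # scenario label -> {layer: shift}
    seed: int = 0

    def __post_init__(self) -> None:
        for name, r in self.layer_recipes.items():
            if r.smooth_radius <= 0:
                raise ConfigError(
                    f"layer {name!r}: smoothing radius must be positive"
                )
            if r.direction not in ("ns", "ew"):
                raise ConfigError(f"layer {name!r}: direction must be 'ns' or 'ew'")
        for label, deltas in self.future_deltas.items():
            if not deltas:
                raise ConfigError(f"scenario {label!r} shifts no layer")
            unknown = set(deltas) - set(self.layer_recipes)
            if unknown:
                raise ConfigError(
                    f"scenario {label!r} shifts unknown layer(s) {sorted(unknown)}"
                )


@dataclass(frozen=True)
class VirtualSpeciesConfig:
    """Gaussian product niche over named layers plus sampling settings."""

    niche: dict[str, tuple[float, float]]  # variable -> (mu, sigma)
    suitability_threshold: float = 0.3
    n_presences: int = 300
    sampling_seed: int = 0
    detection_bias: float = 1.0
    species: str = "virtualis exempli"

    def __post_init__(self) -> None:
        for v, (_, sigma) in self.niche.items():
            if sigma <= 0:
                raise ConfigError(f"niche variable {v!r}: sigma must be positive")
        if not 0 < self.suitability_threshold < 1:
            raise ConfigError("suitability_threshold must lie in (0, 1)")


@dataclass
class GroundTruth:
    """True range masks and the net range change the generator implies."""

    true_current_range: np.ndarray
    true_future_range: dict[str, np.ndarray]
    true_net_change_pct: dict[str, int]
    grid: Grid


def _base_surface(grid: Grid, recipe: LayerRecipe) -> np.ndarray:
    lon = grid.lon_centers()
    lat = grid.lat_centers()
    if recipe.direction == "ns":
        coord = lat - grid.y_min
        col_vec = recipe.intercept + recipe.slope * coord
        return np.repeat(col_vec[:, None], grid.n_cols, axis=1)
    coord = lon - grid.x_min
    row_vec = recipe.intercept + recipe.slope * coord
    return np.repeat(row_vec[None, :], grid.n_rows, axis=0)


def simulate_landscape(cfg: ScenarioConfig) -> dict[str, PredictorStack]:
    """Build the 'current' stack plus one stack per future scenario.

    Deterministic given ``cfg.seed``.  The noise field generated for the
    current scenario is re-used verbatim in every future scenario; future
    layers differ from current ones only by the configured additive deltas.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(cfg.layer_recipes))
    current_values: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for child, (name, recipe) in zip(children, cfg.layer_recipes.items()):
        rng = np.random.default_rng(child)
        base = _base_surface(cfg.grid, recipe)
        noise = rng.normal(0.0, 1.0, size=cfg.grid.shape)
        noise = gaussian_filter(noise, sigma=recipe.smooth_radius) * recipe.noise_sd
        values = base + noise
        if recipe.n_classes > 0:
            edges = np.quantile(values, np.linspace(0, 1, recipe.n_classes + 1)[1:-1])
            values = np.digitize(values, edges).astype(float)
            kinds[name] = CATEGORICAL
        else:
            kinds[name] = CONTINUOUS
        if not np.all(np.isfinite(values)):
            raise ConfigError(f"layer {name!r} recipe produced non-finite values")
        current_values[name] = values

    out: dict[str, PredictorStack] = {}
    current = PredictorStack(scenario_id="current")
    for name, values in current_values.items():
        current.add(RasterLayer(cfg.grid, name, values, kind=kinds[name]))
    out["current"] = current
    for label, deltas in cfg.future_deltas.items():
        stack = PredictorStack(scenario_id=label)
        for name, values in current_values.items():
            shifted = values + deltas.get(name, 0.0)
            stack.add(RasterLayer(cfg.grid, name, shifted, kind=kinds[name]))
        out[label] = stack
    return out


def true_suitability(stack: PredictorStack, cfg: VirtualSpeciesConfig) -> RasterLayer:
    """Product-Gaussian suitability in [0, 1]; 1 at the niche centre."""
    missing = set(cfg.niche) - set(stack.names)
    if missing:
        raise ConfigError(f"niche variable(s) {sorted(missing)} not in stack")
    suit = np.ones(stack.grid.shape)
    for var, (mu, sigma) in cfg.niche.items():
        x = stack.layers[var].values
        suit = suit * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))
    return RasterLayer(stack.grid, "true_suitability", suit, kind=CONTINUOUS)


def sample_presences(
    suitability: RasterLayer, cfg: VirtualSpeciesConfig
) -> OccurrenceSet:
    """Rejection-sample presence points: propose cells uniformly, accept
    with probability suitability × detection_bias, place the point
    uniformly inside the accepted cell.  Reproducible by sampling_seed."""
    grid = suitability.grid
    p = np.nan_to_num(suitability.values, nan=0.0) * cfg.detection_bias
    p = np.clip(p, 0.0, 1.0)
    if not np.any(p > 0):
        raise CannotSampleError("suitability is identically zero; nothing to sample")
    rng = np.random.default_rng(cfg.sampling_seed)
    n_cells = grid.n_rows * grid.n_cols
    flat_p = p.ravel()
    pts: list[tuple[float, float]] = []
    while len(pts) < cfg.n_presences:
        batch = max(64, 2 * (cfg.n_presences - len(pts)))
        idx = rng.integers(0, n_cells, size=batch)
        accept = rng.random(batch) < flat_p[idx]
        for cell in idx[accept]:
            if len(pts) >= cfg.n_presences:
                break
            row, col = divmod(int(cell), grid.n_cols)
            lon = grid.x_min + (col + rng.random()) * grid.cell_size
            lat = grid.y_max - (row + rng.random()) * grid.cell_size
            pts.append((lon, lat))
    return OccurrenceSet(
        species=cfg.species,
        points=np.array(pts),
        provenance=["simulated"] * len(pts),
    )


def ground_truth(
    stacks: dict[str, PredictorStack],
    cfg: VirtualSpeciesConfig,
    area_mode: str = "spherical",
) -> GroundTruth:
    """Threshold the true suitability of every scenario and account the
    net range change with the same arithmetic the pipeline reports."""
    grid = stacks["current"].grid
    cur = true_suitability(stacks["current"], cfg).values >= cfg.suitability_threshold
    future_masks: dict[str, np.ndarray] = {}
    net: dict[str, int] = {}
    for label, stack in stacks.items():
        if label == "current":
            continue
        fut = true_suitability(stack, cfg).values >= cfg.suitability_threshold
        future_masks[label] = fut
        loss = mask_area_km2(cur & ~fut, grid, area_mode)
        gain = mask_area_km2(~cur & fut, grid, area_mode)
        current_area = mask_area_km2(cur, grid, area_mode)
        net[label] = net_change_percent(current_area, loss, gain)
    return GroundTruth(
        true_current_range=cur,
        true_future_range=future_masks,
        true_net_change_pct=net,
        grid=grid,
    )


def simulate_protected_areas(
    grid: Grid, n: int, seed: int, max_attempts_per_area: int = 200
) -> ProtectedAreaSet:
    """Place ``n`` disjoint axis-aligned rectangles inside the extent and
    attach 0–3 protected species plus one ecosystem label from the fixed
    vocabularies.  Reproducible by seed."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    width_span = grid.x_max - grid.x_min
    height_span = grid.y_max - grid.y_min
    placed: list[ProtectedArea] = []
    geoms = []
    for i in range(n):
        ok = False
        for _ in range(max_attempts_per_area):
            w = rng.uniform(0.04, 0.12) * width_span
            h = rng.uniform(0.04, 0.12) * height_span
            x0 = rng.uniform(grid.x_min, grid.x_max - w)
            y0 = rng.uniform(grid.y_min, grid.y_max - h)
            rect = shapely_box(x0, y0, x0 + w, y0 + h)
            if all(not rect.intersects(g) for g in geoms):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place {n} disjoint reserves (stuck at {i})"
            )
        geoms.append(rect)
        n_sp = int(rng.integers(0, 4))
        species = list(
            rng.choice(PROTECTED_SPECIES_VOCAB, size=n_sp, replace=False)
        )
        eco = str(rng.choice(ECOSYSTEM_VOCAB))
        placed.append(
            ProtectedArea(
                id=f"PA{i:03d}",
                name=f"Simulated Reserve {i:03d}",
                geometry=rect,
                protected_species=[str(s) for s in species],
                protected_ecosystem=eco,
            )
        )
    return ProtectedAreaSet(areas=placed)


# ---------------------------------------------------------------------------
# Default study conditions for the end-to-end demonstration


def default_scenario_config(seed: int = 0) -> ScenarioConfig:
    """A 60×60-cell, 10×10-degree landscape at ~10-km-scale cells (1/6 deg).

    ``tmin`` cools northward at 0.8 °C per degree latitude; ``precip``
    rises eastward; ``soil`` is a 4-class categorical layer.  The two
    warming scenarios lift ``tmin`` by +1.6 °C ('warm-low', low-emission-
    like) and +2.4 °C ('warm-high', high-emission-like, within the 2–3.7 °C
    mid-century projection band for the region the landscape emulates).
    """
    grid = Grid.from_origin(
        x_min=100.0, y_min=20.0, cell_size=1.0 / 6.0, n_rows=60, n_cols=60
    )
    return ScenarioConfig(
        grid=grid,
        layer_recipes={
            "tmin": LayerRecipe("ns", slope=-0.8, intercept=26.0, noise_sd=0.5,
                                smooth_radius=2.0),
            "precip": LayerRecipe("ew", slope=30.0, intercept=500.0, noise_sd=40.0,
                                  smooth_radius=2.0),
            "soil": LayerRecipe("ew", slope=1.0, intercept=0.0, noise_sd=3.0,
                                smooth_radius=3.0, n_classes=4),
        },
        future_deltas={
            "warm-low": {"tmin": 1.6},
            "warm-high": {"tmin": 2.4},
        },
        seed=seed,
    )


def default_species_config(seed: int = 0, n_presences: int = 300) -> VirtualSpeciesConfig:
    """A species occupying a temperature band fully interior to the
    landscape under the current climate.  Warming pushes the band
    poleward so that it partly exits the study extent — a range signal
    that is visible in the occurrence data and therefore recoverable, as
    opposed to expansion into environments never sampled under the
    current climate (which no presence-only model can learn)."""
    return VirtualSpeciesConfig(
        niche={"tmin": (20.8, 1.0), "precip": (650.0, 100.0)},
        suitability_threshold=0.3,
        n_presences=n_presences,
        sampling_seed=seed,
    )
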