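"""Range-change accounting and protected-area threat assessment.

Under the full-dispersal assumption, comparing the binarized current and
future range maps classifies every cell as loss (suitable now only),
stable (suitable in both periods) or gain (suitable in the future only);
areas are summed with per-row spherical cell areas and the net change is
reported as a signed integer percentage of the current range.  A
protected area counts as newly threatened by a species under a scenario
iff the species' current range does not touch it but its future range
does.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .errors import GridMismatchError
from .grids import Grid, ProtectedAreaSet, row_areas


def net_change_percent(current_km2: float, loss_km2: float, gain_km2: float) -> int:
    """Signed integer net range change: round(100·(gain−loss)/current),
    half away from zero."""
    if current_km2 <= 0:
        raise ValueError("current area must be positive")
    pct = 100.0 * (gain_km2 - loss_km2) / current_km2
    return int(math.floor(pct + 0.5) if pct >= 0 else math.ceil(pct - 0.5))


@dataclass
class RangeChange:
    species: str
    scenario_id: str
    current_km2: float
    loss_km2: float
    stable_km2: float
    gain_km2: float
    future_km2: float
    net_pct: int
    loss_mask: np.ndarray = field(repr=False, default=None)
    stable_mask: np.ndarray = field(repr=False, default=None)
    gain_mask: np.ndarray = field(repr=False, default=None)


@dataclass
class PAThreat:
    area_id: str
    area_name: str
    species: str
    scenario_id: str
    threatened: bool
    overlap_km2: float
    affected_species: list[str]
    affected_ecosystem: str


@dataclass
class RiskReport:
    changes: list[RangeChange]
    threats: list[PAThreat]

    def range_change_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": c.species,
                    "scenario": c.scenario_id,
                    "current_km2": c.current_km2,
                    "loss_km2": c.loss_km2,
                    "stable_km2": c.stable_km2,
                    "gain_km2": c.gain_km2,
                    "net_pct": c.net_pct,
                }
                for c in self.changes
            ]
        )

    def threat_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "area_id": t.area_id,
                    "area_name": t.area_name,
                    "species": t.species,
                    "scenario": t.scenario_id,
                    "overlap_km2": t.overlap_km2,
                    "affected_species": ";".join(t.affected_species),
                    "affected_ecosystem": t.affected_ecosystem,
                }
                for t in self.threats
                if t.threatened
            ]
        )

    def summary_table(self) -> pd.DataFrame:
        """Per species × scenario: threatened-reserve count, deduplicated
        affected plant-species and ecosystem counts, total threatened area."""
        rows = []
        keys = sorted({(c.species, c.scenario_id) for c in self.changes})
        for species, scenario in keys:
            sel = [
                t
                for t in self.threats
                if t.threatened and t.species == species and t.scenario_id == scenario
            ]
            plant_species = set()
            ecosystems = set()
            for t in sel:
                plant_species.update(t.affected_species)
                if t.affected_ecosystem:
                    ecosystems.add(t.affected_ecosystem)
            rows.append(
                {
                    "species": species,
                    "scenario": scenario,
                    "n_reserves": len(sel),
                    "n_affected_plant_species": len(plant_species),
                    "n_affected_ecosystems": len(ecosystems),
                    "total_area_km2": float(sum(t.overlap_km2 for t in sel)),
                }
            )
        return pd.DataFrame(rows)

    def write(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.range_change_table().to_csv(directory / "rangechange.csv", index=False)
        self.summary_table().rename(
            columns={"n_affected_ecosystems": "n_affected_ecosystems"}
        ).to_csv(directory / "risk.csv", index=False)
        self.threat_table().to_csv(directory / "pa_threats.csv", index=False)


def summarize_range_change(current, future, area_mode: str = "spherical") -> RangeChange:
    """Classify cells into loss/stable/gain and account areas.

    ``current`` and ``future`` are BinaryRangeMaps on one grid; cells
    missing in either map are excluded from every class, so
    loss + stable = current and stable + gain = future exactly.
    """
    if not current.layer.grid.approx_equal(future.layer.grid):
        raise GridMismatchError("current and future maps are on different grids")
    if current.species != future.species:
        raise ValueError("maps belong to different species")
    grid = current.layer.grid
    cur = current.layer.values == 1
    fut = future.layer.values == 1
    loss = cur & ~fut
    stable = cur & fut
    gain = ~cur & fut
    areas = row_areas(grid, area_mode)

    def area_of(mask: np.ndarray) -> float:
        return float((mask.sum(axis=1) * areas).sum())

    loss_km2 = area_of(loss)
    stable_km2 = area_of(stable)
    gain_km2 = area_of(gain)
    current_km2 = loss_km2 + stable_km2
    future_km2 = stable_km2 + gain_km2
    return RangeChange(
        species=current.species,
        scenario_id=future.scenario_id,
        current_km2=current_km2,
        loss_km2=loss_km2,
        stable_km2=stable_km2,
        gain_km2=gain_km2,
        future_km2=future_km2,
        net_pct=net_change_percent(current_km2, loss_km2, gain_km2),
        loss_mask=loss,
        stable_mask=stable,
        gain_mask=gain,
    )


def rasterize_protected_area(geometry: BaseGeometry, grid: Grid) -> np.ndarray:
    """Boolean mask: a cell belongs to the protected area iff its center
    lies strictly inside the polygon (cell-center containment rule)."""
    if geometry.is_empty or geometry.area == 0:
        warnings.warn("degenerate (zero-area) protected-area polygon", stacklevel=2)
        return np.zeros(grid.shape, dtype=bool)
    lon = grid.lon_centers()
    lat = grid.lat_centers()
    lon2d, lat2d = np.meshgrid(lon, lat)
    mask = shapely.contains_xy(geometry, lon2d.ravel(), lat2d.ravel()).reshape(
        grid.shape
    )
    if not mask.any():
        warnings.warn(
            "protected-area polygon covers no cell center (possibly outside extent)",
            stacklevel=2,
        )
    return mask


def assess_pa_threat(current, future, pas: ProtectedAreaSet) -> list[PAThreat]:
    """Apply the newly-exposed rule per protected area: threatened iff the
    current range has zero overlap with the area but the future range has
    at least one suitable cell inside it.  ``overlap_km2`` is the area of
    future-suitable cells inside the PA (spherical cell areas)."""
    if not current.layer.grid.approx_equal(future.layer.grid):
        raise GridMismatchError("maps are on different grids")
    grid = current.layer.grid
    cur = current.layer.values == 1
    fut = future.layer.values == 1
    areas = row_areas(grid)
    out: list[PAThreat] = []
    for pa in pas.areas:
        mask = rasterize_protected_area(pa.geometry, grid)
        cur_overlap = bool((cur & mask).any())
        fut_cells = fut & mask
        overlap_km2 = float((fut_cells.sum(axis=1) * areas).sum())
        threatened = (not cur_overlap) and bool(fut_cells.any())
        out.append(
            PAThreat(
                area_id=pa.id,
                area_name=pa.name,
                species=current.species,
                scenario_id=future.scenario_id,
                threatened=threatened,
                overlap_km2=overlap_km2 if threatened else overlap_km2,
                affected_species=list(pa.protected_species),
                affected_ecosystem=pa.protected_ecosystem,
            )
        )
    return out


def build_risk_report(
    threats: list[PAThreat], changes: list[RangeChange]
) -> RiskReport:
    return RiskReport(changes=changes, threats=threats)
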