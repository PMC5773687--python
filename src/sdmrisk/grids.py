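"""Grid geometry, raster/vector/tabular I/O, and spherical cell areas.

The whole pipeline works on one lon/lat lattice (WGS84 decimal degrees):
north-up rasters, row 0 the northernmost row, cells half-open
``[edge, edge + cell_size)`` on both axes, 0-based indices.  Rasters are
read and written as ESRI ASCII grids (a plain-text, axis-aligned,
square-cell dialect that matches this model exactly); occurrences as CSV
with a ``species,lon,lat[,source]`` header; protected areas as a GeoJSON
FeatureCollection.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .errors import FormatError, GridMismatchError, RowError

#: Mean Earth radius in km (IUGG), used for spherical cell areas.
EARTH_RADIUS_KM = 6371.0088

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class Grid:
    """A regular lon/lat lattice.

    ``(x_max - x_min) / cell_size`` must equal ``n_cols`` (and the analogue
    for rows) to within 1e-9 of a cell.  Row 0 is the northernmost row.
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        for span, n, axis in (
            (self.x_max - self.x_min, self.n_cols, "x"),
            (self.y_max - self.y_min, self.n_rows, "y"),
        ):
            if abs(span / self.cell_size - n) > 1e-9 * max(1, n):
                raise ValueError(
                    f"{axis}-extent {span} is not n * cell_size "
                    f"(n={n}, cell_size={self.cell_size})"
                )

    @classmethod
    def from_origin(
        cls, x_min: float, y_min: float, cell_size: float, n_rows: int, n_cols: int
    ) -> "Grid":
        return cls(
            n_rows=n_rows,
            n_cols=n_cols,
            x_min=x_min,
            y_min=y_min,
            x_max=x_min + n_cols * cell_size,
            y_max=y_min + n_rows * cell_size,
            cell_size=cell_size,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def contains(self, lon, lat):
        """Vectorised half-open extent test."""
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (
            (lon >= self.x_min)
            & (lon < self.x_max)
            & (lat >= self.y_min)
            & (lat < self.y_max)
        )

    def cell_of(self, lon, lat):
        """Map points to (row, col); callers must ensure points are in extent."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_min) / self.cell_size).astype(int)
        row_from_s = np.floor((lat - self.y_min) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_from_s
        return row, col

    def cell_center(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.x_min + (col + 0.5) * self.cell_size
        lat = self.y_max - (row + 0.5) * self.cell_size
        return lon, lat

    def lon_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, row 0 (north) first."""
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def approx_equal(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_min - other.x_min) <= tol
            and abs(self.y_min - other.y_min) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


def cell_area(grid: Grid, row: int) -> float:
    """Spherical area (km²) of any cell in ``row``.

    A = R² · Δλ · (sin φ_top − sin φ_bottom); constant along a row because
    the grid is equiangular in longitude.
    """
    if not 0 <= row < grid.n_rows:
        raise IndexError(f"row {row} outside [0, {grid.n_rows})")
    lat_top = grid.y_max - row * grid.cell_size
    lat_bot = lat_top - grid.cell_size
    dlon = np.radians(grid.cell_size)
    return float(
        EARTH_RADIUS_KM**2
        * dlon
        * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
    )


def row_areas(grid: Grid, mode: str = "spherical") -> np.ndarray:
    """Per-row cell areas, length n_rows.  ``mode='unit'`` returns ones
    (used by synthetic tests that want pure cell counting)."""
    if mode == "unit":
        return np.ones(grid.n_rows)
    if mode != "spherical":
        raise ValueError(f"unknown area mode {mode!r}")
    lat_top = grid.y_max - np.arange(grid.n_rows) * grid.cell_size
    lat_bot = lat_top - grid.cell_size
    dlon = np.radians(grid.cell_size)
    return (
        EARTH_RADIUS_KM**2
        * dlon
        * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
    )


def mask_area_km2(mask: np.ndarray, grid: Grid, mode: str = "spherical") -> float:
    """Total area of True cells."""
    if mask.shape != grid.shape:
        raise GridMismatchError("mask shape does not match grid")
    return float((mask.sum(axis=1) * row_areas(grid, mode)).sum())


@dataclass
class RasterLayer:
    """One named single-band layer on a Grid; NaN is the missing sentinel."""

    grid: Grid
    name: str
    values: np.ndarray
    kind: str = CONTINUOUS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"layer {self.name!r}: values shape {self.values.shape} != "
                f"grid shape {self.grid.shape}"
            )
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == CATEGORICAL:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and not np.allclose(finite, np.round(finite)):
                raise ValueError(
                    f"categorical layer {self.name!r} has non-integer codes"
                )

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class PredictorStack:
    """Ordered, co-registered named layers for one scenario."""

    scenario_id: str
    layers: dict[str, RasterLayer] = field(default_factory=dict)

    def add(self, layer: RasterLayer) -> None:
        if layer.name in self.layers:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        if self.layers:
            first = next(iter(self.layers.values()))
            if not layer.grid.approx_equal(first.grid):
                raise GridMismatchError(
                    f"layer {layer.name!r} grid differs from stack grid"
                )
        self.layers[layer.name] = layer

    @property
    def grid(self) -> Grid:
        if not self.layers:
            raise ValueError("empty stack has no grid")
        return next(iter(self.layers.values())).grid

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def kinds(self) -> dict[str, str]:
        return {n: l.kind for n, l in self.layers.items()}

    def continuous_names(self) -> list[str]:
        return [n for n, l in self.layers.items() if l.kind == CONTINUOUS]

    def features_at(self, rows, cols) -> "np.ndarray":
        """(n_cells, n_layers) feature matrix in layer order."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        return np.column_stack([l.values[rows, cols] for l in self.layers.values()])


@dataclass
class OccurrenceSet:
    """Presence-only points for one species; rejected out-of-extent rows are
    counted, never silently dropped."""

    species: str
    points: np.ndarray  # (n, 2) lon, lat
    provenance: list[str] = field(default_factory=list)
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not self.provenance:
            self.provenance = [""] * len(self.points)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ProtectedArea:
    id: str
    name: str
    geometry: BaseGeometry
    protected_species: list[str] = field(default_factory=list)
    protected_ecosystem: str = ""


@dataclass
class ProtectedAreaSet:
    areas: list[ProtectedArea] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [a.id for a in self.areas]
        if len(set(ids)) != len(ids):
            raise ValueError("protected area ids are not unique")
        for a in self.areas:
            if not a.geometry.is_valid:
                raise ValueError(f"protected area {a.id!r} has invalid geometry")

    def __len__(self) -> int:
        return len(self.areas)


# ---------------------------------------------------------------------------
# Occurrence CSV I/O


def read_occurrences(
    path, grid: Grid, species: str | None = None
) -> OccurrenceSet:
    """Read a ``species,lon,lat[,source]`` CSV, keeping in-extent points.

    Out-of-extent rows are tallied in ``n_rejected``.  Missing header
    columns raise :class:`FormatError`; a non-numeric coordinate raises
    :class:`RowError` carrying the 1-based line number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        missing = {"species", "lon", "lat"} - set(cols)
        if missing:
            raise FormatError(
                f"{path.name}: missing required column(s) {sorted(missing)}"
            )
        pts: list[tuple[float, float]] = []
        prov: list[str] = []
        names: set[str] = set()
        n_rejected = 0
        for lineno, row in enumerate(reader, start=2):
            sp = (row["species"] or "").strip()
            if species is not None and sp != species:
                continue
            try:
                lon = float(row["lon"])
                lat = float(row["lat"])
            except (TypeError, ValueError):
                raise RowError(
                    f"non-numeric coordinates lon={row['lon']!r} lat={row['lat']!r}",
                    line=lineno,
                ) from None
            if not bool(grid.contains(lon, lat)):
                n_rejected += 1
                continue
            names.add(sp)
            pts.append((lon, lat))
            prov.append((row.get("source") or "").strip())
    if species is None:
        if len(names) > 1:
            raise FormatError(
                f"{path.name}: multiple species {sorted(names)}; "
                "pass species= to select one"
            )
        species = names.pop() if names else ""
    return OccurrenceSet(
        species=species,
        points=np.array(pts, dtype=float).reshape(-1, 2),
        provenance=prov,
        n_rejected=n_rejected,
    )


def write_occurrences(occ: OccurrenceSet, path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "lon", "lat", "source"])
        for (lon, lat), src in zip(occ.points, occ.provenance):
            w.writerow([occ.species, repr(float(lon)), repr(float(lat)), src])


# ---------------------------------------------------------------------------
# ESRI ASCII raster I/O

_DEFAULT_NODATA = -9999.0


def read_raster(path, name: str | None = None, kind: str = CONTINUOUS) -> RasterLayer:
    """Read a single-band ESRI ASCII grid.

    The format is axis-aligned with square cells by construction, so
    rotated or sheared geometries cannot occur.  Cells equal to the file's
    ``NODATA_value`` map to NaN.  The layer name defaults to the file stem.
    """
    path = Path(path)
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= set(header):
        raise FormatError(
            f"{path.name}: missing header keys {sorted(required - set(header))}"
        )
    values = np.loadtxt(path, skiprows=n_header, ndmin=2, dtype=float)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise FormatError(
            f"{path.name}: data shape {values.shape} != header ({n_rows}, {n_cols})"
        )
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    values = np.where(values == nodata, np.nan, values)
    grid = Grid.from_origin(
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return RasterLayer(grid=grid, name=name or path.stem, values=values, kind=kind)


def write_raster(layer: RasterLayer, path, nodata: float = _DEFAULT_NODATA) -> None:
    path = Path(path)
    g = layer.grid
    values = np.where(np.isfinite(layer.values), layer.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.x_min!r}\n")
        fh.write(f"yllcorner {g.y_min!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def write_stack(stack: PredictorStack, directory) -> None:
    """Write each layer as ``<name>.asc`` plus a ``manifest.yml`` sidecar
    recording scenario id, layer order and kinds."""
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, layer in stack.layers.items():
        write_raster(layer, directory / f"{name}.asc")
    manifest = {
        "scenario_id": stack.scenario_id,
        "layers": [{"name": n, "kind": l.kind} for n, l in stack.layers.items()],
    }
    with open(directory / "manifest.yml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_stack(directory) -> PredictorStack:
    import yaml

    directory = Path(directory)
    with open(directory / "manifest.yml") as fh:
        manifest = yaml.safe_load(fh)
    stack = PredictorStack(scenario_id=manifest["scenario_id"])
    for entry in manifest["layers"]:
        stack.add(
            read_raster(
                directory / f"{entry['name']}.asc",
                name=entry["name"],
                kind=entry["kind"],
            )
        )
    return stack


# ---------------------------------------------------------------------------
# Protected-area GeoJSON I/O


def read_protected_areas(path) -> ProtectedAreaSet:
    """Read a GeoJSON FeatureCollection of polygons with properties
    ``id, name, protected_species`` (semicolon-separated), ``protected_ecosystem``."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path.name}: not a GeoJSON FeatureCollection")
    areas = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {}) or {}
        geom = shapely_shape(feat["geometry"])
        species = [
            s.strip()
            for s in (props.get("protected_species") or "").split(";")
            if s.strip()
        ]
        areas.append(
            ProtectedArea(
                id=str(props.get("id", "")),
                name=str(props.get("name", "")),
                geometry=geom,
                protected_species=species,
                protected_ecosystem=str(props.get("protected_ecosystem") or ""),
            )
        )
    return ProtectedAreaSet(areas=areas)


def write_protected_areas(pas: ProtectedAreaSet, path) -> None:
    features = []
    for a in pas.areas:
        features.append(
            {
                "type": "Feature",
                "geometry": shapely_mapping(a.geometry),
                "properties": {
                    "id": a.id,
                    "name": a.name,
                    "protected_species": ";".join(a.protected_species),
                    "protected_ecosystem": a.protected_ecosystem,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
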