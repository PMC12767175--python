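"""Raster grids: geometry, ESRI ASCII I/O, multi-layer stacks, alignment, correlation.

Array convention: row 0 is the *northernmost* row (the ESRI ASCII on-disk order),
while :class:`GridGeometry` carries the lower-left corner, as the format's header
does.  Invalid (nodata) cells are NaN in-memory.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "GridGeometry",
    "EnvStack",
    "RasterFormatError",
    "AlignmentError",
    "read_ascii_grid",
    "write_ascii_grid",
    "align_stack",
    "correlation_matrix",
]

#: decimal significant digits used when writing .asc values; round-trip identity
#: holds to this precision.
ASC_FLOAT_FORMAT = "%.10g"


class RasterFormatError(ValueError):
    """Malformed ESRI ASCII grid (bad header, row length mismatch, ...)."""


class AlignmentError(ValueError):
    """Layer cannot be resampled onto the target geometry (no overlap)."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular square-celled grid anchored at its lower-left corner.

    Cells are half-open ``[x, x+cs) x [y, y+cs)``; points on the top/right
    boundary of the grid belong to the last cell.
    """

    n_rows: int
    n_cols: int
    x_ll: float
    y_ll: float
    cell_size: float

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x_ur(self) -> float:
        return self.x_ll + self.n_cols * self.cell_size

    @property
    def y_ur(self) -> float:
        return self.y_ll + self.n_rows * self.cell_size

    def contains(self, x, y):
        """Vectorized point-in-grid test (closed on the top/right edge)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_ll) & (x <= self.x_ur) & (y >= self.y_ll) & (y <= self.y_ur)

    def cell_index(self, x, y):
        """Map coordinates to (row, col); row 0 is the top (northern) row.

        Points outside the grid get index -1 in both entries.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)
        col = np.floor((x - self.x_ll) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.y_ll) / self.cell_size).astype(int)
        # top/right boundary points belong to the last cell
        col = np.clip(col, 0, self.n_cols - 1)
        row_from_bottom = np.clip(row_from_bottom, 0, self.n_rows - 1)
        row = self.n_rows - 1 - row_from_bottom
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col

    def cell_center(self, row, col):
        """Center coordinates of cell (row, col) in the top-row-first convention."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x_ll + (col + 0.5) * self.cell_size
        y = self.y_ll + (self.n_rows - 1 - row + 0.5) * self.cell_size
        return x, y

    def row_latitudes(self) -> np.ndarray:
        """Latitude (y) of each row's cell centers, top row first."""
        rows = np.arange(self.n_rows)
        return self.y_ll + (self.n_rows - 1 - rows + 0.5) * self.cell_size


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry, float]:
    """Read one ESRI ASCII grid layer.

    Returns ``(values, geometry, nodata_value)``; nodata cells are NaN.
    Raises :class:`RasterFormatError` with the offending line number on
    malformed input.
    """
    path = Path(path)
    header: dict[str, float] = {}
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and len(header) < 6:
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in keys:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(
                    f"{path}: line {i + 1}: bad header value {parts[1]!r}"
                ) from exc
            i += 1
        else:
            break
    missing = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"} - set(header)
    if missing:
        raise RasterFormatError(f"{path}: missing header keys {sorted(missing)}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    for j, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        try:
            row = np.array(line.split(), dtype=float)
        except ValueError as exc:
            raise RasterFormatError(f"{path}: line {j}: non-numeric value") from exc
        if row.size != n_cols:
            raise RasterFormatError(
                f"{path}: line {j}: expected {n_cols} values, got {row.size}"
            )
        rows.append(row)
    if len(rows) != n_rows:
        raise RasterFormatError(
            f"{path}: header declares {n_rows} rows, found {len(rows)}"
        )
    values = np.vstack(rows)
    values = np.where(values == nodata, np.nan, values)
    geom = GridGeometry(
        n_rows=n_rows,
        n_cols=n_cols,
        x_ll=header["xllcorner"],
        y_ll=header["yllcorner"],
        cell_size=header["cellsize"],
    )
    return values, geom, nodata


def write_ascii_grid(path, values: np.ndarray, geom: GridGeometry, nodata: float = -9999.0):
    """Write one layer as ESRI ASCII grid; NaN cells become ``nodata``."""
    values = np.asarray(values, dtype=float)
    if values.shape != geom.shape:
        raise ValueError(f"array shape {values.shape} != geometry shape {geom.shape}")
    out = np.where(np.isnan(values), nodata, values)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"ncols {geom.n_cols}\n")
        fh.write(f"nrows {geom.n_rows}\n")
        fh.write(f"xllcorner {ASC_FLOAT_FORMAT % geom.x_ll}\n")
        fh.write(f"yllcorner {ASC_FLOAT_FORMAT % geom.y_ll}\n")
        fh.write(f"cellsize {ASC_FLOAT_FORMAT % geom.cell_size}\n")
        fh.write(f"NODATA_value {ASC_FLOAT_FORMAT % nodata}\n")
        for row in out:
            fh.write(" ".join(ASC_FLOAT_FORMAT % v for v in row))
            fh.write("\n")


class EnvStack:
    """Aligned multi-layer environmental raster stack.

    All layers share one :class:`GridGeometry` and one validity mask (the union
    of each layer's nodata footprint).  Each layer has a role, ``"climate"``
    (subject to scenario shifts) or ``"static"`` (soils, topography, ...).
    """

    def __init__(self, layers: dict[str, np.ndarray], geometry: GridGeometry,
                 roles: dict[str, str] | None = None, scenario_id: str = "baseline"):
        if not layers:
            raise ValueError("stack needs at least one layer")
        self.geometry = geometry
        self.scenario_id = scenario_id
        self.layers: dict[str, np.ndarray] = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != geometry.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != {geometry.shape}")
            self.layers[name] = arr.copy()
        self.roles = dict(roles) if roles else {n: "climate" for n in self.layers}
        for n in self.layers:
            self.roles.setdefault(n, "climate")
        # shared nodata footprint: a cell invalid in any layer is invalid in all
        valid = np.ones(geometry.shape, dtype=bool)
        for arr in self.layers.values():
            valid &= np.isfinite(arr)
        for arr in self.layers.values():
            arr[~valid] = np.nan
        self.valid = valid

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def climate_layers(self) -> list[str]:
        return [n for n in self.layers if self.roles[n] == "climate"]

    @property
    def static_layers(self) -> list[str]:
        return [n for n in self.layers if self.roles[n] == "static"]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def subset(self, names: list[str]) -> "EnvStack":
        unknown = set(names) - set(self.layers)
        if unknown:
            raise KeyError(f"unknown layers {sorted(unknown)}")
        return EnvStack({n: self.layers[n] for n in names}, self.geometry,
                        {n: self.roles[n] for n in names}, self.scenario_id)

    def copy(self, scenario_id: str | None = None) -> "EnvStack":
        return EnvStack({n: a.copy() for n, a in self.layers.items()}, self.geometry,
                        dict(self.roles), scenario_id or self.scenario_id)

    def table(self, names: list[str] | None = None) -> np.ndarray:
        """Valid-cell design table, shape (n_valid, n_layers), column order = names."""
        names = names or self.layer_names
        return np.column_stack([self.layers[n][self.valid] for n in names])

    def values_at(self, rows, cols, names: list[str] | None = None) -> np.ndarray:
        names = names or self.layer_names
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def write(self, directory, nodata: float = -9999.0) -> Path:
        """Write every layer as .asc plus a JSON manifest; returns manifest path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        for name, arr in self.layers.items():
            fn = f"{name}.asc"
            write_ascii_grid(directory / fn, arr, self.geometry, nodata)
            entries.append({"name": name, "path": fn, "role": self.roles[name]})
        manifest = {"scenario_id": self.scenario_id, "layers": entries}
        mpath = directory / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return mpath

    @classmethod
    def read(cls, manifest_path) -> "EnvStack":
        manifest_path = Path(manifest_path)
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        layers, roles = {}, {}
        geom = None
        for entry in manifest["layers"]:
            arr, g, _ = read_ascii_grid(manifest_path.parent / entry["path"])
            if geom is None:
                geom = g
            elif g != geom:
                raise AlignmentError(
                    f"layer {entry['name']!r} geometry differs from the stack's"
                )
            layers[entry["name"]] = arr
            roles[entry["name"]] = entry.get("role", "climate")
        return cls(layers, geom, roles, manifest.get("scenario_id", "baseline"))


def _resample(arr: np.ndarray, src: GridGeometry, dst: GridGeometry, order: int) -> np.ndarray:
    """Resample one layer between grids by sampling at target cell centers."""
    rows = np.arange(dst.n_rows)
    cols = np.arange(dst.n_cols)
    cx, cy = dst.cell_center(*np.meshgrid(rows, cols, indexing="ij"))
    if not np.any(src.contains(cx, cy)):
        raise AlignmentError("target geometry does not overlap the source layer")
    # fractional array indices in the source (top-row-first)
    fi = (src.y_ur - cy) / src.cell_size - 0.5
    fj = (cx - src.x_ll) / src.cell_size - 0.5
    out = ndimage.map_coordinates(arr, [fi, fj], order=order, mode="nearest", cval=np.nan)
    out[~src.contains(cx, cy)] = np.nan
    return out


def align_stack(layers: dict[str, tuple[np.ndarray, GridGeometry]],
                target: GridGeometry,
                roles: dict[str, str] | None = None,
                categorical: set[str] | frozenset[str] = frozenset(),
                scenario_id: str = "baseline") -> EnvStack:
    """Resample heterogeneous layers onto a shared target geometry.

    Continuous layers are interpolated bilinearly; names listed in
    ``categorical`` use nearest-neighbor.  Missingness is unioned into the
    stack's shared mask by :class:`EnvStack`.
    """
    aligned = {}
    for name, (arr, geom) in layers.items():
        if geom == target:
            aligned[name] = np.asarray(arr, dtype=float)
            continue
        order = 0 if name in categorical else 1
        aligned[name] = _resample(np.asarray(arr, dtype=float), geom, target, order)
    return EnvStack(aligned, target, roles, scenario_id)


def correlation_matrix(stack: EnvStack, sample_size: int = 10_000,
                       seed: int | None = None, names: list[str] | None = None) -> np.ndarray:
    """Pairwise Pearson correlation between layers over background cells.

    Computed on a uniform random sample of valid cells (all cells if the grid
    is smaller than ``sample_size``).  Zero-variance layers get correlation 0
    against everything (with a warning); the diagonal is always 1.
    """
    names = names or stack.layer_names
    tab = stack.table(names)
    if tab.shape[0] < 2:
        raise ValueError("need at least 2 valid cells")
    if tab.shape[0] > sample_size:
        rng = np.random.default_rng(seed)
        idx = rng.choice(tab.shape[0], size=sample_size, replace=False)
        tab = tab[idx]
    sd = tab.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        bad = [names[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(f"zero-variance layers {bad}: correlations reported as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(tab, rowvar=False)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)
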