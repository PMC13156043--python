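"""Aligned raster stacks, GeoTIFF/GeoJSON I/O and district rasterization.

Conventions: projected planar metres; origin at the upper-left cell corner;
row-major (row, col) indexing with y decreasing down rows; a cell belongs to
the polygon containing its centre point. Nodata is a per-layer sentinel plus
a boolean mask; masked cells never enter statistics downstream.

GeoTIFF files are written with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA) so they open in QGIS/GDAL.
Continuous layers are stored as float64 so that write→read round-trips are
exact; int32 is used for label grids. Reprojection between CRSs is out of
scope — all grids live in one projected plane and must be born aligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.strtree import STRtree

__all__ = [
    "AlignmentError",
    "GridLayer",
    "EnvGrid",
    "DistrictGeometry",
    "read_grid",
    "write_grid",
    "read_districts",
    "write_districts",
    "rasterize_districts",
]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113

LABEL_NODATA = -1


class AlignmentError(ValueError):
    """Raised when layers/grids do not share shape, origin or cell size."""


@dataclass
class GridLayer:
    """One 2-D raster layer with georeferencing and a nodata mask."""

    values: np.ndarray
    origin: tuple[float, float]
    cell_size_m: float
    nodata: float = -9999.0
    mask: np.ndarray = field(default=None)  # True where nodata

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("layer must be 2-D")
        if self.mask is None:
            self.mask = np.asarray(self.values == self.nodata)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise AlignmentError("mask shape does not match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]


class EnvGrid:
    """Aligned stack of named raster layers over one grid geometry.

    Monthly layers use names like ``"precip_mm[3]"``; :meth:`precip` and
    :meth:`runoff` provide indexed access. All layers must share shape,
    origin and cell size (enforced on :meth:`add_layer`).
    """

    def __init__(self, n_rows: int, n_cols: int, cell_size_m: float = 100.0,
                 origin: tuple[float, float] = (0.0, 0.0)):
        if n_rows < 1 or n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        self.cell_size_m = float(cell_size_m)
        self.origin = (float(origin[0]), float(origin[1]))
        self.layers: dict[str, np.ndarray] = {}
        self.masks: dict[str, np.ndarray] = {}

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def add_layer(self, name: str, values: np.ndarray,
                  mask: np.ndarray | None = None) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise AlignmentError(
                f"layer {name!r} shape {values.shape} != grid shape {self.shape}")
        if mask is None:
            mask = np.zeros(self.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.shape:
            raise AlignmentError(f"mask for {name!r} misaligned")
        self.layers[name] = values
        self.masks[name] = mask

    def add_layer_from(self, name: str, layer: GridLayer) -> None:
        if layer.shape != self.shape:
            raise AlignmentError(
                f"layer {name!r} shape {layer.shape} != grid shape {self.shape}")
        if layer.origin != self.origin or layer.cell_size_m != self.cell_size_m:
            raise AlignmentError(f"layer {name!r} georeferencing mismatch")
        self.add_layer(name, layer.values, layer.mask)

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def layer(self, name: str) -> np.ndarray:
        return self.layers[name]

    def mask(self, name: str) -> np.ndarray:
        return self.masks[name]

    @property
    def n_months(self) -> int:
        return sum(1 for k in self.layers if k.startswith("precip_mm["))

    def precip(self, month: int) -> np.ndarray:
        return self.layers[f"precip_mm[{month}]"]

    def runoff(self, month: int) -> np.ndarray:
        return self.layers[f"runoff_mm[{month}]"]

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y coordinates of every cell centre, each shaped (n_rows, n_cols)."""
        ox, oy = self.origin
        cs = self.cell_size_m
        cols = ox + (np.arange(self.n_cols) + 0.5) * cs
        rows = oy - (np.arange(self.n_rows) + 0.5) * cs
        xs, ys = np.meshgrid(cols, rows)
        return xs, ys

    def validate(self) -> None:
        """Check the domain invariants of the standard layers, if present."""
        if "slope_deg" in self.layers:
            s = self.layers["slope_deg"][~self.masks["slope_deg"]]
            if s.size and (s.min() < 0 or s.max() > 90):
                raise ValueError("slope_deg outside [0, 90]")
        if "soc_percent" in self.layers:
            v = self.layers["soc_percent"][~self.masks["soc_percent"]]
            if v.size and v.min() < 0:
                raise ValueError("soc_percent negative")
        for m in range(self.n_months):
            p = self.precip(m)
            q = self.runoff(m)
            ok = ~(self.masks[f"precip_mm[{m}]"] | self.masks[f"runoff_mm[{m}]"])
            if np.any(p[ok] < 0) or np.any(q[ok] < 0):
                raise ValueError(f"negative precip/runoff in month {m}")
            if np.any(q[ok] > p[ok] + 1e-9):
                raise ValueError(f"runoff exceeds precipitation in month {m}")


@dataclass
class DistrictGeometry:
    """One district polygon with its identifier (UBIGEO-like string)."""

    district_id: str
    polygon: shapely.Geometry
    area_km2: float = None

    def __post_init__(self):
        if self.area_km2 is None:
            self.area_km2 = self.polygon.area / 1e6


def write_grid(path, values: np.ndarray, origin=(0.0, 0.0),
               cell_size_m: float = 100.0, nodata: float = -9999.0,
               mask: np.ndarray | None = None) -> None:
    """Write a single-band GeoTIFF (float64 continuous, int32 labels)."""
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("only 2-D single-band grids are written")
    if np.issubdtype(values.dtype, np.integer):
        data = values.astype(np.int32)
        nodata_out = int(nodata)
    else:
        data = values.astype(np.float64)
        nodata_out = float(nodata)
    if mask is not None:
        data = data.copy()
        data[np.asarray(mask, dtype=bool)] = nodata_out
    cs = float(cell_size_m)
    ox, oy = float(origin[0]), float(origin[1])
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_GDAL_NODATA, "s", 0, str(nodata_out)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_grid(path, expect_like: EnvGrid | None = None) -> GridLayer:
    """Read one GeoTIFF band into a :class:`GridLayer`.

    If ``expect_like`` is given, the file's geometry must match that grid's
    shape, origin and cell size; otherwise :class:`AlignmentError` is raised.
    """
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        if values.ndim == 3:  # single-band stored with a trailing axis
            values = values[..., 0]
        tags = page.tags
        cs = 1.0
        ox = oy = 0.0
        nodata = -9999.0
        if _MODEL_PIXEL_SCALE in tags:
            cs = float(tags[_MODEL_PIXEL_SCALE].value[0])
        if _MODEL_TIEPOINT in tags:
            tp = tags[_MODEL_TIEPOINT].value
            ox, oy = float(tp[3]), float(tp[4])
        if _GDAL_NODATA in tags:
            nodata = float(str(tags[_GDAL_NODATA].value))
    layer = GridLayer(values=values, origin=(ox, oy), cell_size_m=cs,
                      nodata=nodata)
    if expect_like is not None:
        if layer.shape != expect_like.shape:
            raise AlignmentError(
                f"{path}: shape {layer.shape} != expected {expect_like.shape}")
        if (layer.origin != expect_like.origin
                or layer.cell_size_m != expect_like.cell_size_m):
            raise AlignmentError(f"{path}: georeferencing mismatch")
    return layer


def write_districts(path, districts: list[DistrictGeometry]) -> None:
    """Write districts as a GeoJSON FeatureCollection (district_id property)."""
    features = []
    for d in districts:
        features.append({
            "type": "Feature",
            "properties": {"district_id": d.district_id, "area_km2": d.area_km2},
            "geometry": shapely_mapping(d.polygon),
        })
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_districts(path) -> list[DistrictGeometry]:
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    out = []
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        if "district_id" not in props:
            raise ValueError("GeoJSON feature missing mandatory district_id")
        out.append(DistrictGeometry(
            district_id=str(props["district_id"]),
            polygon=shapely_shape(feat["geometry"]),
            area_km2=props.get("area_km2"),
        ))
    return out


def _check_no_overlap(districts: list[DistrictGeometry]) -> None:
    geoms = [d.polygon for d in districts]
    tree = STRtree(geoms)
    offenders = []
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if inter.area > 1e-9 * min(g.area, geoms[j].area):
                offenders.append((districts[i].district_id,
                                  districts[j].district_id))
    if offenders:
        raise ValueError(f"overlapping district polygons: {offenders}")


def rasterize_districts(districts: list[DistrictGeometry],
                        grid: EnvGrid) -> np.ndarray:
    """Label every grid cell with the index of the district covering its centre.

    Returns an int32 array; cells covered by no district get ``LABEL_NODATA``
    (-1). Labels index into ``districts`` (label k ↔ districts[k]).
    Overlapping polygons are rejected with the offending id pairs listed.
    """
    if not districts:
        raise ValueError("empty district list")
    _check_no_overlap(districts)
    xs, ys = grid.cell_centres()
    labels = np.full(grid.shape, LABEL_NODATA, dtype=np.int32)
    for k, d in enumerate(districts):
        inside = shapely.contains_xy(d.polygon, xs.ravel(), ys.ravel())
        inside = inside.reshape(grid.shape)
        labels[inside] = k
    return labels
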