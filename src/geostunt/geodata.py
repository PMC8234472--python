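"""Geographic IO and covariate extraction.

Everything lives in a local equirectangular plane in kilometres; longitude/
latitude inputs are converted once on read (spherical equirectangular about
the data centroid) and never touched again, so a single Euclidean metric
serves the whole pipeline.

Cluster tables are CSV, zone polygons GeoJSON, rasters either ESRI ASCII
grids (plain text, the interchange default) or single-band float TIFF with an
explicit nodata tag.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon, mapping, shape

__all__ = [
    "ClusterRecord",
    "RasterGrid",
    "ZonePolygon",
    "read_cluster_table",
    "write_cluster_table",
    "extract_buffered",
    "merge_geocovariates",
    "classify_climate",
    "tercile_codes",
    "read_zones_geojson",
    "write_zones_geojson",
]

EARTH_RADIUS_KM = 6371.0


def lonlat_to_km(lon, lat, lon0: float, lat0: float):
    """Equirectangular projection to km about (lon0, lat0)."""
    x = np.radians(np.asarray(lon) - lon0) * EARTH_RADIUS_KM * math.cos(
        math.radians(lat0)
    )
    y = np.radians(np.asarray(lat) - lat0) * EARTH_RADIUS_KM
    return x, y


@dataclass
class ClusterRecord:
    """One survey cluster: location (km), design metadata, binomial stunting
    counts and named covariate values (categorical level codes or reals)."""

    cluster_id: str
    x: float
    y: float
    urban: bool
    stratum: str
    weight: float
    n_children: int
    n_stunted: int
    covariates: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(
                f"cluster {self.cluster_id}: weight must be > 0, got {self.weight}"
            )
        if self.n_children < 0:
            raise ValueError(
                f"cluster {self.cluster_id}: n_children must be >= 0"
            )
        if not 0 <= self.n_stunted <= self.n_children:
            raise ValueError(
                f"cluster {self.cluster_id}: n_stunted={self.n_stunted} outside "
                f"[0, n_children={self.n_children}]"
            )

    @property
    def location(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class RasterGrid:
    """Regular single-band raster.  ``origin`` is the lower-left corner of the
    lower-left cell; row 0 of ``values`` is the bottom row.  Missing cells are
    NaN in memory and ``nodata`` on disk."""

    origin: tuple
    resolution: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")

    @property
    def shape(self):
        return self.values.shape

    def cell_centres(self):
        """(ny*nx, 2) array of cell-centre coordinates (bottom row first)."""
        ny, nx = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.resolution
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.resolution
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def value_at(self, x: float, y: float) -> float:
        """Nearest-cell value (NaN outside the raster or on nodata)."""
        j = int(np.floor((x - self.origin[0]) / self.resolution))
        i = int(np.floor((y - self.origin[1]) / self.resolution))
        ny, nx = self.values.shape
        if not (0 <= i < ny and 0 <= j < nx):
            return float("nan")
        return float(self.values[i, j])

    # --- text (ESRI ASCII grid) serialization -------------------------------
    def save_ascii(self, path) -> None:
        ny, nx = self.values.shape
        vals = np.where(np.isnan(self.values), self.nodata, self.values)
        with open(path, "w") as fh:
            fh.write(f"ncols {nx}\nnrows {ny}\n")
            fh.write(f"xllcorner {self.origin[0]:.10g}\n")
            fh.write(f"yllcorner {self.origin[1]:.10g}\n")
            fh.write(f"cellsize {self.resolution:.10g}\n")
            fh.write(f"NODATA_value {self.nodata:.10g}\n")
            # ESRI convention: first data row is the top row
            for row in vals[::-1]:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def load_ascii(cls, path) -> "RasterGrid":
        header = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                }:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        vals = np.array(rows)[::-1]
        nodata = header.get("nodata_value", -9999.0)
        vals[vals == nodata] = np.nan
        return cls(
            origin=(header["xllcorner"], header["yllcorner"]),
            resolution=header["cellsize"],
            values=vals,
            nodata=nodata,
        )

    # --- TIFF serialization --------------------------------------------------
    def save_tiff(self, path) -> None:
        import tifffile

        vals = np.where(np.isnan(self.values), self.nodata, self.values)
        tifffile.imwrite(
            path,
            vals[::-1].astype(np.float32),
            extratags=[(42113, "s", 0, str(self.nodata), True)],
            metadata={
                "origin_x": self.origin[0],
                "origin_y": self.origin[1],
                "resolution_km": self.resolution,
            },
        )

    @classmethod
    def load_tiff(cls, path, origin=(0.0, 0.0), resolution=1.0) -> "RasterGrid":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            vals = page.asarray().astype(float)[::-1]
            nodata = -9999.0
            tag = page.tags.get(42113)
            if tag is not None:
                nodata = float(tag.value)
            meta = tf.shaped_metadata or tf.imagej_metadata
            if meta:
                m = meta[0] if isinstance(meta, (list, tuple)) else meta
                origin = (m.get("origin_x", origin[0]), m.get("origin_y", origin[1]))
                resolution = m.get("resolution_km", resolution)
        vals[vals == nodata] = np.nan
        return cls(origin=origin, resolution=resolution, values=vals, nodata=nodata)


@dataclass
class ZonePolygon:
    """Named administrative zone (admin-2 analogue)."""

    zone_name: str
    region_name: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError(f"zone {self.zone_name}: invalid or empty polygon")


# ---------------------------------------------------------------------------
# cluster tables
# ---------------------------------------------------------------------------

_REQUIRED = [
    "cluster_id", "x_km", "y_km", "urban", "stratum",
    "weight", "n_children", "n_stunted",
]


def write_cluster_table(records, path) -> None:
    records = list(records)
    cov_names = sorted({k for r in records for k in r.covariates})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_REQUIRED + cov_names)
        for r in records:
            row = [
                r.cluster_id, repr(r.x), repr(r.y), int(r.urban),
                r.stratum, repr(r.weight), r.n_children, r.n_stunted,
            ]
            row += [r.covariates.get(c, "") for c in cov_names]
            w.writerow(row)


def read_cluster_table(path):
    """Parse a cluster CSV; malformed rows raise with the offending line."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_REQUIRED) <= set(reader.fieldnames):
            missing = set(_REQUIRED) - set(reader.fieldnames or [])
            raise ValueError(f"cluster table missing columns: {sorted(missing)}")
        cov_names = [c for c in reader.fieldnames if c not in _REQUIRED]
        for lineno, row in enumerate(reader, start=2):
            try:
                covs = {}
                for c in cov_names:
                    v = row[c]
                    if v == "" or v is None:
                        continue
                    try:
                        covs[c] = float(v)
                    except ValueError:
                        covs[c] = v
                records.append(
                    ClusterRecord(
                        cluster_id=row["cluster_id"],
                        x=float(row["x_km"]),
                        y=float(row["y_km"]),
                        urban=bool(int(row["urban"])),
                        stratum=row["stratum"],
                        weight=float(row["weight"]),
                        n_children=int(row["n_children"]),
                        n_stunted=int(row["n_stunted"]),
                        covariates=covs,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# zones GeoJSON
# ---------------------------------------------------------------------------

def write_zones_geojson(zones, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"zone_name": z.zone_name, "region_name": z.region_name},
            "geometry": mapping(z.polygon),
        }
        for z in zones
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_zones_geojson(path):
    with open(path) as fh:
        data = json.load(fh)
    zones = []
    for feat in data["features"]:
        props = feat.get("properties", {})
        zones.append(
            ZonePolygon(
                zone_name=props.get("zone_name", "zone"),
                region_name=props.get("region_name", ""),
                polygon=shape(feat["geometry"]),
            )
        )
    return zones


# ---------------------------------------------------------------------------
# buffered extraction
# ---------------------------------------------------------------------------

URBAN_BUFFER_KM = 2.0
RURAL_BUFFER_KM = 10.0


def extract_buffered(raster: RasterGrid, point, urban: bool, with_count: bool = False):
    """Mean of non-nodata cell values whose centres fall within the circular
    buffer (2 km urban, 10 km rural) around ``point``.

    Returns the mean (NaN if every in-buffer cell is nodata).  Raises if the
    buffer contains no cell centre at all.  ``with_count=True`` also returns
    the number of contributing cells.
    """
    radius = URBAN_BUFFER_KM if urban else RURAL_BUFFER_KM
    point = np.asarray(point, dtype=float)
    centres = raster.cell_centres()
    d2 = ((centres - point) ** 2).sum(axis=1)
    inside = d2 <= radius**2
    if not np.any(inside):
        raise ValueError(
            f"buffer of {radius} km around ({point[0]:.2f}, {point[1]:.2f}) "
            "contains no raster cell centre"
        )
    vals = raster.values.ravel()[inside]
    ok = ~np.isnan(vals)
    count = int(ok.sum())
    mean = float(vals[ok].mean()) if count else float("nan")
    if with_count:
        return mean, count
    return mean


def merge_geocovariates(records, rasters: dict):
    """Attach one buffered-extraction covariate per raster to each cluster,
    keyed by the raster's name; clusters are merged by unique cluster_id."""
    records = list(records)
    ids = [r.cluster_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate cluster_id(s): {dup}")
    for name, raster in rasters.items():
        for r in records:
            val = extract_buffered(raster, (r.x, r.y), r.urban)
            r.covariates[name] = val  # NaN flags a missing extraction
    return records


# ---------------------------------------------------------------------------
# climatic band classification
# ---------------------------------------------------------------------------

DLST_LEVELS = ("<30 °C", "30–34.99 °C", "+35 °C")
RAINFALL_LEVELS = ("<141 mm", "142–1199 mm", "≥1200 mm")
ARIDITY_LEVELS = ("Arid", "Semi-arid", "Wet")
WETDAYS_LEVELS = ("Low", "Medium", "High")


def classify_climate(value: float, scheme: str) -> str:
    """Categorise a climatic covariate into its reporting band.

    Bands follow the printed labels: daytime land-surface temperature
    (<30 / [30, 35) / >=35 °C), annual rainfall (<141 / [141, 1200) /
    >=1200 mm; the printed 141-142 gap is closed half-open), aridity index
    (UNEP convention: arid < 0.2, semi-arid [0.2, 0.5), wet >= 0.5).
    """
    if scheme == "dlst":
        if value < 30.0:
            return DLST_LEVELS[0]
        if value < 35.0:
            return DLST_LEVELS[1]
        return DLST_LEVELS[2]
    if scheme == "rainfall":
        if value < 141.0:
            return RAINFALL_LEVELS[0]
        if value < 1200.0:
            return RAINFALL_LEVELS[1]
        return RAINFALL_LEVELS[2]
    if scheme == "aridity_index":
        if value < 0.2:
            return ARIDITY_LEVELS[0]
        if value < 0.5:
            return ARIDITY_LEVELS[1]
        return ARIDITY_LEVELS[2]
    raise ValueError(f"unknown classification scheme: {scheme!r}")


def tercile_codes(values) -> list:
    """Low/Medium/High codes by tercile split (used for wet-days per year)."""
    values = np.asarray(values, dtype=float)
    lo, hi = np.quantile(values, [1 / 3, 2 / 3])
    out = []
    for v in values:
        if v <= lo:
            out.append(WETDAYS_LEVELS[0])
        elif v <= hi:
            out.append(WETDAYS_LEVELS[1])
        else:
            out.append(WETDAYS_LEVELS[2])
    return out
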