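"""Posterior prevalence surfaces, zonal aggregation and map rendering.

Prediction follows the draw-wise rule: for each posterior draw, prevalence at
a pixel is ``expit(x'beta + projected field)``; pixel and zone summaries are
percentiles over draws.  Zones are aggregated *before* summarizing
(aggregate-then-summarize), which keeps zonal credible intervals coherent
with the joint posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import shapely
from scipy.special import expit
from shapely.geometry import Polygon

from .geodata import RasterGrid, classify_climate
from .model import FitResult
from .spde import Mesh, projector

__all__ = [
    "PredictionGrid",
    "PredictionSurface",
    "ZonalEstimate",
    "make_prediction_grid",
    "predict_surface",
    "zonal_aggregate",
    "render_map",
]


@dataclass
class PredictionGrid:
    """Regular lattice clipped to a boundary polygon; ``centres`` holds only
    the in-boundary pixel centres, ``index`` their (row, col) positions."""

    origin: tuple
    resolution: float
    nx: int
    ny: int
    centres: np.ndarray
    index: np.ndarray  # (n_pixels, 2) of (row, col)
    boundary: Polygon

    @property
    def n_pixels(self) -> int:
        return len(self.centres)

    def to_raster(self, values, nodata: float = -9999.0) -> RasterGrid:
        grid = np.full((self.ny, self.nx), np.nan)
        grid[self.index[:, 0], self.index[:, 1]] = values
        return RasterGrid(
            origin=self.origin, resolution=self.resolution,
            values=grid, nodata=nodata,
        )


@dataclass
class PredictionSurface:
    grid: PredictionGrid
    median: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    draws: np.ndarray | None = None  # (draws, n_pixels), thinned

    def __post_init__(self) -> None:
        bad = (self.lo95 > self.median) | (self.median > self.hi95)
        if np.any(bad):
            raise ValueError("pixel summaries violate lo95 <= median <= hi95")


@dataclass
class ZonalEstimate:
    zone_name: str
    median: float
    lo95: float
    hi95: float
    n_pixels: int


def make_prediction_grid(boundary: Polygon, resolution_km: float = 5.0) -> PredictionGrid:
    """Pixel centres on a regular ``resolution_km`` lattice clipped to the
    boundary (5 km is the reporting default)."""
    if resolution_km <= 0:
        raise ValueError("resolution_km must be > 0")
    minx, miny, maxx, maxy = boundary.bounds
    nx = max(1, int(np.ceil((maxx - minx) / resolution_km - 1e-9)))
    ny = max(1, int(np.ceil((maxy - miny) / resolution_km - 1e-9)))
    xs = minx + (np.arange(nx) + 0.5) * resolution_km
    ys = miny + (np.arange(ny) + 0.5) * resolution_km
    gx, gy = np.meshgrid(xs, ys)
    centres = np.column_stack([gx.ravel(), gy.ravel()])
    rows, cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    index = np.column_stack([rows.ravel(), cols.ravel()])
    inside = shapely.contains_xy(boundary, centres[:, 0], centres[:, 1])
    return PredictionGrid(
        origin=(minx, miny), resolution=resolution_km, nx=nx, ny=ny,
        centres=centres[inside], index=index[inside], boundary=Polygon(boundary),
    )


def _pixel_design(fit: FitResult, grid: PredictionGrid, covariate_rasters,
                  schemes) -> np.ndarray:
    """Design matrix at pixel centres matching the fit's coefficients.

    Raster values are read at pixel centres; categorical model terms are
    produced by passing raster values through their classification scheme and
    one-hot coding against the fitted coefficient names.
    """
    covariate_rasters = covariate_rasters or {}
    schemes = schemes or {}
    values: dict = {}
    for name, raster in covariate_rasters.items():
        v = np.array([raster.value_at(px, py) for px, py in grid.centres])
        if name in schemes:
            values[name] = np.array(
                [classify_climate(x, schemes[name]) if np.isfinite(x) else ""
                 for x in v],
                dtype=object,
            )
        else:
            values[name] = v
    cols = []
    for term_name in fit.beta_names:
        if term_name == "intercept":
            cols.append(np.ones(grid.n_pixels))
        elif "=" in term_name:
            base, lvl = term_name.split("=", 1)
            if base not in values:
                raise KeyError(f"no raster provided for covariate {base!r}")
            cols.append((values[base] == lvl).astype(float))
        else:
            if term_name not in values:
                raise KeyError(f"no raster provided for covariate {term_name!r}")
            v = np.asarray(values[term_name], dtype=float)
            if np.any(~np.isfinite(v)):
                raise ValueError(f"raster {term_name!r} is nodata at some pixels")
            cols.append(v)
    return np.column_stack(cols)


def predict_surface(fit: FitResult, grid: PredictionGrid,
                    covariate_rasters: dict | None = None,
                    mesh: Mesh | None = None,
                    schemes: dict | None = None,
                    max_draws: int = 500,
                    keep_draws: bool = True) -> PredictionSurface:
    """Posterior prevalence surface at the grid's pixel centres.

    Draws are thinned to at most ``max_draws`` to bound memory.  Every pixel
    must lie inside the mesh hull when the fit has a spatial field.
    """
    x_pix = _pixel_design(fit, grid, covariate_rasters, schemes)
    n_avail = fit.beta_draws.shape[0]
    take = np.linspace(0, n_avail - 1, min(max_draws, n_avail)).astype(int)
    psi = fit.beta_draws[take] @ x_pix.T
    if fit.field_draws is not None:
        use_mesh = mesh or fit.mesh
        if use_mesh is None:
            raise ValueError("a mesh is required to project the spatial field")
        a_pix = projector(use_mesh, grid.centres)
        psi = psi + fit.field_draws[take] @ a_pix.T.toarray()
    prev = expit(psi)
    lo, med, hi = np.percentile(prev, [2.5, 50.0, 97.5], axis=0)
    return PredictionSurface(
        grid=grid, median=med, lo95=lo, hi95=hi,
        draws=prev if keep_draws else None,
    )


def zonal_aggregate(surface: PredictionSurface, zones,
                    weights: RasterGrid | None = None) -> list:
    """Per-zone posterior prevalence, aggregate-then-summarize.

    For each posterior draw, the zone value is the (optionally
    population-weighted) mean of its member pixels; the zonal median and 95%
    CrI are percentiles over those draw-wise values.
    """
    if surface.draws is None:
        raise ValueError("surface must retain draws for zonal aggregation")
    centres = surface.grid.centres
    out = []
    for z in zones:
        member = shapely.contains_xy(z.polygon, centres[:, 0], centres[:, 1])
        n_pix = int(member.sum())
        if n_pix == 0:
            raise ValueError(f"zone {z.zone_name!r} contains no grid pixel")
        if weights is not None:
            w = np.array(
                [weights.value_at(px, py) for px, py in centres[member]]
            )
            w = np.where(np.isfinite(w) & (w > 0), w, 0.0)
            if w.sum() == 0:
                w = np.ones(n_pix)
        else:
            w = np.ones(n_pix)
        w = w / w.sum()
        zone_draws = surface.draws[:, member] @ w
        lo, med, hi = np.percentile(zone_draws, [2.5, 50.0, 97.5])
        out.append(
            ZonalEstimate(
                zone_name=z.zone_name, median=float(med),
                lo95=float(lo), hi95=float(hi), n_pixels=n_pix,
            )
        )
    return out


def zonal_table(estimates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "zone_name": e.zone_name, "median": e.median,
                "lo95": e.lo95, "hi95": e.hi95, "n_pixels": e.n_pixels,
            }
            for e in estimates
        ]
    )


def render_map(obj, png_path, tiff_path=None, zones=None, title: str | None = None):
    """Write a PNG choropleth (and optionally a TIFF of the median band).

    ``obj`` is a PredictionSurface or a list of ZonalEstimate (the latter
    requires ``zones`` for the polygon geometries).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Polygon as MplPolygon

    fig, ax = plt.subplots(figsize=(7, 6))
    if isinstance(obj, PredictionSurface):
        raster = obj.grid.to_raster(obj.median)
        extent = [
            raster.origin[0],
            raster.origin[0] + raster.shape[1] * raster.resolution,
            raster.origin[1],
            raster.origin[1] + raster.shape[0] * raster.resolution,
        ]
        im = ax.imshow(
            raster.values, origin="lower", extent=extent, cmap="viridis",
            vmin=0.0, vmax=max(1e-9, float(np.nanmax(raster.values))),
        )
        fig.colorbar(im, ax=ax, label="posterior median prevalence")
        if tiff_path is not None:
            raster.save_tiff(tiff_path)
    else:
        if zones is None:
            raise ValueError("zonal rendering requires the zone polygons")
        by_name = {z.zone_name: z.polygon for z in zones}
        patches, vals = [], []
        for est in obj:
            poly = by_name[est.zone_name]
            patches.append(MplPolygon(np.asarray(poly.exterior.coords)))
            vals.append(est.median)
        coll = PatchCollection(patches, cmap="viridis", edgecolor="black")
        coll.set_array(np.array(vals))
        ax.add_collection(coll)
        ax.autoscale()
        fig.colorbar(coll, ax=ax, label="posterior median prevalence")
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    if title:
        ax.set_title(title)
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
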