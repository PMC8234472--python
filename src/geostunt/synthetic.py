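"""DHS-like synthetic survey generator with known ground truth.

Emulates the design features of a two-stage stratified cluster survey of
child anthropometry: probability-proportional-to-size selection of
enumeration areas, a fixed take of 28 households per cluster, child-level
height-for-age z-scores dichotomised at HAZ < -2.0, confidentiality
displacement of cluster GPS positions (up to 2 km urban / 10 km rural,
restricted to the admin-2 zone), and smooth raster covariates.  The stunting
outcome is driven by categorical fixed effects plus a latent Matérn (nu = 1)
spatial field, so downstream model fits can be scored against the generating
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.spatial import Voronoi
from scipy.stats import norm
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram

from .geodata import ClusterRecord, RasterGrid, ZonePolygon
from .spde import MaternParams, gp_covariance

__all__ = [
    "StudyRegion",
    "CovariateSpec",
    "SimulationConfig",
    "GroundTruth",
    "make_study_region",
    "sample_clusters",
    "simulate_spatial_field",
    "simulate_outcomes",
    "apply_geomasking",
    "simulate_covariate_raster",
    "simulate_survey",
]

HAZ_CUTOFF = -2.0


@dataclass
class StudyRegion:
    """Square study area partitioned into named zones (admin-2 analogue)
    with a set of urban centres."""

    boundary: Polygon
    zones: list
    urban_centres: np.ndarray

    def zone_of(self, x: float, y: float):
        p = Point(x, y)
        for z in self.zones:
            if z.polygon.covers(p):
                return z
        # displaced/boundary points: nearest zone
        return min(self.zones, key=lambda z: z.polygon.distance(p))


@dataclass(frozen=True)
class CovariateSpec:
    """A categorical covariate: levels with sampling frequencies and a
    log-odds effect per non-reference level.  ``level='cluster'`` assigns one
    level per cluster, ``'child'`` one per child (aggregated to per-cluster
    level proportions on the records)."""

    name: str
    levels: tuple
    probs: tuple
    effects: dict  # level -> log-odds, reference level absent (0)
    level: str = "cluster"

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probs):
            raise ValueError(f"{self.name}: levels/probs length mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: probs must sum to 1")


def _default_covariates() -> tuple:
    # frequencies loosely patterned on under-five survey factor distributions
    return (
        CovariateSpec(
            "maternal_education", ("none", "primary", "secondary+"),
            (0.5, 0.35, 0.15), {"primary": -0.25, "secondary+": -0.5},
        ),
        CovariateSpec(
            "household_wealth", ("poor", "middle", "rich"),
            (0.4, 0.3, 0.3), {"middle": -0.2, "rich": -0.4},
        ),
        CovariateSpec(
            "aridity", ("Wet", "Semi-arid", "Arid"),
            (0.4, 0.35, 0.25), {"Semi-arid": 0.3, "Arid": 0.6},
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants for a synthetic survey.

    Defaults reproduce the reference design: 28 households per enumeration
    area, displacement caps of 2 km (urban) / 10 km (rural), 622 clusters, and
    a child-per-household rate chosen so a cluster yields ~14.6 measured
    children on average (9089 children across 622 clusters).
    """

    n_clusters: int = 622
    households_per_cluster: int = 28
    children_per_household_rate: float = 9089 / 622 / 28
    urban_fraction: float = 0.25
    covariates: tuple = field(default_factory=_default_covariates)
    intercept: float = -0.6
    matern: MaternParams = field(
        default_factory=lambda: MaternParams(kappa=0.04, sigma2=0.3)
    )
    haz_sd: float = 1.0
    displacement_urban_km: float = 2.0
    displacement_rural_km: float = 10.0
    age_group_probs: tuple = (0.4, 0.6)  # 0-23 / 24-59 months
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters <= 0 or self.households_per_cluster <= 0:
            raise ValueError("n_clusters and households_per_cluster must be > 0")
        if self.children_per_household_rate <= 0:
            raise ValueError("children_per_household_rate must be > 0")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ValueError("urban_fraction must lie in [0, 1]")
        if self.haz_sd < 0:
            raise ValueError("haz_sd must be >= 0")

    @property
    def beta(self) -> dict:
        """Flat map 'covariate=level' -> log-odds for non-reference levels."""
        return {
            f"{c.name}={lvl}": eff
            for c in self.covariates
            for lvl, eff in c.effects.items()
        }


@dataclass
class GroundTruth:
    """Generator-side truth used to score recovery: true (pre-displacement)
    locations, latent field values, effects and per-cluster prevalence."""

    beta: dict
    intercept: float
    true_locations: np.ndarray
    field_values: np.ndarray
    cluster_prevalence: np.ndarray
    matern: MaternParams

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "beta": self.beta,
                    "intercept": self.intercept,
                    "true_locations": self.true_locations.tolist(),
                    "field_values": self.field_values.tolist(),
                    "cluster_prevalence": self.cluster_prevalence.tolist(),
                    "matern": {
                        "kappa": self.matern.kappa,
                        "sigma2": self.matern.sigma2,
                        "nu": self.matern.nu,
                    },
                },
                fh,
            )


def make_study_region(n_zones: int, extent_km: float, seed: int) -> StudyRegion:
    """Square region of side ``extent_km`` split into ``n_zones`` Voronoi
    zones, with one urban centre per zone; deterministic given ``seed``."""
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    if extent_km <= 0:
        raise ValueError("extent_km must be > 0")
    rng = np.random.default_rng(seed)
    boundary = box(0.0, 0.0, extent_km, extent_km)
    if n_zones == 1:
        polys = [boundary]
    else:
        seeds = rng.uniform(0.05 * extent_km, 0.95 * extent_km, size=(n_zones, 2))
        vd = voronoi_diagram(MultiPoint([tuple(p) for p in seeds]), envelope=boundary)
        cells = list(vd.geoms)
        # match each seed to its cell so naming is deterministic
        polys = []
        for p in seeds:
            pt = Point(p)
            cell = next(c for c in cells if c.covers(pt))
            polys.append(cell.intersection(boundary))
    zones = [
        ZonePolygon(zone_name=f"zone_{i:02d}", region_name="synthetic", polygon=poly)
        for i, poly in enumerate(polys)
    ]
    centres = []
    for z in zones:
        c = z.polygon.representative_point()
        centres.append([c.x, c.y])
    return StudyRegion(boundary=boundary, zones=zones, urban_centres=np.array(centres))


def _uniform_in(poly: Polygon, rng, n: int) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(max(4 * n, 16), 2))
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[keep]])
    return pts[:n]


def sample_clusters(region: StudyRegion, config: SimulationConfig):
    """Place clusters and draw their design metadata.

    Urban clusters are placed near urban centres chosen with probability
    proportional to a simulated enumeration-area size measure; rural clusters
    are uniform over the region.  Each cluster receives a stratum label
    (zone x urban/rural), an inverse-inclusion-probability design weight, and
    a Poisson child count (households x per-household rate).

    Returns ``(records, true_locations)`` where the records have counts and
    covariates still unset (``n_stunted = 0``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_clusters
    n_urban = int(round(config.urban_fraction * n))
    sizes = rng.gamma(shape=3.0, scale=1.0, size=len(region.urban_centres))
    p_centre = sizes / sizes.sum()

    records = []
    locs = np.empty((n, 2))
    for i in range(n):
        urban = i < n_urban
        if urban:
            j = rng.choice(len(region.urban_centres), p=p_centre)
            while True:
                loc = region.urban_centres[j] + rng.normal(0.0, 5.0, size=2)
                if region.boundary.covers(Point(loc)):
                    break
            # inclusion probability ~ centre selection prob
            weight = 1.0 / (p_centre[j] * len(p_centre))
        else:
            loc = _uniform_in(region.boundary, rng, 1)[0]
            weight = 1.0
        locs[i] = loc
        zone = region.zone_of(*loc)
        n_children = int(
            rng.poisson(
                config.households_per_cluster * config.children_per_household_rate
            )
        )
        records.append(
            ClusterRecord(
                cluster_id=f"c{i:04d}",
                x=float(loc[0]),
                y=float(loc[1]),
                urban=urban,
                stratum=f"{zone.zone_name}/{'U' if urban else 'R'}",
                weight=float(weight),
                n_children=n_children,
                n_stunted=0,
            )
        )
    return records, locs


def simulate_spatial_field(locations, params: MaternParams, seed: int) -> np.ndarray:
    """One exact zero-mean Matérn Gaussian-process draw at ``locations``
    via dense Cholesky factorization."""
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    rng = np.random.default_rng(seed)
    if params.sigma2 == 0:
        return np.zeros(len(locations))
    if len(np.unique(locations, axis=0)) < len(locations):
        raise ValueError(
            "duplicate locations make the covariance singular; deduplicate "
            "them or add coordinate jitter"
        )
    cov = gp_covariance(locations, params)
    try:
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "covariance is singular (duplicate locations?); deduplicate or "
            "add jitter"
        ) from exc
    return chol @ rng.standard_normal(len(locations))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def simulate_outcomes(records, truth_field: np.ndarray, config: SimulationConfig,
                      return_children: bool = False):
    """Draw covariates and child outcomes; fill counts on the records.

    Per child, HAZ ~ Normal(mu_c, haz_sd) with mu_c set so that
    P(HAZ < -2.0) equals the child's true prevalence under the logistic
    model; a child is stunted iff HAZ < -2.0 (strict).  Returns
    ``(records, GroundTruth)`` and, optionally, a child-level table.
    """
    rng = np.random.default_rng(config.seed + 1)
    records = list(records)
    n = len(records)
    if len(truth_field) != n:
        raise ValueError("field length does not match number of clusters")

    child_rows = []
    cluster_prev = np.empty(n)
    for i, rec in enumerate(records):
        # cluster-level covariate draws
        cluster_eff = 0.0
        cluster_levels = {}
        for cov in config.covariates:
            if cov.level == "cluster":
                lvl = rng.choice(cov.levels, p=cov.probs)
                cluster_levels[cov.name] = lvl
                cluster_eff += cov.effects.get(lvl, 0.0)
                rec.covariates[cov.name] = str(lvl)
        m = rec.n_children
        # child-level covariate draws
        child_eff = np.zeros(m)
        child_levels = {}
        for cov in config.covariates:
            if cov.level == "child":
                lv = rng.choice(cov.levels, p=cov.probs, size=m)
                child_levels[cov.name] = lv
                child_eff += np.array([cov.effects.get(l, 0.0) for l in lv])
                for lvl in cov.levels[1:]:
                    rec.covariates[f"{cov.name}:{lvl}"] = (
                        float(np.mean(lv == lvl)) if m else 0.0
                    )
        psi = config.intercept + cluster_eff + child_eff + truth_field[i]
        p_child = _invlogit(psi)
        cluster_prev[i] = float(
            _invlogit(config.intercept + cluster_eff + truth_field[i])
        )
        # HAZ mechanism: mu chosen so P(Normal(mu, sd) < cutoff) = p_child
        if config.haz_sd == 0:
            mu = np.where(p_child >= 0.5, HAZ_CUTOFF - 1.0, HAZ_CUTOFF + 1.0)
            haz = mu
        else:
            mu = HAZ_CUTOFF - config.haz_sd * norm.ppf(p_child)
            haz = mu + config.haz_sd * rng.standard_normal(m)
        stunted = haz < HAZ_CUTOFF
        rec.n_stunted = int(stunted.sum())
        if return_children:
            ages = rng.choice(["0-23", "24-59"], p=config.age_group_probs, size=m)
            for k in range(m):
                row = {
                    "cluster_id": rec.cluster_id,
                    "stratum": rec.stratum,
                    "weight": rec.weight,
                    "haz": float(haz[k]),
                    "stunted": int(stunted[k]),
                    "age_group": ages[k],
                }
                row.update({nm: str(v) for nm, v in cluster_levels.items()})
                row.update({nm: str(lv[k]) for nm, lv in child_levels.items()})
                child_rows.append(row)

    truth = GroundTruth(
        beta=config.beta,
        intercept=config.intercept,
        true_locations=np.array([[r.x, r.y] for r in records]),
        field_values=np.asarray(truth_field, dtype=float),
        cluster_prevalence=cluster_prev,
        matern=config.matern,
    )
    if return_children:
        import pandas as pd

        return records, truth, pd.DataFrame(child_rows)
    return records, truth


def apply_geomasking(records, config: SimulationConfig, region: StudyRegion,
                     seed: int, max_attempts: int = 1000):
    """Displace cluster coordinates for confidentiality.

    Direction uniform on [0, 2pi), distance uniform on [0, max] with max
    2 km (urban) / 10 km (rural); the draw is rejected and repeated until the
    displaced point stays inside the cluster's own zone polygon, mirroring the
    admin-2 restriction.  Original coordinates live only in GroundTruth.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        zone = region.zone_of(rec.x, rec.y)
        max_km = (
            config.displacement_urban_km if rec.urban
            else config.displacement_rural_km
        )
        for _ in range(max_attempts):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            dist = rng.uniform(0.0, max_km)
            nx = rec.x + dist * np.cos(theta)
            ny = rec.y + dist * np.sin(theta)
            if zone.polygon.covers(Point(nx, ny)):
                break
        else:
            raise RuntimeError(
                f"cluster {rec.cluster_id}: no admissible displaced point in "
                f"zone {zone.zone_name} after {max_attempts} attempts"
            )
        out.append(replace_coords(rec, nx, ny))
    return out


def replace_coords(rec: ClusterRecord, x: float, y: float) -> ClusterRecord:
    return ClusterRecord(
        cluster_id=rec.cluster_id, x=float(x), y=float(y), urban=rec.urban,
        stratum=rec.stratum, weight=rec.weight, n_children=rec.n_children,
        n_stunted=rec.n_stunted, covariates=dict(rec.covariates),
    )


def simulate_covariate_raster(region: StudyRegion, params: MaternParams,
                              resolution_km: float, seed: int) -> RasterGrid:
    """Smooth Gaussian-field raster over the region's bounding box, with
    nodata (NaN) outside the boundary.

    Simulated exactly by dense Cholesky when the grid is small; on large
    grids the field is drawn on a coarse lattice (spacing <= half the
    correlation range) and interpolated, which preserves the variance to
    within the smoothing of scales below the range.
    """
    if resolution_km <= 0:
        raise ValueError("resolution_km must be > 0")
    minx, miny, maxx, maxy = region.boundary.bounds
    nx = int(round((maxx - minx) / resolution_km))
    ny = int(round((maxy - miny) / resolution_km))
    xs = minx + (np.arange(nx) + 0.5) * resolution_km
    ys = miny + (np.arange(ny) + 0.5) * resolution_km
    gx, gy = np.meshgrid(xs, ys)
    centres = np.column_stack([gx.ravel(), gy.ravel()])

    if params.sigma2 == 0:
        vals = np.zeros(len(centres))
    elif len(centres) <= 3000:
        vals = simulate_spatial_field(centres, params, seed)
    else:
        from scipy.interpolate import RegularGridInterpolator

        range_km = np.sqrt(8.0) / params.kappa
        coarse = max(resolution_km, range_km / 2.0)
        # cap the coarse lattice at ~3000 nodes
        while ((maxx - minx) / coarse + 2) * ((maxy - miny) / coarse + 2) > 3000:
            coarse *= 1.4
        cx = np.arange(minx - coarse, maxx + 2 * coarse, coarse)
        cy = np.arange(miny - coarse, maxy + 2 * coarse, coarse)
        cgx, cgy = np.meshgrid(cx, cy)
        cpts = np.column_stack([cgx.ravel(), cgy.ravel()])
        cvals = simulate_spatial_field(cpts, params, seed).reshape(len(cy), len(cx))
        interp = RegularGridInterpolator((cy, cx), cvals)
        vals = interp(np.column_stack([centres[:, 1], centres[:, 0]]))

    inside = shapely.contains_xy(region.boundary, centres[:, 0], centres[:, 1])
    vals = np.where(inside, vals, np.nan)
    return RasterGrid(
        origin=(minx, miny), resolution=resolution_km,
        values=vals.reshape(ny, nx),
    )


def simulate_survey(region: StudyRegion, config: SimulationConfig,
                    geomask: bool = True, return_children: bool = False):
    """End-to-end convenience: clusters -> field -> outcomes -> geomasking.

    Returns ``(records, truth)`` (plus a child table when requested); the
    records carry displaced coordinates when ``geomask`` is on, while the
    truth holds the original ones.
    """
    skeletons, locs = sample_clusters(region, config)
    fld = simulate_spatial_field(locs, config.matern, config.seed + 7)
    out = simulate_outcomes(
        skeletons, fld, config, return_children=return_children
    )
    records, truth = out[0], out[1]
    if geomask:
        records = apply_geomasking(records, config, region, config.seed + 13)
    if return_children:
        return records, truth, out[2]
    return records, truth
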