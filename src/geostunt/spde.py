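"""Matérn spatial engine: correlation, practical range, mesh, projector, SPDE precision.

A stationary isotropic Matérn field (smoothness ``nu = 1``) is represented two
ways:

* exactly, through :func:`gp_covariance` (dense covariance, usable as an
  oracle and for small simulations), and
* approximately, as a Gaussian Markov random field on a triangulated mesh via
  the stochastic-PDE (SPDE) link, ``(kappa^2 - Delta)^(alpha/2) x = W`` with
  ``alpha = nu + d/2 = 2`` in two dimensions.  The GMRF precision is assembled
  from linear finite elements with a lumped mass matrix, which keeps it
  sparse.

All coordinates are planar kilometres; ``kappa`` is a decay per km.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.tri import Triangulation
from scipy import sparse
from scipy.optimize import brentq
from scipy.spatial import Delaunay, cKDTree
from scipy.special import gamma as gamma_fn
from scipy.special import kv
from shapely.geometry import Point, Polygon

__all__ = [
    "MaternParams",
    "Mesh",
    "matern_correlation",
    "practical_range",
    "range_sqrt8nu",
    "kappa_for_range",
    "build_mesh",
    "projector",
    "fem_matrices",
    "spde_precision",
    "gp_covariance",
]


@dataclass(frozen=True)
class MaternParams:
    """Matérn hyperparameters: decay ``kappa`` (1/km), marginal variance
    ``sigma2``, smoothness ``nu`` (fixed at 1 unless overridden)."""

    kappa: float
    sigma2: float
    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")
        if self.nu <= 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")


def matern_correlation(d, kappa: float, nu: float = 1.0):
    """Matérn correlation at distance ``d`` km.

    ``rho(d) = 2^(1-nu)/Gamma(nu) * (kappa d)^nu * K_nu(kappa d)`` with the
    limit 1 at d = 0.  For the default ``nu = 1`` this is ``(kappa d) K_1(kappa d)``.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    kd = kappa * d
    out = np.ones_like(kd)
    pos = kd > 0
    kdp = kd[pos]
    out[pos] = (2.0 ** (1 - nu) / gamma_fn(nu)) * kdp**nu * kv(nu, kdp)
    # K_nu underflows for large arguments; the correlation limit is 0 there
    out = np.nan_to_num(out, nan=0.0)
    if out.ndim == 0:
        return float(out)
    return out


def range_sqrt8nu(kappa: float, nu: float = 1.0) -> float:
    """Conventional range ``sqrt(8 nu)/kappa`` (correlation ~0.14)."""
    return float(np.sqrt(8.0 * nu) / kappa)


def practical_range(kappa: float, threshold: float = 0.1, nu: float = 1.0) -> float:
    """Distance (km) at which the Matérn correlation drops to ``threshold``.

    The default threshold 0.1 is the convention under which spatial dependence
    is reported as negligible; the alternative ``sqrt(8 nu)/kappa`` convention
    is exposed as :func:`range_sqrt8nu`.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    # solve in the dimensionless variable t = kappa*d, then scale by 1/kappa
    f = lambda t: matern_correlation(t, 1.0, nu) - threshold
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
    t_star = brentq(f, 1e-12, hi, xtol=1e-14, rtol=1e-12)
    return float(t_star / kappa)


def kappa_for_range(range_km: float, threshold: float = 0.1, nu: float = 1.0) -> float:
    """Inverse of :func:`practical_range`: decay giving the stated range."""
    return practical_range(1.0, threshold, nu) / range_km


@dataclass
class Mesh:
    """Triangulation of the (extended) study region.

    ``vertices`` is (n, 2) km coordinates, ``triangles`` (m, 3) vertex
    indices with positive signed area, ``boundary`` the original study
    polygon (the mesh extends beyond it to damp boundary effects).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    boundary: Polygon
    _trifinder: object = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangulation(self) -> Triangulation:
        return Triangulation(
            self.vertices[:, 0], self.vertices[:, 1], self.triangles
        )

    def trifinder(self):
        if self._trifinder is None:
            self._trifinder = self.triangulation().get_trifinder()
        return self._trifinder

    def save_text(self, path) -> None:
        """OFF-like plain-text serialization (vertex list + triangle list)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vertices)} {len(self.triangles)}\n")
            for x, y in self.vertices:
                fh.write(f"{x:.10g} {y:.10g}\n")
            for a, b, c in self.triangles:
                fh.write(f"{a} {b} {c}\n")
            ext = np.asarray(self.boundary.exterior.coords)
            fh.write(f"boundary {len(ext)}\n")
            for x, y in ext:
                fh.write(f"{x:.10g} {y:.10g}\n")

    @classmethod
    def load_text(cls, path) -> "Mesh":
        with open(path) as fh:
            nv, nt = map(int, fh.readline().split())
            verts = np.array(
                [list(map(float, fh.readline().split())) for _ in range(nv)]
            )
            tris = np.array(
                [list(map(int, fh.readline().split())) for _ in range(nt)]
            )
            header = fh.readline().split()
            nb = int(header[1])
            bnd = np.array(
                [list(map(float, fh.readline().split())) for _ in range(nb)]
            )
        return cls(verts, tris, Polygon(bnd))


def _signed_areas(verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p0, p1, p2 = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    return 0.5 * (
        (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1])
        - (p2[:, 0] - p0[:, 0]) * (p1[:, 1] - p0[:, 1])
    )


def _delaunay_mesh(points: np.ndarray, boundary: Polygon) -> tuple[np.ndarray, np.ndarray]:
    dt = Delaunay(points)
    tris = dt.simplices.copy()
    areas = _signed_areas(points, tris)
    flip = areas < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    keep = np.abs(areas) > 1e-9
    return points, tris[keep]


def build_mesh(
    locations,
    boundary: Polygon,
    max_edge_km: float,
    cutoff_km: float = 0.0,
    extension_km: float | None = None,
) -> Mesh:
    """Triangulate data locations plus filler vertices.

    The mesh is a Delaunay triangulation of the (cutoff-deduplicated) data
    locations, a regular interior grid at spacing ``~0.7 max_edge`` and a
    coarser ring of extension vertices out to ``extension_km`` beyond the
    study boundary (default twice ``max_edge``-scaled, intended to be set to
    roughly twice the prior-median range).  Long interior edges are refined by
    midpoint insertion until no edge inside the boundary exceeds
    ``max_edge_km``.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    if len(locations) < 3:
        raise ValueError("need at least 3 locations to build a mesh")
    # collinearity check
    span = locations - locations[0]
    if np.linalg.matrix_rank(span, tol=1e-9) < 2:
        raise ValueError("locations are collinear; cannot triangulate")
    if max_edge_km <= 0:
        raise ValueError("max_edge_km must be > 0")
    if extension_km is None:
        extension_km = 2.0 * max_edge_km

    # deduplicate data locations within cutoff (greedy)
    kept: list[np.ndarray] = []
    if cutoff_km > 0:
        tree_pts: list[np.ndarray] = []
        for p in locations:
            if not tree_pts or np.min(
                np.linalg.norm(np.array(tree_pts) - p, axis=1)
            ) > cutoff_km:
                tree_pts.append(p)
        kept = tree_pts
    else:
        kept = list(locations)
    data = np.array(kept)

    spacing = 0.7 * max_edge_km
    minx, miny, maxx, maxy = boundary.bounds
    outer = boundary.buffer(extension_km, quad_segs=4)
    ominx, ominy, omaxx, omaxy = outer.bounds

    xs = np.arange(ominx, omaxx + spacing, spacing)
    ys = np.arange(ominy, omaxy + spacing, spacing)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    import shapely

    inside_outer = shapely.contains_xy(outer, grid[:, 0], grid[:, 1])
    inside_inner = shapely.contains_xy(boundary, grid[:, 0], grid[:, 1])
    # extension ring vertices at double spacing to keep the mesh small
    ring = grid[inside_outer & ~inside_inner]
    if len(ring):
        coarse = (
            np.isclose(np.mod((ring[:, 0] - ominx) / spacing, 2), 0, atol=0.25)
            & np.isclose(np.mod((ring[:, 1] - ominy) / spacing, 2), 0, atol=0.25)
        )
        ring = ring[coarse]
    grid = np.vstack([grid[inside_inner], ring])
    # drop filler vertices too close to data vertices (conditioning)
    if len(grid):
        tree = cKDTree(data)
        d, _ = tree.query(grid)
        grid = grid[d > 0.35 * spacing]
    # boundary vertices of the outer hull
    hull = np.asarray(outer.exterior.coords)[:-1]
    points = np.vstack([data, grid, hull])

    points, tris = _delaunay_mesh(points, boundary)
    # refinement: split interior edges longer than max_edge
    for _ in range(8):
        p0, p1, p2 = points[tris[:, 0]], points[tris[:, 1]], points[tris[:, 2]]
        new_pts = []
        for a, b in ((p0, p1), (p1, p2), (p2, p0)):
            length = np.linalg.norm(a - b, axis=1)
            mid = 0.5 * (a + b)
            long = length > max_edge_km
            if np.any(long):
                m = mid[long]
                keep = shapely.contains_xy(boundary, m[:, 0], m[:, 1])
                new_pts.append(m[keep])
        if not new_pts:
            break
        add = np.unique(np.round(np.vstack(new_pts), 6), axis=0)
        if len(add) == 0:
            break
        points = np.vstack([points, add])
        points, tris = _delaunay_mesh(points, boundary)
    return Mesh(points, tris, Polygon(boundary))


def projector(mesh: Mesh, locations) -> sparse.csr_matrix:
    """Sparse barycentric projector (rows: locations, cols: mesh vertices).

    Each row holds the barycentric weights of the triangle containing the
    point; weights are in [0, 1] and sum to 1.  Points outside the mesh hull
    raise an error naming the offending point.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    finder = mesh.trifinder()
    t_idx = finder(locations[:, 0], locations[:, 1])
    bad = np.where(t_idx < 0)[0]
    if len(bad):
        p = locations[bad[0]]
        raise ValueError(
            f"location ({p[0]:.3f}, {p[1]:.3f}) lies outside the mesh hull"
        )
    tri = mesh.triangles[t_idx]
    v0 = mesh.vertices[tri[:, 0]]
    v1 = mesh.vertices[tri[:, 1]]
    v2 = mesh.vertices[tri[:, 2]]
    d = (v1[:, 0] - v0[:, 0]) * (v2[:, 1] - v0[:, 1]) - (v2[:, 0] - v0[:, 0]) * (
        v1[:, 1] - v0[:, 1]
    )
    w1 = (
        (locations[:, 0] - v0[:, 0]) * (v2[:, 1] - v0[:, 1])
        - (v2[:, 0] - v0[:, 0]) * (locations[:, 1] - v0[:, 1])
    ) / d
    w2 = (
        (v1[:, 0] - v0[:, 0]) * (locations[:, 1] - v0[:, 1])
        - (locations[:, 0] - v0[:, 0]) * (v1[:, 1] - v0[:, 1])
    ) / d
    w0 = 1.0 - w1 - w2
    weights = np.column_stack([w0, w1, w2]).clip(0.0, 1.0)
    weights /= weights.sum(axis=1, keepdims=True)
    rows = np.repeat(np.arange(len(locations)), 3)
    cols = tri.ravel()
    a = sparse.coo_matrix(
        (weights.ravel(), (rows, cols)),
        shape=(len(locations), mesh.n_vertices),
    )
    return a.tocsr()


def save_projector_text(a: sparse.spmatrix, path) -> None:
    """Coordinate-list text export of a sparse projector."""
    coo = a.tocoo()
    with open(path, "w") as fh:
        fh.write(f"{coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {v:.12g}\n")


def fem_matrices(mesh: Mesh) -> tuple[np.ndarray, sparse.csr_matrix]:
    """Lumped mass vector ``c`` and stiffness matrix ``G`` for P1 elements."""
    verts, tris = mesh.vertices, mesh.triangles
    n = len(verts)
    area = _signed_areas(verts, tris)
    c = np.zeros(n)
    np.add.at(c, tris.ravel(), np.repeat(area / 3.0, 3))
    rows, cols, vals = [], [], []
    p = verts[tris]  # (m, 3, 2)
    # edge vectors opposite each vertex
    e = np.stack(
        [p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]], axis=1
    )  # (m, 3, 2)
    for i in range(3):
        for j in range(3):
            gij = (e[:, i] * e[:, j]).sum(axis=1) / (4.0 * area)
            rows.append(tris[:, i])
            cols.append(tris[:, j])
            vals.append(gij)
    g = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return c, g


@dataclass
class SpdePrecision:
    """SPDE (alpha = 2) precision over mesh vertices, scaled so the field's
    marginal variance targets ``params.sigma2``."""

    q: sparse.csr_matrix
    tau: float
    params: MaternParams


def spde_precision(mesh: Mesh, params: MaternParams) -> SpdePrecision:
    """Assemble the alpha = 2 GMRF precision
    ``Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^-1 G)`` with lumped mass C.

    ``tau^2 = 1 / (4 pi kappa^2 sigma2)`` gives marginal variance ``sigma2``
    away from the mesh boundary.
    """
    if params.sigma2 <= 0:
        raise ValueError("sigma2 must be > 0 for a proper GMRF precision")
    c, g = fem_matrices(mesh)
    if np.any(c <= 0):
        raise ValueError("degenerate mesh: non-positive lumped mass entries")
    kappa2 = params.kappa**2
    cinv = sparse.diags(1.0 / c)
    cmat = sparse.diags(c)
    tau2 = 1.0 / (4.0 * np.pi * kappa2 * params.sigma2)
    q = tau2 * (kappa2**2 * cmat + 2.0 * kappa2 * g + g @ cinv @ g)
    q = ((q + q.T) * 0.5).tocsr()
    return SpdePrecision(q=q, tau=float(np.sqrt(tau2)), params=params)


def gp_covariance(locations, params: MaternParams, jitter: float = 0.0) -> np.ndarray:
    """Dense Matérn covariance of a set of locations (the exact-GP oracle)."""
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    d = np.linalg.norm(
        locations[:, None, :] - locations[None, :, :], axis=-1
    )
    cov = params.sigma2 * matern_correlation(d, params.kappa, params.nu)
    if jitter:
        cov = cov + jitter * np.eye(len(locations))
    return cov
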