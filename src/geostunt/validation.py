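"""Hold-out validation and spatial autocorrelation checks.

Clusters are split 75/25 at random; the model is fitted on the training
clusters and its posterior prevalence (median and 95% CrI of the binomial
proportion) is compared with the observed stunting proportions of the test
clusters through RMSE (percentage-point scale), 95% CrI coverage and
Pearson correlation.  Global spatial autocorrelation is measured by Moran's
I with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import FitResult, McmcConfig, ModelSpec, PriorSpec, fit_geostatistical
from .spde import Mesh, projector

__all__ = [
    "ValidationReport",
    "MoranResult",
    "split_train_test",
    "rmse",
    "pearson",
    "interval_coverage",
    "validate_fit",
    "morans_i",
]


@dataclass
class ValidationReport:
    rmse: float          # percentage-point scale
    coverage95: float
    pearson_r: float     # NaN when undefined (constant predictions)
    n_test: int
    converged: bool = True


@dataclass
class MoranResult:
    i: float
    expected: float      # -1/(n-1)
    p_perm: float
    n_perm: int


def split_train_test(records, fraction: float = 0.75, seed: int = 0):
    """Cluster-level random split; train size = round-half-up(fraction*n)."""
    records = list(records)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(records)
    if n < 4:
        raise ValueError("need at least 4 clusters to split")
    n_train = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = set(order[:n_train].tolist())
    train = [r for i, r in enumerate(records) if i in train_idx]
    test = [r for i, r in enumerate(records) if i not in train_idx]
    return train, test


def rmse(obs, pred) -> float:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 1:
        raise ValueError("obs and pred must have equal nonzero length")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def pearson(obs, pred) -> float:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("pearson needs two aligned vectors of length >= 2")
    if np.std(obs) == 0 or np.std(pred) == 0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def interval_coverage(obs, lo, hi) -> float:
    obs = np.asarray(obs, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if not (obs.shape == lo.shape == hi.shape) or obs.size < 1:
        raise ValueError("obs, lo, hi must have equal nonzero length")
    return float(np.mean((obs >= lo) & (obs <= hi)))


def validate_fit(train, test, spec: ModelSpec, mesh: Mesh,
                 priors: PriorSpec | None = None,
                 mcmc: McmcConfig | None = None,
                 method: str = "laplace", seed: int = 0) -> ValidationReport:
    """Fit on training clusters, score posterior prevalence at test clusters.

    RMSE is reported in percentage points (proportions x 100) and Pearson r
    between observed proportions and posterior-median prevalences (NaN when
    predictions are constant).  Coverage is against the 95% interval of the
    *posterior predictive* distribution of the observed proportion (a
    binomial draw of the cluster's size per posterior prevalence draw), so a
    well-specified model is calibrated despite finite cluster sizes.
    """
    fit = fit_geostatistical(
        spec, train, mesh, priors=priors, mcmc=mcmc, method=method, seed=seed
    )
    test = [r for r in test if r.n_children > 0]
    from .model import build_design

    y_t, n_t, x_t, _ = build_design(test, spec)
    locs = np.array([[r.x, r.y] for r in test], dtype=float)
    a_t = projector(mesh, locs)
    psi = fit.beta_draws @ x_t.T + fit.field_draws @ a_t.T.toarray()
    prev = 1.0 / (1.0 + np.exp(-psi))
    med = np.percentile(prev, 50.0, axis=0)
    rng = np.random.default_rng(seed + 77003)
    pred_prop = rng.binomial(
        n_t.astype(int)[None, :], prev
    ) / n_t[None, :]
    lo, hi = np.percentile(pred_prop, [2.5, 97.5], axis=0)
    obs = y_t / n_t
    return ValidationReport(
        rmse=rmse(100.0 * obs, 100.0 * med),
        coverage95=interval_coverage(obs, lo, hi),
        pearson_r=pearson(obs, med),
        n_test=len(test),
        converged=fit.converged,
    )


def _knn_weights(locations, k: int) -> np.ndarray:
    n = len(locations)
    tree = cKDTree(locations)
    _, idx = tree.query(locations, k=min(k + 1, n))
    w = np.zeros((n, n))
    for i in range(n):
        for j in idx[i][1:]:
            w[i, j] = 1.0
    return w


def _inverse_distance_weights(locations) -> np.ndarray:
    locations = np.asarray(locations, dtype=float)
    d = np.linalg.norm(locations[:, None] - locations[None, :], axis=-1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    return w


def morans_i(values, locations=None, weight_scheme: str = "knn", k: int = 5,
             weights: np.ndarray | None = None, row_standardize: bool = True,
             n_perm: int = 999, seed: int = 0) -> MoranResult:
    """Global Moran's I with a label-permutation p-value.

    ``I = (n / sum_ij w_ij) * sum_ij w_ij (x_i - xbar)(x_j - xbar) /
    sum_i (x_i - xbar)^2``.  Weights: row-standardized k-nearest (default,
    k=5), inverse distance, or an explicit matrix.  The permutation p-value
    is two-sided-upper: the share of permuted |I - E[I]| >= observed, with
    the observed statistic counted among the permutations.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 observations")
    if np.std(x) == 0:
        raise ValueError("Moran's I is undefined for constant values")
    if weights is not None:
        w = np.asarray(weights, dtype=float).copy()
    elif weight_scheme == "knn":
        w = _knn_weights(np.asarray(locations, dtype=float), k)
    elif weight_scheme == "inverse_distance":
        w = _inverse_distance_weights(locations)
    else:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    np.fill_diagonal(w, 0.0)
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs

    def stat(xv):
        z = xv - xv.mean()
        return float(n / w.sum() * (z @ w @ z) / (z @ z))

    i_obs = stat(x)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    count = 1  # include the observed statistic
    for _ in range(n_perm):
        i_perm = stat(rng.permutation(x))
        if abs(i_perm - expected) >= abs(i_obs - expected) - 1e-15:
            count += 1
    return MoranResult(
        i=i_obs, expected=expected,
        p_perm=count / (n_perm + 1), n_perm=n_perm,
    )
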