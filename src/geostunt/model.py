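"""Bayesian grouped-binomial logit models, non-spatial and geostatistical.

Two inference routes share one model:

* a blocked Gibbs sampler in which the logistic likelihood is made
  conditionally Gaussian by Pólya-Gamma augmentation — (coefficients, latent
  field) are drawn jointly from their Gaussian full conditional and the
  Matérn hyperparameters (log kappa, log sigma2) move by random-walk
  Metropolis; and
* a Laplace route (``method='laplace'``): Gaussian approximation of the
  latent posterior at its mode for each hyperparameter value, a quadratic
  approximation of the hyperparameter posterior on the log scale, and
  posterior draws from the resulting mixture.  This is the fast mode used for
  replicate studies.

Priors follow the reference workflow: effectively flat intercept (normal,
precision 1e-6), normal(0, precision 0.001) coefficients, gamma(1, 0.00005)
on the spatial decay kappa and gamma(1, 0.00005) on the field precision
1/sigma2 (an inverse-gamma prior on the variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import chi2 as chi2_dist

from .spde import Mesh, MaternParams, practical_range, projector, spde_precision, fem_matrices

__all__ = [
    "CategoricalTerm",
    "NumericTerm",
    "ModelSpec",
    "PriorSpec",
    "McmcConfig",
    "FitResult",
    "build_design",
    "fit_nonspatial",
    "fit_geostatistical",
    "summarize_or",
    "interaction_test",
    "compute_dic",
    "compute_waic",
    "forward_select",
    "sample_polya_gamma",
]


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoricalTerm:
    """Named categorical covariate; the reference level (default: first
    listed) is absorbed into the intercept."""

    name: str
    levels: tuple
    reference: str | None = None

    @property
    def ref(self) -> str:
        return self.reference if self.reference is not None else self.levels[0]

    @property
    def coded_levels(self) -> tuple:
        return tuple(l for l in self.levels if l != self.ref)


@dataclass(frozen=True)
class NumericTerm:
    """Numeric covariate entering the linear predictor directly (used for
    child-level covariates aggregated to per-cluster proportions)."""

    name: str


@dataclass
class ModelSpec:
    covariates: list = dc_field(default_factory=list)
    spatial: bool = False
    interaction_group: str | None = None


@dataclass(frozen=True)
class PriorSpec:
    """Prior settings (see module docstring)."""

    intercept_precision: float = 1e-6
    coef_precision: float = 0.001
    # spatial decay: the default is a log-normal prior on kappa centred at a
    # scale set from the data extent (range ~ 1/5 of the bounding-box
    # diagonal), the convention of SPDE software defaults; the literal
    # gamma(shape, rate) prior on kappa is available via decay_prior="gamma"
    # but is near-flat out to 1/rate and lets the posterior drift into the
    # degenerate no-field regime.
    decay_prior: str = "lognormal"
    decay_gamma: tuple = (1.0, 0.00005)       # gamma(shape, rate) on kappa
    decay_lognormal_sd: float = 1.0
    decay_kappa0: float | None = None         # None: set from data extent
    precision_gamma: tuple = (1.0, 0.00005)   # gamma(shape, rate) on 1/sigma2
    fix_kappa: float | None = None
    fix_sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.intercept_precision < 0 or self.coef_precision < 0:
            raise ValueError("prior precisions must be >= 0")
        if min(self.decay_gamma) <= 0 or min(self.precision_gamma) <= 0:
            raise ValueError("hyperprior parameters must be positive")
        if self.decay_prior not in ("lognormal", "gamma"):
            raise ValueError("decay_prior must be 'lognormal' or 'gamma'")


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 4
    n_draws: int = 2500
    n_warmup: int = 1000
    hyper_step: float = 0.35
    pg_terms: int = 200
    hyper_init: tuple | None = None  # (kappa, sigma2)


def build_design(data, spec: ModelSpec):
    """Assemble (y, n, X, names) from cluster records or a (y, n, ...) frame.

    X has an intercept column first, then treatment-coded dummies for
    categorical terms and raw columns for numeric terms.
    """
    if isinstance(data, pd.DataFrame):
        df = data
        y = df["y"].to_numpy(dtype=float)
        n = df["n"].to_numpy(dtype=float)
        get = lambda name: df[name]
    else:
        records = list(data)
        y = np.array([r.n_stunted for r in records], dtype=float)
        n = np.array([r.n_children for r in records], dtype=float)
        get = lambda name: pd.Series([r.covariates.get(name) for r in records])

    cols = [np.ones(len(y))]
    names = ["intercept"]
    for term in spec.covariates:
        if isinstance(term, NumericTerm):
            vals = pd.to_numeric(get(term.name)).to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)):
                raise ValueError(f"covariate {term.name!r} has missing values")
            cols.append(vals)
            names.append(term.name)
        else:
            vals = get(term.name).astype(str)
            observed = set(vals)
            unknown = observed - set(map(str, term.levels))
            if unknown:
                raise ValueError(
                    f"covariate {term.name!r}: unknown level(s) {sorted(unknown)}"
                )
            for lvl in term.coded_levels:
                cols.append((vals == str(lvl)).to_numpy(dtype=float))
                names.append(f"{term.name}={lvl}")
    x = np.column_stack(cols)
    return y, n, x, names


def _prior_precision(names, priors: PriorSpec) -> np.ndarray:
    prec = np.full(len(names), priors.coef_precision)
    prec[0] = priors.intercept_precision
    return prec


# ---------------------------------------------------------------------------
# Pólya-Gamma sampling
# ---------------------------------------------------------------------------

def _pg_mean(b, c):
    c = np.abs(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(c > 1e-8, b / (2.0 * np.maximum(c, 1e-300)) * np.tanh(c / 2.0), b / 4.0)
    return out


def sample_polya_gamma(rng, b, c, n_terms: int = 200) -> np.ndarray:
    """Draw PG(b, c) variates by the truncated infinite convolution of
    gammas, with the truncated tail replaced by its exact mean.

    ``PG(b, c) = (2 pi^2)^-1 sum_k g_k / ((k - 1/2)^2 + c^2/(4 pi^2))`` with
    ``g_k ~ Gamma(b, 1)``; the first ``n_terms`` terms are sampled and the
    remainder enters through ``E[PG(b, c)] = b tanh(c/2) / (2c)``.
    """
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    m = b.shape[0]
    k = np.arange(1, n_terms + 1) - 0.5
    denom = k[:, None] ** 2 + (c[None, :] / (2.0 * np.pi)) ** 2
    g = rng.gamma(np.broadcast_to(b, (n_terms, m)))
    x = (g / denom).sum(axis=0) / (2.0 * np.pi**2)
    trunc_mean = (np.broadcast_to(b, (n_terms, m)) / denom).sum(axis=0) / (
        2.0 * np.pi**2
    )
    return x + (_pg_mean(b, c) - trunc_mean)


# ---------------------------------------------------------------------------
# likelihood helpers
# ---------------------------------------------------------------------------

def _binom_loglik_pointwise(y, n, psi):
    """log Binomial(y | n, expit(psi)) including the combinatorial constant;
    psi may be (draws, rows) or (rows,)."""
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return const + y * psi - n * np.logaddexp(0.0, psi)


def _newton_mode(y, n, z_mat, prior_prec, offset=0.0, max_iter=60, tol=1e-9):
    """Posterior mode and Hessian of a Gaussian-prior logit model.

    ``prior_prec`` may be a dense/sparse matrix or a 1-D diagonal.  Returns
    (mode, hessian_dense, loglik_at_mode).
    """
    p = z_mat.shape[1]
    if sparse.issparse(prior_prec):
        pmat = prior_prec.toarray()
    else:
        pmat = np.diag(prior_prec) if np.ndim(prior_prec) == 1 else np.asarray(prior_prec)
    z = np.zeros(p)
    dense_z = z_mat.toarray() if sparse.issparse(z_mat) else np.asarray(z_mat)

    def objective(zv):
        psi = dense_z @ zv + offset
        return float(
            _binom_loglik_pointwise(y, n, psi).sum() - 0.5 * zv @ pmat @ zv
        )

    obj = objective(z)
    for _ in range(max_iter):
        psi = dense_z @ z + offset
        mu = expit(psi)
        w = n * mu * (1.0 - mu)
        grad = dense_z.T @ (y - n * mu) - pmat @ z
        hess = dense_z.T @ (dense_z * w[:, None]) + pmat
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step-halving line search
        t = 1.0
        for _ in range(30):
            cand = z + t * step
            cobj = objective(cand)
            if cobj >= obj - 1e-12:
                break
            t *= 0.5
        moved = np.max(np.abs(t * step))
        z = z + t * step
        obj = objective(z)
        if moved < tol:
            break
    psi = dense_z @ z + offset
    mu = expit(psi)
    w = n * mu * (1.0 - mu)
    hess = dense_z.T @ (dense_z * w[:, None]) + pmat
    ll = float(_binom_loglik_pointwise(y, n, psi).sum())
    return z, hess, ll


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Posterior summaries and draws from either inference route."""

    method: str
    beta_names: list
    beta_draws: np.ndarray                      # (draws, p)
    field_draws: np.ndarray | None = None       # (draws, n_vertices)
    hyper_draws: dict = dc_field(default_factory=dict)
    loglik_pointwise: np.ndarray | None = None  # (draws, rows)
    rhat: dict = dc_field(default_factory=dict)
    ess: dict = dc_field(default_factory=dict)
    converged: bool = True
    marginal_loglik: float | None = None
    mesh: Mesh | None = None
    _y: np.ndarray | None = None
    _n: np.ndarray | None = None
    _x: np.ndarray | None = None
    _a: sparse.spmatrix | None = None

    def psi_draws(self) -> np.ndarray:
        psi = self.beta_draws @ self._x.T
        if self.field_draws is not None and self._a is not None:
            psi = psi + self.field_draws @ self._a.T.toarray()
        return psi

    def beta_summary(self) -> pd.DataFrame:
        qs = np.percentile(self.beta_draws, [2.5, 50.0, 97.5], axis=0)
        return pd.DataFrame(
            {
                "term": self.beta_names,
                "median": qs[1],
                "lo95": qs[0],
                "hi95": qs[2],
            }
        )

    def hyper_summary(self) -> pd.DataFrame:
        rows = []
        for name, draws in self.hyper_draws.items():
            lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
            rows.append({"param": name, "median": med, "lo95": lo, "hi95": hi})
        return pd.DataFrame(rows)

    def save(self, outdir) -> None:
        """Serialize draws (npz) + JSON summaries into a directory."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            out / "draws.npz",
            beta=self.beta_draws,
            field=(
                self.field_draws
                if self.field_draws is not None
                else np.empty((0, 0))
            ),
            **{f"hyper_{k}": v for k, v in self.hyper_draws.items()},
        )
        summary = {
            "method": self.method,
            "converged": bool(self.converged),
            "beta": self.beta_summary().to_dict(orient="records"),
            "hyper": self.hyper_summary().to_dict(orient="records"),
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "marginal_loglik": self.marginal_loglik,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)


def _store_pointwise(fit: FitResult) -> None:
    fit.loglik_pointwise = _binom_loglik_pointwise(
        fit._y[None, :], fit._n[None, :], fit.psi_draws()
    )


def _diagnostics(chains: dict) -> tuple[dict, dict, bool]:
    """Split-Rhat and bulk ESS per parameter from (chains, draws) arrays."""
    import arviz as az

    rhat, ess = {}, {}
    for name, arr in chains.items():
        da = az.convert_to_dataset(arr[..., None] if arr.ndim == 2 else arr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat[name] = float(az.rhat(da)["x"].values.ravel()[0])
            ess[name] = float(az.ess(da)["x"].values.ravel()[0])
    finite = [v for v in rhat.values() if np.isfinite(v)]
    converged = all(v < 1.05 for v in finite) if finite else True
    return rhat, ess, converged


# ---------------------------------------------------------------------------
# non-spatial fits
# ---------------------------------------------------------------------------

def _check_rank(x, names) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn(
            "design matrix is rank deficient (separable or aliased levels); "
            "posteriors will be prior-dominated for the aliased directions",
            stacklevel=3,
        )


def fit_nonspatial(spec: ModelSpec, data, priors: PriorSpec | None = None,
                   mcmc: McmcConfig | None = None, method: str = "gibbs",
                   seed: int = 0, n_draws_laplace: int = 1000) -> FitResult:
    """Posterior for the fixed effects of a grouped binomial logit model."""
    if spec.spatial:
        raise ValueError("spec.spatial must be False for fit_nonspatial")
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    y, n, x, names = build_design(data, spec)
    keep = n > 0
    y, n, x = y[keep], n[keep], x[keep]
    _check_rank(x, names)
    prec = _prior_precision(names, priors)

    if method == "laplace":
        mode, hess, _ = _newton_mode(y, n, x, prec)
        chol = cho_factor(hess, lower=True)
        rng = np.random.default_rng(seed)
        xi = rng.standard_normal((n_draws_laplace, len(names)))
        # draws = mode + L^-T xi for H = L L^T
        lmat = np.linalg.cholesky(hess)
        draws = mode[None, :] + np.linalg.solve(lmat.T, xi.T).T
        sign, logdet_h = np.linalg.slogdet(hess)
        logdet_p = float(np.sum(np.log(np.maximum(prec, 1e-300))))
        psi = x @ mode
        ll = float(_binom_loglik_pointwise(y, n, psi).sum())
        marg = (
            ll - 0.5 * mode @ (prec * mode)
            + 0.5 * logdet_p - 0.5 * logdet_h
        )
        fit = FitResult(
            method="laplace", beta_names=names, beta_draws=draws,
            marginal_loglik=marg, _y=y, _n=n, _x=x,
        )
        _store_pointwise(fit)
        return fit

    if method != "gibbs":
        raise ValueError(f"unknown method {method!r}")

    p = len(names)
    all_chains = np.empty((mcmc.n_chains, mcmc.n_draws, p))
    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng((seed, chain))
        beta = np.zeros(p)
        kept = 0
        for it in range(mcmc.n_warmup + mcmc.n_draws):
            psi = x @ beta
            omega = sample_polya_gamma(rng, n, psi, mcmc.pg_terms)
            h = x.T @ (x * omega[:, None]) + np.diag(prec)
            lmat = np.linalg.cholesky(h)
            m = cho_solve((lmat, True), x.T @ (y - n / 2.0))
            beta = m + np.linalg.solve(
                lmat.T, rng.standard_normal(p)
            )
            if it >= mcmc.n_warmup:
                all_chains[chain, kept] = beta
                kept += 1
    chains = {names[j]: all_chains[:, :, j] for j in range(p)}
    rhat, ess, converged = _diagnostics(chains)
    fit = FitResult(
        method="gibbs", beta_names=names,
        beta_draws=all_chains.reshape(-1, p),
        rhat=rhat, ess=ess, converged=converged,
        _y=y, _n=n, _x=x,
    )
    _store_pointwise(fit)
    return fit


# ---------------------------------------------------------------------------
# geostatistical fits
# ---------------------------------------------------------------------------

def _hyper_logprior(kappa, sigma2, priors: PriorSpec, kappa0: float = 1.0):
    """Log prior density of (log kappa, log sigma2), Jacobians included."""
    if priors.decay_prior == "lognormal":
        lk = -0.5 * ((np.log(kappa) - np.log(kappa0))
                     / priors.decay_lognormal_sd) ** 2
    else:
        a_k, b_k = priors.decay_gamma
        lk = a_k * np.log(kappa) - b_k * kappa      # gamma on kappa + Jacobian
    a_p, b_p = priors.precision_gamma
    ls = -a_p * np.log(sigma2) - b_p / sigma2       # gamma on 1/sigma2 + Jacobian
    return lk + ls


class _SpdeCache:
    """Precision assembly Q(kappa, sigma2) with the mesh's FEM matrices
    factored out, plus dense log-determinants."""

    def __init__(self, mesh: Mesh):
        c, g = fem_matrices(mesh)
        self.cvec = c
        self.g = g.toarray()
        self.k3 = self.g @ np.diag(1.0 / c) @ self.g
        self.cmat = np.diag(c)
        self.nv = len(c)

    def q(self, kappa: float, sigma2: float) -> np.ndarray:
        tau2 = 1.0 / (4.0 * np.pi * kappa**2 * sigma2)
        q = tau2 * (kappa**4 * self.cmat + 2.0 * kappa**2 * self.g + self.k3)
        return 0.5 * (q + q.T)

    def logdet_and_chol(self, qmat: np.ndarray):
        lmat = np.linalg.cholesky(qmat)
        return 2.0 * float(np.sum(np.log(np.diag(lmat)))), lmat


def fit_geostatistical(spec: ModelSpec, data, mesh: Mesh,
                       priors: PriorSpec | None = None,
                       mcmc: McmcConfig | None = None,
                       method: str = "laplace", seed: int = 0,
                       n_draws_laplace: int = 1000) -> FitResult:
    """Joint posterior over fixed effects, latent Matérn field and
    hyperparameters for the geostatistical grouped binomial logit model."""
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    y, n, x, names = build_design(data, spec)
    if isinstance(data, pd.DataFrame):
        locs = data[["x", "y"]].to_numpy(dtype=float)
    else:
        locs = np.array([[r.x, r.y] for r in data], dtype=float)
    keep = n > 0
    y, n, x, locs = y[keep], n[keep], x[keep], locs[keep]
    _check_rank(x, names)
    a_mat = projector(mesh, locs)
    prec_beta = _prior_precision(names, priors)
    cache = _SpdeCache(mesh)
    p = len(names)
    nv = cache.nv

    diag_km = float(np.linalg.norm(np.ptp(locs, axis=0)))
    kappa0 = (
        priors.decay_kappa0
        if priors.decay_kappa0 is not None
        else np.sqrt(8.0) / max(diag_km / 5.0, 1e-6)
    )
    if priors.fix_kappa is not None and priors.fix_sigma2 is not None:
        phi0 = np.log([priors.fix_kappa, priors.fix_sigma2])
        fixed = True
    else:
        if mcmc.hyper_init is not None:
            phi0 = np.log(mcmc.hyper_init)
        else:
            phi0 = np.log([kappa0, 0.3])
        fixed = False

    z_mat = np.hstack([x, a_mat.toarray()])

    def latent_laplace(phi):
        kappa, sigma2 = np.exp(phi)
        qmat = cache.q(kappa, sigma2)
        pmat = np.zeros((p + nv, p + nv))
        pmat[:p, :p] = np.diag(prec_beta)
        pmat[p:, p:] = qmat
        mode, hess, ll = _newton_mode(y, n, z_mat, pmat)
        logdet_q, _ = cache.logdet_and_chol(
            qmat + 1e-12 * np.eye(nv)
        )
        sign, logdet_h = np.linalg.slogdet(hess)
        logmarg = (
            ll - 0.5 * mode @ pmat @ mode + 0.5 * logdet_q - 0.5 * logdet_h
            + _hyper_logprior(kappa, sigma2, priors, kappa0)
        )
        return logmarg, mode, hess

    if method == "laplace":
        rng = np.random.default_rng(seed)
        if fixed:
            phi_hat = phi0
            sig_phi = np.zeros((2, 2))
        else:
            res = minimize(
                lambda ph: -latent_laplace(ph)[0], phi0,
                method="Nelder-Mead",
                options={"maxiter": 80, "xatol": 0.02, "fatol": 0.05},
            )
            phi_hat = res.x
            # finite-difference Hessian of the log marginal
            h = 0.15
            hmat = np.zeros((2, 2))
            f0 = latent_laplace(phi_hat)[0]
            fs = {}

            def feval(dx, dy):
                key = (dx, dy)
                if key not in fs:
                    fs[key] = latent_laplace(
                        phi_hat + np.array([dx, dy]) * h
                    )[0]
                return fs[key]

            hmat[0, 0] = (feval(1, 0) - 2 * f0 + feval(-1, 0)) / h**2
            hmat[1, 1] = (feval(0, 1) - 2 * f0 + feval(0, -1)) / h**2
            hmat[0, 1] = hmat[1, 0] = (
                feval(1, 1) - feval(1, -1) - feval(-1, 1) + feval(-1, -1)
            ) / (4 * h**2)
            neg = -hmat
            try:
                eig = np.linalg.eigvalsh(neg)
                if np.any(eig <= 1e-8):
                    raise np.linalg.LinAlgError
                sig_phi = np.linalg.inv(neg)
            except np.linalg.LinAlgError:
                sig_phi = np.diag([0.25, 0.25])

        if fixed:
            phi_draws = np.tile(phi_hat, (n_draws_laplace, 1))
        else:
            lphi = np.linalg.cholesky(sig_phi + 1e-12 * np.eye(2))
            phi_draws = phi_hat[None, :] + (
                lphi @ rng.standard_normal((2, n_draws_laplace))
            ).T

        # latent conditionals on a lattice of standardized hyper values
        if fixed:
            cells = np.zeros((n_draws_laplace, 2), dtype=int)
            lphi_inv = np.eye(2)
        else:
            lphi_inv = np.linalg.inv(lphi)
            std = (phi_draws - phi_hat) @ lphi_inv.T
            cells = np.clip(np.rint(std), -2, 2).astype(int)
        cell_cache: dict = {}
        z_draws = np.empty((n_draws_laplace, p + nv))
        for i in range(n_draws_laplace):
            key = (int(cells[i, 0]), int(cells[i, 1]))
            if key not in cell_cache:
                if fixed:
                    phi_cell = phi_hat
                else:
                    phi_cell = phi_hat + lphi @ np.array(key, dtype=float)
                _, mode, hess = latent_laplace(phi_cell)
                lh = np.linalg.cholesky(hess)
                cell_cache[key] = (mode, lh)
            mode, lh = cell_cache[key]
            z_draws[i] = mode + np.linalg.solve(
                lh.T, rng.standard_normal(p + nv)
            )

        kappa_draws = np.exp(phi_draws[:, 0])
        sigma2_draws = np.exp(phi_draws[:, 1])
        range_draws = np.array([practical_range(k) for k in kappa_draws])
        fit = FitResult(
            method="laplace", beta_names=names,
            beta_draws=z_draws[:, :p], field_draws=z_draws[:, p:],
            hyper_draws={
                "kappa": kappa_draws, "sigma2": sigma2_draws,
                "range_km": range_draws,
            },
            marginal_loglik=float(latent_laplace(phi_hat)[0]),
            mesh=mesh, _y=y, _n=n, _x=x, _a=a_mat,
        )
        _store_pointwise(fit)
        return fit

    if method != "gibbs":
        raise ValueError(f"unknown method {method!r}")

    # --- blocked Gibbs with PG augmentation + collapsed Metropolis ---------
    # Given the PG draws the latent block (beta, u) is Gaussian, so the
    # Metropolis step on (log kappa, log sigma2) targets the hyperparameter
    # density with the latent block integrated out (partially collapsed
    # Gibbs), which mixes far better than conditioning on the field.
    n_keep = mcmc.n_draws
    beta_ch = np.empty((mcmc.n_chains, n_keep, p))
    field_ch = np.empty((mcmc.n_chains, n_keep, nv))
    hyper_ch = np.empty((mcmc.n_chains, n_keep, 2))
    pdiag = np.concatenate([prec_beta, np.zeros(nv)])
    rhs_const = z_mat.T @ (y - n / 2.0)

    def collapsed(phi_val, omega):
        """log p(phi | omega, y) up to a constant, latent integrated out;
        also returns the Cholesky of the conditional latent precision."""
        kappa, sigma2 = np.exp(phi_val)
        qmat = cache.q(kappa, sigma2)
        logdet_q, _ = cache.logdet_and_chol(qmat)
        m_prec = z_mat.T @ (z_mat * omega[:, None])
        m_prec[np.diag_indices(p + nv)] += pdiag
        m_prec[p:, p:] += qmat
        lmat = np.linalg.cholesky(m_prec)
        mean = cho_solve((lmat, True), rhs_const)
        logdet_m = 2.0 * float(np.sum(np.log(np.diag(lmat))))
        lp = (
            0.5 * logdet_q - 0.5 * logdet_m
            + 0.5 * float(rhs_const @ mean)
            + _hyper_logprior(kappa, sigma2, priors, kappa0)
        )
        return lp, lmat, mean

    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng((seed, 101 + chain))
        phi = phi0.copy()
        z = np.zeros(p + nv)
        kept = 0
        step = mcmc.hyper_step
        for it in range(mcmc.n_warmup + n_keep):
            psi = z_mat @ z
            omega = sample_polya_gamma(rng, n, psi, mcmc.pg_terms)
            lp_cur, lmat, mean = collapsed(phi, omega)
            if not fixed:
                prop = phi + step * rng.standard_normal(2)
                lp_new, lmat_new, mean_new = collapsed(prop, omega)
                accepted = np.log(rng.uniform()) < lp_new - lp_cur
                if accepted:
                    phi, lmat, mean = prop, lmat_new, mean_new
                if it < mcmc.n_warmup:
                    # Robbins-Monro adaptation toward ~30% acceptance
                    step *= np.exp(((1.0 if accepted else 0.0) - 0.3) * 0.05)
                    step = float(np.clip(step, 0.02, 3.0))
            z = mean + np.linalg.solve(
                lmat.T, rng.standard_normal(p + nv)
            )
            if it >= mcmc.n_warmup:
                beta_ch[chain, kept] = z[:p]
                field_ch[chain, kept] = z[p:]
                hyper_ch[chain, kept] = np.exp(phi)
                kept += 1

    chains = {names[j]: beta_ch[:, :, j] for j in range(p)}
    if not fixed:
        chains["log_kappa"] = np.log(hyper_ch[:, :, 0])
        chains["log_sigma2"] = np.log(hyper_ch[:, :, 1])
    rhat, ess, converged = _diagnostics(chains)
    kappa_draws = hyper_ch[:, :, 0].reshape(-1)
    fit = FitResult(
        method="gibbs", beta_names=names,
        beta_draws=beta_ch.reshape(-1, p),
        field_draws=field_ch.reshape(-1, nv),
        hyper_draws={
            "kappa": kappa_draws,
            "sigma2": hyper_ch[:, :, 1].reshape(-1),
            "range_km": np.array([practical_range(k) for k in kappa_draws]),
        },
        rhat=rhat, ess=ess, converged=converged,
        mesh=mesh, _y=y, _n=n, _x=x, _a=a_mat,
    )
    _store_pointwise(fit)
    return fit


# ---------------------------------------------------------------------------
# summaries, tests, criteria, selection
# ---------------------------------------------------------------------------

def summarize_or(fit: FitResult) -> pd.DataFrame:
    """Odds ratios with 95% credible intervals, draw-wise exponentiation.

    Reference levels are absent (implicit OR 1.00); the intercept is skipped.
    """
    rows = []
    for j, name in enumerate(fit.beta_names):
        if name == "intercept":
            continue
        draws = np.exp(fit.beta_draws[:, j])
        lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
        rows.append({"term": name, "or": med, "lo95": lo, "hi95": hi})
    return pd.DataFrame(rows)


def interaction_test(rows: pd.DataFrame, covariates: list, group_term: str,
                     priors: PriorSpec | None = None) -> dict:
    """Bayesian-Wald test of effect modification by a binary group.

    Fits a non-spatial model with all main effects, the group main effect and
    group interactions for every listed covariate, then tests per covariate
    the joint null that its interaction coefficients vanish using the
    posterior mean and covariance (chi-square reference).  Returns a map
    covariate name -> p-value.
    """
    priors = priors or PriorSpec()
    groups = sorted(map(str, rows[group_term].unique()))
    if len(groups) != 2:
        raise ValueError(f"group term {group_term!r} must be binary, got {groups}")
    y = rows["y"].to_numpy(dtype=float)
    n = rows["n"].to_numpy(dtype=float)
    gvec = (rows[group_term].astype(str) == groups[1]).to_numpy(dtype=float)

    cols = [np.ones(len(rows)), gvec]
    names = ["intercept", f"{group_term}={groups[1]}"]
    blocks: dict = {}
    for term in covariates:
        if isinstance(term, NumericTerm):
            main = [pd.to_numeric(rows[term.name]).to_numpy(dtype=float)]
            lbls = [term.name]
        else:
            vals = rows[term.name].astype(str)
            present = {
                g: set(vals[rows[group_term].astype(str) == g])
                for g in groups
            }
            for lvl in term.levels:
                in_groups = [str(lvl) in present[g] for g in groups]
                if any(in_groups) and not all(in_groups):
                    raise ValueError(
                        f"level {lvl!r} of {term.name!r} is absent in one group"
                    )
            main = [
                (vals == str(lvl)).to_numpy(dtype=float)
                for lvl in term.coded_levels
            ]
            lbls = [f"{term.name}={lvl}" for lvl in term.coded_levels]
        if not main:
            raise ValueError(f"covariate {term.name!r} has a single level")
        idx = []
        for v, lbl in zip(main, lbls):
            cols.append(v)
            names.append(lbl)
        for v, lbl in zip(main, lbls):
            cols.append(v * gvec)
            names.append(f"{lbl}:x:{group_term}")
            idx.append(len(cols) - 1)
        blocks[term.name] = idx
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("interaction design is rank deficient")
    prec = _prior_precision(names, priors)
    mode, hess, _ = _newton_mode(y, n, x, prec)
    cov = np.linalg.inv(hess)
    out = {}
    for name, idx in blocks.items():
        m = mode[idx]
        v = cov[np.ix_(idx, idx)]
        stat = float(m @ np.linalg.solve(v, m))
        out[name] = float(chi2_dist.sf(stat, df=len(idx)))
    return out


def compute_dic(fit: FitResult, data=None) -> float:
    """Deviance information criterion: ``DIC = Dbar + pD`` with
    ``pD = Dbar - D(posterior mean)``."""
    ll = fit.loglik_pointwise
    if ll is None or ll.shape[0] < 2:
        raise ValueError("need at least 2 posterior draws with stored log-likelihoods")
    dbar = float(np.mean(-2.0 * ll.sum(axis=1)))
    psi_mean = fit.psi_draws().mean(axis=0)
    d_hat = float(
        -2.0 * _binom_loglik_pointwise(fit._y, fit._n, psi_mean).sum()
    )
    return dbar + (dbar - d_hat)


def compute_waic(fit: FitResult, data=None) -> float:
    """Watanabe-Akaike criterion: ``-2 (lppd - pWAIC)`` with pWAIC the summed
    posterior variances of the pointwise log-likelihood."""
    ll = fit.loglik_pointwise
    if ll is None or ll.shape[0] < 2:
        raise ValueError("need at least 2 posterior draws with stored log-likelihoods")
    d = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(d)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic)


def forward_select(candidate_terms: list, data, criterion: str = "waic",
                   priors: PriorSpec | None = None, tol: float = 2.0,
                   seed: int = 0):
    """Greedy forward selection on non-spatial fits.

    A term is accepted if it lowers the criterion by more than ``tol``
    (default 2.0); candidate order breaks ties.  Returns the chosen
    ``ModelSpec`` and the full criterion trace.
    """
    if not candidate_terms:
        raise ValueError("candidate_terms must be nonempty")
    crit_fn = {"waic": compute_waic, "dic": compute_dic}[criterion]

    def score(terms):
        spec = ModelSpec(covariates=list(terms))
        fit = fit_nonspatial(spec, data, priors=priors, method="laplace", seed=seed)
        return crit_fn(fit)

    chosen: list = []
    current = score(chosen)
    trace = [{"terms": [], "criterion": current}]
    remaining = list(candidate_terms)
    while remaining:
        scores = [(score(chosen + [t]), i, t) for i, t in enumerate(remaining)]
        best, idx, term = min(scores, key=lambda s: (s[0], s[1]))
        if current - best > tol:
            chosen.append(term)
            remaining.remove(term)
            current = best
            trace.append(
                {"terms": [t.name for t in chosen], "criterion": current}
            )
        else:
            break
    return ModelSpec(covariates=chosen), trace
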