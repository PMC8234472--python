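"""Replicate simulation studies: the package's evaluation harness.

Each function simulates from the generator, runs the estimators and returns
summary operating characteristics — engine-vs-oracle agreement, SPDE/Matérn
equivalence, credible-interval calibration and parameter recovery,
information-criterion selection behaviour, interaction-test error rates and
hold-out validation metrics.  They are used by the test suite and by
``scripts/acceptance.py``; sizes are chosen so the full battery runs on one
CPU in minutes (see docs/methods.md for the study designs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import model, synthetic as syn, validation
from .model import CategoricalTerm, McmcConfig, ModelSpec
from .spde import MaternParams, build_mesh, kappa_for_range, matern_correlation, projector, spde_precision

__all__ = [
    "engine_vs_grid_study",
    "spde_equivalence_study",
    "recovery_study",
    "model_selection_study",
    "interaction_operating_characteristics",
    "holdout_validation_study",
    "geomasking_distance_study",
]

DESK_TERMS = (
    CategoricalTerm("maternal_education", ("none", "primary", "secondary+")),
    CategoricalTerm("household_wealth", ("poor", "middle", "rich")),
    CategoricalTerm("aridity", ("Wet", "Semi-arid", "Arid")),
)


# ---------------------------------------------------------------------------
# 1. Pólya-Gamma Gibbs vs brute-force grid integration
# ---------------------------------------------------------------------------

def engine_vs_grid_study(seed: int = 0, n_draws: int = 12_000) -> dict:
    """Total-variation distance between the Gibbs posterior and a 2-D grid
    posterior on a 2-cluster, intercept + 1 covariate toy.

    The grid oracle integrates the exact unnormalized posterior on a fine
    lattice; TV is evaluated on the marginal of each coefficient over a
    shared coarse grid.
    """
    df = pd.DataFrame({"y": [12, 5], "n": [30, 25], "g": ["a", "b"]})
    spec = ModelSpec(covariates=[CategoricalTerm("g", ("a", "b"))])
    fit = model.fit_nonspatial(
        spec, df, method="gibbs", seed=seed,
        mcmc=McmcConfig(n_chains=2, n_draws=n_draws, n_warmup=1000),
    )
    y, n, x, _ = model.build_design(df, spec)
    prec = np.array([1e-6, 0.001])
    b0 = np.linspace(-3.0, 3.0, 241)
    b1 = np.linspace(-4.5, 4.5, 241)
    bb0, bb1 = np.meshgrid(b0, b1, indexing="ij")
    lp = np.zeros_like(bb0)
    for i in range(len(y)):
        psi = bb0 * x[i, 0] + bb1 * x[i, 1]
        lp += y[i] * psi - n[i] * np.logaddexp(0.0, psi)
    lp -= 0.5 * (prec[0] * bb0**2 + prec[1] * bb1**2)
    post = np.exp(lp - lp.max())
    post /= post.sum()

    tvs = {}
    for j, grid in enumerate((b0, b1)):
        marg = post.sum(axis=1 - j)
        step = grid[1] - grid[0]
        edges = np.concatenate(
            [[grid[0] - step / 2], (grid[:-1] + grid[1:]) / 2, [grid[-1] + step / 2]]
        )
        coarse = edges[::8]
        if coarse[-1] != edges[-1]:
            coarse = np.append(coarse, edges[-1])
        oracle = np.add.reduceat(marg, np.arange(0, len(marg), 8))
        hist, _ = np.histogram(fit.beta_draws[:, j], bins=coarse)
        hist = hist / hist.sum()
        tvs[f"tv_beta{j}"] = float(0.5 * np.abs(hist - oracle[: len(hist)]).sum())
    tvs["tv_max"] = max(tvs.values())
    return tvs


# ---------------------------------------------------------------------------
# 2. SPDE/GMRF vs closed-form Matérn
# ---------------------------------------------------------------------------

def spde_equivalence_study(seed: int = 0,
                           max_edges=(60.0, 30.0, 15.0)) -> dict:
    """Max absolute error between GMRF-implied and closed-form Matérn
    correlation at 25 interior test points, across mesh resolutions."""
    from shapely.geometry import box

    boundary = box(0, 0, 400, 400)
    params = MaternParams(kappa=np.sqrt(8.0) / 80.0, sigma2=1.0)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(120, 280, size=(25, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    target = matern_correlation(d, params.kappa)
    errors = []
    for max_edge in max_edges:
        mesh = build_mesh(
            pts, boundary, max_edge_km=max_edge, cutoff_km=1.0,
            extension_km=160.0,
        )
        q = spde_precision(mesh, params).q.toarray()
        a = projector(mesh, pts).toarray()
        cov = a @ np.linalg.solve(q, a.T)
        sd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sd, sd)
        errors.append(float(np.abs(corr - target).max()))
    return {
        "corr_errors_by_resolution": errors,
        "corr_err_fine": errors[-1],
        "monotone_decreasing": bool(
            all(a > b for a, b in zip(errors, errors[1:]))
        ),
    }


# ---------------------------------------------------------------------------
# 3. parameter recovery and CrI calibration
# ---------------------------------------------------------------------------

def _desk_config(seed: int) -> syn.SimulationConfig:
    return syn.SimulationConfig(
        n_clusters=150, seed=seed,
        matern=MaternParams(kappa=kappa_for_range(80.0), sigma2=0.5),
    )


def recovery_study(n_rep: int = 50, seed: int = 0) -> dict:
    """Replicate coverage of fixed-effect and range credible intervals.

    Each replicate simulates a 150-cluster survey (range 80 km, variance
    0.5, three categorical covariates), fits the geostatistical model in
    Laplace mode and records whether each 95% CrI covers its generating
    value.  Returns pooled beta coverage, per-coefficient coverage, range
    coverage and the share of replicates with the posterior-median range
    within a factor of two of the truth.
    """
    region = syn.make_study_region(6, 300.0, seed=1000)
    spec = ModelSpec(covariates=list(DESK_TERMS), spatial=True)
    beta_cov: list = []
    range_cov, range_fac2 = [], []
    for rep in range(n_rep):
        rep_seed = seed * 100_003 + rep
        cfg = _desk_config(rep_seed)
        records, truth = syn.simulate_survey(region, cfg)
        locs = np.array([[r.x, r.y] for r in records])
        mesh = build_mesh(
            locs, region.boundary, max_edge_km=45.0, cutoff_km=3.0,
            extension_km=90.0,
        )
        fit = model.fit_geostatistical(
            spec, records, mesh, method="laplace", seed=rep_seed
        )
        s = fit.beta_summary().set_index("term")
        beta_cov.append(
            {
                name: bool(s.loc[name, "lo95"] <= b <= s.loc[name, "hi95"])
                for name, b in truth.beta.items()
            }
        )
        lo, hi = np.percentile(fit.hyper_draws["range_km"], [2.5, 97.5])
        med = float(np.median(fit.hyper_draws["range_km"]))
        range_cov.append(bool(lo <= 80.0 <= hi))
        range_fac2.append(bool(40.0 <= med <= 160.0))
    cov_df = pd.DataFrame(beta_cov)
    return {
        "beta_coverage": float(cov_df.values.mean()),
        "beta_coverage_by_term": cov_df.mean().to_dict(),
        "range_coverage": float(np.mean(range_cov)),
        "range_within_factor2": float(np.mean(range_fac2)),
        "n_rep": n_rep,
    }


# ---------------------------------------------------------------------------
# 4. WAIC/DIC model selection
# ---------------------------------------------------------------------------

def model_selection_study(n_rep: int = 50, n_rep_spatial: int = 20,
                          seed: int = 0) -> dict:
    """Information-criterion selection behaviour.

    (a) true model vs the same model plus a pure-noise covariate, WAIC and
    DIC, non-spatial fits; (b) spatial vs non-spatial model on strong-field
    simulations (range 80 km, variance 0.5).
    """
    rng = np.random.default_rng(seed)
    waic_true, dic_true = 0, 0
    for rep in range(n_rep):
        rows = []
        for _ in range(100):
            t = rng.choice(["lo", "hi"])
            noise = rng.choice(["u", "v"])
            p = 1.0 / (1.0 + np.exp(-(-0.5 + (0.7 if t == "hi" else 0.0))))
            rows.append(
                {"y": rng.binomial(30, p), "n": 30, "t": t, "noise": noise}
            )
        df = pd.DataFrame(rows)
        spec_true = ModelSpec(covariates=[CategoricalTerm("t", ("lo", "hi"))])
        spec_noise = ModelSpec(
            covariates=[
                CategoricalTerm("t", ("lo", "hi")),
                CategoricalTerm("noise", ("u", "v")),
            ]
        )
        fit_t = model.fit_nonspatial(
            spec_true, df, method="laplace", seed=rep, n_draws_laplace=800
        )
        fit_n = model.fit_nonspatial(
            spec_noise, df, method="laplace", seed=rep, n_draws_laplace=800
        )
        if model.compute_waic(fit_t) < model.compute_waic(fit_n):
            waic_true += 1
        if model.compute_dic(fit_t) < model.compute_dic(fit_n):
            dic_true += 1

    region = syn.make_study_region(6, 300.0, seed=1000)
    spatial_better = 0
    for rep in range(n_rep_spatial):
        rep_seed = seed * 55_001 + rep
        cfg = syn.SimulationConfig(
            n_clusters=120, seed=rep_seed, covariates=(),
            matern=MaternParams(kappa=kappa_for_range(80.0), sigma2=0.5),
        )
        records, _ = syn.simulate_survey(region, cfg)
        locs = np.array([[r.x, r.y] for r in records])
        mesh = build_mesh(
            locs, region.boundary, max_edge_km=50.0, cutoff_km=3.0,
            extension_km=90.0,
        )
        fit_sp = model.fit_geostatistical(
            ModelSpec(spatial=True), records, mesh, method="laplace",
            seed=rep_seed,
        )
        fit_ns = model.fit_nonspatial(
            ModelSpec(), records, method="laplace", seed=rep_seed
        )
        if model.compute_waic(fit_sp) <= model.compute_waic(fit_ns):
            spatial_better += 1
    return {
        "waic_prefers_true_rate": waic_true / n_rep,
        "dic_prefers_true_rate": dic_true / n_rep,
        "waic_prefers_spatial_rate": spatial_better / n_rep_spatial,
        "n_rep": n_rep,
        "n_rep_spatial": n_rep_spatial,
    }


# ---------------------------------------------------------------------------
# 5. interaction-test operating characteristics
# ---------------------------------------------------------------------------

def _interaction_rows(rng, beta_young: float, beta_old: float,
                      n_per_group: int = 5000) -> pd.DataFrame:
    rows = []
    for g, b in (("0-23", beta_young), ("24-59", beta_old)):
        n_exposed = rng.binomial(n_per_group, 0.5)
        for lvl, eff, n_lvl in (
            ("a", 0.0, n_per_group - n_exposed), ("b", b, n_exposed)
        ):
            p = 1.0 / (1.0 + np.exp(-(-0.6 + eff)))
            rows.append(
                {"y": int(rng.binomial(n_lvl, p)), "n": n_lvl,
                 "age_group": g, "f": lvl}
            )
    return pd.DataFrame(rows)


def interaction_operating_characteristics(n_rep_null: int = 200,
                                          n_rep_power: int = 50,
                                          seed: int = 0) -> dict:
    """Type-I error under equal group effects and power for OR 1.2 vs 1.7
    at 5,000 children per age group."""
    rng = np.random.default_rng(seed)
    term = [CategoricalTerm("f", ("a", "b"))]
    rej_null = 0
    for _ in range(n_rep_null):
        df = _interaction_rows(rng, np.log(1.4), np.log(1.4))
        if model.interaction_test(df, term, "age_group")["f"] <= 0.05:
            rej_null += 1
    rej_alt = 0
    for _ in range(n_rep_power):
        df = _interaction_rows(rng, np.log(1.2), np.log(1.7))
        if model.interaction_test(df, term, "age_group")["f"] <= 0.05:
            rej_alt += 1
    return {
        "type1_rate": rej_null / n_rep_null,
        "power": rej_alt / n_rep_power,
        "n_rep_null": n_rep_null,
        "n_rep_power": n_rep_power,
    }


# ---------------------------------------------------------------------------
# 6. hold-out validation on a well-specified simulation
# ---------------------------------------------------------------------------

def holdout_validation_study(seed: int = 0) -> dict:
    """75/25 validation metrics on a 300-cluster, ~30-children simulation,
    plus the analytic Moran's I reference values."""
    region = syn.make_study_region(6, 300.0, seed=1000)
    cfg = syn.SimulationConfig(
        n_clusters=300, seed=seed + 1, covariates=(),
        children_per_household_rate=30 / 28,
        matern=MaternParams(kappa=kappa_for_range(80.0), sigma2=0.5),
    )
    records, _ = syn.simulate_survey(region, cfg)
    locs = np.array([[r.x, r.y] for r in records])
    mesh = build_mesh(
        locs, region.boundary, max_edge_km=45.0, cutoff_km=3.0,
        extension_km=90.0,
    )
    train, test = validation.split_train_test(records, 0.75, seed=seed)
    report = validation.validate_fit(
        train, test, ModelSpec(spatial=True), mesh, seed=seed
    )
    # Moran's I on the full survey's observed cluster proportions
    props = np.array(
        [r.n_stunted / r.n_children for r in records if r.n_children > 0]
    )
    mlocs = np.array(
        [[r.x, r.y] for r in records if r.n_children > 0]
    )
    moran = validation.morans_i(props, mlocs, n_perm=999, seed=seed)
    checker_w = np.array(
        [[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]], dtype=float
    )
    checker = validation.morans_i(
        [1, 0, 0, 1], weights=checker_w, n_perm=99, seed=seed
    )
    return {
        "rmse": report.rmse,
        "coverage95": report.coverage95,
        "pearson_r": report.pearson_r,
        "n_test": report.n_test,
        "moran_i": moran.i,
        "moran_p": moran.p_perm,
        "moran_checkerboard_i": checker.i,
    }


# ---------------------------------------------------------------------------
# 7. deterministic plumbing: geo-masking displacement bounds
# ---------------------------------------------------------------------------

def geomasking_distance_study(n_displacements: int = 10_000,
                              seed: int = 0) -> dict:
    """Max displacement distances over many simulated geo-maskings."""
    region = syn.make_study_region(4, 300.0, seed=7)
    per_round = 500
    max_urban, max_rural = 0.0, 0.0
    done = 0
    rnd = 0
    while done < n_displacements:
        cfg = syn.SimulationConfig(
            n_clusters=per_round, urban_fraction=0.5, seed=seed + rnd
        )
        records, _ = syn.sample_clusters(region, cfg)
        displaced = syn.apply_geomasking(
            records, cfg, region, seed=seed + 9000 + rnd
        )
        for orig, disp in zip(records, displaced):
            d = float(np.hypot(disp.x - orig.x, disp.y - orig.y))
            if orig.urban:
                max_urban = max(max_urban, d)
            else:
                max_rural = max(max_rural, d)
        done += per_round
        rnd += 1
    return {
        "max_urban_displacement_km": max_urban,
        "max_rural_displacement_km": max_rural,
        "n_displacements": done,
    }
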