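"""Design-based survey estimation: weighted prevalence with stratified
cluster sampling, Taylor-linearized variance, and the stunting classifier.

The estimator is the standard ratio estimator ``sum(w*y)/sum(w)``; its
variance follows the with-replacement first-stage approximation used by
survey packages: linearize the ratio, total the linearized scores within
clusters, and accumulate between-cluster variance within strata with the
``n_h/(n_h - 1)`` finite-sample factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SurveyDesign",
    "PrevalenceEstimate",
    "classify_stunting",
    "weighted_prevalence",
    "prevalence_by_factor",
]

HAZ_CUTOFF = -2.0


def classify_stunting(haz: float) -> int:
    """1 iff height-for-age z-score is strictly below -2.0 SD."""
    haz = float(haz)
    if not np.isfinite(haz):
        raise ValueError(f"HAZ must be finite, got {haz}")
    return int(haz < HAZ_CUTOFF)


@dataclass
class SurveyDesign:
    """Per-observation design metadata: stratum, sampling cluster, weight."""

    strata: np.ndarray
    clusters: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata)
        self.clusters = np.asarray(self.clusters)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.weights)
        if len(self.strata) != n or len(self.clusters) != n:
            raise ValueError("strata, clusters and weights must align")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be > 0")
        # a cluster must not straddle strata
        df = pd.DataFrame({"s": self.strata, "c": self.clusters})
        if (df.groupby("c")["s"].nunique() > 1).any():
            raise ValueError("a sampling cluster appears in multiple strata")


@dataclass
class PrevalenceEstimate:
    estimate: float
    se: float
    ci95: tuple
    n: int
    strata_used: int


def weighted_prevalence(y, design: SurveyDesign,
                        single_cluster: str = "error") -> PrevalenceEstimate:
    """Design-based prevalence with stratified between-cluster variance.

    ``single_cluster`` controls strata containing one cluster: ``'error'``
    (default) or ``'center'`` (centre the lone cluster at the overall mean,
    contributing its squared deviation).
    """
    y = np.asarray(y, dtype=float)
    w = design.weights
    if len(y) != len(w):
        raise ValueError("y and design lengths differ")
    wsum = w.sum()
    est = float((w * y).sum() / wsum)

    # linearized score per observation, totalled within clusters
    z = w * (y - est) / wsum
    df = pd.DataFrame({"s": design.strata, "c": design.clusters, "z": z})
    cl = df.groupby(["s", "c"], sort=False)["z"].sum().reset_index()
    var = 0.0
    strata_used = 0
    grand_mean_used = cl["z"].mean()
    for _, grp in cl.groupby("s", sort=False):
        n_h = len(grp)
        strata_used += 1
        if n_h == 1:
            if single_cluster == "center":
                var += float((grp["z"].iloc[0] - grand_mean_used) ** 2)
                continue
            raise ValueError(
                f"stratum {grp['s'].iloc[0]!r} has a single cluster; set "
                "single_cluster='center' to centre it at the grand mean"
            )
        zh = grp["z"].to_numpy()
        var += n_h / (n_h - 1) * float(((zh - zh.mean()) ** 2).sum())
    se = float(np.sqrt(var))
    zcrit = norm.ppf(0.975)
    lo = max(0.0, est - zcrit * se)
    hi = min(1.0, est + zcrit * se)
    return PrevalenceEstimate(
        estimate=est, se=se, ci95=(lo, hi), n=len(y), strata_used=strata_used
    )


def prevalence_by_factor(children: pd.DataFrame, factor: str,
                         age_group: str | None = None,
                         single_cluster: str = "error") -> pd.DataFrame:
    """Weighted stunting prevalence per level of a study factor.

    ``children`` is a child-level table with columns ``stunted``, ``weight``,
    ``stratum``, ``cluster_id``, ``age_group`` and the factor.  Levels with
    zero observations are flagged (``n = 0``, NaN estimate), not dropped.
    Returns a tidy table (factor, level, age_group, estimate, se, lo95, hi95, n).
    """
    if factor not in children.columns:
        raise KeyError(f"unknown factor: {factor!r}")
    df = children
    if age_group is not None:
        df = df[df["age_group"] == age_group]
    if isinstance(children[factor].dtype, pd.CategoricalDtype):
        levels = list(children[factor].cat.categories)
    else:
        levels = list(pd.unique(children[factor]))
    rows = []
    for level in levels:
        sub = df[df[factor] == level]
        if len(sub) == 0:
            rows.append(
                {
                    "factor": factor, "level": level,
                    "age_group": age_group or "all",
                    "estimate": np.nan, "se": np.nan,
                    "lo95": np.nan, "hi95": np.nan, "n": 0,
                }
            )
            continue
        design = SurveyDesign(
            strata=sub["stratum"].to_numpy(),
            clusters=sub["cluster_id"].to_numpy(),
            weights=sub["weight"].to_numpy(),
        )
        estimate = weighted_prevalence(
            sub["stunted"].to_numpy(), design, single_cluster=single_cluster
        )
        rows.append(
            {
                "factor": factor, "level": level,
                "age_group": age_group or "all",
                "estimate": estimate.estimate, "se": estimate.se,
                "lo95": estimate.ci95[0], "hi95": estimate.ci95[1],
                "n": estimate.n,
            }
        )
    return pd.DataFrame(rows)
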