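"""Intra- and inter-individual coefficients of variation and CV-equality tests.

CV = sample SD / mean (n-1 denominator) of a positive-valued trait.
``cv_intra`` quantifies developmental variability: the CV of leaf size
among the leaves of a single plant.  ``cv_inter`` quantifies (the inverse
of) canalization: the CV of a trait among the individuals of one
species x treatment cell.

CVs are computed on raw trait values by default.  Although downstream
mean comparisons log-transform traits first, the CV of log data is not a
coefficient of variation of the trait, so the literal-log reading is
behind ``log_scale=True`` only.

Equality of CVs across groups is tested with the Feltz & Miller (1996)
asymptotic chi-square test (default) or a signed likelihood-ratio test
with a parametric-bootstrap Bartlett-type mean correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["CVEqualityTest", "cv", "cv_intra", "cv_inter", "cv_equality_test"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVEqualityTest:
    statistic: float
    p: float
    method: str
    k_groups: int
    cvs: tuple[float, ...]
    df: int


def cv(values: Sequence[float] | np.ndarray) -> float:
    """Coefficient of variation: sample SD (n-1) divided by the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"cv needs n >= 2 values, got {x.size}")
    mean = x.mean()
    if mean == 0:
        raise ValueError("cv undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def cv_intra(
    summary: pd.DataFrame, min_leaves: int = 2, log_scale: bool = False
) -> pd.DataFrame:
    """Per-individual CV of leaf size across that plant's leaves.

    ``summary`` is a per-leaf summary frame with ``individual_id`` and
    ``ls`` columns.  Individuals with fewer than ``min_leaves`` leaves are
    excluded (count logged).  Returns individual_id, cv_intra_ls, n_leaves.
    """
    sizes = summary.copy()
    if log_scale:
        sizes["ls"] = np.log(sizes["ls"])
    grouped = sizes.groupby("individual_id", observed=True)["ls"]
    n = grouped.size()
    excluded = int((n < min_leaves).sum())
    if excluded:
        logger.warning("cv_intra: excluded %d individuals with < %d leaves",
                       excluded, min_leaves)
    out = pd.DataFrame(
        {
            "cv_intra_ls": grouped.apply(lambda v: cv(v) if len(v) >= min_leaves
                                         else np.nan),
            "n_leaves": n,
        }
    ).reset_index()
    return out[out["n_leaves"] >= min_leaves].reset_index(drop=True)


def cv_inter(
    individuals: pd.DataFrame,
    trait: str,
    group_cols: Sequence[str] = ("species", "early_treatment", "late_treatment"),
    min_n: int = 2,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Per-cell CV of a trait among individuals.

    Cells with fewer than ``min_n`` individuals are skipped with a
    warning.  Returns the group columns plus ``cv_inter`` and ``n``.
    """
    if trait not in individuals.columns:
        raise ValueError(f"trait column {trait!r} not in individual table")
    vals = individuals[[*group_cols, trait]].copy()
    if log_scale:
        vals[trait] = np.log(vals[trait])
    grouped = vals.groupby(list(group_cols), observed=True)[trait]
    out = grouped.agg(n="size").reset_index()
    out["cv_inter"] = grouped.apply(
        lambda v: cv(v) if len(v) >= min_n else np.nan
    ).to_numpy()
    skipped = int((out["n"] < min_n).sum())
    if skipped:
        logger.warning("cv_inter(%s): skipped %d cells with n < %d",
                       trait, skipped, min_n)
    out["trait"] = trait
    return out[out["n"] >= min_n].reset_index(drop=True)


def _feltz_miller(groups: list[np.ndarray]) -> tuple[float, int]:
    cvs = np.array([cv(g) for g in groups])
    taus = np.array([g.size - 1 for g in groups], dtype=float)
    c_pooled = float((taus * cvs).sum() / taus.sum())
    if c_pooled == 0:
        return 0.0, len(groups) - 1
    d_ad = float(
        (taus * (cvs - c_pooled) ** 2).sum() / (c_pooled**2 * (0.5 + c_pooled**2))
    )
    return d_ad, len(groups) - 1


def _normal_loglik(x: np.ndarray, mu: float, sigma: float) -> float:
    if sigma <= 0:
        return -math.inf
    return float(np.sum(stats.norm.logpdf(x, mu, sigma)))


def _profile_loglik_common_cv(groups: list[np.ndarray], c: float) -> float:
    """Max over group means of the normal log-likelihood with sigma_i = c mu_i.

    For fixed common CV c, the score equation for each group mean has the
    closed-form root mu = (-sum(x) + sqrt(sum(x)^2 + 4 n c^2 sum(x^2)))
    / (2 n c^2).
    """
    if c <= 0:
        return -math.inf
    total = 0.0
    for x in groups:
        n, sx, sxx = x.size, x.sum(), float(x @ x)
        mu = (-sx + math.sqrt(sx**2 + 4 * n * c**2 * sxx)) / (2 * n * c**2)
        total += _normal_loglik(x, mu, c * mu)
    return total


def _lrt_statistic(groups: list[np.ndarray]) -> float:
    """2 (l_unrestricted - l_common_cv) under the normal model."""
    l1 = sum(_normal_loglik(x, x.mean(), x.std(ddof=0)) for x in groups)
    cvs = [cv(g) for g in groups]
    c0 = max(float(np.mean(cvs)), 1e-8)

    res = optimize.minimize_scalar(
        lambda log_c: -_profile_loglik_common_cv(groups, math.exp(log_c)),
        bounds=(math.log(c0) - 4.0, math.log(c0) + 4.0),
        method="bounded",
    )
    l0 = -res.fun
    return max(0.0, 2.0 * (l1 - l0))


def cv_equality_test(
    groups: Sequence[Sequence[float] | np.ndarray],
    method: str = "asymptotic",
    n_boot: int = 400,
    seed: int | None = None,
) -> CVEqualityTest:
    """Test equality of coefficients of variation across k groups.

    ``method="asymptotic"`` uses the Feltz-Miller D'AD statistic on a
    chi-square(k-1) reference.  ``method="modified_slrt"`` computes the
    normal-model likelihood-ratio statistic (profiling out group means
    under a common CV) and rescales it by its parametric-bootstrap null
    mean before the chi-square comparison, a Bartlett-type correction.
    All observations must be positive.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("cv_equality_test needs >= 2 groups")
    for i, x in enumerate(arrays):
        if x.size < 2:
            raise ValueError(f"group {i} has n < 2")
        if (x <= 0).any():
            raise ValueError(
                f"group {i} contains non-positive values; CV comparison assumes "
                "positive-valued traits"
            )
    cvs = tuple(cv(x) for x in arrays)
    k = len(arrays)

    if method == "asymptotic":
        statistic, df = _feltz_miller(arrays)
        p = float(stats.chi2.sf(statistic, df))
    elif method == "modified_slrt":
        statistic = _lrt_statistic(arrays)
        df = k - 1
        rng = np.random.default_rng(seed)
        taus = np.array([x.size - 1 for x in arrays], dtype=float)
        c_pooled = float((taus * np.array(cvs)).sum() / taus.sum())
        boot = np.empty(n_boot)
        for b in range(n_boot):
            sim = [
                rng.normal(x.mean(), c_pooled * x.mean(), x.size) for x in arrays
            ]
            boot[b] = _lrt_statistic(sim)
        correction = df / max(boot.mean(), 1e-12)
        statistic = statistic * correction
        p = float(stats.chi2.sf(statistic, df))
    else:
        raise ValueError(f"unknown method {method!r}")

    return CVEqualityTest(
        statistic=float(statistic), p=p, method=method, k_groups=k, cvs=cvs, df=k - 1
    )
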