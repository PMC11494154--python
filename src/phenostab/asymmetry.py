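"""Leaf fluctuating-asymmetry indices and their diagnostic battery.

Given replicate width readings of the right and left half of each leaf,
this module computes per-leaf summaries (side means, signed and absolute
difference, leaf size), the classical FA indices

* ``FA1``  — mean absolute side difference, mean |R - L| (mm);
* ``FA2``  — size-standardized mean |R - L| / LS (dimensionless);
* ``FA10`` — 0.798 x the between-sides SD estimated from a side-by-unit
  factorial ANOVA with the replicate measurement-error variance
  partitioned out,

and the diagnostics that justify interpreting |R - L| as fluctuating
asymmetry: skew and excess kurtosis of the signed difference (a
significantly negative kurtosis suggests antisymmetry), a one-sample
t-test of R - L against zero and the MS_side / MS_interaction F-ratio
(directional asymmetry), the MS_interaction / MS_error F-ratio
(between-sides signal vs measurement error), and the regression of
|R - L| on leaf size (size dependence).

The constant 0.798 = sqrt(2/pi) is E|X|/sd(X) for a centred normal, so
FA1 and FA10 estimate the same quantity when measurement error is
negligible; FA10 remains unbiased when it is not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HALF_NORMAL_CONSTANT",
    "LeafSummary",
    "SidesAnovaTable",
    "FAResult",
    "AsymmetryDiagnostics",
    "summarize_leaves",
    "fa1",
    "fa2",
    "sides_anova",
    "fa10",
    "fa10_per_individual",
    "asymmetry_diagnostics",
    "size_dependence",
]

logger = logging.getLogger(__name__)

#: E|X| / sd(X) for X ~ Normal(0, s^2); the proportionality constant that
#: converts a between-sides standard deviation into a mean |R - L|.
HALF_NORMAL_CONSTANT = math.sqrt(2.0 / math.pi)  # 0.79788...

#: columns of the per-leaf summary frame
LeafSummary = ["individual_id", "leaf_index", "r_bar", "l_bar",
               "signed_diff", "abs_diff", "ls"]


@dataclass(frozen=True)
class SidesAnovaTable:
    """Mean squares from the side x unit factorial ANOVA on raw readings.

    Units are leaves (or individuals, for pooled analyses); M is the
    number of replicate readings per side.  ``f_da`` tests the side main
    effect against the side-by-unit interaction (directional asymmetry);
    ``f_me`` tests the interaction against replicate measurement error.
    """

    ms_side: float
    ms_interaction: float
    ms_error: float
    df_side: int
    df_interaction: int
    df_error: int
    m: int
    n_units: int
    f_da: float
    p_da: float
    f_me: float
    p_me: float


@dataclass(frozen=True)
class FAResult:
    """FA index values for one analysis group."""

    fa1: float
    fa2: float
    fa10: float
    n_leaves: int
    negative_s2_flag: bool


@dataclass(frozen=True)
class AsymmetryDiagnostics:
    gamma1: float
    p_gamma1: float
    gamma2: float
    p_gamma2: float
    t_da: float
    p_da: float
    slope_sizedep: float
    p_sizedep: float
    n: int
    classification: str  # ok | antisymmetry_suspected | directional_asymmetry_suspected
    tests_available: bool


def summarize_leaves(leaves: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate readings to one summary row per leaf.

    ``r_bar`` and ``l_bar`` are the means of the M replicate readings per
    side; ``signed_diff = r_bar - l_bar``; ``ls = (r_bar + l_bar)/2``.
    Leaves missing a side or with unequal replicate counts between sides
    are excluded; the exclusion count is logged and recorded in
    ``result.attrs["n_excluded"]``.
    """
    required = {"individual_id", "leaf_index", "side", "width"}
    missing = required - set(leaves.columns)
    if missing:
        raise ValueError(f"leaf table missing columns: {sorted(missing)}")

    per_side = (
        leaves.groupby(["individual_id", "leaf_index", "side"], observed=True)["width"]
        .agg(["mean", "size"])
        .unstack("side")
    )
    have_both = per_side["mean"].notna().sum(axis=1) == 2
    if {"left", "right"} - set(per_side["mean"].columns):
        have_both[:] = False
    balanced = have_both & (per_side["size"].nunique(axis=1) == 1)
    n_excluded = int((~balanced).sum())
    if n_excluded:
        logger.warning("excluded %d incomplete leaves from summary", n_excluded)
    per_side = per_side[balanced]

    out = pd.DataFrame(
        {
            "r_bar": per_side[("mean", "right")],
            "l_bar": per_side[("mean", "left")],
        }
    ).reset_index()
    out["signed_diff"] = out["r_bar"] - out["l_bar"]
    out["abs_diff"] = out["signed_diff"].abs()
    out["ls"] = (out["r_bar"] + out["l_bar"]) / 2
    out.attrs["n_excluded"] = n_excluded
    return out


def _check_nonempty(summary: pd.DataFrame) -> None:
    if len(summary) == 0:
        raise ValueError("no leaves to summarize (empty input)")


def fa1(summary: pd.DataFrame) -> float:
    """Mean absolute side difference, sum |R - L| / n (mm)."""
    _check_nonempty(summary)
    return float(summary["abs_diff"].mean())


def fa2(summary: pd.DataFrame, signed: bool = False) -> float:
    """Size-standardized asymmetry, mean of |R - L| / LS (dimensionless).

    With ``signed=True`` the signed difference enters the ratio instead,
    so directional asymmetry of opposite signs can cancel.
    """
    _check_nonempty(summary)
    if (summary["ls"] <= 0).any():
        raise ValueError("fa2 requires all leaf sizes > 0")
    num = summary["signed_diff"] if signed else summary["abs_diff"]
    return float((num / summary["ls"]).mean())


def sides_anova(leaves: pd.DataFrame) -> SidesAnovaTable:
    """Side x unit factorial ANOVA on untransformed replicate readings.

    Each (individual, leaf) pair is one unit; the design must be balanced
    (2 sides x M replicates per unit, M >= 2).  Mean squares are computed
    from the balanced-design decomposition
    SS_total = SS_side + SS_unit + SS_interaction + SS_error.
    """
    key = leaves["individual_id"].astype(str) + "#" + leaves["leaf_index"].astype(str)
    wide = leaves.assign(_unit=key).pivot_table(
        index="_unit", columns=["side", "replicate"], values="width", observed=True
    )
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)][:3].tolist()
        raise ValueError(f"unbalanced cells in sides ANOVA, e.g. units {bad}")
    sides = wide.columns.get_level_values("side")
    m_counts = {s: (sides == s).sum() for s in ("left", "right")}
    if set(m_counts) != {"left", "right"} or m_counts["left"] != m_counts["right"]:
        raise ValueError(f"need both sides with equal replicates, got {m_counts}")
    m = m_counts["left"]
    if m < 2:
        raise ValueError("M = 1: measurement-error mean square is inestimable")
    n = len(wide)
    if n < 2:
        raise ValueError("sides ANOVA needs >= 2 units")

    # y[side, unit, rep]
    y = np.stack(
        [wide.xs(s, axis=1, level="side").to_numpy() for s in ("right", "left")]
    )
    cell = y.mean(axis=2)
    side_mean = cell.mean(axis=1)
    unit_mean = cell.mean(axis=0)
    grand = cell.mean()

    ss_side = n * m * float(((side_mean - grand) ** 2).sum())
    ss_inter = m * float(
        ((cell - side_mean[:, None] - unit_mean[None, :] + grand) ** 2).sum()
    )
    ss_err = float(((y - cell[:, :, None]) ** 2).sum())

    df_side, df_inter, df_err = 1, n - 1, 2 * n * (m - 1)
    ms_side = ss_side / df_side
    ms_inter = ss_inter / df_inter
    ms_err = ss_err / df_err

    if ms_inter > 0:
        f_da = ms_side / ms_inter
        p_da = float(stats.f.sf(f_da, df_side, df_inter))
    else:
        f_da = math.inf if ms_side > 0 else 0.0
        p_da = 0.0 if ms_side > 0 else 1.0
    if ms_err > 0:
        f_me = ms_inter / ms_err
        p_me = float(stats.f.sf(f_me, df_inter, df_err))
    else:
        f_me = math.inf if ms_inter > 0 else 0.0
        p_me = 0.0 if ms_inter > 0 else 1.0

    return SidesAnovaTable(
        ms_side=ms_side,
        ms_interaction=ms_inter,
        ms_error=ms_err,
        df_side=df_side,
        df_interaction=df_inter,
        df_error=df_err,
        m=m,
        n_units=n,
        f_da=f_da,
        p_da=p_da,
        f_me=f_me,
        p_me=p_me,
    )


def fa10(anova: SidesAnovaTable) -> tuple[float, bool]:
    """Variance-component FA index with measurement error removed.

    The side-by-unit interaction mean square satisfies
    E[MS_int] = sigma_me^2 + (M/2) Var(R - L), so the between-sides
    variance net of measurement error is s2 = 2 (MS_int - MS_err) / M and
    FA10 = 0.798 sqrt(s2), directly comparable to FA1.  A negative s2
    (interaction below measurement error, possible in small samples) is
    clamped to zero and flagged.
    """
    s2 = 2.0 * (anova.ms_interaction - anova.ms_error) / anova.m
    if s2 < 0:
        return 0.0, True
    return HALF_NORMAL_CONSTANT * math.sqrt(s2), False


def fa_indices(leaves: pd.DataFrame, summary: pd.DataFrame | None = None) -> FAResult:
    """FA1, FA2 and FA10 for one analysis group of leaves."""
    if summary is None:
        summary = summarize_leaves(leaves)
    anova = sides_anova(leaves)
    value, flag = fa10(anova)
    return FAResult(
        fa1=fa1(summary),
        fa2=fa2(summary),
        fa10=value,
        n_leaves=len(summary),
        negative_s2_flag=flag,
    )


def fa10_per_individual(leaves: pd.DataFrame, min_leaves: int = 2) -> pd.DataFrame:
    """FA10 computed per individual, with its leaves as ANOVA units.

    This makes a standard error of FA10 across individuals definable for
    group means; plants with fewer than ``min_leaves`` leaves are skipped.
    Returns individual_id, fa10, negative_s2_flag, n_leaves.
    """
    rows = []
    for ind_id, grp in leaves.groupby("individual_id", observed=True):
        n_leaves = grp[["leaf_index"]].drop_duplicates().shape[0]
        if n_leaves < min_leaves:
            continue
        value, flag = fa10(sides_anova(grp))
        rows.append(
            {
                "individual_id": ind_id,
                "fa10": value,
                "negative_s2_flag": flag,
                "n_leaves": n_leaves,
            }
        )
    return pd.DataFrame(rows, columns=["individual_id", "fa10",
                                       "negative_s2_flag", "n_leaves"])


def _gamma2_se(n: int) -> float:
    """Normal-theory SE of sample excess kurtosis (exact small-sample form)."""
    return math.sqrt(
        24.0 * n * (n - 1) ** 2 / ((n - 3) * (n - 2) * (n + 3) * (n + 5))
    )


def _gamma1_se(n: int) -> float:
    """Normal-theory SE of sample skewness."""
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def asymmetry_diagnostics(
    summary: pd.DataFrame, alpha: float = 0.05
) -> AsymmetryDiagnostics:
    """Distributional diagnostics of the signed difference R - L.

    Skew (gamma1) and excess kurtosis (gamma2) use bias-corrected sample
    estimators; each is tested against zero with its normal-theory
    standard error and a normal reference.  A significant negative gamma2
    flags possible antisymmetry; a significant one-sample t of R - L
    against zero flags directional asymmetry.  The size-dependence slope
    is reported when leaf sizes vary.  With n < 4 the moment tests are
    unavailable (moments still reported when defined).
    """
    _check_nonempty(summary)
    d = summary["signed_diff"].to_numpy(float)
    n = d.size
    available = n >= 4

    g1 = float(stats.skew(d, bias=False)) if n >= 3 else math.nan
    g2 = float(stats.kurtosis(d, fisher=True, bias=False)) if n >= 4 else math.nan
    if available and np.std(d) > 0:
        z1 = g1 / _gamma1_se(n)
        z2 = g2 / _gamma2_se(n)
        p_g1 = float(2 * stats.norm.sf(abs(z1)))
        p_g2 = float(2 * stats.norm.sf(abs(z2)))
        t_da, p_da = stats.ttest_1samp(d, 0.0)
        t_da, p_da = float(t_da), float(p_da)
    else:
        p_g1 = p_g2 = p_da = math.nan
        t_da = math.nan
        available = False

    ls = summary["ls"].to_numpy(float)
    if n >= 3 and np.ptp(ls) > 0:
        res = stats.linregress(ls, summary["abs_diff"].to_numpy(float))
        slope, p_slope = float(res.slope), float(res.pvalue)
    else:
        slope = p_slope = math.nan

    classification = "ok"
    if available:
        if g2 < 0 and p_g2 < alpha:
            classification = "antisymmetry_suspected"
        elif p_da < alpha:
            classification = "directional_asymmetry_suspected"

    return AsymmetryDiagnostics(
        gamma1=g1,
        p_gamma1=p_g1,
        gamma2=g2,
        p_gamma2=p_g2,
        t_da=t_da,
        p_da=p_da,
        slope_sizedep=slope,
        p_sizedep=p_slope,
        n=n,
        classification=classification,
        tests_available=available,
    )


def size_dependence(summary: pd.DataFrame) -> tuple[float, float, float]:
    """OLS regression of |R - L| on leaf size: (slope, intercept, p).

    The slope p-value is the two-sided t-test of zero slope.  Raises when
    fewer than 3 leaves or all leaf sizes are equal.
    """
    _check_nonempty(summary)
    if len(summary) < 3:
        raise ValueError("size dependence regression needs n >= 3 leaves")
    ls = summary["ls"].to_numpy(float)
    if np.ptp(ls) == 0:
        raise ValueError("all leaf sizes equal: size-dependence slope undefined")
    res = stats.linregress(ls, summary["abs_diff"].to_numpy(float))
    return float(res.slope), float(res.intercept), float(res.pvalue)
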