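"""General linear model machinery: ANCOVA effect tests, LSD multiple
comparisons, Pearson and partial Pearson correlations, and slope-difference
tests.

All trait analyses operate on log-transformed values (variance
stabilisation across species and treatments); correlations among derived
indices (FA, CV, PI) are computed across species-level points, optionally
partialling out initial size, which is how treatment-level couplings
between developmental stability, canalization and plasticity are
screened.  Significance tiers follow the three-star convention
* p < 0.10, ** p < 0.05, *** p < 0.01.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "CorrelationResult",
    "SlopeComparison",
    "log_transform",
    "ancova",
    "lsd_compare",
    "pearson_corr",
    "partial_corr",
    "slope_difference_test",
    "correlation_matrix",
    "correlation_tables",
    "significance_stars",
]

logger = logging.getLogger(__name__)

#: significance tiers (threshold, marker), most stringent first
STAR_TIERS = ((0.01, "***"), (0.05, "**"), (0.10, "*"))


def significance_stars(p: float) -> str:
    for threshold, marker in STAR_TIERS:
        if p < threshold:
            return marker
    return ""


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    coefficient: float
    p: float
    kind: str  # "PCC" | "PPCC"
    covariates: tuple[str, ...]
    n: int


@dataclass(frozen=True)
class SlopeComparison:
    response: str
    predictor: str
    slopes: dict[str, float]
    t_interaction: float
    p: float
    n: int


def log_transform(values: Sequence[float] | np.ndarray | pd.Series):
    """Natural-log transform of strictly positive values.

    Raises with the offending positions when any value is <= 0, keeping
    pandas indexes intact so the caller can locate bad rows.
    """
    if isinstance(values, pd.Series):
        bad = values.index[values <= 0].tolist()
        if bad:
            raise ValueError(f"log_transform: non-positive values at rows {bad[:10]}")
        return np.log(values)
    x = np.asarray(values, dtype=float)
    bad = np.flatnonzero(x <= 0)
    if bad.size:
        raise ValueError(
            f"log_transform: non-positive values at positions {bad[:10].tolist()}"
        )
    return np.log(x)


def _formula(response: str, factors: Sequence[str], covariate: str | None,
             order: int) -> str:
    terms: list[str] = []
    for k in range(1, order + 1):
        for combo in itertools.combinations(factors, k):
            terms.append(":".join(f"C({f}, Sum)" for f in combo))
    if covariate:
        terms.append(covariate)
    return f"{response} ~ " + " + ".join(terms)


def ancova(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    covariate: str | None = None,
    order: int | None = None,
) -> pd.DataFrame:
    """Fixed-effects ANCOVA with partial (Type III) term tests.

    Fits ``response ~ factors (+ interactions up to `order`) + covariate``
    with sum-to-zero factor coding and returns the effect table (term,
    sum_sq, df, ms, F, p).  When empty design cells make the full model
    rank deficient, the interaction order is reduced step by step, with a
    warning naming the dropped order.
    """
    factors = list(factors)
    if order is None:
        order = len(factors)
    data = table.dropna(subset=[response, *factors]
                        + ([covariate] if covariate else []))
    while order >= 1:
        formula = _formula(response, factors, covariate, order)
        model = smf.ols(formula, data=data)
        if np.linalg.matrix_rank(model.exog) == model.exog.shape[1]:
            break
        logger.warning(
            "rank-deficient design (empty cells?): dropping order-%d interactions",
            order,
        )
        order -= 1
    else:
        raise ValueError("no full-rank model found, even with main effects only")
    fit = model.fit()
    aov = anova_lm(fit, typ=3)
    aov = aov.rename(columns={"sum_sq": "sum_sq", "PR(>F)": "p"})
    aov["ms"] = aov["sum_sq"] / aov["df"]
    aov.index = [
        idx.replace("C(", "").replace(", Sum)", "") for idx in aov.index
    ]
    aov.index.name = "term"
    aov.attrs["ss_type"] = "III (partial, sum-to-zero coding)"
    aov.attrs["order"] = order
    return aov.reset_index()[["term", "sum_sq", "df", "ms", "F", "p"]]


def _pairwise_lsd_p(
    means: Mapping[str, float],
    residual_ms: float,
    df_resid: int,
    n_per_group: Mapping[str, int],
) -> pd.DataFrame:
    rows = []
    for a, b in itertools.combinations(sorted(means), 2):
        diff = means[a] - means[b]
        se = math.sqrt(residual_ms * (1 / n_per_group[a] + 1 / n_per_group[b]))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
            t = 0.0 if diff == 0 else math.inf
        else:
            t = diff / se
            p = float(2 * stats.t.sf(abs(t), df_resid))
        rows.append({"group_a": a, "group_b": b, "t": t, "p": p})
    return pd.DataFrame(rows)


def lsd_compare(
    means: Mapping[str, float],
    residual_ms: float,
    df_resid: int,
    n_per_group: Mapping[str, int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """LSD pairwise comparisons with a compact letter display.

    Unprotected pairwise t-tests on the pooled residual mean square;
    groups sharing a letter are not significantly different.  A pair is
    declared different only when p is strictly below alpha (p == alpha is
    not significant).  Returns group, mean, letters, sorted by descending
    mean; the pairwise p table is attached as ``result.attrs["pairwise"]``.
    """
    if len(means) < 2:
        raise ValueError("lsd_compare needs >= 2 groups")
    if df_resid < 1:
        raise ValueError("residual df must be >= 1")
    pairwise = _pairwise_lsd_p(means, residual_ms, df_resid, n_per_group)

    ordered = sorted(means, key=means.get, reverse=True)
    # insert-and-absorb compact letter display
    letters: list[set[str]] = [set(ordered)]
    for row in pairwise.itertuples():
        if row.p < alpha:
            for group in [g for g in letters if {row.group_a, row.group_b} <= g]:
                letters.remove(group)
                letters.extend([group - {row.group_a}, group - {row.group_b}])
            letters = [
                g
                for g in letters
                if g and not any(g < other for other in letters)
            ]
            # dedupe while keeping order
            seen: list[set[str]] = []
            for g in letters:
                if g not in seen:
                    seen.append(g)
            letters = seen
    letters.sort(key=lambda g: min(ordered.index(m) for m in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment = {g: "" for g in ordered}
    for i, group in enumerate(letters):
        for member in group:
            assignment[member] += alphabet[i % len(alphabet)]
    out = pd.DataFrame(
        {
            "group": ordered,
            "mean": [means[g] for g in ordered],
            "letters": ["".join(sorted(assignment[g])) for g in ordered],
        }
    )
    out.attrs["pairwise"] = pairwise
    out.attrs["alpha"] = alpha
    return out


def pearson_corr(x: Sequence[float], y: Sequence[float],
                 names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-based p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("pearson_corr needs two equal-length vectors, n >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("pearson_corr undefined for constant input")
    r, p = stats.pearsonr(xa, ya)
    return CorrelationResult(
        x=names[0], y=names[1], coefficient=float(r), p=float(p),
        kind="PCC", covariates=(), n=xa.size,
    )


def partial_corr(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | Sequence[Sequence[float]] | None,
    names: tuple[str, str] = ("x", "y"),
    covariate_names: tuple[str, ...] = (),
) -> CorrelationResult:
    """Partial Pearson correlation by the residual (regress-out) method.

    x and y are each regressed on the covariates (plus intercept); the
    Pearson correlation of the two residual vectors is returned with a
    t-based p on n - k - 2 degrees of freedom.  With no covariates this
    is exactly the plain Pearson correlation.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if covariates is None or (np.size(covariates) == 0):
        res = pearson_corr(xa, ya, names)
        return CorrelationResult(
            x=res.x, y=res.y, coefficient=res.coefficient, p=res.p,
            kind="PPCC", covariates=(), n=res.n,
        )
    z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if z.shape[0] == xa.size and z.shape[1] != xa.size:
        z = z.T  # accept (n, k) or (k, n)
    k = z.shape[0]
    n = xa.size
    if n < k + 3:
        raise ValueError(f"partial_corr needs n >= k + 3 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), z.T])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates in partial correlation")
    rx = xa - design @ np.linalg.lstsq(design, xa, rcond=None)[0]
    ry = ya - design @ np.linalg.lstsq(design, ya, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance: a covariate explains x or y exactly")
    r = float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))
    df = n - k - 2
    r_clamped = min(max(r, -1.0), 1.0)
    if abs(r_clamped) == 1.0:
        p = 0.0
    else:
        t = r_clamped * math.sqrt(df / (1 - r_clamped**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(
        x=names[0], y=names[1], coefficient=r, p=p,
        kind="PPCC", covariates=tuple(covariate_names) or tuple(
            f"z{i+1}" for i in range(k)
        ), n=n,
    )


def slope_difference_test(
    x: Sequence[float],
    y: Sequence[float],
    group: Sequence[str],
    names: tuple[str, str] = ("x", "y"),
) -> SlopeComparison:
    """Test whether two groups share a regression slope.

    Fits the pooled model y ~ x * group and reports the interaction
    t-test together with the per-group slopes.
    """
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "g": list(group)})
    levels = sorted(df["g"].unique())
    if len(levels) != 2:
        raise ValueError(f"slope_difference_test needs exactly 2 groups, got {levels}")
    for lev in levels:
        sub = df[df["g"] == lev]
        if len(sub) < 3:
            raise ValueError(f"group {lev!r} has n < 3")
        if np.ptp(sub["x"].to_numpy()) == 0:
            raise ValueError(f"group {lev!r} has constant x")
    fit = smf.ols("y ~ x * C(g)", data=df).fit()
    inter_term = [t for t in fit.params.index if t.startswith("x:")][0]
    slopes = {
        levels[0]: float(fit.params["x"]),
        levels[1]: float(fit.params["x"] + fit.params[inter_term]),
    }
    return SlopeComparison(
        response=names[1],
        predictor=names[0],
        slopes=slopes,
        t_interaction=float(fit.tvalues[inter_term]),
        p=float(fit.pvalues[inter_term]),
        n=len(df),
    )


def correlation_matrix(
    df: pd.DataFrame,
    variables: Sequence[str],
    covariates: Sequence[str] = (),
    min_n_warn: int = 5,
) -> pd.DataFrame:
    """All-pairs (partial) Pearson correlations among species-level points.

    Returns a long frame var_a, var_b, r, p, stars, n, kind.  Rows with a
    missing value in either variable or any covariate are dropped
    pairwise.  If fewer than ``min_n_warn`` points remain, the row is
    flagged ``low_power``.
    """
    rows = []
    for a, b in itertools.combinations(variables, 2):
        cols = [a, b, *covariates]
        sub = df[cols].dropna()
        n = len(sub)
        if n < 2:
            raise ValueError(f"correlation of {a}/{b} undefined with n={n}")
        try:
            if covariates:
                res = partial_corr(
                    sub[a], sub[b], sub[list(covariates)].to_numpy().T,
                    names=(a, b), covariate_names=tuple(covariates),
                )
            else:
                res = pearson_corr(sub[a], sub[b], names=(a, b))
        except ValueError as exc:
            logger.warning("correlation %s/%s failed: %s", a, b, exc)
            continue
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "r": res.coefficient,
                "p": res.p,
                "stars": significance_stars(res.p),
                "n": n,
                "kind": res.kind,
                "covariates": ",".join(res.covariates),
                "low_power": n < min_n_warn,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["var_a", "var_b", "r", "p", "stars", "n", "kind",
                 "covariates", "low_power"],
    )


FIRST_ROUND_VARS = ("ls", "fa10", "cv_intra_ls", "cv_inter_ls", "cv_inter_tm")


def correlation_tables(
    first_round: pd.DataFrame,
    second_round: pd.DataFrame | None = None,
    pi_summary: pd.DataFrame | None = None,
    covariate: str = "initial_size",
    second_covariate: str = "initial_size",
) -> dict[str, pd.DataFrame]:
    """Correlation screens among stability, canalization and plasticity.

    ``first_round``: one row per species x early treatment with columns
    ls, fa10, cv_intra_ls, cv_inter_ls, cv_inter_tm and the covariate
    (species-mean initial size or cv_inter_is).  Produces, per early
    treatment, the all-pairs partial-correlation matrix among the five
    first-round variables ("first_round" table).

    ``second_round`` (optional): one row per species x early x late
    treatment with cv_inter_tm plus the first-round variables merged in;
    produces partial correlations of second-round cv_inter_tm against
    each first-round variable, per early x late cell ("second_round"
    table, covariate selectable between initial size and the CV of
    initial size).

    ``pi_summary`` (optional): one row per species x early x contrast
    with pi columns and cv_inter_tm; produces PI-vs-CV correlations
    ("plasticity" table).
    """
    if first_round["species"].nunique() < 2:
        raise ValueError("correlations across species need >= 2 species")
    out: dict[str, pd.DataFrame] = {}

    frames = []
    for early, grp in first_round.groupby("early_treatment", observed=True):
        mat = correlation_matrix(grp, FIRST_ROUND_VARS, (covariate,))
        mat.insert(0, "early_treatment", early)
        frames.append(mat)
    out["first_round"] = pd.concat(frames, ignore_index=True)

    if second_round is not None:
        frames = []
        for (early, late), grp in second_round.groupby(
            ["early_treatment", "late_treatment"], observed=True
        ):
            preds = [v for v in FIRST_ROUND_VARS if v in grp.columns]
            mat = correlation_matrix(
                grp, ["cv_inter_tm_2nd", *preds], (second_covariate,)
            )
            mat = mat[mat["var_a"] == "cv_inter_tm_2nd"]
            mat.insert(0, "late_treatment", late)
            mat.insert(0, "early_treatment", early)
            frames.append(mat)
        out["second_round"] = pd.concat(frames, ignore_index=True)

    if pi_summary is not None:
        frames = []
        pi_vars = [c for c in pi_summary.columns if c.startswith("pi_")]
        for (early, contrast), grp in pi_summary.groupby(
            ["early_treatment", "contrast"], observed=True
        ):
            mat = correlation_matrix(grp, [*pi_vars, "cv_inter_tm"], (covariate,))
            mat = mat[mat["var_b"] == "cv_inter_tm"]
            mat.insert(0, "contrast", contrast)
            mat.insert(0, "early_treatment", early)
            frames.append(mat)
        out["plasticity"] = pd.concat(frames, ignore_index=True)
    return out
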