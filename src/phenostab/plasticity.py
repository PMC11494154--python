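"""ANCOVA-adjusted treatment means and phenotypic-plasticity indices.

Plasticity of a trait in response to a late water treatment is scored by
contrasting the adjusted mean in inundation (PI_IM) or drought (PI_DM)
against the moderate-water adjusted mean within the same species and
early-experience group.  Adjusted means come from a one-way ANCOVA
``trait ~ treatment + initial_size`` evaluated at the grand mean of the
covariate, removing initial-size differences among plants.

Two index variants are provided:

* ``ratio``  (default): PI_rel = (Y2 - Y1) / Y1, unbounded above;
* ``srdpi``: simplified relative distance, PI_rel = (Y2 - Y1)/(Y2 + Y1),
  bounded in (-1, 1) for positive traits.

PI_abs is the absolute value of PI_rel under either variant.  The ANCOVA
is fitted on log-transformed traits (variance stabilisation); adjusted
means are back-transformed (geometric means) before the index is formed,
so PI is on the trait scale where a multiplicative treatment effect of m
implies PI_rel = m - 1 under the ratio variant.  Set
``back_transform=False`` to form the index on the log scale instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["AdjustedMeans", "adjusted_means", "compute_pi", "plasticity_table"]

logger = logging.getLogger(__name__)

CONTRASTS = {"IM": "inundation", "DM": "drought"}
BASELINE_LATE = "moderate"


@dataclass(frozen=True)
class AdjustedMeans:
    """Per-level adjusted means from a one-way ANCOVA."""

    trait: str
    factor: str
    levels: tuple[str, ...]
    means: dict[str, float]
    covariate_coef: float
    covariate_mean: float
    residual_ms: float
    df_resid: int
    n_per_level: dict[str, int]
    covariate_used: bool


def adjusted_means(
    table: pd.DataFrame,
    trait: str,
    factor: str,
    covariate: str | None,
) -> AdjustedMeans:
    """Fit ``trait ~ factor + covariate`` and return level means at the
    covariate grand mean.

    Uses the cell-means parametrisation solved by least squares; with no
    covariate, or a covariate that does not vary, the adjusted means
    reduce to the raw level means (the degenerate-covariate case falls
    back with a warning rather than failing).
    """
    data = table.dropna(subset=[c for c in (trait, factor, covariate) if c])
    levels = tuple(sorted(data[factor].astype(str).unique()))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels, got {levels}")
    counts = data.groupby(factor, observed=True)[trait].size()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"levels with < 2 observations: {small}")

    y = data[trait].to_numpy(float)
    dummies = np.column_stack(
        [(data[factor].astype(str) == lev).to_numpy(float) for lev in levels]
    )
    use_cov = covariate is not None
    if use_cov:
        z = data[covariate].to_numpy(float)
        if np.ptp(z) == 0:
            logger.warning(
                "covariate %r constant: falling back to raw level means", covariate
            )
            use_cov = False
    if use_cov:
        x = np.column_stack([dummies, z])
    else:
        x = dummies
        z = np.zeros(len(y))

    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise ValueError("rank-deficient ANCOVA design")
    resid = y - x @ beta
    df_resid = len(y) - x.shape[1]
    residual_ms = float(resid @ resid / df_resid) if df_resid > 0 else float("nan")

    z_bar = float(z.mean()) if use_cov else 0.0
    slope = float(beta[-1]) if use_cov else 0.0
    means = {
        lev: float(beta[i] + slope * z_bar) for i, lev in enumerate(levels)
    }
    return AdjustedMeans(
        trait=trait,
        factor=factor,
        levels=levels,
        means=means,
        covariate_coef=slope,
        covariate_mean=z_bar,
        residual_ms=residual_ms,
        df_resid=df_resid,
        n_per_level={lev: int(counts[lev]) for lev in levels},
        covariate_used=use_cov,
    )


def compute_pi(y1: float, y2: float, variant: str = "ratio") -> tuple[float, float]:
    """Plasticity index from baseline (y1) and alternative (y2) means.

    ``ratio``: (y2 - y1)/y1; ``srdpi``: (y2 - y1)/(y2 + y1).  Returns
    (pi_rel, pi_abs).
    """
    if variant == "ratio":
        if y1 == 0:
            raise ValueError("ratio variant undefined: baseline mean Y1 = 0")
        pi_rel = (y2 - y1) / y1
    elif variant == "srdpi":
        if y1 + y2 == 0:
            raise ValueError("srdpi variant undefined: Y1 + Y2 = 0")
        pi_rel = (y2 - y1) / (y2 + y1)
    else:
        raise ValueError(f"unknown PI variant {variant!r}")
    return float(pi_rel), float(abs(pi_rel))


def plasticity_table(
    individuals: pd.DataFrame,
    traits: Sequence[str] = ("total_mass", "shoot_mass", "root_mass", "rs_ratio"),
    variant: str = "ratio",
    covariate: str | None = "initial_size",
    log_fit: bool = True,
    back_transform: bool = True,
    late_col: str = "late_treatment",
) -> pd.DataFrame:
    """PI_IM and PI_DM per species x early treatment x trait.

    For every species x early-treatment group with second-round data, an
    ANCOVA of each (log-)trait on the late-treatment factor with initial
    size as covariate yields adjusted means; the inundation-vs-moderate
    and drought-vs-moderate contrasts are converted to plasticity
    indices.  Groups missing a needed late-treatment level are skipped
    with a warning.
    """
    second = individuals[
        individuals[late_col].isin([BASELINE_LATE, *CONTRASTS.values()])
    ]
    rows = []
    for (sp, early), grp in second.groupby(
        ["species", "early_treatment"], observed=True
    ):
        for trait in traits:
            data = grp[[late_col, trait] + ([covariate] if covariate else [])].copy()
            if log_fit:
                if (data[trait] <= 0).any():
                    raise ValueError(
                        f"log fit impossible: non-positive {trait} in "
                        f"{sp}/{early}"
                    )
                data[trait] = np.log(data[trait])
            present = set(data[late_col].unique())
            if BASELINE_LATE not in present:
                logger.warning("skipping %s/%s/%s: no %s cell",
                               sp, early, trait, BASELINE_LATE)
                continue
            try:
                adj = adjusted_means(data, trait, late_col, covariate)
            except ValueError as exc:
                logger.warning("skipping %s/%s/%s: %s", sp, early, trait, exc)
                continue
            means = dict(adj.means)
            if log_fit and back_transform:
                means = {k: float(np.exp(v)) for k, v in means.items()}
            y1 = means[BASELINE_LATE]
            for contrast, late in CONTRASTS.items():
                if late not in means:
                    logger.warning("skipping contrast %s for %s/%s/%s",
                                   contrast, sp, early, trait)
                    continue
                pi_rel, pi_abs = compute_pi(y1, means[late], variant)
                rows.append(
                    {
                        "species": sp,
                        "early_treatment": early,
                        "contrast": contrast,
                        "trait": trait,
                        "pi_rel": pi_rel,
                        "pi_abs": pi_abs,
                        "variant": variant,
                        "y1": y1,
                        "y2": means[late],
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["species", "early_treatment", "contrast", "trait",
                 "pi_rel", "pi_abs", "variant", "y1", "y2"],
    )
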