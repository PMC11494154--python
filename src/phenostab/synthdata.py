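"""Synthetic split-plot water-treatment experiments on leaf morphometrics.

The generator emulates a two-round greenhouse design: a whole-plot "early
experience" factor (heterogeneous vs homogeneous watering) crossed with
species, where part of each early-treatment group is harvested after the
first round and the remainder is split across three late water treatments
(inundation / moderate / drought).  Each surviving plant carries a set of
leaves; the width of the right and left half of every leaf is "measured"
M times with independent caliper error, which is exactly the data layout
the fluctuating-asymmetry indices and their side-by-unit ANOVA require.

The latent leaf model is symmetric: a leaf of true half-width ``t`` has
sides ``t + d/2`` and ``t - d/2`` where ``d`` is the signed asymmetry, so
leaf size ``(R + L)/2`` recovers ``t`` exactly.  ``d`` is normal around a
directional offset, optionally mixed over ``±antisym_delta`` to emulate
antisymmetry, with scale optionally growing with leaf size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "AsymmetryModel",
    "TraitModel",
    "generate_experiment",
    "simulate_leaf_pair",
    "apply_mortality",
    "FIRST_ROUND_HARVEST",
]

#: late-treatment label for individuals harvested after the first round
FIRST_ROUND_HARVEST = "first_round_harvest"

MASS_TRAITS = ("shoot_mass", "root_mass")


def _default_species() -> list[str]:
    return [f"sp{i + 1}" for i in range(8)]


@dataclass
class DesignConfig:
    """Factorial layout of the experiment.

    The default layout is 8 species x 2 early treatments x
    (3 late treatments x 10 replicates + 20 first-round-harvest
    replicates) = 800 experimental units, one plant per pot.
    """

    species_labels: Sequence[str] = field(default_factory=_default_species)
    early_treatments: Sequence[str] = ("E_het", "E_hom")
    late_treatments: Sequence[str] = ("inundation", "moderate", "drought")
    reps_late: int = 10
    reps_first_harvest: int = 20
    leaves_min: int = 4
    leaves_max: int = 12
    n_replicate_measurements: int = 2  # M: repeat caliper readings per side
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.species_labels:
            raise ValueError("species_labels must be non-empty")
        if not self.early_treatments:
            raise ValueError("early_treatments must be non-empty")
        if self.reps_late < 0:
            raise ValueError(f"reps_late must be >= 0, got {self.reps_late}")
        if self.reps_first_harvest < 0:
            raise ValueError(
                f"reps_first_harvest must be >= 0, got {self.reps_first_harvest}"
            )
        if self.reps_late > 0 and not self.late_treatments:
            raise ValueError("late_treatments empty but reps_late > 0")
        if self.n_units == 0:
            raise ValueError("design yields zero experimental units")
        if self.leaves_min < 1 or self.leaves_max < self.leaves_min:
            raise ValueError(
                f"invalid leaf count range [{self.leaves_min}, {self.leaves_max}]"
            )
        if self.n_replicate_measurements < 2:
            raise ValueError(
                "n_replicate_measurements must be >= 2 "
                "(the FA10 measurement-error term is inestimable with M = 1)"
            )

    @property
    def n_units(self) -> int:
        """Total experimental units implied by the factorial layout."""
        per_cell = len(self.late_treatments) * self.reps_late + self.reps_first_harvest
        return len(self.species_labels) * len(self.early_treatments) * per_cell


@dataclass
class AsymmetryModel:
    """Generative model for signed leaf asymmetry and measurement error.

    Parameters are in mm.  ``sigma_fa`` is the SD of the true signed
    between-sides difference d = R - L (the fluctuating component);
    ``da_offset`` shifts its mean (directional asymmetry);
    ``antisym_delta`` > 0 makes d a symmetric two-point mixture centred at
    ``±antisym_delta`` (antisymmetry); ``sigma_me`` is the SD of a single
    replicate caliper reading around the true side width; ``size_slope``
    adds a leaf-size-proportional term to the asymmetry SD so that |R - L|
    can scale with leaf size.
    """

    sigma_fa: float = 0.3
    da_offset: float = 0.0
    antisym_delta: float = 0.0
    sigma_me: float = 0.05
    size_slope: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_fa", "sigma_me", "antisym_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.size_slope < 0:
            raise ValueError(f"size_slope must be >= 0, got {self.size_slope}")


@dataclass
class TraitModel:
    """Generative model for individual-level traits.

    Mass traits are lognormal around species-scaled baselines with
    multiplicative treatment effects and a log-log dependence on initial
    size; ``cv_inter`` is the inter-individual coefficient of variation of
    each trait within a design cell, ``cv_intra_leaf`` the leaf-size CV
    among leaves of one plant.  ``treatment_multipliers[trait][late]`` and
    ``early_multipliers[trait][early]`` act multiplicatively on the trait
    baseline ("leaf_size" is accepted as a trait key alongside the mass
    traits).  Mortality is Bernoulli per individual.
    """

    baseline_leaf_size: float = 10.0  # mm, mean half-width
    baseline_initial_size: float = 50.0  # mm, longest-leaf length
    baseline_shoot_mass: float = 1.2  # g
    baseline_root_mass: float = 0.8  # g
    cv_inter: float = 0.3
    cv_initial_size: float = 0.2
    cv_intra_leaf: float = 0.10
    species_sd_log: float = 0.2  # SD of lognormal species-level effects
    treatment_multipliers: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    early_multipliers: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    initial_size_effect: float = 0.5  # log-log slope of traits on initial size
    mortality_rate: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "baseline_leaf_size",
            "baseline_initial_size",
            "baseline_shoot_mass",
            "baseline_root_mass",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("cv_inter", "cv_initial_size", "cv_intra_leaf", "species_sd_log"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.mortality_rate <= 1.0:
            raise ValueError(
                f"mortality_rate must be in [0, 1], got {self.mortality_rate}"
            )
        for table in (self.treatment_multipliers, self.early_multipliers):
            for trait, by_level in table.items():
                for level, mult in by_level.items():
                    if mult <= 0:
                        raise ValueError(
                            f"multiplier for {trait}/{level} must be > 0, got {mult}"
                        )

    def multiplier(self, trait: str, early: str, late: str) -> float:
        m = 1.0
        m *= self.early_multipliers.get(trait, {}).get(early, 1.0)
        m *= self.treatment_multipliers.get(trait, {}).get(late, 1.0)
        return m


def _lognormal_sigma(cv: float) -> float:
    """sigma of a lognormal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv**2)))


def _draw_signed_asymmetry(
    true_size: np.ndarray, asym: AsymmetryModel, rng: np.random.Generator
) -> np.ndarray:
    scale = asym.sigma_fa + asym.size_slope * true_size
    d = rng.normal(asym.da_offset, scale)
    if asym.antisym_delta > 0:
        d = d + asym.antisym_delta * rng.choice([-1.0, 1.0], size=true_size.shape)
    return d


def _simulate_sides(
    true_size: np.ndarray, asym: AsymmetryModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Latent right/left half-widths for an array of leaves.

    Redraws d (rather than truncating) whenever a side would be
    non-positive, so the asymmetry distribution is not biased for leaves
    comfortably larger than |d|/2.
    """
    d = _draw_signed_asymmetry(true_size, asym, rng)
    for _ in range(100):
        bad = (true_size + d / 2 <= 0) | (true_size - d / 2 <= 0)
        if not bad.any():
            break
        d[bad] = _draw_signed_asymmetry(true_size[bad], asym, rng)
    else:
        raise RuntimeError("could not draw positive side widths; check config scales")
    return true_size + d / 2, true_size - d / 2


def _replicate_readings(
    side_width: np.ndarray, m: int, sigma_me: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, M) replicate caliper readings; non-positive readings redrawn."""
    readings = side_width[:, None] + rng.normal(0.0, sigma_me, (side_width.size, m))
    for _ in range(100):
        bad = readings <= 0
        if not bad.any():
            break
        readings[bad] = side_width[:, None].repeat(m, axis=1)[bad] + rng.normal(
            0.0, sigma_me, int(bad.sum())
        )
    else:
        raise RuntimeError("could not draw positive readings; check sigma_me")
    return readings


def simulate_leaf_pair(
    true_size: float,
    asym: AsymmetryModel,
    rng: np.random.Generator,
    m: int = 2,
) -> np.ndarray:
    """Simulate one leaf: replicate width readings for both sides.

    Returns an array of shape (2, M): row 0 holds the M right-side
    readings, row 1 the left-side readings.
    """
    if true_size <= 0:
        raise ValueError(f"true_size must be > 0, got {true_size}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    t = np.asarray([float(true_size)])
    r, l = _simulate_sides(t, asym, rng)
    return np.vstack(
        [
            _replicate_readings(r, m, asym.sigma_me, rng)[0],
            _replicate_readings(l, m, asym.sigma_me, rng)[0],
        ]
    )


def _individual_table(
    design: DesignConfig, traits: TraitModel, rng: np.random.Generator
) -> pd.DataFrame:
    rows: list[tuple[str, str, str]] = []
    for sp in design.species_labels:
        for early in design.early_treatments:
            rows += [(sp, early, FIRST_ROUND_HARVEST)] * design.reps_first_harvest
            for late in design.late_treatments:
                rows += [(sp, early, late)] * design.reps_late
    ind = pd.DataFrame(rows, columns=["species", "early_treatment", "late_treatment"])
    n = len(ind)
    ind.insert(0, "individual_id", [f"ind{i:04d}" for i in range(n)])

    species_effect = {
        sp: float(rng.lognormal(0.0, traits.species_sd_log))
        for sp in design.species_labels
    }
    sp_eff = ind["species"].map(species_effect).to_numpy()

    s_is = _lognormal_sigma(traits.cv_initial_size)
    ind["initial_size"] = rng.lognormal(
        np.log(traits.baseline_initial_size) - s_is**2 / 2, s_is, n
    )
    # centred log initial size drives all traits through a common slope
    is_dev = np.log(ind["initial_size"].to_numpy()) - np.log(
        traits.baseline_initial_size
    )

    s_tr = _lognormal_sigma(traits.cv_inter)
    for trait, baseline in (
        ("shoot_mass", traits.baseline_shoot_mass),
        ("root_mass", traits.baseline_root_mass),
    ):
        mult = np.array(
            [
                traits.multiplier(trait, e, l)
                for e, l in zip(ind["early_treatment"], ind["late_treatment"])
            ]
        )
        mu = (
            np.log(baseline * mult * sp_eff)
            + traits.initial_size_effect * is_dev
            - s_tr**2 / 2
        )
        ind[trait] = rng.lognormal(mu, s_tr)
    ind["total_mass"] = ind["shoot_mass"] + ind["root_mass"]
    ind["rs_ratio"] = ind["root_mass"] / ind["shoot_mass"]

    mult_ls = np.array(
        [
            traits.multiplier("leaf_size", e, l)
            for e, l in zip(ind["early_treatment"], ind["late_treatment"])
        ]
    )
    mu_ls = (
        np.log(traits.baseline_leaf_size * mult_ls * sp_eff)
        + traits.initial_size_effect * is_dev
        - s_tr**2 / 2
    )
    ind["mean_leaf_size"] = rng.lognormal(mu_ls, s_tr)
    ind["alive"] = True
    return ind


def _leaf_table(
    ind: pd.DataFrame,
    design: DesignConfig,
    asym: AsymmetryModel,
    traits: TraitModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    m = design.n_replicate_measurements
    n_leaves = rng.integers(design.leaves_min, design.leaves_max + 1, len(ind))
    ind_ids = np.repeat(ind["individual_id"].to_numpy(), n_leaves)
    leaf_idx = np.concatenate([np.arange(1, k + 1) for k in n_leaves])

    s_w = _lognormal_sigma(traits.cv_intra_leaf)
    plant_mean = np.repeat(ind["mean_leaf_size"].to_numpy(), n_leaves)
    true_size = plant_mean * rng.lognormal(-(s_w**2) / 2, s_w, plant_mean.size)

    r, l = _simulate_sides(true_size, asym, rng)
    readings = {
        "right": _replicate_readings(r, m, asym.sigma_me, rng),
        "left": _replicate_readings(l, m, asym.sigma_me, rng),
    }
    frames = []
    for side, vals in readings.items():
        for rep in range(m):
            frames.append(
                pd.DataFrame(
                    {
                        "individual_id": ind_ids,
                        "leaf_index": leaf_idx,
                        "side": side,
                        "replicate": rep + 1,
                        "width": vals[:, rep],
                    }
                )
            )
    leaves = pd.concat(frames, ignore_index=True)
    return leaves.sort_values(
        ["individual_id", "leaf_index", "side", "replicate"], ignore_index=True
    )


def generate_experiment(
    design: DesignConfig | None = None,
    asym: AsymmetryModel | None = None,
    traits: TraitModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic experiment.

    Returns ``(individuals, leaves)``: one row per plant with design cell,
    initial size and mass traits, and one row per replicate width reading
    of each leaf side.  The same ``(config, seed)`` always yields the same
    tables.  Mortality is NOT applied here; see :func:`apply_mortality`.
    """
    design = design if design is not None else DesignConfig()
    asym = asym if asym is not None else AsymmetryModel()
    traits = traits if traits is not None else TraitModel()
    rng = np.random.default_rng(design.rng_seed)
    ind = _individual_table(design, traits, rng)
    leaves = _leaf_table(ind, design, asym, traits, rng)
    ind = ind.drop(columns=["mean_leaf_size"])
    return ind, leaves


def apply_mortality(
    individuals: pd.DataFrame,
    leaves: pd.DataFrame,
    traits: TraitModel,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Remove individuals that die before harvest.

    Death is Bernoulli(``traits.mortality_rate``) independently per
    individual.  Returns the filtered individual and leaf tables plus a
    per-cell summary of realized mortality rates.
    """
    orphans = set(leaves["individual_id"]) - set(individuals["individual_id"])
    if orphans:
        raise ValueError(
            f"leaf table contains {len(orphans)} individual_id(s) missing from "
            f"the individual table, e.g. {sorted(orphans)[:3]}"
        )
    dead = rng.random(len(individuals)) < traits.mortality_rate
    out = individuals.copy()
    out["alive"] = ~dead
    rates = (
        out.groupby(["species", "early_treatment", "late_treatment"], observed=True)[
            "alive"
        ]
        .agg(n_total="size", n_dead=lambda a: int((~a).sum()))
        .reset_index()
    )
    rates["mortality_rate"] = rates["n_dead"] / rates["n_total"]
    survivors = out[out["alive"]].reset_index(drop=True)
    leaves_out = leaves[
        leaves["individual_id"].isin(set(survivors["individual_id"]))
    ].reset_index(drop=True)
    return survivors, leaves_out, rates


def config_to_dict(
    design: DesignConfig, asym: AsymmetryModel, traits: TraitModel
) -> dict:
    """JSON/YAML-serializable view of a full generator configuration."""
    return {
        "design": dataclasses.asdict(design),
        "asymmetry": dataclasses.asdict(asym),
        "traits": dataclasses.asdict(traits),
    }
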