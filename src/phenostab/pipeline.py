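"""End-to-end orchestration: data in, all analysis stages, tables out.

A run either loads a measured dataset (leaf CSV + individual-trait CSV)
or generates a synthetic experiment, then computes per-cell fluctuating
asymmetry and diagnostics, intra-/inter-individual CVs, plasticity
indices, ANCOVA effect tables with LSD letters, and species-level
correlation screens.  Every output carries the run seed and a config
hash so any number is traceable to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import asymmetry, inference, plasticity, synthdata, variation
from .synthdata import (
    FIRST_ROUND_HARVEST,
    AsymmetryModel,
    DesignConfig,
    TraitModel,
)

__all__ = ["RunConfig", "ResultBundle", "load_dataset", "run_full_analysis",
           "write_results"]

logger = logging.getLogger(__name__)

LEAF_COLUMNS = ["individual_id", "leaf_index", "side", "replicate", "width"]
INDIVIDUAL_COLUMNS = [
    "individual_id", "species", "early_treatment", "late_treatment",
    "initial_size", "shoot_mass", "root_mass", "total_mass", "rs_ratio", "alive",
]
CELL = ["species", "early_treatment", "late_treatment"]
MASS_TRAITS = ["shoot_mass", "root_mass", "total_mass", "rs_ratio"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one input mode is active: ``synthetic=True`` (the generator
    blocks apply) or paths to the two CSVs.  Analysis options mirror the
    module-level switches; ``seed`` drives every source of randomness.
    """

    synthetic: bool = True
    leaf_path: str | None = None
    trait_path: str | None = None
    design: DesignConfig = field(default_factory=DesignConfig)
    asym: AsymmetryModel = field(default_factory=AsymmetryModel)
    traits: TraitModel = field(default_factory=TraitModel)
    apply_mortality: bool = True
    fa2_signed: bool = False
    pi_variant: str = "ratio"
    pi_traits: tuple[str, ...] = ("total_mass", "shoot_mass", "root_mass", "rs_ratio")
    cv_log_scale: bool = False
    correlation_covariate: str = "initial_size"
    second_round_covariate: str = "initial_size"
    effect_traits: tuple[str, ...] = ("total_mass",)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        paths = self.leaf_path is not None and self.trait_path is not None
        if self.synthetic == paths:
            raise ValueError(
                "exactly one of synthetic mode or (leaf_path, trait_path) "
                "must be active"
            )


@dataclass
class ResultBundle:
    fa_table: pd.DataFrame
    diagnostics_table: pd.DataFrame
    cv_table: pd.DataFrame
    cv_intra_table: pd.DataFrame
    pi_table: pd.DataFrame
    effect_tables: pd.DataFrame
    lsd_table: pd.DataFrame
    correlation_tables: dict[str, pd.DataFrame]
    mortality_table: pd.DataFrame | None
    metadata: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "fa": self.fa_table,
            "diagnostics": self.diagnostics_table,
            "cv": self.cv_table,
            "cv_intra": self.cv_intra_table,
            "pi": self.pi_table,
            "effects": self.effect_tables,
            "lsd": self.lsd_table,
        }
        for name, tab in self.correlation_tables.items():
            out[f"corr_{name}"] = tab
        if self.mortality_table is not None:
            out["mortality"] = self.mortality_table
        return out


def load_dataset(
    leaf_path: str | Path,
    trait_path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate the leaf and individual CSVs.

    ``column_map`` renames external column headers to the package schema
    (an adapter for differently named exports).  Duplicate measurement
    keys, orphan leaves and leaves missing a side are rejected.
    """
    leaves = pd.read_csv(leaf_path)
    individuals = pd.read_csv(trait_path)
    if column_map:
        leaves = leaves.rename(columns=column_map)
        individuals = individuals.rename(columns=column_map)

    for frame, required, label in (
        (leaves, LEAF_COLUMNS, "leaf table"),
        (individuals, INDIVIDUAL_COLUMNS[:-1], "individual table"),
    ):
        missing = set(required) - set(frame.columns)
        if missing:
            raise ValueError(f"{label} missing columns: {sorted(missing)}")
    if "alive" not in individuals.columns:
        individuals["alive"] = True

    key = ["individual_id", "leaf_index", "side", "replicate"]
    dup = leaves.duplicated(subset=key)
    if dup.any():
        raise ValueError(
            f"duplicate measurement keys in leaf table: "
            f"{leaves.loc[dup, key].head(3).to_dict('records')}"
        )
    if individuals["individual_id"].duplicated().any():
        raise ValueError("duplicate individual_id in individual table")
    orphans = set(leaves["individual_id"]) - set(individuals["individual_id"])
    if orphans:
        raise ValueError(f"orphan leaves for unknown individuals: {sorted(orphans)[:5]}")

    sides = leaves.groupby(["individual_id", "leaf_index"], observed=True)["side"].nunique()
    incomplete = sides[sides < 2]
    if len(incomplete):
        raise ValueError(
            f"leaves missing a side: {list(incomplete.index[:5])}"
        )
    return individuals, leaves


def _fa_cell_tables(
    individuals: pd.DataFrame, leaves: pd.DataFrame, fa2_signed: bool, alpha: float
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-cell FA indices and diagnostics + per-individual FA10/summary."""
    merged = leaves.merge(individuals[["individual_id", *CELL]], on="individual_id")
    summary_all = asymmetry.summarize_leaves(leaves)
    summary_all = summary_all.merge(
        individuals[["individual_id", *CELL]], on="individual_id"
    )
    fa10_ind = asymmetry.fa10_per_individual(leaves)
    fa10_ind = fa10_ind.merge(individuals[["individual_id", *CELL]], on="individual_id")

    fa_rows, diag_rows = [], []
    for cell_key, grp in merged.groupby(CELL, observed=True):
        cell_summary = summary_all[
            (summary_all[CELL] == cell_key).all(axis=1)
        ]
        if len(cell_summary) < 2:
            logger.warning("skipping FA for undersized cell %s", cell_key)
            continue
        anova = asymmetry.sides_anova(grp)
        fa10_pooled, flag = asymmetry.fa10(anova)
        per_ind = fa10_ind[(fa10_ind[CELL] == cell_key).all(axis=1)]
        diag = asymmetry.asymmetry_diagnostics(cell_summary, alpha=alpha)
        base = dict(zip(CELL, cell_key))
        fa_rows.append(
            {
                **base,
                "n_leaves": len(cell_summary),
                "n_individuals": grp["individual_id"].nunique(),
                "fa1": asymmetry.fa1(cell_summary),
                "fa2": asymmetry.fa2(cell_summary, signed=fa2_signed),
                "fa10_pooled": fa10_pooled,
                "fa10_pooled_negative_s2": flag,
                "fa10_mean_individual": per_ind["fa10"].mean(),
                "fa10_se_individual": per_ind["fa10"].sem(),
                "n_negative_s2_individuals": int(per_ind["negative_s2_flag"].sum()),
            }
        )
        diag_rows.append(
            {
                **base,
                **dataclasses.asdict(diag),
                "ms_side": anova.ms_side,
                "ms_interaction": anova.ms_interaction,
                "ms_error": anova.ms_error,
                "f_da_anova": anova.f_da,
                "p_da_anova": anova.p_da,
                "f_me": anova.f_me,
                "p_me": anova.p_me,
            }
        )
    return pd.DataFrame(fa_rows), pd.DataFrame(diag_rows), summary_all


def _cv_tables(
    individuals: pd.DataFrame, summary_all: pd.DataFrame, log_scale: bool
) -> tuple[pd.DataFrame, pd.DataFrame]:
    cv_intra = variation.cv_intra(summary_all, log_scale=log_scale)
    cv_intra = cv_intra.merge(individuals[["individual_id", *CELL]], on="individual_id")

    mean_ls = (
        summary_all.groupby("individual_id", observed=True)["ls"]
        .mean()
        .rename("leaf_size")
        .reset_index()
    )
    traits_df = individuals.merge(mean_ls, on="individual_id", how="left")
    frames = []
    for trait in ["leaf_size", "initial_size", *MASS_TRAITS]:
        frames.append(
            variation.cv_inter(traits_df.dropna(subset=[trait]), trait,
                               log_scale=log_scale)
        )
    return pd.concat(frames, ignore_index=True), cv_intra


def _species_level_summaries(
    individuals: pd.DataFrame,
    summary_all: pd.DataFrame,
    cv_table: pd.DataFrame,
    cv_intra: pd.DataFrame,
    leaves: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First- and second-round species x treatment summaries for the
    correlation screens."""
    fa10_ind = asymmetry.fa10_per_individual(leaves).merge(
        individuals[["individual_id", *CELL]], on="individual_id"
    )
    mean_ls = (
        summary_all.groupby("individual_id", observed=True)["ls"].mean().rename("ls")
    )
    ind = individuals.merge(mean_ls, left_on="individual_id", right_index=True)

    def cell_var(trait: str, name: str) -> pd.DataFrame:
        sub = cv_table[cv_table["trait"] == trait]
        return sub.set_index(CELL)["cv_inter"].rename(name)

    base = (
        ind.groupby(CELL, observed=True)
        .agg(ls=("ls", "mean"), initial_size=("initial_size", "mean"))
    )
    base = base.join(
        fa10_ind.groupby(CELL, observed=True)["fa10"].mean().rename("fa10")
    )
    base = base.join(
        cv_intra.groupby(CELL, observed=True)["cv_intra_ls"].mean().rename("cv_intra_ls")
    )
    base = base.join(cell_var("leaf_size", "cv_inter_ls"))
    base = base.join(cell_var("total_mass", "cv_inter_tm"))
    base = base.join(cell_var("initial_size", "cv_inter_is"))
    base = base.reset_index()

    first = base[base["late_treatment"] == FIRST_ROUND_HARVEST].drop(
        columns="late_treatment"
    )
    second = base[base["late_treatment"] != FIRST_ROUND_HARVEST].copy()
    second = second.rename(columns={"cv_inter_tm": "cv_inter_tm_2nd"})
    second = second.merge(
        first[["species", "early_treatment",
               *inference.FIRST_ROUND_VARS]].rename(
            columns={"cv_inter_tm": "cv_inter_tm"}
        ),
        on=["species", "early_treatment"],
        suffixes=("_2nd_cell", ""),
    )
    return first, second


def _effects_and_lsd(
    individuals: pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    second = individuals[individuals["late_treatment"] != FIRST_ROUND_HARVEST].copy()
    effect_frames, lsd_frames = [], []
    for trait in config.effect_traits:
        data = second.copy()
        data["log_trait"] = inference.log_transform(data[trait])
        aov = inference.ancova(
            data, "log_trait", ["early_treatment", "late_treatment", "species"],
            covariate="initial_size", order=2,
        )
        aov.insert(0, "trait", trait)
        effect_frames.append(aov)

        adj = plasticity.adjusted_means(
            data, "log_trait", "late_treatment", "initial_size"
        )
        letters = inference.lsd_compare(
            adj.means, adj.residual_ms, adj.df_resid, adj.n_per_level,
            alpha=config.alpha,
        )
        letters.insert(0, "trait", trait)
        lsd_frames.append(letters)
    return (
        pd.concat(effect_frames, ignore_index=True),
        pd.concat(lsd_frames, ignore_index=True),
    )


def run_full_analysis(config: RunConfig) -> ResultBundle:
    """Execute the full pipeline and return all result tables."""
    mortality_table = None
    if config.synthetic:
        design = dataclasses.replace(config.design, rng_seed=config.seed)
        individuals, leaves = synthdata.generate_experiment(
            design, config.asym, config.traits
        )
        if config.apply_mortality:
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed).spawn(2)[1]
            )
            individuals, leaves, mortality_table = synthdata.apply_mortality(
                individuals, leaves, config.traits, rng
            )
    else:
        individuals, leaves = load_dataset(config.leaf_path, config.trait_path)
        individuals = individuals[individuals["alive"]].reset_index(drop=True)
        leaves = leaves[
            leaves["individual_id"].isin(set(individuals["individual_id"]))
        ].reset_index(drop=True)

    fa_table, diagnostics, summary_all = _fa_cell_tables(
        individuals, leaves, config.fa2_signed, config.alpha
    )
    cv_table, cv_intra = _cv_tables(individuals, summary_all, config.cv_log_scale)
    pi_table = plasticity.plasticity_table(
        individuals, traits=config.pi_traits, variant=config.pi_variant
    )
    effects, lsd_table = _effects_and_lsd(individuals, config)

    first, second = _species_level_summaries(
        individuals, summary_all, cv_table, cv_intra, leaves
    )
    pi_wide = pi_table[pi_table["trait"] == "total_mass"][
        ["species", "early_treatment", "contrast", "pi_rel", "pi_abs"]
    ].merge(first[["species", "early_treatment", "cv_inter_tm", "initial_size"]],
            on=["species", "early_treatment"])
    corr = inference.correlation_tables(
        first,
        second_round=second,
        pi_summary=pi_wide if len(pi_wide) else None,
        covariate=config.correlation_covariate,
        second_covariate=config.second_round_covariate,
    )

    cfg_dict = _config_dict(config)
    metadata = {
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "n_individuals": int(len(individuals)),
        "n_leaf_rows": int(len(leaves)),
        "fa2_variant": "signed" if config.fa2_signed else "absolute",
        "pi_variant": config.pi_variant,
        "log_transform": "natural log on mass traits before linear models",
    }
    return ResultBundle(
        fa_table=fa_table,
        diagnostics_table=diagnostics,
        cv_table=cv_table,
        cv_intra_table=cv_intra,
        pi_table=pi_table,
        effect_tables=effects,
        lsd_table=lsd_table,
        correlation_tables=corr,
        mortality_table=mortality_table,
        metadata=metadata,
    )


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def write_results(bundle: ResultBundle, outdir: str | Path,
                  overwrite: bool = False) -> list[Path]:
    """Write one CSV per table plus metadata.json; stable filenames."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in bundle.tables().items():
        path = outdir / f"{name}.csv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True")
        table.to_csv(path, index=False)
        written.append(path)
    meta_path = outdir / "metadata.json"
    if meta_path.exists() and not overwrite:
        raise FileExistsError(f"{meta_path} exists; pass overwrite=True")
    meta_path.write_text(json.dumps(bundle.metadata, indent=2, default=str))
    written.append(meta_path)
    return written
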