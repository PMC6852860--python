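"""Pipeline orchestration: simulate -> traits -> popgen -> association -> gene action.

Stages communicate through plain CSV tables (UTF-8, header row, '.'
decimal), so each stage can also be run alone on externally supplied herd
data with the same layout.  Every stage logs row counts and exclusions
with machine-parsable reason codes, and outputs are written atomically
(temp file + rename).
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, gene_action, popgen
from .synthetic_herd import (
    Herd,
    HerdConfig,
    generate_herd,
    load_reference_counts,
    load_reference_lsm,
    read_herd,
    write_herd,
)
from .traits import TargetScheme, covariate_columns_for, derive_traits

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "standard_traits",
    "assemble_marker_data",
    "association_scan",
    "run_pipeline",
    "reference_popgen_summary",
    "reference_gene_action",
]


@dataclass
class RunConfig:
    """Paths and knobs for a full pipeline run."""

    herd_dir: Path
    out_dir: Path
    targets: tuple[float, ...] = (100.0, 200.0, 300.0, 400.0, 450.0)
    alpha: float = 0.05
    min_count: int = 3
    seed: int = 0
    simulate: bool = False
    n_animals: int = 296
    interactions: tuple[tuple[str, ...], ...] = ()


def standard_traits(scheme: TargetScheme) -> list[str]:
    """The trait battery analyzed per marker (DTRs, intervals, totals, FW)."""
    labels = scheme.labels
    intervals = [f"{a}-{b}" for a, b in zip(labels, labels[1:])]
    traits = [f"DTR{w}" for w in labels]
    traits += [f"{iv} FP" for iv in intervals]
    traits += ["FW"]
    traits += [f"{iv} DMI" for iv in intervals] + ["TDMI"]
    traits += [f"{iv} DDMI" for iv in intervals] + ["TDDMI"]
    traits += [f"{iv} FCR" for iv in intervals] + ["TFCR"]
    traits += [f"{iv} ADWG" for iv in intervals] + ["TADWG"]
    return traits


def assemble_marker_data(
    traits_df: pd.DataFrame,
    genotypes_df: pd.DataFrame,
    marker: str,
    trait: str,
) -> pd.DataFrame:
    """Join one marker's genotype calls to one trait with its covariates.

    Output columns: animal_id, the trait, genotype, age, season.
    """
    age_col, season_col = covariate_columns_for(trait)
    g = genotypes_df[genotypes_df["marker"] == marker][["animal_id", "genotype"]]
    cols = ["animal_id", trait, age_col, season_col]
    d = traits_df[cols].merge(g, on="animal_id", how="inner")
    d = d.rename(columns={age_col: "age", season_col: "season"})
    return d


def association_scan(
    traits_df: pd.DataFrame,
    genotypes_df: pd.DataFrame,
    markers: list[str] | None = None,
    traits: list[str] | None = None,
    scheme: TargetScheme | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-marker x per-trait genotype F-test p-values and LSM tables.

    Returns (p_grid, lsm_long): the grid has one row per trait and one
    column per marker; the long table has one row per marker x trait x
    genotype with LSM, SE and Tukey letters (letters only where the
    genotype term is significant at ``alpha``, as in published tables).
    """
    scheme = scheme or TargetScheme()
    markers = markers or sorted(genotypes_df["marker"].unique())
    traits = traits or standard_traits(scheme)
    pgrid: dict[str, dict[str, float]] = {m: {} for m in markers}
    lsm_rows = []
    for marker in markers:
        for trait in traits:
            data = assemble_marker_data(traits_df, genotypes_df, marker, trait)
            spec = association.ModelSpec(trait=trait, alpha=alpha)
            try:
                fit = association.fit_model(spec, data)
            except (association.DegenerateFactorError, association.SingularDesignError) as e:
                logger.info("SKIPPED_FIT marker=%s trait=%s reason=%s", marker, trait, e)
                pgrid[marker][trait] = np.nan
                continue
            p = fit.f_tests["genotype"].p
            pgrid[marker][trait] = p
            letters = (
                association.tukey_posthoc(fit).letters
                if p < alpha
                else {lev: "" for lev in fit.factor_levels}
            )
            for lev in fit.factor_levels:
                lsm_rows.append(
                    {
                        "marker": marker,
                        "trait": trait,
                        "genotype": lev,
                        "n": int(fit.lsm.loc[lev, "n"]),
                        "lsm": fit.lsm.loc[lev, "lsm"],
                        "se": fit.lsm.loc[lev, "se"],
                        "letters": letters[lev],
                        "overall_p": p,
                    }
                )
    grid = pd.DataFrame({m: pd.Series(pgrid[m]) for m in markers})
    grid.index.name = "trait"
    grid = grid.reindex(traits)
    return grid, pd.DataFrame(lsm_rows)


def _atomic_write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, index=index)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def reference_popgen_summary(freq_decimals: int | None = 2) -> pd.DataFrame:
    """Diversity/HWE summary recomputed from the packaged reference counts."""
    return popgen.summary_from_counts(load_reference_counts(), freq_decimals=freq_decimals)


def reference_gene_action() -> pd.DataFrame:
    """Gene-action table recomputed from the packaged reference LSMs."""
    return gene_action.gene_action_table(load_reference_lsm())


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages in dependency order; returns the written file map."""
    out = Path(config.out_dir)
    herd_dir = Path(config.herd_dir)
    scheme = TargetScheme(tuple(config.targets))
    written: dict[str, Path] = {}

    if config.simulate:
        logger.info("STAGE simulate seed=%d n_animals=%d", config.seed, config.n_animals)
        herd = generate_herd(
            HerdConfig(
                n_animals=config.n_animals,
                target_weights=tuple(config.targets),
                seed=config.seed,
            )
        )
        write_herd(herd, herd_dir)
    herd = read_herd(herd_dir)
    logger.info(
        "STAGE load herd animals=%d genotype_rows=%d weigh_rows=%d feed_rows=%d",
        len(herd.animals), len(herd.genotypes), len(herd.weights), len(herd.feed),
    )

    summary = popgen.summarize_markers(herd.genotypes)
    _atomic_write(summary, out / "popgen_summary.csv")
    written["popgen_summary"] = out / "popgen_summary.csv"

    traits_df = derive_traits(herd.weights, herd.feed, herd.animals, scheme)
    n_missing = int(traits_df[[f"DTR{w}" for w in scheme.labels]].isna().any(axis=1).sum())
    logger.info(
        "STAGE traits animals=%d NOT_REACHED_ANY_TARGET=%d", len(traits_df), n_missing
    )
    _atomic_write(traits_df, out / "traits.csv")
    written["traits"] = out / "traits.csv"

    grid, lsm_long = association_scan(
        traits_df, herd.genotypes, scheme=scheme, alpha=config.alpha
    )
    _atomic_write(grid, out / "assoc_pvalues.csv", index=True)
    written["assoc_pvalues"] = out / "assoc_pvalues.csv"
    for marker, sub in lsm_long.groupby("marker"):
        path = out / f"lsm_{marker}.csv"
        _atomic_write(sub.drop(columns="marker"), path)
        written[f"lsm_{marker}"] = path

    sig = lsm_long[lsm_long["overall_p"] < config.alpha]
    ga = gene_action.gene_action_table(
        sig.rename(columns={})[["trait", "marker", "genotype", "lsm", "overall_p"]]
    )
    _atomic_write(ga, out / "gene_action.csv")
    written["gene_action"] = out / "gene_action.csv"

    if config.interactions:
        inter_rows = []
        for markers_pair in config.interactions:
            for trait in standard_traits(scheme):
                wide = traits_df[["animal_id", trait] + list(covariate_columns_for(trait))]
                for m in markers_pair:
                    g = herd.genotypes[herd.genotypes["marker"] == m][
                        ["animal_id", "genotype"]
                    ].rename(columns={"genotype": f"g_{m}"})
                    wide = wide.merge(g, on="animal_id")
                age_col, season_col = covariate_columns_for(trait)
                wide = wide.rename(columns={age_col: "age", season_col: "season"})
                spec = association.ModelSpec(trait=trait, alpha=config.alpha)
                try:
                    fit = association.fit_interaction(
                        spec, wide, [f"g_{m}" for m in markers_pair], config.min_count
                    )
                except (association.DegenerateFactorError, association.SingularDesignError) as e:
                    logger.info(
                        "SKIPPED_INTERACTION markers=%s trait=%s reason=%s",
                        "x".join(markers_pair), trait, e,
                    )
                    continue
                p = fit.f_tests["genotype"].p
                letters = (
                    association.tukey_posthoc(fit).letters
                    if p < config.alpha
                    else {lev: "" for lev in fit.factor_levels}
                )
                for lev in fit.factor_levels:
                    inter_rows.append(
                        {
                            "markers": "x".join(markers_pair),
                            "trait": trait,
                            "combination": lev,
                            "n": int(fit.lsm.loc[lev, "n"]),
                            "lsm": fit.lsm.loc[lev, "lsm"],
                            "se": fit.lsm.loc[lev, "se"],
                            "letters": letters[lev],
                            "overall_p": p,
                        }
                    )
        _atomic_write(pd.DataFrame(inter_rows), out / "interactions.csv")
        written["interactions"] = out / "interactions.csv"
    return written
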