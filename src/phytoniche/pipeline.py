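"""Input validation, configuration and the end-to-end pipeline driver.

The driver chains chemotaxonomy -> microscopy comparison -> niche
estimation -> ordination and writes every stage's table plus a
machine-readable ``report.json`` summarising: the total chlorophyll-a range,
per-season group percentages of TChl a, the NOx/DRP molar-ratio summary,
the niche table, CCA proportion explained, PCA variance fractions and the
trait-space cluster assignment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemtax, microscopy, niche, ordination
from .synthetic import season_of_month

__all__ = ["PipelineConfig", "ValidationReport", "validate_inputs",
           "run_pipeline"]

log = logging.getLogger("phytoniche")

DEFAULT_VARIABLES = ("temperature", "pH", "DO", "NOx", "DRP", "DSi")


@dataclass
class PipelineConfig:
    pigments: str
    environment: str
    counts: str | None = None
    ratios: str | None = None
    outdir: str = "phytoniche_out"
    variables: tuple[str, ...] = DEFAULT_VARIABLES
    cca_variables: tuple[str, ...] | None = None  # default: variables
    n_runs: int = 10
    ratio_limit: float = 0.5
    n_boot: int = 100
    level: float = 0.95
    seed: int = 0
    cluster_k: int | str = "auto"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("variables", "cca_variables"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def _read(path) -> pd.DataFrame:
    return pd.read_csv(path)


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Schema, sign and alignment checks on the input tables.

    Misaligned sample ids between pigments and environment are fatal;
    a requested niche variable missing from the environment table is only a
    warning (it is skipped downstream).
    """
    rep = ValidationReport()
    for name in ("pigments", "environment"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            rep.fatal.append(f"{name} table not found: {p}")
    if rep.fatal:
        return rep
    pig = _read(config.pigments)
    env = _read(config.environment)
    for name, df in (("pigments", pig), ("environment", env)):
        if "sample_id" not in df.columns:
            rep.fatal.append(f"{name} table lacks a sample_id column")
        elif df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"]
            rep.fatal.append(f"{name}: duplicated sample_id(s) "
                             f"{sorted(set(dups))[:5]}")
    if rep.fatal:
        return rep
    num = pig.drop(columns=["sample_id"]).select_dtypes("number")
    neg = num < 0
    if neg.any().any():
        for col in num.columns[neg.any()]:
            row = int(np.argmax(neg[col].to_numpy()))
            rep.fatal.append(
                f"pigments: negative value at row {row}, column {col!r}")
    try:
        chemtax._chla_column(pig.columns)
    except KeyError as e:
        rep.fatal.append(str(e))
    misaligned = set(pig["sample_id"]) ^ set(env["sample_id"])
    if misaligned:
        rep.fatal.append(
            "sample_ids differ between pigments and environment: "
            f"{sorted(misaligned)[:10]}")
    for v in config.variables:
        if v not in env.columns:
            rep.warnings.append(
                f"variable {v!r} missing from environment table; it will "
                "be skipped")
    if config.counts is not None:
        if not Path(config.counts).exists():
            rep.warnings.append(f"counts table not found: {config.counts}; "
                                "method comparison skipped")
        else:
            cnt = _read(config.counts)
            need = {"sample_id", "group", "n", "A", "Ac", "V0", "V1", "V"}
            missing = need - set(cnt.columns)
            if missing:
                rep.fatal.append(
                    f"counts table lacks column(s): {sorted(missing)}")
            elif (cnt["n"] < 0).any():
                rep.fatal.append("counts: negative cell count")
    if config.ratios is not None and not Path(config.ratios).exists():
        rep.fatal.append(f"ratio matrix not found: {config.ratios}")
    return rep


def _seasons(env: pd.DataFrame) -> pd.Series:
    if "season" in env.columns:
        return env["season"]
    if "date" in env.columns:
        months = pd.to_datetime(env["date"]).dt.month
        return months.map(season_of_month)
    return pd.Series("all", index=env.index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all outputs under ``config.outdir``.

    Returns the report dictionary (also written as report.json).  A stage
    failure is recorded in the report under ``failures`` and subsequent
    stages that depend on it are skipped.
    """
    rep = validate_inputs(config)
    if not rep.ok:
        raise ValueError("input validation failed:\n" +
                         "\n".join(rep.fatal))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pig = _read(config.pigments)
    env = _read(config.environment)
    if config.ratios is not None:
        ratios = pd.read_csv(config.ratios, index_col=0)
    else:
        from .synthetic import default_ratio_matrix
        ratios = default_ratio_matrix()
    chla = chemtax._chla_column(pig.columns)
    report: dict = {
        "validation_warnings": rep.warnings,
        "failures": {},
        "settings": {
            "n_runs": config.n_runs, "ratio_limit": config.ratio_limit,
            "n_boot": config.n_boot, "level": config.level,
            "seed": config.seed,
        },
        "tchla_ng_per_l": {"min": float(pig[chla].min()),
                           "max": float(pig[chla].max())},
    }
    seasons = _seasons(env.set_index("sample_id").loc[
        pig["sample_id"]].reset_index())

    # --- chemotaxonomy -----------------------------------------------------
    log.info("chemtax: %d samples x %d pigments, %d runs, seed=%d",
             len(pig), ratios.shape[1], config.n_runs, config.seed)
    result = chemtax.successive_runs(pig, ratios, n_runs=config.n_runs,
                                     ratio_limit=config.ratio_limit)
    comp = result.composition
    comp.to_csv(outdir / "composition.csv", index=False)
    result.ratios.to_csv(outdir / "final_ratios.csv", index_label="group")
    pd.DataFrame({"run": np.arange(1, result.n_runs + 1),
                  "rmse": result.rmse_trajectory}).to_csv(
        outdir / "rmse_trajectory.csv", index=False)
    report["chemtax"] = {"final_rmse": result.rmse_trajectory[-1],
                         "warnings": result.warnings}
    groups = list(ratios.index)
    markers = chemtax.validate_against_markers(comp, pig)
    markers.to_csv(outdir / "marker_correlations.csv", index=False)
    report["marker_correlations"] = {
        row.group: None if pd.isna(row.r) else round(float(row.r), 4)
        for row in markers.itertuples()}

    # per-season group percentages of total chlorophyll a
    pct = comp[groups].div(pig[chla].to_numpy(), axis=0) * 100.0
    pct["season"] = seasons.to_numpy()
    season_pct = pct.groupby("season").mean().round(2)
    season_pct.to_csv(outdir / "season_percentages.csv")
    report["season_group_percent_tchla"] = {
        s: {g: float(season_pct.loc[s, g]) for g in groups}
        for s in season_pct.index}

    # NOx/DRP molar ratio per sample
    if {"NOx", "DRP"}.issubset(env.columns):
        ratio = env["NOx"] / env["DRP"]
        ratio = ratio[np.isfinite(ratio)]
        report["nox_drp_molar_ratio"] = {
            "min": float(ratio.min()), "median": float(ratio.median()),
            "max": float(ratio.max())}

    # --- microscopy comparison --------------------------------------------
    if config.counts is not None and Path(config.counts).exists():
        try:
            counts = _read(config.counts)
            abund = microscopy.aggregate_replicates(counts)
            abund.to_csv(outdir / "abundance.csv", index=False)
            cmp_tab = microscopy.compare_methods(abund, comp, groups=groups)
            cmp_tab.to_csv(outdir / "method_comparison.csv", index=False)
            report["method_comparison_r"] = {
                row.group: None if pd.isna(row.r) else round(float(row.r), 4)
                for row in cmp_tab.itertuples()}
        except Exception as e:  # pragma: no cover - defensive
            report["failures"]["microscopy"] = str(e)

    # --- niche estimation --------------------------------------------------
    variables = [v for v in config.variables if v in env.columns]
    try:
        log.info("niche: %d groups x %d variables, n_boot=%d",
                 len(groups), len(variables), config.n_boot)
        niches = niche.estimate_all(comp, env, variables, groups=groups,
                                    n_boot=config.n_boot,
                                    level=config.level, seed=config.seed)
        niches.to_csv(outdir / "niches.csv", index=False)
        report["niches"] = niches[["group", "variable", "mu", "sigma"]] \
            .round(4).to_dict("records")
    except Exception as e:
        report["failures"]["niche_estimation"] = str(e)
        niches = None

    # --- ordination --------------------------------------------------------
    cca_vars = [v for v in (config.cca_variables or config.variables)
                if v in env.columns]
    try:
        aligned_env = env.set_index("sample_id").loc[
            comp["sample_id"]].reset_index()
        cca_res = ordination.cca(comp[groups],
                                 aligned_env[cca_vars])
        pd.DataFrame({"eigenvalue": cca_res.eigenvalues}).to_csv(
            outdir / "cca_summary.csv", index=False)
        cca_res.site_scores.to_csv(outdir / "cca_site_scores.csv")
        cca_res.species_scores.to_csv(outdir / "cca_species_scores.csv")
        cca_res.biplot_scores.to_csv(outdir / "cca_biplot_scores.csv")
        report["cca"] = {
            "proportion_explained": float(cca_res.proportion_explained),
            "total_inertia": float(cca_res.total_inertia),
            "aliased": cca_res.aliased}
    except Exception as e:
        report["failures"]["cca"] = str(e)

    if niches is not None:
        try:
            space = ordination.pca_traits(niches)
            space.scores.to_csv(outdir / "traits_pca.csv")
            labels, scree = ordination.cluster_trait_space(
                space, config.cluster_k)
            labels.to_frame().to_csv(outdir / "clusters.csv")
            scree.to_csv(outdir / "cluster_scree.csv", index=False)
            report["trait_pca_variance_fractions"] = [
                round(float(f), 4) for f in space.variance_fractions]
            report["clusters"] = {str(g): int(l) for g, l in labels.items()}
        except Exception as e:
            report["failures"]["trait_space"] = str(e)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
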