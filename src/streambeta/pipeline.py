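"""One-call reproduction of the full beta-diversity analysis chain.

``run_full_analysis`` wires the stages together: read (or simulate) the
survey, merge repeated surveys, exclude empty transects, screen the
environmental variables for collinearity, partition pairwise beta
diversity, build the explanatory distances, and run Mantel tests,
distance-decay fits, MRM and hierarchical partitioning. Every stochastic
stage consumes an independent substream of one master seed, so adding a
stage never perturbs earlier draws and a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .distances import (
    elevational_distance,
    environmental_distance,
    geographic_distance,
    screen_variables,
    single_variable_distance,
    standardize,
    substrate_columns,
)
from .io import DistanceMatrix, EnvTable, OccurrenceMatrix, TransectMeta, ValidationError
from .mantel import MantelResult, RegressionFit, distance_decay, mantel_table
from .partition import BetaSummary, beta_matrices, beta_summary
from .simulate import ScenarioConfig, generate_scenario
from .varpart import hier_part, mrm, partition_table, standardize_matrix

__version__ = "0.1.0"

#: Conventional short labels for the MRM/partitioning predictors.
ABBREVIATIONS = {
    "geography": "Geo",
    "elevation": "Ele",
    "pH": "pH",
    "conductivity": "Con",
    "dissolved_oxygen": "Do",
    "river_width": "Rw",
    "water_depth": "Wd",
    "current_velocity": "Cv",
    "chlorophyll_a": "chl.a",
    "total_N": "TN",
    "ammonium_N": "NN",
    "total_P": "TP",
    "substrate": "Sub",
    "water_temperature": "Wt",
}


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for one end-to-end run."""

    occurrence_paths: tuple[str, ...] = ()
    meta_path: str | None = None
    env_path: str | None = None
    scenario: ScenarioConfig | None = None
    n_perm: int = 9999
    seed: int = 0
    collinearity_threshold: float = 0.7
    priority: tuple[str, ...] = ("elevation",)
    substrate_encoding: str = "proportions"
    tail: str = "greater"
    ratio_threshold: float = 0.5
    alpha: float = 0.05
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValidationError("n_perm must be >= 99")
        if self.scenario is None and not self.occurrence_paths:
            raise ValidationError("provide occurrence paths or a scenario config")


@dataclass
class AnalysisReport:
    """Everything the chain computes, plus the provenance manifest."""

    occurrence: OccurrenceMatrix
    meta: TransectMeta
    env: EnvTable
    excluded_sites: list[str]
    screening: object
    summary: BetaSummary
    beta: dict[str, DistanceMatrix]
    predictors: dict[str, DistanceMatrix]
    mantel: dict[str, dict[str, MantelResult]]
    decay: dict[str, dict[str, RegressionFit]]
    partition: dict[str, dict]
    manifest: io.RunManifest = field(default=None)


def _load_inputs(
    cfg: RunConfig,
) -> tuple[OccurrenceMatrix, TransectMeta, EnvTable, dict]:
    if cfg.scenario is not None:
        occ, meta, env, truth = generate_scenario(cfg.scenario)
        return occ, meta, env, {"scenario": cfg.scenario.to_dict()}
    surveys = [io.read_occurrence(p) for p in cfg.occurrence_paths]
    occ = io.merge_surveys(surveys)
    if cfg.meta_path is None or cfg.env_path is None:
        raise ValidationError("meta_path and env_path are required with file input")
    meta = io.read_meta(cfg.meta_path)
    env = io.read_env(cfg.env_path)
    return occ, meta, env, {
        "occurrence": list(cfg.occurrence_paths),
        "meta": cfg.meta_path,
        "env": cfg.env_path,
    }


def build_predictor_distances(
    env: EnvTable,
    meta: TransectMeta,
    kept_variables: list[str],
    substrate_encoding: str = "proportions",
) -> dict[str, DistanceMatrix]:
    """The MRM predictor set: Geo, Ele, one matrix per kept variable, Sub."""
    predictors: dict[str, DistanceMatrix] = {
        "Geo": geographic_distance(meta),
        "Ele": elevational_distance(meta),
    }
    sub_cols = set(substrate_columns(env))
    for var in kept_variables:
        if var in sub_cols or var == "elevation":
            continue
        predictors[ABBREVIATIONS.get(var, var)] = single_variable_distance(env, var)
    if sub_cols:
        predictors["Sub"] = single_variable_distance(
            env, "substrate", substrate_encoding=substrate_encoding
        )
    return predictors


def run_full_analysis(cfg: RunConfig) -> AnalysisReport:
    occ_raw, meta, env, input_record = _load_inputs(cfg)

    occ, removed_sites = io.drop_empty_sites(occ_raw)
    keep = list(occ.site_ids)
    meta = meta.subset_sites(keep)
    env = env.subset_sites(keep)

    # screening operates on the environment plus elevation, so an
    # elevation-tracking variable (water temperature) can be dropped
    screen_input = EnvTable(
        env.table.assign(elevation=meta.table["elevation"].to_numpy())
    )
    screening = screen_variables(
        screen_input, threshold=cfg.collinearity_threshold, priority=list(cfg.priority)
    )
    kept_env = [v for v in screening.kept if v != "elevation"]

    D_sor, D_sim, D_sne = beta_matrices(occ)
    summary = beta_summary(D_sor, D_sim, D_sne)
    beta = {"total": D_sor, "turnover": D_sim, "nestedness": D_sne}

    pooled = {
        "geography": geographic_distance(meta),
        "elevation": elevational_distance(meta),
        "environment": environmental_distance(
            standardize(env.subset_variables(kept_env)), standardized=True
        ),
    }

    ss = np.random.SeedSequence(cfg.seed)
    seed_mantel, seed_mrm = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))

    grid = mantel_table(
        beta, pooled, n_perm=cfg.n_perm, seed=seed_mantel, tail=cfg.tail,
        on_degenerate="skip",
    )
    decay = {
        pred: {b: distance_decay(beta[b], D) for b in beta} for pred, D in pooled.items()
    }

    raw_predictors = build_predictor_distances(
        env, meta, kept_env, substrate_encoding=cfg.substrate_encoding
    )
    predictors = {k: standardize_matrix(D) for k, D in raw_predictors.items()}
    try:
        partition = partition_table(beta, predictors, n_perm=cfg.n_perm, seed=seed_mrm)
    except ValidationError:
        # a degenerate (constant) beta matrix cannot be regressed; the
        # remaining responses are still reported
        partition = {}
        ss_p = np.random.SeedSequence(seed_mrm)
        for beta_name, child in zip(beta, ss_p.spawn(len(beta))):
            child_seed = int(child.generate_state(1)[0] % (2**31))
            try:
                partition[beta_name] = {
                    "mrm": mrm(beta[beta_name], predictors, n_perm=cfg.n_perm, seed=child_seed),
                    "hier_part": hier_part(beta[beta_name], predictors),
                }
            except ValidationError:
                partition[beta_name] = None

    manifest = io.RunManifest(
        inputs=input_record,
        seed=cfg.seed,
        excluded_sites=removed_sites,
        removed_variables=screening.removed,
        decisions={
            "collinearity_threshold": cfg.collinearity_threshold,
            "priority": list(cfg.priority),
            "substrate_encoding": cfg.substrate_encoding,
            "tail": cfg.tail,
            "n_perm": cfg.n_perm,
            "ratio_threshold": cfg.ratio_threshold,
            "predictors": list(predictors),
        },
        software_version=__version__,
    )
    report = AnalysisReport(
        occurrence=occ,
        meta=meta,
        env=env,
        excluded_sites=removed_sites,
        screening=screening,
        summary=summary,
        beta=beta,
        predictors=pooled,
        mantel=grid,
        decay=decay,
        partition=partition,
        manifest=manifest,
    )
    if cfg.out_dir is not None:
        write_report(report, cfg.out_dir)
    return report


def mantel_frame(grid: dict[str, dict[str, MantelResult]], what: str = "p") -> pd.DataFrame:
    """Tabulate the Mantel grid (rows: predictors, columns: beta indices)."""
    return pd.DataFrame(
        {
            b: {
                pred: getattr(grid[pred][b], what) if grid[pred][b] is not None else np.nan
                for pred in grid
            }
            for b in next(iter(grid.values()))
        }
    )


def partition_frames(partition: dict[str, dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MRM table (R², p, per-predictor b and p) and independent-% table."""
    mrm_rows: dict[str, dict] = {}
    pct: dict[str, dict] = {}
    for resp, res in partition.items():
        if res is None:
            continue
        m = res["mrm"]
        row = {"R2": m.r_squared, "p_model": m.p_model}
        for name in m.coefficients:
            row[f"b_{name}"] = m.coefficients[name]
            row[f"p_{name}"] = m.p_coef[name]
        mrm_rows[resp] = row
        pct[resp] = res["hier_part"].independent_pct
    return pd.DataFrame(mrm_rows).T, pd.DataFrame(pct)


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_occurrence(report.occurrence, out / "occurrence_retained.csv")
    io.write_meta(report.meta, out / "meta_retained.csv")
    io.write_env(report.env, out / "env_retained.csv")
    for name, D in report.beta.items():
        io.write_distance(D, out / f"beta_{name}.csv")
    for name, D in report.predictors.items():
        io.write_distance(D, out / f"distance_{name}.csv")
    pd.Series(report.summary.to_dict()).to_csv(out / "beta_summary.csv", header=False)
    (out / "beta_summary.json").write_text(
        json.dumps(report.summary.to_dict(), indent=2) + "\n"
    )
    report.screening.spearman_rho.to_csv(out / "screening_rho.csv")
    (out / "screening.json").write_text(
        json.dumps(report.screening.to_dict(), indent=2) + "\n"
    )
    mantel_frame(report.mantel, "p").to_csv(out / "mantel_p.csv")
    mantel_frame(report.mantel, "r").to_csv(out / "mantel_r.csv")
    decay_rows = {
        f"{b}~{pred}": fit.to_dict()
        for pred, fits in report.decay.items()
        for b, fit in fits.items()
    }
    pd.DataFrame(decay_rows).T.to_csv(out / "decay_fits.csv")
    mrm_df, pct_df = partition_frames(report.partition)
    mrm_df.to_csv(out / "mrm.csv")
    pct_df.to_csv(out / "hierpart_independent_pct.csv")
    report.manifest.write(out / "manifest.json")
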