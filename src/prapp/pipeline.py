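"""End-to-end orchestration: simulate/load -> select -> encode -> fit ->
bootstrap -> reason analysis, with on-disk artifacts and a JSON report.

A single master seed fans out to the stage seeds by fixed offsets (cohort
+0, cross-validation +1, bootstrap +2), so stages stay reproducible in
isolation and the whole run is bit-for-bit repeatable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .barriers import (
    build_reason_analysis,
    participation_table,
    reason_results_frame,
    user_proportion,
)
from .bootstrap import BootstrapConfig, bootstrap_coefficients, summarize
from .covariates import (
    ColumnMeta,
    DensityMap,
    DesignMatrix,
    IncomeSchema,
    build_analysis_frame,
    build_design_matrix,
    default_income_schema,
    density_band,
    recode_missing,
)
from .enet import FittedModel, TuningConfig, tune_and_select
from .records import ParticipantRecord, read_csv, write_csv
from .selection import AnalysisCohort, apply_selection_flow
from .synthetic import CohortConfig, generate_cohort, load_config as load_cohort_config


def load_density_map(path=None) -> DensityMap:
    """Load a YAML density map; default is the packaged synthetic map."""
    if path is None:
        ref = resources.files("prapp.data").joinpath("synthetic_density_map.yaml")
        with ref.open("r", encoding="utf8") as fh:
            data = yaml.safe_load(fh)
    else:
        with open(path, "r", encoding="utf8") as fh:
            data = yaml.safe_load(fh)
    return DensityMap({str(k): float(v) for k, v in data["densities"].items()})


@dataclass
class RunConfig:
    """One of ``input_csv`` / ``cohort_config`` must be set (not both)."""

    input_csv: str | None = None
    cohort_config: CohortConfig | None = None
    density_map: DensityMap | None = None
    income_schema: IncomeSchema | None = None
    gay_population: Mapping[str, int] | None = None
    tuning: TuningConfig = field(default_factory=TuningConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    missing_mode: str = "separate_category"
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.input_csv is None) == (self.cohort_config is None):
            raise ValueError("exactly one of input_csv / cohort_config must be set")


def _density_bands_by_id(cohort: AnalysisCohort, dmap: DensityMap) -> dict:
    return {
        rec.participant_id: density_band(rec.federal_state, dmap)
        for rec in cohort.records
    }


def run_full(config: RunConfig) -> dict:
    """Execute every stage in order and return the machine-readable report."""
    config.validate()
    dmap = config.density_map or load_density_map()
    schema = config.income_schema or default_income_schema()

    if config.cohort_config is not None:
        cohort_cfg = config.cohort_config
        cohort_cfg.seed = config.seed
        records = generate_cohort(cohort_cfg)
    else:
        records = read_csv(config.input_csv)
    records = [recode_missing(r) for r in records]

    cohort = apply_selection_flow(records)
    frame = build_analysis_frame(cohort, schema, dmap)
    matrix = build_design_matrix(frame, missing_mode=config.missing_mode)

    tuning = TuningConfig(**{**asdict(config.tuning), "seed": config.seed + 1})
    grid, candidates, chosen = tune_and_select(matrix, tuning)

    boot_cfg = BootstrapConfig(
        n_samples=config.bootstrap.n_samples,
        ci_level=config.bootstrap.ci_level,
        seed=config.seed + 2,
        max_iter=config.bootstrap.max_iter,
        tol=config.bootstrap.tol,
    )
    replicates = bootstrap_coefficients(matrix, chosen.mixing, chosen.strength, boot_cfg)
    boot_summary = summarize(replicates, chosen, boot_cfg.ci_level)

    reasons_ind = build_reason_analysis(cohort, "indication")
    reasons_den = build_reason_analysis(
        cohort, "density", density_bands=_density_bands_by_id(cohort, dmap)
    )
    proportions = user_proportion(cohort)

    report = {
        "fingerprint": {
            "package_version": __version__,
            "master_seed": config.seed,
            "missing_mode": config.missing_mode,
            "bootstrap_samples": boot_cfg.n_samples,
        },
        "selection_ledger": cohort.ledger.as_dicts(),
        "chosen_model": model_to_dict(chosen),
        "candidate_models": [
            {"mixing": m.mixing, "strength": m.strength, "n_nonzero": m.n_nonzero, "aic": m.aic}
            for m in candidates
        ],
        "bootstrap_summary": boot_summary.reset_index().to_dict(orient="records"),
        "reasons_by_indication": reason_results_frame(reasons_ind).to_dict(orient="records"),
        "reasons_by_density": reason_results_frame(reasons_den).to_dict(orient="records"),
        "user_proportion_by_state": proportions.to_dict(orient="records"),
    }
    if config.gay_population is not None:
        part = participation_table(
            {
                row["federal_state"]: row["n_participants"]
                for row in proportions.to_dict(orient="records")
            },
            config.gay_population,
        )
        report["participation"] = part.to_dict(orient="records")

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_csv(records, out / "records.csv")
        write_csv(cohort.records, out / "cohort.csv")
        (out / "ledger.json").write_text(
            json.dumps(cohort.ledger.as_dicts(), indent=2) + "\n"
        )
        write_design_matrix(matrix, out / "design_matrix.csv", out / "design_columns.json")
        grid.to_csv(out / "tuning_grid.csv", index=False, lineterminator="\n")
        (out / "chosen_model.json").write_text(
            json.dumps(model_to_dict(chosen), indent=2, sort_keys=True) + "\n"
        )
        boot_summary.to_csv(out / "bootstrap_summary.csv", lineterminator="\n")
        reason_results_frame(reasons_ind).to_csv(
            out / "reasons_indication.csv", index=False, lineterminator="\n"
        )
        reason_results_frame(reasons_den).to_csv(
            out / "reasons_density.csv", index=False, lineterminator="\n"
        )
        proportions.to_csv(out / "user_proportion.csv", index=False, lineterminator="\n")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


# ---------------------------------------------------------------------------
# artifact (de)serialization helpers shared with the CLI


def model_to_dict(model: FittedModel) -> dict:
    return {
        "mixing": model.mixing,
        "strength": model.strength,
        "intercept": model.intercept,
        "coefficients": {k: float(v) for k, v in model.coef.items()},
        "n_nonzero": model.n_nonzero,
        "log_likelihood": model.log_likelihood,
        "aic": model.aic,
    }


def write_design_matrix(matrix: DesignMatrix, csv_path, meta_path) -> None:
    out = matrix.X.copy()
    out.insert(0, "outcome", matrix.y)
    out.to_csv(csv_path, index=False, lineterminator="\n")
    meta = {
        "missing_mode": matrix.missing_mode,
        "reference": matrix.reference,
        "columns": [
            {
                "name": c.name,
                "source_variable": c.source_variable,
                "category": c.category,
                "is_missing_indicator": c.is_missing_indicator,
            }
            for c in matrix.columns
        ],
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_design_matrix(csv_path, meta_path) -> DesignMatrix:
    frame = pd.read_csv(csv_path)
    meta = json.loads(Path(meta_path).read_text())
    columns = [
        ColumnMeta(c["source_variable"], c["category"], c["is_missing_indicator"])
        for c in meta["columns"]
    ]
    return DesignMatrix(
        y=frame["outcome"].to_numpy(dtype=int),
        X=frame.drop(columns=["outcome"]),
        columns=columns,
        reference=meta["reference"],
        missing_mode=meta["missing_mode"],
    )
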