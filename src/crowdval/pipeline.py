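"""End-to-end orchestration: cohort -> scores -> reliability -> MTMM ->
validity -> prediction battery, with validated CSV ingestion and a
reproducible report bundle."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import crowdval
from crowdval.cohort import (
    AGES,
    GENDERS,
    RACE_ETHNICITIES,
    REGIONS,
    CohortConfig,
    default_grids,
    generate_cohort,
    save_cohort,
)
from crowdval.crowds import CROWDS, N_BEST, N_LEAST, N_VMLS_QUESTIONS, SUBSTANCES
from crowdval.instruments import score_table
from crowdval.mtmm import (
    MtmmMatrix,
    build_mtmm,
    evaluate_validity,
    load_published_matrix,
)
from crowdval.predictive import battery_wide, run_prediction_battery
from crowdval.reliability import reliability_table

log = logging.getLogger("crowdval")


class SchemaError(ValueError):
    """Respondent CSV header does not match the column dictionary."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# respondent CSV ingestion
# ---------------------------------------------------------------------------


def expected_columns(n_grids: int = 2) -> list[str]:
    """The documented cohort column dictionary (minus oracle-only columns)."""
    cols = ["respondent_id"]
    for q in range(1, N_VMLS_QUESTIONS + 1):
        cols += [f"vmls_q{q}_rank1", f"vmls_q{q}_rank2"]
    for g in range(1, n_grids + 1):
        cols += [f"ibase_g{g}_best_{j}" for j in range(1, N_BEST + 1)]
        cols += [f"ibase_g{g}_least_{j}" for j in range(1, N_LEAST + 1)]
    cols += [f"ace_{i}" for i in range(1, 10)]
    cols += [f"brs_{i}" for i in range(1, 7)]
    cols += [f"spi_{i}" for i in range(1, 9)]
    cols += [f"bsss_{i}" for i in range(1, 9)]
    cols += [f"use_days_{s}" for s in SUBSTANCES]
    cols += ["sad_hopeless", "age", "gender", "race_ethnicity", "region"]
    return cols


@dataclass
class LoadResult:
    """Validated respondent table plus per-row rejection report."""

    table: pd.DataFrame
    row_errors: list[dict]  # {"line": csv line number, "error": message}


def _row_problems(row: pd.Series, grids: Sequence[Mapping[str, str]]) -> list[str]:
    problems = []
    for q in range(1, N_VMLS_QUESTIONS + 1):
        r1, r2 = row[f"vmls_q{q}_rank1"], row[f"vmls_q{q}_rank2"]
        if r1 not in CROWDS or r2 not in CROWDS:
            problems.append(f"question {q}: unknown crowd")
        elif r1 == r2:
            problems.append(f"question {q}: rank1 == rank2")
    photo_map = {}
    for grid in grids:
        photo_map.update(grid)
    for g in range(1, len(grids) + 1):
        best = [row[f"ibase_g{g}_best_{j}"] for j in range(1, N_BEST + 1)]
        least = [row[f"ibase_g{g}_least_{j}"] for j in range(1, N_LEAST + 1)]
        if any(p not in photo_map for p in best + least):
            problems.append(f"grid {g}: unknown photo id")
        elif set(best) & set(least) or len(set(best)) < N_BEST or len(set(least)) < N_LEAST:
            problems.append(f"grid {g}: best/least sets not disjoint 3+3")
    for i in range(1, 10):
        if row[f"ace_{i}"] not in (0, 1):
            problems.append(f"ace_{i}: not binary")
    for name, rng_, count in (("brs", (1, 5), 6), ("spi", (1, 5), 8), ("bsss", (1, 5), 8)):
        for i in range(1, count + 1):
            v = row[f"{name}_{i}"]
            if not (rng_[0] <= v <= rng_[1]):
                problems.append(f"{name}_{i}: {v!r} outside {rng_[0]}-{rng_[1]}")
    for s in SUBSTANCES:
        v = row[f"use_days_{s}"]
        if not (0 <= v <= 30):
            problems.append(f"use_days_{s}: {v!r} outside 0-30")
    if row["sad_hopeless"] not in (0, 1):
        problems.append("sad_hopeless: not binary")
    if row["age"] not in AGES:
        problems.append(f"age: {row['age']!r} outside 13-18")
    if row["gender"] not in GENDERS:
        problems.append(f"gender: unknown category {row['gender']!r}")
    if row["race_ethnicity"] not in RACE_ETHNICITIES:
        problems.append(f"race_ethnicity: unknown category {row['race_ethnicity']!r}")
    if row["region"] not in REGIONS:
        problems.append(f"region: unknown category {row['region']!r}")
    return problems


def load_respondents_csv(path: str | Path,
                         grids: Sequence[Mapping[str, str]] | None = None) -> LoadResult:
    """Read and validate a respondent CSV.

    The header must contain the documented column dictionary (an oracle-only
    ``latent_crowd`` column is tolerated).  Rows failing validation are
    dropped and reported with their 1-based CSV line numbers; valid rows
    proceed.
    """
    path = Path(path)
    if grids is None:
        grids = default_grids()
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in expected_columns(len(grids)) if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    errors = []
    bad_idx = []
    for idx, row in table.iterrows():
        problems = _row_problems(row, grids)
        if problems:
            bad_idx.append(idx)
            errors.append({"line": int(idx) + 2, "error": "; ".join(problems)})
    if bad_idx:
        table = table.drop(index=bad_idx).reset_index(drop=True)
    return LoadResult(table=table, row_errors=errors)


# ---------------------------------------------------------------------------
# descriptives (sample-characteristics analog)
# ---------------------------------------------------------------------------


def describe_cohort(scored: pd.DataFrame) -> pd.DataFrame:
    """Frequencies and means/SDs describing the scored sample."""
    n = len(scored)
    rows = []

    def freq(block: str, series: pd.Series, categories) -> None:
        counts = series.value_counts()
        for cat in categories:
            c = int(counts.get(cat, 0))
            rows.append({"block": block, "characteristic": str(cat),
                         "n": c, "pct": 100.0 * c / n if n else np.nan,
                         "mean": np.nan, "sd": np.nan})

    freq("gender", scored["gender"], GENDERS)
    freq("race_ethnicity", scored["race_ethnicity"], RACE_ETHNICITIES)
    freq("region", scored["region"], REGIONS)
    age_band = np.where(scored["age"] <= 15, "13-15", "16-18")
    freq("age", pd.Series(age_band), ("13-15", "16-18"))
    freq("ibase_crowd", scored["ibase_assignment"], list(CROWDS) + ["Tied"])
    freq("vmls_crowd", scored["vmls_assignment"], list(CROWDS) + ["Tied"])
    for s in SUBSTANCES:
        c = int(scored[f"current_use_{s}"].sum())
        rows.append({"block": "behavior", "characteristic": f"current_{s}_use",
                     "n": c, "pct": 100.0 * c / n, "mean": np.nan, "sd": np.nan})
    c = int(scored["sad_hopeless"].sum())
    rows.append({"block": "behavior", "characteristic": "sad_hopeless",
                 "n": c, "pct": 100.0 * c / n, "mean": np.nan, "sd": np.nan})
    for col, label in (("ace_score", "ace_score"), ("brs_score", "resilience_score"),
                       ("spi_score", "spi_score"), ("bsss_score", "sensation_seeking_score")):
        rows.append({"block": "scale", "characteristic": label, "n": n,
                     "pct": np.nan, "mean": float(scored[col].mean()),
                     "sd": float(scored[col].std(ddof=1)) if n > 1 else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``cohort`` (generator config) or ``cohort_csv`` (path)
    must be set.  ``use_published_matrix`` bypasses cohort stages and
    evaluates the packaged printed matrix instead.
    """

    cohort: CohortConfig | None = None
    cohort_csv: str | None = None
    alpha: float = 0.05
    omega_method: str = "uls"
    battery_mode: str = "separate"
    out_dir: str = "crowdval_run"
    mtmm_only: bool = False
    use_published_matrix: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.use_published_matrix:
            if (self.cohort is None) == (self.cohort_csv is None):
                raise ValueError("exactly one cohort source required "
                                 "(cohort config or cohort_csv)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.battery_mode not in ("separate", "joint"):
            raise ValueError(f"unknown battery mode {self.battery_mode!r}")


@dataclass
class ReportBundle:
    config: RunConfig
    scored: pd.DataFrame | None
    descriptives: pd.DataFrame | None
    reliability: pd.DataFrame | None
    matrix: MtmmMatrix
    validity: "crowdval.ValidityReport"
    battery: pd.DataFrame | None
    manifest: dict
    row_errors: list[dict] = field(default_factory=list)


def _config_hash(config: RunConfig) -> str:
    payload = {
        "cohort": config.cohort.to_dict() if config.cohort else None,
        "cohort_csv": config.cohort_csv,
        "alpha": config.alpha,
        "omega_method": config.omega_method,
        "battery_mode": config.battery_mode,
        "mtmm_only": config.mtmm_only,
        "use_published_matrix": config.use_published_matrix,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages and write outputs under ``config.out_dir``.

    Outputs are deterministic for a fixed config (seed included); partial
    outputs are preserved when a stage fails, and the raised
    :class:`PipelineError` names the failing stage.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    timings: dict[str, float] = {}

    def run_stage(name, fn):
        nonlocal stage
        stage = name
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 4)
        log.info("stage %s: done in %.3fs", name, timings[name])
        return result

    scored = descriptives = reliab = battery = None
    row_errors: list[dict] = []
    grids = (config.cohort.grids if config.cohort else default_grids())

    if config.use_published_matrix:
        matrix = run_stage("published_matrix", load_published_matrix)
    else:
        if config.cohort is not None:
            cohort = run_stage("generate", lambda: generate_cohort(config.cohort))
            run_stage("write_cohort",
                      lambda: save_cohort(cohort, config.cohort, out / "cohort.csv"))
        else:
            loaded = run_stage("load", lambda: load_respondents_csv(
                config.cohort_csv, grids))
            cohort, row_errors = loaded.table, loaded.row_errors
            if row_errors:
                (out / "row_errors.json").write_text(json.dumps(row_errors, indent=2))

        scored = run_stage("score", lambda: score_table(cohort, grids))
        scored.to_csv(out / "scored.csv", index=False)
        descriptives = run_stage("describe", lambda: describe_cohort(scored))
        descriptives.to_csv(out / "descriptives.csv", index=False)
        reliab = run_stage("reliability", lambda: reliability_table(
            scored, grids, method=config.omega_method))
        reliab.to_csv(out / "reliability.csv", index=False)
        omegas = {(r.instrument, r.crowd): r.omega for r in reliab.itertuples()}
        matrix = run_stage("mtmm", lambda: build_mtmm(scored, omegas))

    matrix.to_dataframe("r").to_csv(out / "mtmm.csv")
    matrix.to_dataframe("p").to_csv(out / "mtmm_pvalues.csv")
    validity = run_stage("validity", lambda: evaluate_validity(matrix, config.alpha))
    (out / "validity.json").write_text(validity.to_json())
    (out / "validity.txt").write_text(validity.to_text())

    if scored is not None and not config.mtmm_only:
        battery = run_stage("battery", lambda: run_prediction_battery(
            scored, mode=config.battery_mode))
        battery.to_csv(out / "battery_long.csv", index=False)
        battery_wide(battery).to_csv(out / "battery_wide.csv")

    manifest = {
        "package_version": crowdval.__version__,
        "config_hash": _config_hash(config),
        "seed": config.cohort.seed if config.cohort else None,
        "alpha": config.alpha,
        "omega_method": config.omega_method,
        "battery_mode": config.battery_mode,
        "mtmm_only": config.mtmm_only,
        "use_published_matrix": config.use_published_matrix,
        "n_respondents": int(len(scored)) if scored is not None else None,
        "n_rejected_rows": len(row_errors),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    bundle = ReportBundle(config=config, scored=scored, descriptives=descriptives,
                          reliability=reliab, matrix=matrix, validity=validity,
                          battery=battery, manifest=manifest, row_errors=row_errors)
    write_report(bundle, out / "report.txt")
    return bundle


def write_report(bundle: ReportBundle, path: str | Path) -> str:
    """Render a human-readable summary (matrix and battery layouts included)."""
    lines = ["Peer-crowd instrument validation report",
             "=" * 40, ""]
    lines.append(f"config hash: {bundle.manifest['config_hash']}")
    lines.append(f"seed: {bundle.manifest['seed']}")
    lines.append("")
    if bundle.row_errors:
        lines.append(f"Rejected input rows: {len(bundle.row_errors)}")
        for e in bundle.row_errors:
            lines.append(f"  line {e['line']}: {e['error']}")
        lines.append("")
    if bundle.descriptives is not None:
        lines.append("Sample descriptives")
        lines.append(bundle.descriptives.to_string(index=False,
                                                   float_format=lambda v: f"{v:.2f}"))
        lines.append("")
    lines.append("Multi-trait multi-method matrix (diagonal = omega)")
    lines.append(bundle.matrix.to_dataframe("r").round(3).to_string())
    lines.append("")
    lines.append(bundle.validity.to_text())
    lines.append("")
    if bundle.battery is not None:
        failed = bundle.battery[bundle.battery["error"] != ""]
        lines.append("Prediction battery (AOR for behaviors, B otherwise)")
        lines.append(battery_wide(bundle.battery).round(3).to_string())
        if len(failed):
            lines.append("")
            lines.append("Failed battery cells:")
            for r in failed.itertuples():
                lines.append(f"  {r.instrument} {r.crowd} -> {r.outcome}: {r.error}")
        lines.append("")
    text = "\n".join(lines)
    Path(path).write_text(text)
    return text
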