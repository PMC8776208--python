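"""CSV schema validation and the staged pipeline runner.

The pipeline ties the five stages together — simulate (or load) → nightly →
daily → windows → models — writing each stage's CSV, refusing floor-flagged
outcomes, and recording a JSON run manifest (config hash, seed, per-file
content hashes, warnings) so a rerun with the same config is verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import association_models as am
from . import daily_features, questionnaire, trend_windows
from .config import RunConfig
from .synthetic import simulate_cohort

logger = logging.getLogger(__name__)

#: Per-schema required columns and duplicate-detection keys.
SCHEMAS: dict[str, dict] = {
    "ibi": {
        "columns": ["participant_id", "night_date", "t_seconds", "ibi_ms"],
        "keys": None,
    },
    "nightly_hrv": {
        "columns": ["participant_id", "night_date", "rmssd_ms", "ln_rmssd",
                    "n_valid_segments", "n_total_segments"],
        "keys": ["participant_id", "night_date"],
    },
    "ema": {"columns": ["participant_id", "timestamp", "drinks"], "keys": None},
    "activity": {
        "columns": ["participant_id", "date", "tst_min", "mvpa_min"],
        "keys": ["participant_id", "date"],
    },
    "daily": {
        "columns": daily_features.DAILY_COLUMNS,
        "keys": ["participant_id", "date"],
    },
    "fdsq_scores": {
        "columns": ["participant_id", "date", "stress", "anxiety", "depression", "somatisation"],
        "keys": ["participant_id", "date"],
    },
    "fdsq_responses": {
        "columns": ["participant_id", "date"] + [f"item_{i}" for i in range(1, 51)],
        "keys": ["participant_id", "date"],
    },
    "windows": {
        "columns": ["participant_id", "start_date", "end_date"]
        + trend_windows.CHANGE_COLUMNS + trend_windows.TREND_COLUMNS,
        "keys": ["participant_id", "start_date"],
    },
}

_DATE_COLUMNS = {"night_date", "date", "start_date", "end_date", "timestamp"}


class SchemaError(ValueError):
    pass


def validate_csv(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a pipeline CSV against its named schema.

    Checks required columns, parseability of date/time columns, and duplicate
    keys; logs the row count.  Returns the parsed table.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    rules = SCHEMAS[schema]
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in rules["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for schema {schema!r}")
    for col in set(rules["columns"]) & _DATE_COLUMNS:
        try:
            pd.to_datetime(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column {col!r} is not ISO-8601 parseable: {exc}") from exc
    if rules["keys"]:
        dup = df.duplicated(subset=rules["keys"])
        if dup.any():
            key = tuple(df.loc[dup, rules["keys"]].iloc[0])
            raise SchemaError(f"{path}: duplicate key {key} on {rules['keys']}")
    logger.info("%s: %d rows, %d columns (schema %s)", path, len(df), len(df.columns), schema)
    return df


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute simulate → nightly → daily → windows → models; return manifest.

    Each stage writes its CSV under ``out_dir``.  Outcomes whose scale fails
    the floor-effect screen are refused (recorded in the manifest) unless
    listed in ``config.force_outcomes``.  The manifest records the config
    hash, seed, per-file SHA-256 hashes, refusals and warnings; identical
    config implies an identical manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    outputs: dict[str, str] = {}
    stage = "simulate"
    try:
        cohort = simulate_cohort(config.sim)
        _write_csv(cohort.nightly_hrv, out / "nightly_hrv.csv")
        _write_csv(cohort.ema, out / "ema.csv")
        _write_csv(cohort.activity, out / "activity.csv")
        _write_csv(cohort.responses, out / "fdsq_responses.csv")
        _write_csv(cohort.truth, out / "latent_truth.csv")

        stage = "daily"
        daily = daily_features.build_daily_table(
            cohort.nightly_hrv, cohort.ema, cohort.activity,
            window_days=config.window_days, min_obs=config.min_obs,
            include_current=config.include_current,
        )
        daily_out = daily.copy()
        daily_out["date"] = [d.isoformat() for d in daily_out["date"]]
        _write_csv(daily_out, out / "daily.csv")

        stage = "questionnaire"
        scored = questionnaire.score_table(cohort.responses)
        _write_csv(questionnaire.scores_frame(scored), out / "fdsq_scores.csv")

        stage = "windows"
        windows = trend_windows.assemble_windows(daily, scored, config.min_trend_obs)
        wtable = trend_windows.windows_table(windows)
        _write_csv(wtable, out / "windows.csv")

        stage = "model"
        floor_reports = {}
        for scale in questionnaire.SCALES:
            all_scores = [getattr(s, scale) for pid in scored for s in scored[pid]]
            floor_reports[scale] = questionnaire.floor_effect_check(
                all_scores, scale, config.floor_threshold
            )
        model_summaries: dict[str, dict] = {}
        refusals: dict[str, str] = {}
        for scale in config.outcomes:
            outcome = f"{scale}_increase"
            report = floor_reports[scale]
            try:
                sample = am.standardize(wtable)
                fit = am.fit_hierarchical(
                    sample, outcome,
                    floor_flagged=report.flagged,
                    force=scale in config.force_outcomes,
                    cluster_robust=config.cluster_robust,
                )
            except am.FloorEffectRefusal as exc:
                refusals[scale] = str(exc)
                warnings.append(f"{scale}: {exc}")
                continue
            _write_csv(am.fit_summary_table(fit), out / f"model_{outcome}.csv")
            summary = am.fit_summary_dict(fit)
            (out / f"model_{outcome}.json").write_text(json.dumps(summary, indent=2) + "\n")
            profile = am.simple_slopes(fit)
            _write_csv(am.simple_slope_table(profile), out / f"interaction_{outcome}.csv")
            if config.make_plots:
                am.scatter_plot(sample, outcome, out / f"scatter_{outcome}.png")
                am.interaction_plot(profile, outcome, out / f"interaction_{outcome}.png")
            model_summaries[outcome] = summary
        _write_csv(am.correlation_table(am.standardize(wtable)), out / "correlations.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            outputs[f.name] = _sha256(f)
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_windows": len(wtable),
        "floor_flagged": sorted(s for s, r in floor_reports.items() if r.flagged),
        "refusals": refusals,
        "models": sorted(model_summaries),
        "outputs": outputs,
        "warnings": warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
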