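"""End-to-end benchmark orchestration.

``run_benchmark`` sweeps a cohort (synthetic or minute-CSV) over
signals x resolutions x cross-validation methods x prediction types:
reduce resolution, apply the gap rule, model the longest contiguous
segment, run the chosen CV scheme, and collect metric rows, stationarity
diagnostics and (optionally) full prediction traces.  Outputs are plain
CSV/JSON files; metrics.csv is bit-deterministic given config + seed
(wall-clock timings go to timings.csv and the manifest instead).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .arima import OrderGrid
from .derive import MINUTE_COLUMNS, derive_minute_record
from .metrics import (
    MetricRow,
    metric_row_from_trace,
    summarize_cohort,
    heatmap_table,
)
from .resolution import (
    RESOLUTION_LADDER,
    SIGNAL_NAMES,
    adf_test,
    kpss_test,
    handle_gaps,
    longest_segment,
    reduce_resolution,
)
from .simulate import SimulationConfig, WaveformRecord, generate_patient_waveforms
from .splits import (
    METHODS,
    blocked_folds,
    one_step_folds,
    run_interval_cv,
    run_point_cv,
    tss_folds,
)

__all__ = [
    "RunConfig",
    "run_benchmark",
    "generate_cohort",
    "load_minute_csv",
    "write_minute_csv",
    "write_waveform_csv",
    "load_waveform_csv",
]

logger = logging.getLogger(__name__)

PREDICTION_TYPES = ("point", "interval")


@dataclass
class RunConfig:
    """Validated configuration of one benchmark run."""

    out_dir: str = "neurocast_run"
    seed: int = 0
    n_patients: int = 5
    duration_minutes: float = 720.0
    csv_dir: Optional[str] = None  # if set, load minute CSVs instead of simulating
    patient_overrides: dict = field(default_factory=dict)
    signals: tuple[str, ...] = SIGNAL_NAMES
    resolutions: tuple[int, ...] = RESOLUTION_LADDER
    methods: tuple[str, ...] = METHODS
    prediction_types: tuple[str, ...] = PREDICTION_TYPES
    grid_p: tuple[int, ...] = tuple(range(1, 11))
    grid_d: tuple[int, ...] = (0, 1, 2)
    grid_q: tuple[int, ...] = tuple(range(0, 11))
    horizon: int = 5
    level: float = 0.95
    n_folds: int = 5
    min_points: int = 30
    save_traces: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for s in self.signals:
            if s not in SIGNAL_NAMES:
                raise ValueError(f"unknown signal {s!r}; allowed: {SIGNAL_NAMES}")
        for r in self.resolutions:
            if r not in RESOLUTION_LADDER:
                raise ValueError(f"resolution {r} not in the ladder {RESOLUTION_LADDER}")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; allowed: {METHODS}")
        for t in self.prediction_types:
            if t not in PREDICTION_TYPES:
                raise ValueError(f"unknown prediction type {t!r}")
        if self.horizon < 1 or not (0 < self.level < 1) or self.n_folds < 2:
            raise ValueError("invalid horizon/level/n_folds")

    @property
    def grid(self) -> OrderGrid:
        return OrderGrid(p=tuple(self.grid_p), d=tuple(self.grid_d), q=tuple(self.grid_q))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key in (
            "signals",
            "resolutions",
            "methods",
            "prediction_types",
            "grid_p",
            "grid_d",
            "grid_q",
        ):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def generate_cohort(config: RunConfig) -> list[WaveformRecord]:
    """Simulate the cohort with per-patient child seeds from the run seed."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    records = []
    for i, child in enumerate(children):
        pid = f"synthetic-{i:03d}"
        overrides = dict(config.patient_overrides.get(pid, {}))
        overrides.setdefault("duration_minutes", config.duration_minutes)
        overrides["seed"] = int(child.generate_state(1)[0] % (2**31))
        sim = SimulationConfig(**overrides)
        records.append(generate_patient_waveforms(sim, patient_id=pid))
    return records


# ---------------------------------------------------------------------------
# minute CSV exchange format


def write_minute_csv(table: pd.DataFrame, path: "str | Path") -> None:
    """Write a minute table; missing values become empty fields."""
    if list(table.columns) != MINUTE_COLUMNS:
        raise ValueError(f"table columns must be exactly {MINUTE_COLUMNS}")
    table.to_csv(path, index=False, na_rep="")


def load_minute_csv(path: "str | Path") -> pd.DataFrame:
    """Read a minute table, enforcing the exact column schema.

    Extra or misnamed columns are rejected with a named-column diagnostic;
    malformed rows raise with their line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    cols = header.split(",")
    unexpected = [c for c in cols if c not in MINUTE_COLUMNS]
    missing = [c for c in MINUTE_COLUMNS if c not in cols]
    if unexpected or missing:
        raise ValueError(
            f"{path.name}: unexpected columns {unexpected}, missing columns {missing}"
        )
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        logger.warning("%s: empty data section", path.name)
        return pd.DataFrame({c: pd.Series(dtype=float) for c in MINUTE_COLUMNS}).astype(
            {"minute": int}
        )
    for line_no, value in zip(df.index + 2, df["minute"]):
        if not float(value).is_integer():
            raise ValueError(f"{path.name}: malformed minute index on line {line_no}")
    df["minute"] = df["minute"].astype(int)
    for col in MINUTE_COLUMNS[1:]:
        bad = df[col].apply(
            lambda v: not (isinstance(v, (int, float, np.floating, np.integer)))
        )
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(f"{path.name}: malformed value in column {col} on line {line}")
        df[col] = df[col].astype(float)
    return df


def write_waveform_csv(record: WaveformRecord, out_dir: "str | Path") -> list[Path]:
    """Per-channel CSV export: sample_index, value, missing_flag."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in record.channel_names():
        df = pd.DataFrame(
            {
                "sample_index": np.arange(record.n_samples),
                "value": record.channel(name),
                "missing_flag": record.missing_mask[name].astype(int),
            }
        )
        p = out_dir / f"{record.patient_id}_{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


def load_waveform_csv(
    patient_id: str, in_dir: "str | Path", sampling_rate: float
) -> WaveformRecord:
    """Rebuild a WaveformRecord from per-channel CSVs written by this package."""
    in_dir = Path(in_dir)
    channels = {}
    masks = {}
    for name in ("abp", "icp", "pbto2"):
        p = in_dir / f"{patient_id}_{name}.csv"
        if not p.exists():
            if name == "pbto2":
                continue
            raise FileNotFoundError(p)
        df = pd.read_csv(p)
        channels[name] = df["value"].to_numpy(dtype=float)
        masks[name] = df["missing_flag"].to_numpy(dtype=bool)
    return WaveformRecord(
        patient_id=patient_id,
        sampling_rate=sampling_rate,
        abp=channels["abp"],
        icp=channels["icp"],
        pbto2=channels.get("pbto2"),
        missing_mask=masks,
    )


# ---------------------------------------------------------------------------
# the sweep


def _diagnostics_row(pid: str, signal: str, resolution: int, segment: np.ndarray) -> dict:
    row = {
        "patient_id": pid,
        "signal_name": signal,
        "resolution": resolution,
        "n": len(segment),
        "adf_stat": np.nan,
        "adf_reject": np.nan,
        "kpss_stat": np.nan,
        "kpss_reject": np.nan,
        "lags": np.nan,
    }
    try:
        adf = adf_test(segment)
        row.update(
            adf_stat=adf.adf_statistic,
            adf_reject=adf.adf_reject_unit_root,
            lags=adf.lags_used,
        )
        kpss = kpss_test(segment)
        row.update(kpss_stat=kpss.kpss_statistic, kpss_reject=kpss.kpss_reject_stationarity)
    except ValueError as exc:
        logger.info("diagnostics skipped for %s/%s@%d: %s", pid, signal, resolution, exc)
    return row


def run_benchmark(config: RunConfig) -> Path:
    """Run the full sweep and write outputs under ``config.out_dir``.

    Returns the output directory.  Partial failures are isolated per
    (patient, signal, resolution) and logged; only configuration errors
    abort the run.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_seconds: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.csv_dir is not None:
        minute_tables = {
            p.stem: load_minute_csv(p) for p in sorted(Path(config.csv_dir).glob("*.csv"))
        }
    else:
        minute_tables = {}
        for record in generate_cohort(config):
            minute_tables[record.patient_id] = derive_minute_record(record)
    stage_seconds["cohort_and_derivation"] = time.perf_counter() - t0

    rows: list[MetricRow] = []
    diag_rows: list[dict] = []
    traces_dir = out_dir / "traces"
    if config.save_traces:
        traces_dir.mkdir(exist_ok=True)

    t0 = time.perf_counter()
    for pid, table in minute_tables.items():
        for signal in config.signals:
            minute_values = table[signal].to_numpy(dtype=float)
            for resolution in config.resolutions:
                try:
                    series = handle_gaps(
                        reduce_resolution(minute_values, resolution, signal)
                    )
                    segment = longest_segment(series)
                except Exception as exc:
                    logger.warning("%s/%s@%d: preprocessing failed (%s)", pid, signal, resolution, exc)
                    continue
                if len(series.segment_bounds) > 1:
                    logger.info(
                        "%s/%s@%d: %d segments after gap removal; modeling the longest (%d points)",
                        pid, signal, resolution, len(series.segment_bounds), len(segment),
                    )
                if len(segment) < config.min_points:
                    logger.info(
                        "%s/%s@%d skipped: %d points < min_points=%d",
                        pid, signal, resolution, len(segment), config.min_points,
                    )
                    continue
                diag_rows.append(_diagnostics_row(pid, signal, resolution, segment))
                for method in config.methods:
                    for ptype in config.prediction_types:
                        if ptype == "interval" and method == "blocked":
                            continue  # point-prediction only
                        try:
                            t_start = time.perf_counter()
                            if ptype == "point":
                                if method == "one_step":
                                    plan = one_step_folds(len(segment), config.n_folds)
                                elif method == "blocked":
                                    plan = blocked_folds(len(segment), config.n_folds)
                                else:
                                    plan = tss_folds(len(segment), config.n_folds)
                                trace = run_point_cv(segment, plan, config.grid)
                            else:
                                trace = run_interval_cv(
                                    segment,
                                    method,
                                    horizon=config.horizon,
                                    level=config.level,
                                    grid=config.grid,
                                    n_splits=config.n_folds,
                                )
                            elapsed = time.perf_counter() - t_start
                        except Exception as exc:
                            logger.warning(
                                "%s/%s@%d %s/%s failed (%s)",
                                pid, signal, resolution, method, ptype, exc,
                            )
                            continue
                        rows.append(
                            metric_row_from_trace(
                                trace, pid, signal, resolution,
                                train_seconds=elapsed, test_seconds=0.0,
                            )
                        )
                        if config.save_traces:
                            trace.entries.to_csv(
                                traces_dir / f"{pid}_{signal}_{resolution}_{method}_{ptype}.csv",
                                index=False,
                            )
    stage_seconds["sweep"] = time.perf_counter() - t0

    metrics_df = pd.DataFrame([asdict(r) for r in rows])
    timing_cols = ["train_seconds", "test_seconds"]
    if not metrics_df.empty:
        metrics_df.drop(columns=timing_cols).to_csv(out_dir / "metrics.csv", index=False)
        metrics_df[
            ["patient_id", "signal_name", "resolution", "method", "prediction_type"]
            + timing_cols
        ].to_csv(out_dir / "timings.csv", index=False)
        summary = summarize_cohort(metrics_df)
        summary.to_csv(out_dir / "summary.csv", index=False)
        for method in config.methods:
            for ptype in config.prediction_types:
                if ptype == "interval" and method == "blocked":
                    continue
                table = heatmap_table(summary, method, ptype, "r2_mean")
                companion = heatmap_table(summary, method, ptype, "rmse_mean")
                if table.empty:
                    continue
                merged = pd.concat(
                    {"r2_mean": table, "rmse_mean": companion}, axis=1
                )
                merged.to_csv(out_dir / f"summary_{method}_{ptype}.csv")
    else:
        pd.DataFrame().to_csv(out_dir / "metrics.csv", index=False)
    pd.DataFrame(diag_rows).to_csv(out_dir / "diagnostics.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seconds": stage_seconds,
        "n_metric_rows": len(rows),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir
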