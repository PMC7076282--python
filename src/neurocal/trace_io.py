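"""Trace tables, epoch plans, and result tables.

The on-disk dialect is deliberately plain: UTF-8 delimiter-separated text
with a header row, first column ``time_s`` (seconds), one column per
ROI/cell (fluorescence, arbitrary units), ``.`` decimal separator. Lines
starting with ``#`` are schema/provenance comments and are skipped on read.
Ratiometric recordings use one file per excitation channel (340 nm, 380 nm)
with identical shape and time stamps, or a single long-format file with a
``channel`` column.

Epoch plans are YAML: an ordered list of labelled, non-overlapping, 0-based
half-open frame intervals ``[start_frame, end_frame)``, each annotated with
the treatment applied during the interval. Two presets mirror the standard
protocols: a 10-min Fluo-4 recording at 1 frame/s with a 4-min spontaneous
baseline followed by 4 min of TTX, and a 17-min Fura-2 SOCE run at 5 s/frame
with epochs of 12/84/60/24/24 frames (zero-Ca basal, thapsigargin store
release, Ca2+ add-back, ionomycin, EGTA).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

SCHEMA_COMMENT = "# neurocal table schema=1"

#: relative tolerance on |dt_i - median dt| for "uniform sampling"
DT_RTOL = 1e-6


class TraceIOError(ValueError):
    """Malformed trace table, epoch plan, or result table."""


@dataclass
class TraceSet:
    """A single-wavelength multi-ROI recording.

    ``values`` is frames x cells, fluorescence in a.u.; ``times`` in seconds,
    strictly increasing with uniform spacing ``dt``.
    """

    times: np.ndarray
    values: np.ndarray
    cell_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 2:
            raise TraceIOError("times must be 1-D and values 2-D")
        if self.values.shape != (self.times.size, len(self.cell_ids)):
            raise TraceIOError(
                f"shape mismatch: {self.values.shape} values vs "
                f"{self.times.size} times and {len(self.cell_ids)} cell ids"
            )
        if self.times.size < 2:
            raise TraceIOError("need at least 2 frames")
        if len(self.cell_ids) < 1:
            raise TraceIOError("need at least 1 cell")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise TraceIOError("cell ids must be unique")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise TraceIOError("non-finite values in trace")
        _check_uniform(self.times)
        self.meta.setdefault("dt", float(np.median(np.diff(self.times))))

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def dt(self) -> float:
        return float(self.meta["dt"])


@dataclass
class RatioTraceSet:
    """A dual-excitation (340/380 nm) recording: one matrix per channel."""

    times: np.ndarray
    f340: np.ndarray
    f380: np.ndarray
    cell_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f340 = np.asarray(self.f340, dtype=float)
        self.f380 = np.asarray(self.f380, dtype=float)
        if self.f340.shape != self.f380.shape:
            raise TraceIOError(
                f"channel shape mismatch: f340 {self.f340.shape} vs f380 {self.f380.shape}"
            )
        if self.f340.shape != (self.times.size, len(self.cell_ids)):
            raise TraceIOError("channel shape does not match times/cell_ids")
        if not (np.all(np.isfinite(self.f340)) and np.all(np.isfinite(self.f380))):
            raise TraceIOError("non-finite values in ratio trace")
        _check_uniform(self.times)
        self.meta.setdefault("dt", float(np.median(np.diff(self.times))))
        # zero/negative F380 makes the ratio undefined; flag, never drop
        bad = np.where((self.f380 <= 0).any(axis=0))[0]
        self.meta["f380_nonpositive_cells"] = [self.cell_ids[i] for i in bad]

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def dt(self) -> float:
        return float(self.meta["dt"])


@dataclass(frozen=True)
class Epoch:
    label: str
    start_frame: int  # inclusive
    end_frame: int    # exclusive
    treatment: str = ""

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    def frames(self) -> np.ndarray:
        return np.arange(self.start_frame, self.end_frame)


@dataclass
class EpochPlan:
    """Ordered, labelled, non-overlapping 0-based half-open frame intervals."""

    epochs: list[Epoch]
    dt: float | None = None

    def __post_init__(self) -> None:
        if not self.epochs:
            raise TraceIOError("epoch plan is empty")
        labels = [e.label for e in self.epochs]
        if len(set(labels)) != len(labels):
            raise TraceIOError(f"duplicate epoch labels: {labels}")
        prev = self.epochs[0]
        if prev.start_frame < 0 or prev.end_frame <= prev.start_frame:
            raise TraceIOError(f"epoch '{prev.label}' has an invalid frame range")
        for e in self.epochs[1:]:
            if e.end_frame <= e.start_frame:
                raise TraceIOError(f"epoch '{e.label}' has an invalid frame range")
            if e.start_frame < prev.end_frame:
                raise TraceIOError(
                    f"epochs '{prev.label}' and '{e.label}' overlap or are out of order"
                )
            prev = e

    def __getitem__(self, label: str) -> Epoch:
        for e in self.epochs:
            if e.label == label:
                return e
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(e.label == label for e in self.epochs)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.epochs]

    @property
    def n_frames(self) -> int:
        """Frames up to the end of the last epoch."""
        return self.epochs[-1].end_frame

    def total_duration_s(self) -> float:
        if self.dt is None:
            raise TraceIOError("epoch plan has no dt; cannot convert frames to seconds")
        return sum(e.n_frames for e in self.epochs) * self.dt

    def validate_against(self, n_frames: int) -> None:
        if self.epochs[-1].end_frame > n_frames:
            raise TraceIOError(
                f"epoch '{self.epochs[-1].label}' ends at frame "
                f"{self.epochs[-1].end_frame} but the recording has {n_frames} frames"
            )


def _check_uniform(times: np.ndarray) -> None:
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        i = int(np.argmax(diffs <= 0))
        raise TraceIOError(f"times not strictly increasing at interval {i} -> {i + 1}")
    med = float(np.median(diffs))
    dev = np.abs(diffs - med)
    if np.any(dev > DT_RTOL * med):
        i = int(np.argmax(dev))
        raise TraceIOError(
            f"non-uniform sampling: interval {i} -> {i + 1} is {diffs[i]:.9g} s "
            f"vs median {med:.9g} s"
        )


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    sep = {"csv": ",", "tsv": "\t", None: _sep_for(path)}[dialect]
    try:
        df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    except (ValueError, OSError) as exc:
        raise TraceIOError(f"cannot parse table {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise TraceIOError(f"{path}: need a time column plus at least one ROI column")
    return df


def _coerce_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    if out.isna().to_numpy().any():
        rows, cols = np.where(out.isna().to_numpy())
        r, c = int(rows[0]), int(cols[0])
        raise TraceIOError(
            f"{path}: non-numeric value at data row {r}, column '{df.columns[c]}'"
        )
    return out


def read_trace_table(path: str | Path, dialect: str | None = None,
                     meta: dict | None = None) -> TraceSet:
    """Read a wide trace table (first column time in s, one column per ROI)."""
    df = _coerce_numeric(_read_table(path, dialect), path)
    times = df.iloc[:, 0].to_numpy(float)
    values = df.iloc[:, 1:].to_numpy(float)
    cell_ids = [str(c) for c in df.columns[1:]]
    return TraceSet(times=times, values=values, cell_ids=cell_ids, meta=dict(meta or {}))


def read_ratio_table(path340: str | Path, path380: str | Path | None = None,
                     dialect: str | None = None, meta: dict | None = None) -> RatioTraceSet:
    """Read a two-channel recording.

    Either two wide files (one per channel, identical times and columns) or a
    single long-format file with columns ``time_s, channel, cell, value``
    where channel is 340 or 380.
    """
    if path380 is None:
        df = _read_table(path340, dialect)
        required = {"time_s", "channel", "cell", "value"}
        if not required.issubset(df.columns):
            raise TraceIOError(
                f"{path340}: single-file ratio input needs columns {sorted(required)}"
            )
        wide = df.pivot_table(index="time_s", columns=["channel", "cell"],
                              values="value", sort=False)
        wide = wide.sort_index()
        ch = sorted({c for c, _ in wide.columns})
        if len(ch) != 2:
            raise TraceIOError(f"{path340}: expected exactly 2 channels, found {ch}")
        c340 = wide[[c for c in wide.columns if str(c[0]).startswith("340")
                     or c[0] in (340, "340")]]
        c380 = wide[[c for c in wide.columns if str(c[0]).startswith("380")
                     or c[0] in (380, "380")]]
        cell_ids = [str(c[1]) for c in c340.columns]
        if [str(c[1]) for c in c380.columns] != cell_ids:
            raise TraceIOError(f"{path340}: channel cell sets differ")
        return RatioTraceSet(times=wide.index.to_numpy(float),
                             f340=c340.to_numpy(float), f380=c380.to_numpy(float),
                             cell_ids=cell_ids, meta=dict(meta or {}))

    t340 = read_trace_table(path340, dialect)
    t380 = read_trace_table(path380, dialect)
    if t340.values.shape != t380.values.shape:
        raise TraceIOError(
            f"channel shape mismatch: {path340} has {t340.values.shape}, "
            f"{path380} has {t380.values.shape}"
        )
    if not np.allclose(t340.times, t380.times, rtol=0, atol=1e-9):
        raise TraceIOError("channel time stamps differ")
    if t340.cell_ids != t380.cell_ids:
        raise TraceIOError("channel cell ids differ")
    return RatioTraceSet(times=t340.times, f340=t340.values, f380=t380.values,
                         cell_ids=t340.cell_ids, meta=dict(meta or {}))


def read_epoch_plan(config: str | Path | dict, strict: bool = False) -> EpochPlan:
    """Build an EpochPlan from YAML (path or already-parsed mapping).

    Each epoch entry carries ``label`` and ``treatment`` plus either
    ``start_frame``/``end_frame``, ``duration_frames``, or ``duration_s``
    (the last requires a top-level ``dt``). Durations are laid out
    consecutively after the previous epoch. With ``strict=True``, gaps
    between consecutive epochs are rejected too.
    """
    if isinstance(config, (str, Path)):
        if isinstance(config, str) and "\n" in config:
            cfg = yaml.safe_load(io.StringIO(config))
        else:
            with open(config, "r", encoding="utf-8") as fh:
                cfg = yaml.safe_load(fh)
    else:
        cfg = config
    if not isinstance(cfg, dict) or "epochs" not in cfg:
        raise TraceIOError("epoch plan config must be a mapping with an 'epochs' list")
    dt = cfg.get("dt")
    epochs: list[Epoch] = []
    cursor = 0
    for entry in cfg["epochs"]:
        label = str(entry["label"])
        treatment = str(entry.get("treatment", ""))
        if "start_frame" in entry and "end_frame" in entry:
            start, end = int(entry["start_frame"]), int(entry["end_frame"])
        elif "duration_frames" in entry:
            start, end = cursor, cursor + int(entry["duration_frames"])
        elif "duration_s" in entry:
            if dt is None:
                raise TraceIOError(
                    f"epoch '{label}' uses duration_s but the plan has no dt"
                )
            n = float(entry["duration_s"]) / float(dt)
            if abs(n - round(n)) > 1e-9:
                raise TraceIOError(
                    f"epoch '{label}': duration_s {entry['duration_s']} is not a "
                    f"multiple of dt {dt}"
                )
            start, end = cursor, cursor + int(round(n))
        else:
            raise TraceIOError(
                f"epoch '{label}' needs start/end frames or a duration"
            )
        if strict and epochs and start != cursor:
            raise TraceIOError(
                f"gap before epoch '{label}' (frames {cursor}..{start}) in strict mode"
            )
        epochs.append(Epoch(label, start, end, treatment))
        cursor = end
    plan = EpochPlan(epochs=epochs, dt=float(dt) if dt is not None else None)
    if "n_frames" in cfg:
        plan.validate_against(int(cfg["n_frames"]))
    return plan


def fluo4_epoch_plan(dt: float = 1.0, baseline_s: float = 240.0,
                     treatment_s: float = 240.0, treatment: str = "TTX") -> EpochPlan:
    """Preset: 4-min spontaneous baseline, then an activity-blocking treatment."""
    return read_epoch_plan({
        "dt": dt,
        "epochs": [
            {"label": "baseline", "treatment": "none", "duration_s": baseline_s},
            {"label": "treatment", "treatment": treatment, "duration_s": treatment_s},
        ],
    })


def soce_epoch_plan(dt: float = 5.0,
                    frames: Sequence[int] = (12, 84, 60, 24, 24)) -> EpochPlan:
    """Preset SOCE plan: basal / thapsigargin / Ca2+ add-back / ionomycin / EGTA.

    Default frame counts 12/84/60/24/24 at 5 s per frame (17 min total).
    """
    labels = [("basal", "zero-Ca HBSS"), ("tg", "thapsigargin 10 uM"),
              ("caadd", "CaCl2 2 mM"), ("iono", "ionomycin 20 uM"),
              ("egta", "EGTA 4 mM + Triton")]
    if len(frames) != 5:
        raise TraceIOError("SOCE preset needs exactly 5 epoch frame counts")
    return read_epoch_plan({
        "dt": dt,
        "epochs": [
            {"label": lab, "treatment": trt, "duration_frames": int(n)}
            for (lab, trt), n in zip(labels, frames)
        ],
    })


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  dialect: str = "tsv") -> list[Path]:
    """Write result tables with a schema comment line; returns written paths.

    Column order is whatever the DataFrame carries (our producers use fixed
    orders); full float precision via repr round-trip.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sep = "," if dialect == "csv" else "\t"
    ext = "csv" if dialect == "csv" else "tsv"
    written = []
    for name, df in tables.items():
        if df.columns.empty:
            raise TraceIOError(f"table '{name}' has no columns")
        path = out_dir / f"{name}.{ext}"
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(SCHEMA_COMMENT + f" table={name}\n")
            # %.17g round-trips any float64 exactly
            df.to_csv(fh, sep=sep, index=False, float_format="%.17g")
        written.append(path)
    return written


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep=_sep_for(path), comment="#",
                       float_precision="round_trip")


def write_trace_table(trace: TraceSet, path: str | Path) -> Path:
    """Write a TraceSet in the wide dialect read_trace_table reads."""
    path = Path(path)
    df = pd.DataFrame(trace.values, columns=trace.cell_ids)
    df.insert(0, "time_s", trace.times)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")
    return path


def write_ratio_tables(rt: RatioTraceSet, path340: str | Path,
                       path380: str | Path) -> tuple[Path, Path]:
    """Write a RatioTraceSet as two wide channel files."""
    p340 = write_trace_table(
        TraceSet(rt.times, rt.f340, rt.cell_ids, dict(rt.meta)), path340)
    p380 = write_trace_table(
        TraceSet(rt.times, rt.f380, rt.cell_ids, dict(rt.meta)), path380)
    return p340, p380
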