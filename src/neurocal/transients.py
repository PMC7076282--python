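"""Spontaneous Ca2+ transient detection and summarisation.

The pipeline follows the standard single-wavelength workflow for somatic
transients in cultured neurons:

1. normalise every cell to its first baseline frame: ``norm = F / F0``,
   ``dff = norm - 1``;
2. take the raw first difference of dff (no smoothing by default);
3. set a per-cell threshold at ``mean + k_sd * SD`` (population SD) of the
   derivative over transient-free ("quiet") frames, either given explicitly
   or found by iterative exclusion;
4. group supra-threshold derivative runs into events with an onset, a peak,
   and an amplitude measured as peak dff minus a local pre-onset median;
5. summarise per cell: spikes per 4-min window, amplitude list, and whether
   a treatment epoch (e.g. TTX) abolished activity.

Amplitude distributions are binned into proportion histograms with explicit
underflow/overflow bins so proportions always sum to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from neurocal.trace_io import TraceSet, EpochPlan

__all__ = [
    "NormalizedTrace", "DetectionParams", "TransientEvent",
    "CellActivitySummary", "AmplitudeHistogram",
    "normalize", "first_derivative", "estimate_threshold",
    "detect_events", "summarize_activity", "bin_amplitudes",
    "events_to_frame", "summaries_to_frame",
]

MIN_QUIET_FRAMES = 5


@dataclass
class NormalizedTrace:
    """F/F0-normalised recording; ``dff = norm - 1`` elementwise."""

    times: np.ndarray
    norm: np.ndarray          # frames x cells, F/F0
    dff: np.ndarray           # frames x cells, F/F0 - 1
    f0: np.ndarray            # per-cell reference intensity, a.u.
    cell_ids: list[str]
    reference_frame: int
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass
class DetectionParams:
    """Knobs of the derivative-threshold detector.

    ``k_sd`` is the SD multiplier of the event criterion (mean + k_sd * SD of
    the quiet-region derivative; default 2). ``quiet_region`` is either an
    explicit frame index array (derivative-index space) or ``"auto"``, which
    iterates from the baseline frames, excluding supra-threshold frames until
    a fixpoint. ``stat_on`` selects where the threshold statistics are
    computed: on the ``"derivative"`` (default) or on the normalised
    ``"intensity"`` itself — an alternative reading of the same criterion.
    """

    k_sd: float = 2.0
    quiet_region: np.ndarray | str = "auto"
    min_separation: int = 2
    min_event_frames: int = 1
    local_baseline_window: int = 5
    max_auto_iterations: int = 10
    stat_on: str = "derivative"
    smooth_window: int = 1          # moving-average pre-filter; 1 = off

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be > 0")
        for name in ("min_separation", "min_event_frames",
                     "local_baseline_window", "max_auto_iterations",
                     "smooth_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.stat_on not in ("derivative", "intensity"):
            raise ValueError("stat_on must be 'derivative' or 'intensity'")


@dataclass(frozen=True)
class TransientEvent:
    cell_id: str
    onset_frame: int
    peak_frame: int
    amplitude: float      # dF/F0 units: peak dff minus local pre-onset median
    duration: int         # frames with derivative above threshold

    def __post_init__(self) -> None:
        if self.peak_frame < self.onset_frame:
            raise ValueError("peak before onset")
        if not np.isfinite(self.amplitude):
            raise ValueError("non-finite amplitude")


@dataclass
class CellActivitySummary:
    cell_id: str
    spikes_per_4min: int
    amplitudes: list[float]
    abolished: dict[str, bool]
    threshold_used: float


@dataclass
class AmplitudeHistogram:
    """Per-condition proportion histogram with explicit under/overflow bins."""

    bin_edges: np.ndarray
    proportions: dict[str, np.ndarray]   # condition -> len(edges)+1 proportions
    counts: dict[str, np.ndarray]

    @property
    def bin_labels(self) -> list[str]:
        e = self.bin_edges
        labels = [f"<{e[0]:g}"]
        labels += [f"[{a:g},{b:g})" for a, b in zip(e[:-1], e[1:])]
        labels += [f">={e[-1]:g}"]
        return labels

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin": self.bin_labels})
        for cond, p in self.proportions.items():
            df[cond] = p
        return df


def normalize(trace: TraceSet, reference_frame: int = 0) -> NormalizedTrace:
    """Normalise each cell to its intensity at ``reference_frame``.

    Cells whose reference intensity is zero or negative cannot be normalised;
    they are excluded from the returned matrices and recorded (cell id ->
    reason) in ``excluded``.
    """
    if not 0 <= reference_frame < trace.n_frames:
        raise ValueError(f"reference frame {reference_frame} outside recording")
    f0 = trace.values[reference_frame, :]
    keep = f0 > 0
    excluded = {cid: f"non-positive reference intensity {f0[i]:g}"
                for i, cid in enumerate(trace.cell_ids) if not keep[i]}
    values = trace.values[:, keep]
    f0k = f0[keep]
    norm = values / f0k
    return NormalizedTrace(
        times=trace.times.copy(), norm=norm, dff=norm - 1.0, f0=f0k.copy(),
        cell_ids=[cid for cid, k in zip(trace.cell_ids, keep) if k],
        reference_frame=reference_frame, excluded=excluded)


def first_derivative(nt: NormalizedTrace, smooth_window: int = 1) -> np.ndarray:
    """Frame-to-frame difference of dff: ``d[t] = dff[t+1] - dff[t]``.

    Length is frames - 1. ``smooth_window > 1`` applies a centred moving
    average to dff before differencing (off by default).
    """
    dff = nt.dff
    if dff.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        dff = np.apply_along_axis(
            lambda x: np.convolve(x, kernel, mode="same"), 0, dff)
    return np.diff(dff, axis=0)


def _population_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=0))


def estimate_threshold(d: np.ndarray, params: DetectionParams,
                       baseline_frames: np.ndarray | None = None,
                       nt: NormalizedTrace | None = None) -> np.ndarray:
    """Per-cell event threshold: mean + k_sd * population SD over quiet frames.

    Statistics are computed on the derivative matrix ``d`` (default) or, with
    ``params.stat_on == "intensity"``, on the normalised intensity of ``nt``
    at the same frames. ``quiet_region`` may be an explicit index array into
    the derivative frames; in ``"auto"`` mode the quiet set starts from
    ``baseline_frames`` (all derivative frames if omitted) and frames above
    the current threshold are excluded iteratively until a fixpoint or
    ``max_auto_iterations``.
    """
    d = np.atleast_2d(d.T).T if d.ndim == 1 else d
    n_dframes, n_cells = d.shape
    if params.stat_on == "intensity":
        if nt is None:
            raise ValueError("stat_on='intensity' needs the NormalizedTrace")
        stat = nt.norm[:n_dframes, :]
    else:
        stat = d

    if isinstance(params.quiet_region, str):
        if params.quiet_region != "auto":
            raise ValueError(f"unknown quiet_region '{params.quiet_region}'")
        start = (np.arange(n_dframes) if baseline_frames is None
                 else np.asarray(baseline_frames, dtype=int))
        start = start[start < n_dframes]
        thresholds = np.empty(n_cells)
        for c in range(n_cells):
            quiet = start
            thr = _mean_sd_threshold(stat[quiet, c], params.k_sd, c, stat[:, c])
            for _ in range(params.max_auto_iterations):
                new_quiet = start[d[start, c] <= thr]
                if new_quiet.size < MIN_QUIET_FRAMES:
                    break  # keep last viable quiet set
                if new_quiet.size == quiet.size and np.array_equal(new_quiet, quiet):
                    break
                quiet = new_quiet
                thr = _mean_sd_threshold(stat[quiet, c], params.k_sd, c, stat[:, c])
            thresholds[c] = thr
        return thresholds

    quiet = np.asarray(params.quiet_region, dtype=int)
    if quiet.size < MIN_QUIET_FRAMES:
        raise ValueError(
            f"insufficient quiet frames: {quiet.size} < {MIN_QUIET_FRAMES}")
    if quiet.max(initial=-1) >= n_dframes or quiet.min(initial=0) < 0:
        raise ValueError("quiet region outside derivative range")
    return np.array([_mean_sd_threshold(stat[quiet, c], params.k_sd, c, stat[:, c])
                     for c in range(n_cells)])


def _mean_sd_threshold(x: np.ndarray, k_sd: float, cell: int,
                       full_column: np.ndarray | None = None) -> float:
    if x.size < MIN_QUIET_FRAMES:
        raise ValueError(
            f"insufficient quiet frames for cell {cell}: {x.size} < {MIN_QUIET_FRAMES}")
    mean, sd = float(np.mean(x)), _population_sd(x)
    if sd == 0 and full_column is not None \
            and not np.allclose(full_column, mean):
        warnings.warn(f"cell {cell}: quiet SD is 0 with signal elsewhere; "
                      "threshold = mean")
    return mean + k_sd * sd


def detect_events(nt: NormalizedTrace, d: np.ndarray, threshold: np.ndarray,
                  params: DetectionParams | None = None) -> list[TransientEvent]:
    """Group supra-threshold derivative runs into transient events.

    A run is a maximal stretch of derivative frames with ``d > threshold``
    (positive side only). Runs separated by fewer than ``min_separation``
    sub-threshold frames are merged; runs shorter than ``min_event_frames``
    are discarded. For each surviving run:

    * onset = the dff frame the first supra-threshold step rises into
      (run start + 1 in frame space);
    * peak = argmax of dff from onset through the post-run decay, up to
      dff's first local minimum after the run;
    * amplitude = dff[peak] minus the median dff over the
      ``local_baseline_window`` frames immediately before onset (clipped at
      the recording start);
    * duration = number of supra-threshold derivative frames in the run.
    """
    params = params or DetectionParams()
    d = np.atleast_2d(d.T).T if d.ndim == 1 else d
    threshold = np.asarray(threshold, dtype=float)
    if threshold.size != d.shape[1]:
        raise ValueError("need one threshold per cell")
    events: list[TransientEvent] = []
    for c, cid in enumerate(nt.cell_ids):
        runs = _threshold_runs(d[:, c], float(threshold[c]),
                               params.min_separation, params.min_event_frames)
        for start, end in runs:   # inclusive derivative indices
            events.append(_measure_event(nt.dff[:, c], cid, start, end,
                                         params.local_baseline_window))
    return events


def _threshold_runs(dcol: np.ndarray, thr: float, min_separation: int,
                    min_event_frames: int) -> list[tuple[int, int]]:
    """Maximal runs of d > thr, merged across gaps < min_separation,
    then filtered by min_event_frames. Inclusive index pairs."""
    above = dcol > thr
    if not above.any():
        return []
    idx = np.where(above)[0]
    runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        gap = int(i) - runs[-1][1] - 1
        if gap < min_separation:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    out = []
    for s, e in runs:
        n_above = int(above[s:e + 1].sum())
        if n_above >= min_event_frames:
            out.append((s, e))
    return out


def _measure_event(dff: np.ndarray, cell_id: str, run_start: int, run_end: int,
                   baseline_window: int) -> TransientEvent:
    n = dff.size
    onset = run_start + 1                     # frame the first rise lands on
    last_rise = min(run_end + 1, n - 1)       # frame the last rise lands on
    # walk down the decay to dff's first local minimum after the run
    m = last_rise
    while m + 1 < n and dff[m + 1] < dff[m]:
        m += 1
    peak = onset + int(np.argmax(dff[onset:m + 1]))
    lo = max(0, onset - baseline_window)
    local_base = float(np.median(dff[lo:onset])) if onset > lo else 0.0
    return TransientEvent(cell_id=cell_id, onset_frame=onset, peak_frame=peak,
                          amplitude=float(dff[peak]) - local_base,
                          duration=run_end - run_start + 1)


def summarize_activity(events: list[TransientEvent], plan: EpochPlan,
                       nt: NormalizedTrace, threshold: np.ndarray,
                       window_s: float = 240.0,
                       abolition_fraction: float = 0.0) -> list[CellActivitySummary]:
    """Per-cell spikes/4-min counts and treatment-abolition calls.

    The counting window starts at the first epoch's start and must fit inside
    it. A treatment epoch is "abolished" when its event rate is at most
    ``abolition_fraction`` times the baseline rate (default 0: strictly no
    events, the behaviour expected of complete TTX block).
    """
    dt = nt.dt
    base = plan.epochs[0]
    window_frames = window_s / dt
    if abs(window_frames - round(window_frames)) > 1e-9:
        raise ValueError("window is not a multiple of dt")
    window_frames = int(round(window_frames))
    if window_frames > base.n_frames:
        raise ValueError(
            f"window of {window_frames} frames exceeds epoch "
            f"'{base.label}' ({base.n_frames} frames)")
    win_lo, win_hi = base.start_frame, base.start_frame + window_frames

    by_cell: dict[str, list[TransientEvent]] = {cid: [] for cid in nt.cell_ids}
    for ev in events:
        by_cell[ev.cell_id].append(ev)

    treatments = plan.epochs[1:]
    summaries = []
    for c, cid in enumerate(nt.cell_ids):
        evs = by_cell[cid]
        in_window = [ev for ev in evs if win_lo <= ev.onset_frame < win_hi]
        base_rate = (sum(base.start_frame <= ev.onset_frame < base.end_frame
                         for ev in evs) / (base.n_frames * dt))
        abolished = {}
        for ep in treatments:
            rate = (sum(ep.start_frame <= ev.onset_frame < ep.end_frame
                        for ev in evs) / (ep.n_frames * dt))
            abolished[ep.label] = bool(rate <= abolition_fraction * base_rate)
        summaries.append(CellActivitySummary(
            cell_id=cid, spikes_per_4min=len(in_window),
            amplitudes=[ev.amplitude for ev in in_window],
            abolished=abolished, threshold_used=float(threshold[c])))
    return summaries


def bin_amplitudes(amplitudes_by_condition: dict[str, np.ndarray],
                   bin_edges: np.ndarray) -> AmplitudeHistogram:
    """Proportion histogram of event amplitudes per condition.

    Half-open bins [e_i, e_{i+1}); values below the first edge and at or
    above the last go to explicit underflow/overflow bins, so each
    condition's proportions sum to exactly 1.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be sorted and strictly increasing")
    proportions, counts = {}, {}
    for cond, amps in amplitudes_by_condition.items():
        amps = np.asarray(amps, dtype=float)
        if amps.size == 0:
            raise ValueError(f"condition '{cond}' has no events")
        inner = np.array([np.sum((amps >= a) & (amps < b))
                          for a, b in zip(edges[:-1], edges[1:])])
        under = int(np.sum(amps < edges[0]))
        over = int(np.sum(amps >= edges[-1]))
        cnt = np.concatenate([[under], inner, [over]])
        counts[cond] = cnt
        proportions[cond] = cnt / amps.size
    return AmplitudeHistogram(bin_edges=edges, proportions=proportions,
                              counts=counts)


def events_to_frame(events: list[TransientEvent]) -> pd.DataFrame:
    cols = ["cell_id", "onset_frame", "peak_frame", "amplitude", "duration"]
    return pd.DataFrame([{k: getattr(ev, k) for k in cols} for ev in events],
                        columns=cols)


def summaries_to_frame(summaries: list[CellActivitySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"cell_id": s.cell_id, "spikes_per_4min": s.spikes_per_4min,
               "threshold_used": s.threshold_used,
               "mean_amplitude": float(np.mean(s.amplitudes)) if s.amplitudes
               else np.nan}
        for label, val in s.abolished.items():
            row[f"abolished_{label}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
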