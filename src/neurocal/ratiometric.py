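"""Fura-2 ratiometric analysis and SOCE quantification.

The 340/380 excitation ratio R is converted to cytosolic free calcium with
the Grynkiewicz relation

    [Ca2+] (nM) = Kd * SF * (R - Rmin) / (Rmax - R),

where Kd is the dye dissociation constant (225 nM for Fura-2 in human
cells), Rmin and Rmax are the ratios of the Ca2+-free and Ca2+-saturated dye,
and SF is the per-cell scaling factor, the F380 emission of the free form
divided by the F380 emission of the bound form.

Calibration constants are estimated per cell from the two terminal epochs of
the SOCE protocol: ionomycin saturates the dye (provides Rmax and the bound
F380), EGTA + detergent strips Ca2+ (provides Rmin and the free F380). To
resist single-frame noise, extremes are taken as medians of the k most
extreme frames rather than a single frame.

Store-operated entry is summarised per cell as: basal (mean [Ca2+] over the
zero-Ca epoch), store release (thapsigargin-epoch peak minus basal), and
SOCE (Ca2+ add-back-epoch peak minus basal) — "rise above basal" in both
cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from neurocal.trace_io import RatioTraceSet, EpochPlan

__all__ = [
    "CalibrationParams", "CalciumConcTrace", "SOCESummary",
    "compute_ratio", "estimate_calibration", "grynkiewicz", "quantify_soce",
    "soce_summaries_to_frame", "DEFAULT_KD_NM",
]

#: Fura-2 dissociation constant in human cells, nM
DEFAULT_KD_NM = 225.0

FLAG_OK = 0
FLAG_SATURATED_HIGH = 1   # R >= rmax: concentration undefined
FLAG_BELOW_RMIN = 2       # R < rmin: clamped to 0
FLAG_BAD_F380 = 3         # f380 <= 0: ratio undefined


@dataclass
class CalibrationParams:
    """Per-cell Grynkiewicz constants. Arrays are aligned with cell order."""

    kd: float
    sf: np.ndarray
    rmin: np.ndarray
    rmax: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sf = np.atleast_1d(np.asarray(self.sf, dtype=float))
        self.rmin = np.atleast_1d(np.asarray(self.rmin, dtype=float))
        self.rmax = np.atleast_1d(np.asarray(self.rmax, dtype=float))
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if np.any(self.sf <= 0):
            raise ValueError("sf must be > 0")
        if self.valid is None:
            self.valid = self.rmin < self.rmax
        if np.any(self.rmin[self.valid] >= self.rmax[self.valid]):
            raise ValueError("rmin must be < rmax for valid cells")

    @property
    def n_cells(self) -> int:
        return self.sf.size


@dataclass
class CalciumConcTrace:
    """[Ca2+]i(t) in nM with per-frame quality flags."""

    times: np.ndarray
    conc: np.ndarray     # frames x cells, nM; NaN where undefined
    flags: np.ndarray    # frames x cells, FLAG_* codes
    cell_ids: list[str]

    def unflagged(self, frames: np.ndarray, cell: int) -> np.ndarray:
        sel = self.flags[frames, cell] == FLAG_OK
        return self.conc[frames[sel], cell]


@dataclass
class SOCESummary:
    cell_id: str
    basal_nM: float
    store_release_delta_nM: float
    soce_delta_nM: float
    flags: str = ""


def compute_ratio(rt: RatioTraceSet) -> tuple[np.ndarray, np.ndarray]:
    """340/380 ratio per frame and cell, with FLAG_BAD_F380 where f380 <= 0.

    Returns ``(R, flags)``; flagged entries hold NaN and are excluded from
    all downstream statistics.
    """
    flags = np.where(rt.f380 > 0, FLAG_OK, FLAG_BAD_F380).astype(np.int8)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(flags == FLAG_OK, rt.f340 / np.where(rt.f380 > 0, rt.f380, 1.0),
                     np.nan)
    return r, flags


def _median_top_k(x: np.ndarray, k: int) -> float:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan
    k = min(k, x.size)
    return float(np.median(np.sort(x)[-k:]))


def estimate_calibration(r: np.ndarray, rt: RatioTraceSet, plan: EpochPlan,
                         kd: float = DEFAULT_KD_NM,
                         k_frames: int = 5) -> CalibrationParams:
    """Per-cell Rmin, Rmax, SF from the ionomycin and EGTA epochs.

    * Rmax: median of the ``k_frames`` largest ratios in the ionomycin epoch.
    * Rmin: median of the last ``k_frames`` ratios of the EGTA epoch (the
      dye is fully stripped only at the end of the chelation step).
    * SF: median F380 over the EGTA window (Ca2+-free form) divided by the
      median F380 over the ionomycin window (Ca2+-bound form).

    Cells with Rmin >= Rmax are marked invalid, not dropped.
    """
    for label in ("iono", "egta"):
        if label not in plan:
            raise ValueError(f"epoch plan lacks required '{label}' epoch")
    iono, egta = plan["iono"], plan["egta"]
    plan.validate_against(rt.n_frames)
    n_cells = rt.n_cells
    rmax = np.empty(n_cells)
    rmin = np.empty(n_cells)
    sf = np.empty(n_cells)
    for c in range(n_cells):
        r_iono = r[iono.start_frame:iono.end_frame, c]
        r_egta = r[egta.start_frame:egta.end_frame, c]
        rmax[c] = _median_top_k(r_iono, k_frames)
        tail = r_egta[np.isfinite(r_egta)][-k_frames:]
        rmin[c] = float(np.median(tail)) if tail.size else np.nan
        f380_free = np.median(rt.f380[egta.start_frame:egta.end_frame, c])
        f380_bound = np.median(rt.f380[iono.start_frame:iono.end_frame, c])
        sf[c] = f380_free / f380_bound if f380_bound > 0 else np.nan
    valid = np.isfinite(rmin) & np.isfinite(rmax) & np.isfinite(sf) \
        & (rmin < rmax) & (sf > 0)
    sf = np.where(valid, sf, 1.0)  # placeholder for invalid cells
    return CalibrationParams(kd=kd, sf=sf, rmin=rmin, rmax=rmax, valid=valid)


def grynkiewicz(r: np.ndarray, params: CalibrationParams,
                ratio_flags: np.ndarray | None = None,
                times: np.ndarray | None = None,
                cell_ids: list[str] | None = None) -> CalciumConcTrace:
    """Convert 340/380 ratios to [Ca2+]i in nM.

    ``conc = kd * sf * (r - rmin) / (rmax - r)``. Frames with R >= Rmax are
    flagged saturated-high (conc NaN); frames with R < Rmin are flagged and
    clamped to 0 nM. Incoming ratio flags (bad F380) propagate.
    """
    r = np.atleast_2d(r.T).T if r.ndim == 1 else r
    n_frames, n_cells = r.shape
    if params.n_cells != n_cells:
        raise ValueError("calibration does not match cell count")
    rmin, rmax, sf = params.rmin, params.rmax, params.sf
    flags = np.zeros((n_frames, n_cells), dtype=np.int8)
    if ratio_flags is not None:
        flags = ratio_flags.astype(np.int8).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = params.kd * sf * (r - rmin) / (rmax - r)
    ok = flags == FLAG_OK
    sat = ok & (r >= rmax)
    low = ok & (r < rmin)
    flags[sat] = FLAG_SATURATED_HIGH
    flags[low] = FLAG_BELOW_RMIN
    conc[sat] = np.nan
    conc[low] = 0.0
    conc[~np.isfinite(r) & ok] = np.nan
    bad_cells = ~params.valid
    if bad_cells.any():
        conc[:, bad_cells] = np.nan
        flags[:, bad_cells] = FLAG_SATURATED_HIGH
    if times is None:
        times = np.arange(n_frames, dtype=float)
    if cell_ids is None:
        cell_ids = [f"cell{c:03d}" for c in range(n_cells)]
    return CalciumConcTrace(times=times, conc=conc, flags=flags,
                            cell_ids=cell_ids)


def quantify_soce(ct: CalciumConcTrace, plan: EpochPlan,
                  robust_peak: bool = False,
                  k_frames: int = 5) -> list[SOCESummary]:
    """Basal, store-release and SOCE amplitudes per cell.

    * basal = mean [Ca2+] over the basal epoch;
    * store_release_delta = peak [Ca2+] in the thapsigargin epoch - basal;
    * soce_delta = peak [Ca2+] in the add-back epoch - basal.

    Peaks are plain epoch maxima by default ("rise above basal");
    ``robust_peak=True`` uses the same median-of-top-k estimator as the
    calibration step. Flagged frames are excluded; a cell with every frame
    of a required epoch flagged is excluded with a reason in its flags field.
    """
    for label in ("basal", "tg", "caadd"):
        if label not in plan:
            raise ValueError(f"epoch plan lacks required '{label}' epoch")
    out = []
    for c, cid in enumerate(ct.cell_ids):
        vals = {}
        reason = ""
        for label in ("basal", "tg", "caadd"):
            ep = plan[label]
            good = ct.unflagged(ep.frames(), c)
            if good.size == 0:
                reason = f"all frames flagged in epoch '{label}'"
                break
            vals[label] = good
        if reason:
            out.append(SOCESummary(cell_id=cid, basal_nM=np.nan,
                                   store_release_delta_nM=np.nan,
                                   soce_delta_nM=np.nan, flags=reason))
            continue
        basal = float(np.mean(vals["basal"]))
        peak = (lambda x: _median_top_k(x, k_frames)) if robust_peak \
            else (lambda x: float(np.max(x)))
        sr = peak(vals["tg"]) - basal
        soce = peak(vals["caadd"]) - basal
        flags = ""
        if sr < 0 or soce < 0:
            flags = "negative-delta"
        out.append(SOCESummary(cell_id=cid, basal_nM=basal,
                               store_release_delta_nM=sr,
                               soce_delta_nM=soce, flags=flags))
    return out


def soce_summaries_to_frame(summaries: list[SOCESummary]) -> pd.DataFrame:
    cols = ["cell_id", "basal_nM", "store_release_delta_nM",
            "soce_delta_nM", "flags"]
    return pd.DataFrame([{k: getattr(s, k) for k in cols} for s in summaries],
                        columns=cols)
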