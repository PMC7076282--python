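"""Forward simulators with known ground truth.

Two generators mirror the two imaging modalities the analysis modules
consume:

``simulate_spiking``
    A 10-min, 1 frame/s single-wavelength (Fluo-4-like) recording. Each cell
    fires spontaneous somatic transients at an epoch-specific rate (default:
    a 4-min baseline at a few spikes/min followed by a treatment epoch at
    rate 0, emulating TTX abolition). The fluorescence model is

        F(t) = f0 * exp(-t/bleach_tau) * (1 + sum_k A_k * exp(-(t-t_k)/decay_tau) * [t >= t_k])
               + Gaussian noise,

    an instantaneous rise with single-exponential decay. Spike times are the
    frame-grid discretisation of a homogeneous Poisson process: each frame in
    an epoch spikes independently with probability rate*dt (at most one spike
    per frame), so a noise-free, bleach-free isolated spike has dF/F0 exactly
    equal to its drawn amplitude at the spike frame.

``simulate_soce``
    A 17-min, 5 s/frame ratiometric (Fura-2-like) store-operated Ca2+ entry
    experiment with the five-epoch program basal / thapsigargin store release /
    Ca2+ add-back / ionomycin / EGTA (12/84/60/24/24 frames). True [Ca2+](t)
    follows a piecewise program whose within-epoch peaks equal the programmed
    deltas exactly; the two channels are generated by the exact algebraic
    inverse of the Grynkiewicz equation,

        R(t)    = (c*Rmax + Kd*SF*Rmin) / (c + Kd*SF)
        F380(t) = (F380_free*Kd*SF + F380_bound*c) / (Kd*SF + c),   F380_free = SF*F380_bound
        F340(t) = R(t) * F380(t),

    so that ratio -> Grynkiewicz recovers c(t) to machine precision at zero
    noise. During the ionomycin epoch the dye is driven to its Ca2+-bound
    asymptote (R = Rmax) by default (``saturate_iono``), matching ionomycin's
    experimental role of saturating the indicator.

Reproducibility: one seed per simulation; per-cell substreams are spawned by
cell index, so cell k's trace does not depend on n_cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from neurocal.trace_io import (
    TraceSet, RatioTraceSet, EpochPlan, fluo4_epoch_plan, soce_epoch_plan,
)

__all__ = [
    "SpikingSimParams", "SOCESimParams", "SimulationTruth",
    "simulate_spiking", "simulate_soce",
]


@dataclass
class SpikingSimParams:
    """Parameters of the single-wavelength spiking simulation.

    Rates are spikes per minute per epoch label; amplitudes are log-normal in
    dF/F0 units with the given median and log-space dispersion (sigma).
    """

    n_cells: int = 30
    duration_s: float = 480.0
    dt: float = 1.0
    epoch_rates: dict[str, float] = field(
        default_factory=lambda: {"baseline": 3.0, "treatment": 0.0})
    amplitude_median: float = 0.5
    amplitude_sigma: float = 0.4
    decay_tau: float = 2.0
    baseline_f0_range: tuple[float, float] = (0.8, 1.2)
    bleach_tau: float = math.inf
    noise_sd: float = 0.02
    seed: int = 0
    plan: EpochPlan | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        n = self.duration_s / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration {self.duration_s} s is not a multiple of dt {self.dt} s")
        if any(r < 0 for r in self.epoch_rates.values()):
            raise ValueError("epoch rates must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude_median <= 0 or self.amplitude_sigma < 0:
            raise ValueError("amplitude law needs median > 0 and sigma >= 0")
        if self.decay_tau <= 0 or self.bleach_tau <= 0:
            raise ValueError("time constants must be > 0")
        lo, hi = self.baseline_f0_range
        if not (0 < lo <= hi):
            raise ValueError("baseline_f0_range must satisfy 0 < lo <= hi")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.dt))


@dataclass
class SOCESimParams:
    """Parameters of the ratiometric SOCE simulation (concentrations in nM)."""

    n_cells: int = 25
    dt: float = 5.0
    epoch_frames: tuple[int, int, int, int, int] = (12, 84, 60, 24, 24)
    basal_ca: float = 50.0
    store_release_delta: float = 120.0
    store_rise_tau: float = 20.0
    store_decay_tau: float = 120.0
    soce_delta: float = 200.0
    soce_rise_tau: float = 30.0
    iono_ca: float = 1e6
    egta_ca: float = 0.0
    saturate_iono: bool = True
    kd: float = 225.0
    sf: float = 2.0
    rmin: float = 0.5
    rmax: float = 5.0
    f380_bound: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.dt <= 0:
            raise ValueError("need n_cells >= 1 and dt > 0")
        if not self.rmin < self.rmax:
            raise ValueError("rmin must be < rmax")
        if self.sf <= 0 or self.kd <= 0:
            raise ValueError("sf and kd must be > 0")
        for name in ("basal_ca", "store_release_delta", "soce_delta",
                     "iono_ca", "egta_ca"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.epoch_frames) < 1 or len(self.epoch_frames) != 5:
            raise ValueError("epoch_frames must be 5 positive counts")

    @property
    def n_frames(self) -> int:
        return int(sum(self.epoch_frames))


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run.

    Spiking runs fill ``spike_times``/``spike_amplitudes`` (per-cell lists);
    SOCE runs fill ``conc`` (true [Ca2+](t) in nM, frames x cells) and
    ``calibration`` (the constants used per cell).
    """

    spike_times: list[np.ndarray] | None = None
    spike_amplitudes: list[np.ndarray] | None = None
    conc: np.ndarray | None = None
    calibration: dict[str, np.ndarray] | None = None
    params: dict = field(default_factory=dict)

    def spike_frames(self, dt: float) -> list[np.ndarray]:
        if self.spike_times is None:
            raise ValueError("not a spiking-simulation truth")
        return [np.round(t / dt).astype(int) for t in self.spike_times]


def _cell_rngs(seed: int, n_cells: int) -> list[np.random.Generator]:
    # indexed substream per cell: cell k is reproducible regardless of n_cells
    return [np.random.Generator(
                np.random.Philox(np.random.SeedSequence(seed, spawn_key=(k,))))
            for k in range(n_cells)]


def simulate_spiking(params: SpikingSimParams) -> tuple[TraceSet, SimulationTruth]:
    """Simulate a single-wavelength spiking recording with known spikes."""
    plan = params.plan or fluo4_epoch_plan(dt=params.dt)
    n_frames, n_cells = params.n_frames, params.n_cells
    times = np.arange(n_frames) * params.dt
    rate_per_frame = np.zeros(n_frames)
    for epoch in plan.epochs:
        if epoch.label not in params.epoch_rates:
            raise ValueError(f"no rate given for epoch '{epoch.label}'")
        lam = params.epoch_rates[epoch.label] / 60.0  # spikes/s
        hi = min(epoch.end_frame, n_frames)
        rate_per_frame[epoch.start_frame:hi] = lam * params.dt
    if np.any(rate_per_frame > 1):
        raise ValueError("rate*dt exceeds 1 spike/frame; reduce rate or dt")

    rngs = _cell_rngs(params.seed, n_cells)
    values = np.empty((n_frames, n_cells))
    spike_times: list[np.ndarray] = []
    spike_amps: list[np.ndarray] = []
    mu = math.log(params.amplitude_median)
    for c, rng in enumerate(rngs):
        f0 = rng.uniform(*params.baseline_f0_range)
        fired = rng.random(n_frames) < rate_per_frame
        frames = np.where(fired)[0]
        amps = np.exp(mu + params.amplitude_sigma * rng.standard_normal(frames.size))
        dff = np.zeros(n_frames)
        for t0, a in zip(frames, amps):
            tail = times[t0:] - times[t0]
            dff[t0:] += a * np.exp(-tail / params.decay_tau)
        bleach = (np.exp(-times / params.bleach_tau)
                  if math.isfinite(params.bleach_tau) else 1.0)
        f = f0 * bleach * (1.0 + dff)
        if params.noise_sd > 0:
            f = f + params.noise_sd * rng.standard_normal(n_frames)
        values[:, c] = f
        spike_times.append(times[frames].copy())
        spike_amps.append(amps)

    trace = TraceSet(times=times, values=values,
                     cell_ids=[f"cell{c:03d}" for c in range(n_cells)],
                     meta={"dye": "Fluo-4", "dt": params.dt, "seed": params.seed})
    truth = SimulationTruth(spike_times=spike_times, spike_amplitudes=spike_amps,
                            params={k: v for k, v in asdict(params).items()
                                    if k != "plan"})
    return trace, truth


def _soce_conc_program(params: SOCESimParams) -> np.ndarray:
    """True [Ca2+](t) in nM for one cell (deterministic, shared by all cells).

    Within the thapsigargin and add-back epochs the transient shapes are
    normalised over the sampled frames so the epoch maxima equal
    basal + store_release_delta and basal + soce_delta exactly.
    """
    n_b, n_tg, n_ca, n_io, n_eg = params.epoch_frames
    dt = params.dt
    c = np.empty(params.n_frames)
    i = 0
    c[i:i + n_b] = params.basal_ca
    i += n_b
    # store release: rise-and-decay bump, peak == basal + delta on the grid
    t = np.arange(n_tg) * dt
    bump = (1.0 - np.exp(-t / params.store_rise_tau)) * np.exp(-t / params.store_decay_tau)
    peak = bump.max()
    c[i:i + n_tg] = params.basal_ca + (
        params.store_release_delta * bump / peak if peak > 0 else 0.0)
    i += n_tg
    # SOCE: saturating rise, peak == basal + delta on the grid
    t = np.arange(n_ca) * dt
    rise = 1.0 - np.exp(-t / params.soce_rise_tau)
    top = rise.max()
    c[i:i + n_ca] = params.basal_ca + (
        params.soce_delta * rise / top if top > 0 else 0.0)
    i += n_ca
    c[i:i + n_io] = params.iono_ca
    i += n_io
    c[i:i + n_eg] = params.egta_ca
    return c


def _forward_channels(c: np.ndarray, params: SOCESimParams,
                      saturated: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (R, F380) from true concentration via the inverse Grynkiewicz map."""
    kdsf = params.kd * params.sf
    r = (c * params.rmax + kdsf * params.rmin) / (c + kdsf)
    f380_free = params.sf * params.f380_bound
    f380 = (f380_free * kdsf + params.f380_bound * c) / (kdsf + c)
    if saturated.any():
        r = np.where(saturated, params.rmax, r)
        f380 = np.where(saturated, params.f380_bound, f380)
    return r, f380


def simulate_soce(params: SOCESimParams) -> tuple[RatioTraceSet, SimulationTruth]:
    """Simulate a ratiometric SOCE experiment with known [Ca2+](t) and constants."""
    n_frames, n_cells = params.n_frames, params.n_cells
    times = np.arange(n_frames) * params.dt
    c = _soce_conc_program(params)
    plan = soce_epoch_plan(dt=params.dt, frames=params.epoch_frames)
    iono = plan["iono"]
    saturated = np.zeros(n_frames, dtype=bool)
    if params.saturate_iono:
        saturated[iono.start_frame:iono.end_frame] = True
    r0, f380_0 = _forward_channels(c, params, saturated)
    f340_0 = r0 * f380_0

    rngs = _cell_rngs(params.seed, n_cells)
    f340 = np.empty((n_frames, n_cells))
    f380 = np.empty((n_frames, n_cells))
    for k, rng in enumerate(rngs):
        n340 = params.noise_sd * rng.standard_normal(n_frames) if params.noise_sd else 0.0
        n380 = params.noise_sd * rng.standard_normal(n_frames) if params.noise_sd else 0.0
        f340[:, k] = f340_0 + n340
        f380[:, k] = f380_0 + n380

    ones = np.ones(n_cells)
    rt = RatioTraceSet(times=times, f340=f340, f380=f380,
                       cell_ids=[f"cell{k:03d}" for k in range(n_cells)],
                       meta={"dye": "Fura-2", "dt": params.dt, "seed": params.seed})
    truth = SimulationTruth(
        conc=np.tile(c[:, None], (1, n_cells)),
        calibration={"kd": params.kd * ones, "sf": params.sf * ones,
                     "rmin": params.rmin * ones, "rmax": params.rmax * ones},
        params=asdict(params))
    return rt, truth
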