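# Methods

`neurocal` quantifies cytosolic Ca²⁺ signals in cultured neurons from
ROI-level fluorescence traces, for the two standard acquisition modes:
single-wavelength intensity imaging (Fluo-4-like dyes) of spontaneous
somatic transients, and dual-excitation ratiometric imaging (Fura-2) of
absolute [Ca²⁺] during store-operated entry (SOCE) protocols. It also
implements the small, exact arithmetic used downstream of qPCR and RNA-seq
tooling. This note records the models, the defaults, and the design choices
made where the procedures admit more than one reading.

## Single-wavelength transient detection

**Normalisation.** Each cell's trace is divided by its intensity at a single
reference frame, the first frame of the baseline epoch: `norm = F/F0`,
`dff = F/F0 − 1`. Both are kept because "ΔF" conventions vary; all
amplitudes reported by the detector are in `dff` units. Cells with a
non-positive reference intensity cannot be normalised and are excluded with
a logged reason rather than silently dropped.

**Event criterion.** The detector thresholds the raw first difference of
`dff` (`d[t] = dff[t+1] − dff[t]`, no smoothing by default) at

    threshold = mean(d_quiet) + k_sd × SD(d_quiet),   k_sd = 2 by default,

with both statistics taken over transient-free ("quiet") frames and SD the
population (1/n) form. The criterion admits a second reading — statistics on
the normalised intensity itself — which is available behind
`DetectionParams(stat_on="intensity")` but is not the default, because the
spike counting is done on the derivative trace. The quiet region is either
given explicitly or found by iterative exclusion (`"auto"`): start from all
baseline frames, drop frames whose derivative exceeds the current threshold,
recompute, and stop at a fixpoint or after `max_auto_iterations` (10). The
iteration only removes *positive* excursions; the negative derivatives of
transient decays remain in the quiet set and inflate its SD somewhat. This
is a conservative bias (fewer false events) inherent to the stated
criterion, and it is visible in the recovery benchmarks below.

**Events.** Maximal runs of derivative frames above threshold (positive side
only) become events; runs separated by fewer than `min_separation` (2)
sub-threshold frames are merged, runs with fewer than `min_event_frames` (1)
supra-threshold frames are dropped. The onset is the frame the first
supra-threshold step rises into; the peak is the `dff` argmax from the onset
through the post-run decay, up to the first local minimum; the amplitude is
peak `dff` minus the **median `dff` over the `local_baseline_window` (5)
frames before onset**. A local rather than global baseline makes amplitudes
robust to slow drift; no detrending or bleach correction is applied by
default (an exponential detrend is exposed through the bleach parameters of
the simulator only — measured data are analysed as given).

**Summaries.** Spikes per 4 min counts event onsets in a 240-s window at the
start of the baseline epoch. A treatment epoch (TTX, nimodipine) is called
*abolished* for a cell when its event rate is at most `abolition_fraction`
(default 0, i.e. strictly no events) times the baseline rate. Amplitude
histograms use half-open bins with explicit underflow/overflow bins, so
proportions always sum to 1; bin edges are user configuration (no canonical
set is claimed).

## Ratiometric analysis

With R the 340/380 excitation ratio, cytosolic calcium follows the
Grynkiewicz relation

    [Ca²⁺] (nM) = Kd · SF · (R − Rmin) / (Rmax − R),

Kd = 225 nM by default (Fura-2 in human cells; overridable per run).
Per-cell constants are estimated from the two terminal epochs of the SOCE
protocol:

* **Rmax** — median of the 5 largest R values in the ionomycin epoch;
* **Rmin** — median of the last 5 R values of the EGTA epoch (chelation is
  only complete at the end of the epoch);
* **SF** — median F380 over the EGTA window (Ca²⁺-free dye) divided by the
  median F380 over the ionomycin window (Ca²⁺-bound dye).

Median-of-extremes rather than single-frame extrema: a single max/min frame
estimator is noise-biased with no offsetting benefit. Frames with R ≥ Rmax
are flagged `saturated-high` (concentration undefined); R < Rmin is clamped
to 0 nM with a flag; F380 ≤ 0 flags the frame. Flagged frames are excluded
from every downstream statistic, and cells whose required epoch is entirely
flagged are excluded with a reason. Camera-offset background subtraction is
deliberately not applied (offset 0): it is acquisition-specific and should
be done upstream if needed.

**SOCE quantification.** Per cell: basal = mean [Ca²⁺] over the zero-Ca
basal epoch; store release = thapsigargin-epoch peak − basal; SOCE =
add-back-epoch peak − basal. The peak is the plain epoch maximum by default
(the quantity is a *rise above basal*); `robust_peak=True` substitutes the
same median-of-top-5 used in calibration. With channel SNR ≈ 50 the plain
max overshoots a few nM per cell (max of ~60–84 noisy frames) while the
noisy Rmax estimate pulls concentrations down slightly; cohort means recover
the programmed amplitudes to within ~3% in the bundled benchmarks, single
cells to within ~±6%.

## The simulators

Both generators exist so that every analysis stage has a parameter-recovery
test with known ground truth; they emulate the acquisition geometry of the
protocols, not the biophysics.

**Spiking simulator.** 480 s at 1 frame/s by default: a 240-s spontaneous
baseline (3 spikes/min) followed by a 240-s silent treatment epoch (rate 0,
the TTX condition). Fluorescence per cell:

    F(t) = f0 · e^(−t/bleach_tau) · (1 + Σ_k A_k · e^(−(t−t_k)/τ) · [t ≥ t_k]) + ε(t)

with instantaneous rise and single-exponential decay (τ = 2 s — at 1 Hz
sampling the rise is sub-frame, and no kinetics are claimed beyond that).
Spike times are the frame-grid discretisation of a homogeneous Poisson
process: each frame fires independently with probability rate·dt, at most
one spike per frame, so a noise-free isolated spike has `dff` exactly equal
to its drawn amplitude at the spike frame — which is what makes amplitude
recovery exactly testable. Amplitudes are log-normal (median 0.5 ΔF/F0,
log-SD 0.4): strictly positive and right-skewed, as observed amplitude
distributions are. Baseline intensities f0 are uniform in (0.8, 1.2) a.u. —
order-1 by design, so the additive Gaussian noise (SD 0.02 a.u.) is
commensurate with ΔF/F0 units and detection benchmarks are non-trivial.
Photobleaching is off (τ = ∞) by default.

**SOCE simulator.** 204 frames at 5 s (17 min) in five epochs of
12/84/60/24/24 frames: zero-Ca basal, thapsigargin store release, Ca²⁺
add-back, ionomycin, EGTA. True [Ca²⁺](t) is piecewise: constant basal
(50 nM); a rise-and-decay bump (τ_rise 20 s, τ_decay 120 s) whose grid
maximum equals basal + 120 nM exactly; a saturating rise (τ 30 s) whose
grid maximum equals basal + 200 nM exactly — the programmed deltas are
therefore exact targets for recovery, not approximations. Channels are
generated by the algebraic inverse of the Grynkiewicz relation,

    R = (c·Rmax + Kd·SF·Rmin)/(c + Kd·SF),
    F380 = (F380_free·Kd·SF + F380_bound·c)/(Kd·SF + c),  F380_free = SF·F380_bound,
    F340 = R·F380,

so ratio → Grynkiewicz recovers c(t) to machine precision at zero noise.
The F380 concentration dependence is a hyperbola with half-point Kd·SF,
the unique form consistent with that inversion. During the ionomycin epoch
the dye is driven to its Ca²⁺-bound asymptote (R = Rmax, F380 = F380_bound)
by default (`saturate_iono=True`): ionomycin's role in the protocol *is* to
saturate the indicator, and with any finite concentration the hyperbola
never reaches Rmax, which would make exact calibration recovery impossible.
`saturate_iono=False` exposes the plain hyperbola at `iono_ca` (default
10⁶ nM, within 0.1% of Rmax) for studying near-saturation behaviour.
Noise is additive Gaussian, i.i.d. per channel and frame; shot noise and
autofluorescence are out of scope.

**Reproducibility.** One seed per simulation; per-cell substreams are
spawned by cell index (`Philox(SeedSequence(seed, spawn_key=(k,)))`), so
cell k's trace is bit-identical regardless of how many cells are simulated.

**What a green test establishes.** The generators produce frame-aligned
spikes, stationary Gaussian noise, and cells that share one concentration
program. Real recordings add sub-frame onset jitter, movement and focus
drift, heterogeneous indicator loading, and correlated (network) activity —
recovery scores on synthetic data are upper bounds, not calibration claims.

## Expression arithmetic

* **2^−ΔCt**: technical replicates are averaged (mean; the convention) per
  gene and sample before differencing against the reference gene (GAPDH);
  replicate SD > 0.5 cycles flags the pair. `log2(rel) = −ΔCt` holds to
  machine precision by construction.
* **DE classification**: up iff log2FC ≥ +1.5 ∧ p < 0.05 ∧ FDR < 0.05;
  down symmetric at ≤ −1.5. The fold-change bound is inclusive, the
  significance bounds strict — the asymmetry follows the stated rule
  ("+1.5 and greater" vs "< 0.05"). Model fitting itself (DESeq and kin) is
  out of scope; the module consumes a finished (gene, log2FC, p, FDR) table.
* **Panel z-scores**: per contrast column, z = (x − mean)/population SD over
  the panel genes present; missing panel genes are returned to the caller,
  never silently dropped; a constant column z-scores to zeros with a
  warning. The −1..+1 range seen in heatmap figures is display clipping
  (`clip=1.0`), not a data transformation. The bundled 109-gene calcium
  panel is a synthetic, user-replaceable stand-in assembled from canonical
  calcium-toolkit families.
* **Marker positivity**: 100·positive/total, truncated (not rounded) to two
  decimals, matching the reporting convention of counts such as
  91/283 → 32.15%.

## Numerical choices and degenerate inputs

* Population (1/n) SD throughout the detector and z-scores; for ≥ 20 quiet
  frames the difference from the sample SD is < 3%.
* Uniform-sampling tolerance for trace tables: |dtᵢ − median dt| ≤ 10⁻⁶ ×
  median dt, absorbing acquisition-software timestamp rounding.
* Epoch intervals are 0-based, half-open `[start, end)` everywhere.
* Quiet regions need ≥ 5 frames (hard error below); a quiet SD of 0 with
  signal elsewhere in the trace warns and uses the mean as threshold.
* Tables are written with `%.17g` and read with round-trip float parsing,
  so reader/writer pairs are bit-lossless for finite doubles.
* Ties in the peak search resolve to the earliest frame.

## Known limitations

* The detector has an irreducible false-positive rate on pure noise — a
  mean + 2·SD threshold crosses by chance ~2% of frames when the quiet
  statistics match the data; strict abolition calls (zero events allowed)
  are therefore only guaranteed on noise-free input. With noise, a small
  nonzero `abolition_fraction` is the appropriate setting.
* No deconvolution or spike-time inference beyond threshold crossing; no
  bursting or synchrony statistics; somatic ROIs only.
* Calibration assumes the ionomycin and EGTA epochs actually saturate and
  strip the dye; cells where they do not will show Rmin ≥ Rmax and are
  flagged invalid rather than rescued.
* Mn²⁺-quench calibration for single-wavelength dyes is not implemented.
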