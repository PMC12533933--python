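# Methods

## Scope and data model

The pipeline processes the four streams a multi-metric optical smartwatch
exports during field wear: step cadence, respiration rate (RR) and SpO₂ at a
nominal 60-s cadence, and beat-to-beat intervals (BBI) per heartbeat.
Timestamps are held as UTC epoch seconds throughout; ISO-8601 strings in
exports are converted once at the ingest boundary so multiday records share a
single clock. Ingestion is deliberately lossless: chunked uploads are merged
with exact duplicates dropped, while same-timestamp conflicts are retained
and flagged for downstream cleaning to resolve. The device-export schemas
(JSON upload objects; `timestamp,metric,value` CSV) are project-defined
interchange formats, since wearable vendors do not publish theirs; CSV files
without an explicit participant column take their ID from the file stem.

## Artifact cleaning

Two cleaning notions are kept distinct:

1. **Valid-range deletion.** Samples outside a metric's physiologic validity
   range — steps 0–220 steps/min, RR 6–60 breaths/min, SpO₂ 60–100 %, BBI
   300–1500 ms — are deleted. Bounds are inclusive at both ends: a BBI of
   exactly 1500 ms is a heart rate of exactly 40 bpm, and a step count of 0
   is a legitimate rest value. The deletion rate (*% correction*) is itself a
   signal-quality output, reported per metric with BBI as the headline
   (wrist-motion artifact shows up almost entirely in the beat channel).
2. **NN-interval replacement.** For HRV only, ectopic/outlier beats are
   *replaced*, not deleted, so the series keeps its length. A beat is flagged
   when it deviates from the previous accepted beat by more than 20 % (the
   Malik criterion; threshold configurable). Flagged beats are linearly
   interpolated between the nearest accepted neighbours, with flat extension
   at the edges, and clipped into the BBI range. Replacement requires at
   least 3 beats. The 20 % rule is a documented stand-in for whichever
   detector a given deployment prefers; it is the most widely used default in
   HRV preprocessing.

Valid-range filtering is idempotent and conserving (kept + removed = total),
and on fixtures with a known number of injected out-of-range values the
reported % correction is an exact count, not an estimate.

## Epoch aggregation

Windows are left-closed right-open, wall-clock aligned at
`floor(t/width)·width`. Alignment to the wall clock (rather than to each
record's first sample) makes epochs join across metrics whose streams start
at different times; it also means percentages are invariant to shifting a
record by whole windows, which a test exercises. Both 60-s and 300-s epochs
are computed **from raw cleaned samples**; 5-min statistics are never derived
from 60-s means, because the window SD is a first-class output and the SD of
means would understate it (a test documents the discrepancy on an unbalanced
fixture). Partial leading/trailing windows are kept and carry their true
sample counts, so short (3.5-h) sessions lose nothing. HR is derived as
60000 / mean(BBI) — the mean interval, not the mean of instantaneous rates —
mapping the BBI validity bounds onto HR 40–200 bpm exactly. A window is
*rest* when it has step samples with mean 0, *active* when the mean is
positive, *unknown* with no step samples.

## Wear compliance and data quality

A 5-min window counts as **worn** when at least 2 of the 4 metrics have valid
data in it. A metric is valid in a window when at least one cleaned sample
falls inside (minimum count configurable); requiring a single sample is the
weakest rule consistent with "data present", and anything stricter is a
policy choice the configuration exposes. The wear period runs from the first
to the last valid BBI sample; compliance is worn windows as a percentage of
all 5-min windows in that period. Validity percentages per metric — plus
"HRV windows", defined as windows with at least 120 NN beats (enough to
support a stable 5-min spectrum; configurable) — are reported over worn
windows by default (switchable to all windows) and stratified rest/active.
Strata with no windows report NaN, rendered as an em dash, never as 0.

## Core-temperature estimation

The extended Kalman filter treats core temperature as a random walk
(process-noise SD γ per minute) observed through a quadratic HR model
m(CT) = a₀ + a₁·CT + a₂·CT², linearized at the predicted state each minute.
Defaults — CT₀ = 37.0 °C, v₀ = 0, γ = 0.022 °C, σ = 18.88 bpm,
m(CT) = −7887.1 + 384.4286·CT − 4.5714·CT² — follow the USARIEM
heart-rate-only estimator; the constructor rejects parameter sets whose
observation model is not strictly increasing on 36–41 °C. Two
initialization modes are provided: fixed 37.0 °C (long unattended wear) and
the first reference temperature (supervised sessions with spot checks).

Choices worth stating:

- **Gaps propagate, never interpolate.** Minutes with missing or
  out-of-range HR (outside 40–200 bpm, treated as missing with a warning)
  apply the time update only, so the variance after k missing minutes is
  exactly v + k·γ². Interpolating HR across a non-wear gap would fabricate
  confidence precisely where the device was blind.
- **Reference comparison** matches each spot-check to the nearest trace
  minute within 5 minutes (hand-timed tympanic readings are not synchronized
  to the device clock). Bias is mean (estimate − reference), positive =
  overestimate, per-measurement by default; per-participant averaging is
  supported at cohort level via the returned per-measurement deviations.
- **Exertion summaries** count whole minutes at or above a configurable HR
  threshold (default 125 bpm) and convert to hours, alongside maxima of HR
  and estimated temperature.

## HRV

Time domain: SDNN uses the sample SD (ddof = 1); RMSSD the root-mean-square
of successive differences; pNN50 the percentage of successive differences
whose *magnitude* exceeds 50 ms. Frequency domain: LF 0.04–0.15 Hz and HF
0.15–0.40 Hz band powers of the mean-removed tachogram and their ratio
(NaN when HF power is zero). The default estimator is Lomb–Scargle on the
uneven beat times, scaled to a one-sided density by 2·T/N (T the window
span, N the beat count) so that a sinusoidal modulation of amplitude A
integrates to its variance A²/2 and total power approximates the tachogram
variance (a Parseval test holds this to 5 % on near-uniform data). The
frequency grid runs from 1/(4T) to 0.5 Hz in steps of 1/(4T). A
cubic-spline + Welch backend (4 Hz resampling, 512-sample segments) is
provided as an alternative. Metrics are only emitted for windows meeting the
minimum-beat threshold.

## Synthetic wearer generator

The generator is the package's test bed and defines its study conditions.
Per minute, activity intensity follows a user schedule of blocks in [0, 1];
true core temperature relaxes first-order (τ = 25 min, a typical
thermoregulatory time constant) toward a target obtained by inverting the
filter's observation model at `hr_rest + intensity·hr_range`
(defaults 78 bpm rest, 60 bpm span); true HR is m(CT). This ties HR, core
temperature and activity together through the same model the estimator
assumes, making recovery tests well-posed by construction: on generated data
with observation noise matching σ, the filter recovers the truth with RMSE
≤ 0.3 °C. Beats are emitted sequentially with interval
60000/HR plus sinusoidal LF (25 ms at 0.10 Hz) and HF (35 ms at 0.25 Hz)
modulation and 4-ms jitter; step, RR and SpO₂ streams follow intensity with
small Gaussian noise, kept strictly inside validity ranges so that injected
artifacts — drawn per sample at `artifact_rate` and placed strictly outside
the ranges — are exactly the out-of-range population. Non-wear spans blank
all four streams; record timestamps start on a 5-minute boundary so
whole-window gaps echo exactly in compliance. All randomness flows from one
seed through deterministically spawned substreams; identical configurations
reproduce identical records bit-exactly.

Three presets sketch field deployments: `multiday_fieldwork` (4.25 days,
daily work blocks, short aligned removals, 7.3 % artifacts),
`recruit_training_3p5h` (3.5 h at high intensity with a mid-session break,
6.5 % artifacts), and `inactive_control` (3.5 h, mean step rate ≈ 4.5
steps/min, 9.3 % artifacts — the loose-fit top of the observed band).
Artifact rates sit inside the 5.8–9.3 % band reported for wrist devices in
comparable field use.

**What the generator does not emulate** — and therefore what passing tests
cannot show about real data: optical-sensor motion artifact is reduced to a
uniform out-of-range injection rate (real artifact is burst-correlated with
movement and can fall *inside* validity ranges); skin-tone and fit effects
appear only as preset-level rate choices; the HR–core-temperature coupling is
exactly the filter's model, so recovery results certify implementation
correctness, not physiologic validity of that model; environment (ambient
temperature, humidity) and PPE heat-transfer physics are out of scope.

## Problem sizes and numerics

Simulation-based tests use 2–8 hour records (up to ~46 000 beats), enough
for binomial artifact-rate echoes within ±1 percentage point and stable
spectra, while keeping the suite fast. Rendered report percentages use 1
decimal place; all CSV exports carry full precision, and every number in the
text report is recomputable from the CSVs. CSV ingest uses round-trip float
parsing so write-then-read preserves samples bit-exactly. Degenerate inputs
fail loudly: empty exports, unknown metrics, records with no valid beats
(wear period undefined), HRV on fewer than the minimum beats, and
non-increasing observation models are all errors, not silent defaults.
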