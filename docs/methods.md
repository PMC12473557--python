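# Methods

This note documents the models, conventions and numerical choices behind
`neowear`, and what the synthetic generator does and does not emulate.

## Recording model

A recording day couples five uniform-rate channels — wired PPG (75 Hz),
wireless PPG (64 Hz), wired and wireless SpO₂ (1 Hz), FiO₂ (1 Hz) — with
timestamped bedside annotations (KC kangaroo care, RC routine care, PAU
pause, SR/SA sensor removed/adjusted, O other) and device alert flags
(Bluetooth disconnect, poor skin contact). Time is seconds from the
recording epoch; all intervals are half-open `[start, end)`. Missing
samples are NaN in the value array — never a sentinel physiological
value — so "no data" and "zero" remain distinguishable. On ingestion,
present SpO₂ values outside [0, 100] and FiO₂ outside [0.21, 1.0] are
converted to missing and counted in a load report.

Resampling to the common time base (64 Hz PPG, 1 Hz SpO₂) uses linear
interpolation for PPG, with the hard rule that no output sample is
synthesized where the enclosing input interval touches missing data.
SpO₂/FiO₂ use nearest-neighbour assignment within ±0.5 s — half the 1 Hz
sample interval. Synchronization estimates a single constant offset by
maximizing the cross-correlation of the mean-removed SpO₂ traces over
integer lags (default ±60 s) with at least 60 s of valid overlap; flat
or insufficiently overlapping traces raise, directing the caller to pass
the offset explicitly. No clock-drift model is fitted: the estimator
targets acquisition platforms that already discipline both clocks, and a
smooth saturation trace does not identify sub-sample drift. Note that on
short, noisy traces a 1 s-resolution correlation peak is genuinely
ambiguous; the exact-recovery guarantee holds for a shifted copy of an
otherwise identical stream, which is the designed use (common-clock
acquisition with a constant transport delay).

## Feasibility

A gap is a maximal missing run whose duration **strictly** exceeds
31.25 ms (PPG; two samples at 64 Hz) or 2 s (SpO₂/FiO₂); a run equal to
the threshold is not a gap. Leading and trailing time not covered by the
sample grid counts as missing relative to the planned monitoring period,
so coverage is defined against what was planned, not what was recorded.
Missing runs separated by even a single valid sample stay distinct (no
bridging), which keeps detection deterministic and lets generator-side
bookkeeping predict coverage exactly: coverage% + gap-time% = 100 to
1e-9 by construction.

PPG SNR is estimated per 30 s window (50% overlap, boxcar periodogram of
mean-removed samples). The cardiac peak is the periodogram maximum in
1–4 Hz (neonatal pulse rates 60–240 bpm); signal power is the power
within ±0.3 Hz of the peak and of its first harmonic; noise power is the
remainder of 0.1–10 Hz; the ratio is capped at ±40 dB. Windows with
under 50% valid samples, or without spectral power in the search band,
yield a missing value. Missing samples inside accepted windows are
zero-filled after mean removal, attenuating signal and noise roughly
equally. The estimator is scale-invariant. This estimator is the
package's own documented choice of quality index; all parameters are
keyword-configurable.

Cause attribution applies a fixed-precedence tree per gap, with the gap
interval padded by ±5 s of context: (1) overlap with a Bluetooth
disconnect flag → BD; (2) overlap with an SR/SA annotation → SR/SA;
(3) mean SNR of the estimation windows within 30 s of either gap edge
below 0 dB → LOW_SNR; (4) otherwise UNKNOWN, except on the wired PPG
line where an unexplained hard dropout can only be a cable
disconnection and is labelled CABLE. Precedence is ordered by evidence
specificity: a device flag is direct evidence, an annotation is
observed handling, low flanking SNR is circumstantial. The activity tag
is the care annotation covering the gap midpoint.

## Safety

Before/after NSCS assessments pair per (infant, day); day-level pairs
are treated as independent observations (a per-infant aggregation is
deliberately not the default, matching the pooled-pairs design the
analysis targets). The signed-rank test uses, by default: zeros dropped,
mid-ranks on |d|, `W⁺` on before-minus-after differences,
`z = (W⁺ − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)` with **no** tie
correction and no continuity correction, two-sided normal p. Each
convention is switchable (Pratt zero handling, tie-corrected variance,
after-minus-before direction); the defaults are the unique common
convention set under which the pooled 73-pair reference table yields
z = −1.12. An all-zero delta vector returns a structured
"no usable pairs" result (z = 0, p = 1) rather than raising. The
rank-sum comparison for unpaired distributions follows the same
conventions and reports the rank sum of the first group.

## Accuracy

Differences are `d = wired − wireless` so positive bias means the
wireless sensor under-reads. Bias is the mean of d, spread the sample SD
(n−1), LoA = bias ± 1.96·SD, MoE = 1.96·SD, MAE the mean |d|. The 1.96
multiplier is fixed; no repeated-measures LoA adjustment is applied
because days are summarised individually and aggregated by median/IQR
(linear-interpolation quantiles).

Oxygen grouping is per recording day: SUPPLEMENTAL iff strictly more
than 50% of valid FiO₂ samples exceed 0.21. The modified error grid
gives state agreement precedence over the 5-point band: clinical states
are LOW (≤ 91) vs in-range on room air, and LOW (≤ 88) / in-range /
HIGH (> 95) on supplemental oxygen; same state → A if |d| ≤ 5
percentage points (inclusive, absolute points not relative) else B;
reference actionable with test in range → D (failure to treat); reverse
→ C (unnecessary treatment); opposite actionable states → E. On room
air only two states exist, so E is geometrically unreachable — asserted
by exhaustive enumeration in the tests. The wired monitor is the
reference throughout.

`error_by_snr` stratifies MAE/MoE by the nearest-window SNR of each
device with left-inclusive, right-open bins; cells under 30 pairs are
flagged low-n. `experimental_effect_size` computes the minimally
detectable mean difference `(z_{0.975} + z_{0.90})·s_d/√n`; it is
labelled experimental because its correspondence to any published
effect-size definition is unverified.

## Synthetic generator

The generator's defaults encode the emulated study conditions: 8 h
days, heart rate 150 bpm, wired PPG SNR 7.35 dB, a wireless SNR schedule
alternating 5 dB with −5 dB episodes in the last 20 min of each hour
(about a third of the day, driving a wireless SpO₂ coverage deficit of
the observed order), SpO₂ baseline 96% with ~2 desaturations/h of depth
10 points, device bias 1.34 points with 2.0 points of device noise,
Bluetooth dropouts at 0.8/h with 30 s mean duration, one sensor
adjustment per day, rare wired cable blips and 3.6/h wired SpO₂
dropouts, room-air FiO₂.

Mechanisms, and their deliberate simplifications:

* **PPG**: fundamental plus half-amplitude first harmonic with white
  noise calibrated per schedule segment so the windowed periodogram SNR
  matches the scheduled value, accounting for the white-noise power that
  falls in the cardiac bands. Scheduled values below the estimator's
  white-noise floor (≈ −8.6 dB) saturate at the floor. No motion
  artifacts, baseline wander or waveform morphology variation.
* **SpO₂**: an Ornstein–Uhlenbeck-style walk (relaxation 5 min,
  stationary SD 0.6 points) stands in for the autocorrelation left by
  the monitor's 8 s averaging. Desaturations blend the walk toward
  (baseline − depth) with a raised-cosine profile whose trough equals
  that floor exactly, making the depth contract deterministic. The
  wireless trace is the wired trace minus a constant bias plus Gaussian
  noise, clipped to [0, 100]; clipping perturbs the recovered bias by
  well under 0.01 points at default settings. Real paired oximeters
  have SNR-dependent, occasionally non-Gaussian error; here error is
  homoscedastic by default.
* **Gaps**: Bluetooth dropouts are a Poisson process with exponential
  durations (minimum 3 s) applied to both wireless channels with a
  matching flag; sensor events use listed intervals with matching
  annotations; wireless SpO₂ is additionally missing inside low-SNR
  schedule segments. All injected intervals snap to the channel grid,
  and overlapping injections merge with cause precedence
  BD > SR/SA > LOW_SNR.
* **Identifiability guards**: cause attribution is only testable when
  causes are separated in time, so randomly drawn intervals landing
  within a guard distance (default 40 s ≈ context pad + flanking
  window) of a different-cause interruption are discarded at draw time,
  and low-SNR SpO₂ missingness is inset 60 s inside each low-SNR
  segment so the flanking windows actually sample degraded signal. Real
  data offers no such separation; attribution accuracy on real
  recordings will be lower than the closed-loop 100%.
* **Skin scores**: before-scores drawn from {3: 0.96, 4: 0.04} and
  deltas from {−1: 3/73, 0: 63/73, +1: 7/73}, clipped to the valid
  range (a delta of −1 from a score of 3 is floored at 3, slightly
  shrinking the decrease mass).

Consequently, passing closed-loop tests demonstrates that the
*estimators* are correct and internally consistent at realistic scales
and rates — not that any particular device meets the recovered numbers
on real infants.

## Problem sizes and tolerances

Closed-loop acceptance checks run at full day scale: gap/attribution
recovery on one 8 h day (~1.8 M PPG samples, exact boundary recovery,
conservation to 1e-9, 100% cause agreement) and bias recovery on 28,800
SpO₂ pairs (bias within ±0.1 point, MoE within 5% relative). Unit tests
use 1–30 min segments where exactness is scale-free (round trips,
thresholds, classifiers). The signed-rank implementation is verified
against the exact sign-flip permutation null for tie-free n ≤ 10 and
against scipy's normal-approximation p on a tie-free case. Gap
thresholds use a relative epsilon (1e-12) so grid-exact runs at the
threshold never count as gaps through rounding.

## Known limitations

* The SNR estimator assumes a discernible cardiac peak; arrhythmic or
  extremely noisy PPG yields missing windows rather than estimates.
* Offset estimation needs structure in the SpO₂ trace; flat traces are
  rejected by design.
* The generator's missingness processes are stationary within a day;
  real devices show diurnal and handling-correlated clustering.
* FiO₂ is simulated piecewise-constant and noise-free.
* Wired PPG timestamp jitter (a "nominal" 75 Hz export) is not
  modelled; resampling assumes the nominal uniform grid.
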