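# Methods

This note documents the models implemented in `bim`, the defaults they
ship with, and the design choices made where the problem was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Measurement model

A tetrapolar monitor injects a sinusoidal current (default 2.3 mA
peak-to-peak at 50 kHz) between one scalp and one intracranial electrode
and senses the induced potential on a second pair, so electrode-contact
impedance drops out of the measurement. Eight scalp positions define
eight angular sensitivity sectors; a multiplexer holds each channel for
10 s, giving an 80 s full cycle. Within a channel's active slot the
carrier is demodulated by a matched filter — correlation against
reference quadrature sinusoids, the optimal amplitude estimator in white
noise:

    A = (2/N) · sqrt( (Σ x·cos ωk)² + (Σ x·sin ωk)² ),  ω = 2π f_c / f_s

and impedance is the amplitude ratio |Z| = A_V / A_I per 20 ms block
(1000 samples at the hardware rate), i.e. a 50 Hz impedance stream.
Blocks are dropped, not zero-padded, at slot edges; blocks whose current
amplitude falls below 1 µA (far below the 0.5–5 mA drive range) are
flagged unusable rather than emitted as near-infinite ratios.

Carrier-level synthesis refuses sampling below 4× the carrier: a 50 kHz
carrier sampled at 50 kHz aliases to DC and cannot feed a quadrature
demodulator. Simulated raw acquisitions therefore default to 250 kHz
sampling. Only |Z| is modelled; reactance/phase is out of scope.

## Synthetic recordings: what is emulated

`bim.simulate` generates envelope-level recordings with the statistical
structure the analysis assumes. Defaults (all overridable per scenario):

| parameter | default | meaning |
| --- | --- | --- |
| `baseline_z` | 1000 Ω (±10 % per-channel spread across a cohort) | electrode-pair baseline impedance |
| `noise_sd_ohm` | 0.063 Ω | per-sample Gaussian noise; 20·log10(1000/0.063) ≈ 84 dB sample SNR |
| `focal_gain` | 60 Ω/mL (±15 % across subjects) | nearest-channel response to focal volume |
| `kernel_width_deg` | 45° | Gaussian angular spread of sector sensitivity |
| `inclusion_sector` | 3 | sector containing the balloon/blood inclusion |
| `contrast_sign` / `hematoma_sign` | +1 / −1 | insulative balloon raises Z; conductive blood lowers it |
| `p0_mmhg`, `elastance_per_ml` | 10 mmHg, 0.5 /mL | craniospinal elastance ICP = p0·exp(E·V) |
| `drift` | 5 Ω/h linear + 20 Ω·exp(−t/600 s) settling | electrode settling after instrumentation |
| `global_gain_ohm` | 40 Ω | spatially uniform shift in global phases |
| `sample_rate_hz` | 50 Hz | demodulated envelope rate inside active slots |

The **sector kernel** is Gaussian in wrapped angular distance between
the 45°-spaced channel centers and the inclusion angle. No quantitative
forward model linking inclusion volume to per-channel ΔZ exists for this
geometry, so the linear-gain Gaussian-kernel model is original to this
package: it is the simplest monotone-decay model consistent with
rotating-sector sensitivity. The focal gain default (60 Ω/mL) puts the
per-channel ΔZ spread in the tens of ohms and, through the kernel's mean
weight (≈0.31), puts the mean-channel detection crossing of the 7.1 Ω
threshold near a third of the 1.2 mL inclusion — the regime a monitor of
this class operates in.

**ICP** follows the classic single-exponential craniospinal
pressure–volume relation, producing discrete plateaus for stepped volume
control and monotone growth in cumulative volume. The osmotic phase
removes an effective volume (1 mL over a 900 s ramp) and the terminal
phase decays ICP toward zero (τ = 150 s), modelling loss of physiologic
pressure.

**Global impedance events settle within their phase.** The osmotic
impedance shift ramps over 900 s and the terminal shift saturates as
1 − exp(−t/150 s). This is deliberate: the multiplexer samples the
eight channels 10–70 s apart, so a shift still ramping during the
terminal measurement cycle would imprint a consistent channel ordering —
a localization artifact of the instrument, not of the injury. Physically
both events reach their new state within minutes; the generator encodes
that.

**Artifacts.** Three classes are generated and filtered: CT bursts
(extra broadband noise on all channels while the scanner runs; scheduled
after every volume step by default, matching the serial-CT protocol), DC
shifts (persistent offsets on one channel), and droplets (exponentially
relaxing offsets, e.g. fluid on an electrode).

What the generator does **not** emulate: anatomical heterogeneity of
channel baselines beyond a flat ±10 % spread, physiologic rhythms
(cardiac/respiratory modulation), the compliance-balloon waveform (only
its sync markers), blood tracking away from the injection site (exposed
as `tracking_fraction`, default 0), or channel-dependent drift. Passing
tests therefore show that the *analysis chain* recovers what the forward
model encodes at realistic signal-to-noise; they do not certify
performance on in-vivo recordings, whose channel variability is far
richer.

## Event metrics

Per channel and event: the zero-volume impedance `Z_V0` is the mean of
usable samples in the 80 s (one full cycle) before the event; each
step's `Z_Vn` is the mean of the usable 10 s slot whose midpoint lies
nearest the middle of that step's static-volume window, skipping slots
that overlap a compliance-balloon check (±10 s guard); equidistant slots
tie-break to the earlier one (deterministic and causal). ΔZ is the
final-step value minus `Z_V0`. Unstepped (global) phases use the final
multiplexing cycle of the phase as their terminal window.

Inflation analysis is **de-trended**: a least-squares line fitted to the
final 10 min of baseline is extrapolated and subtracted, removing the
settling response to instrumentation. If fewer than two usable baseline
samples exist the channel falls back to non-de-trended change with a
warning. De-trending is linear by design; the residual curvature of
exponential settling is what the baseline-repeatability noise floor
(below) absorbs.

**Detection** declares the first volume step at which |signal| ≥ 7.1 Ω,
where the signal is the across-usable-channel mean ΔZ, the designated
nearest channel's ΔZ, or the non-de-trended mean. The 7.1 Ω default is
stored as configuration (`detection_threshold_ohm`): it originates from
a hardware SNR measurement with a 10× safety factor whose reference
level is instrument-specific, so recomputing it from simulation would
be false precision.

**DI = ΔZ/ΔICP** is computed per channel (undefined when |ΔICP| ≤
0.1 mmHg — no pressure response) and summarized per subject as the mean
over usable channels, the quantity entering the paired comparison
between injury types. Pearson r pairs each channel's slot means with ICP
averaged over the same slots (the two streams have different native
rates) and needs ≥ 3 paired slots.

## Localization

Within one event, each subject's usable ΔZ vector is min–max rescaled to
nΔZ ∈ [0, 1]. The historical convention "normalized by the highest
channel, ranging 0–1" is ambiguous: dividing by the maximum cannot reach
0 for positive vectors and breaks when signs mix (they always do for
hemorrhage), so the 0–1 range is realised by min–max rescaling. Two
consequences are handled explicitly and were validated by construction:

1. **Noise amplification on uniform responses.** A global event moves
   all channels together; min–max rescaling of a vector whose spread is
   pure measurement noise manufactures a full 0–1 map from nothing. A
   map whose dynamic range falls below 6× the subject's ΔZ noise floor
   is flagged degenerate and set to 0.5 everywhere. The floor is
   estimated from the data, not fixed: the residual standard deviation
   of late-baseline slot means about their linear trend, times √2 (a ΔZ
   differences two such quantities).
2. **Both thresholds always fire on clean focal maps.** Min–max pins the
   map minimum at exactly 0 and the maximum at exactly 1, so a rule of
   the form "min < 1/3 ⇒ focal-low, max > 2/3 ⇒ focal-high" is
   ambiguous for every clean focal map, and a tie-break on distance from
   0.5 is exactly symmetric (|0−0.5| = |1−0.5|). The classifier instead
   takes the element deviating most from the map **median**: the focal
   element is the outlier against the majority background, while the
   median tracks that background.

Classification runs on the cohort mean map (cohort studies report mean
maps); a per-subject mode is exposed for single-patient use.

## Focal vs global statistics

A focal event perturbs near sectors far more than opposite ones; a
global event moves all sectors together. Three tests quantify this, all
on the per-event ΔZ vectors (unbiased n−1 variances):

- **Levene's test** (classical mean-centered W; median-centering
  available) on the pooled per-channel values of the focal vs the global
  event — robust to non-normality at n = 8 channels. Implemented via
  `scipy.stats.levene`, cross-checked in the tests against a
  hand-computed one-way ANOVA on absolute deviations (they are
  definitionally equal) and a permutation oracle.
- **Welch's t** on the per-subject single-value variances, with the
  Welch–Satterthwaite df computed explicitly.
- **ANOM** of per-event standard deviations: each event's mean std is
  compared with the grand mean against decision limits
  `grand ± h · s_pooled · sqrt((k−1)/(k·n))`, with `h` a
  Bonferroni-adjusted two-sided t quantile at df = Σ(nᵢ−1). The
  Bonferroni form is the standard auditable approximation to exact ANOM
  critical values; unbalanced groups use their own n with a warning.

Variance is computed on raw ΔZ (ohms²) for instrument-scale analyses and
is equally available on nΔZ vectors; both framings appear in practice.
Repeated-measures mixed models are intentionally **not** reimplemented —
the cohort results table exports tidy long-format data for any external
statistics package.

## Preprocessing defaults

- CT windows masked on all channels with a 5 s pad. Masked samples are
  excluded from window means, never interpolated — interpolation would
  manufacture data inside bursts. Filtering never alters sample values
  (mask-only contract).
- Step artifacts: difference of medians of adjacent 80 s windows
  exceeding 20 Ω. One multiplexing cycle is the natural window: a 60 s
  window can contain *no* samples of a channel (slots recur every 80 s)
  and a 90 s window spans two slots, shifting the median one boundary
  early. Changes within ±300 s (one step interval) of any protocol
  intervention — volume step *or* phase onset — are signal, not
  artifact. Samples after the first unrepaired step are masked.
- Exclusion: a channel-phase trace is dropped when its masked fraction
  exceeds 0.5 or it accumulates more than one unrepaired step; every
  exclusion carries a reason in the quality report. If all eight
  channels of a phase are excluded the pipeline stops with an error.
  These thresholds are original to this package (the quality criteria of
  the original monitoring study were not published); they are explicit
  and configurable for that reason.

## Power analysis

`paired_sample_size(mean_diff, sd_diff, alpha, power, tails)` searches n
upward from 2 (the df ≥ 1 floor) using the noncentral-t power of a
paired t-test: power(n) = P(|T′(df=n−1, nc=d√n)| > t₁₋α/2,df). The
normal approximation is deliberately not used — at the effect size the
design question is posed for (d = 1.5, power 0.95) the t correction
changes the answer. Two-sided is the default; the test suite
cross-checks against statsmodels' independent solver and a Monte-Carlo
simulation.

## Problem sizes and numerical choices

- Tests and the acceptance script synthesize full-protocol recordings at
  a 5 Hz envelope rate rather than the hardware's 50 Hz. Every event
  metric operates on 10 s slot means (≥ 50 samples at 5 Hz), so slot
  statistics are essentially rate-independent at the default noise
  level; this is a problem-size choice, and one full-rate bundle is
  still exercised in the I/O tests.
- Monte-Carlo cohort properties use 100 cohorts × 9 subjects, the cohort
  size of the study design the simulator emulates.
- Recording bundles store floats at 1e-6 precision (plain CSV/JSON, one
  directory per recording) — inspectable and language-portable; a
  versioned schema field permits future raw-carrier bundles.
- Seeds: a cohort master seed spawns per-subject seeds via numpy's
  `SeedSequence`, so cohorts are reproducible and extensible; identical
  scenario + seed yields bit-identical recordings.

## Known limitations

- The forward model is phenomenological (kernel × gain × volume), not an
  electromagnetic field solution; absolute ΔZ magnitudes are
  order-of-magnitude realistic, not subject-calibrated.
- In-vivo quantities that depend on real anatomy and physiology —
  Pearson-r magnitudes, p-values, ANOM decision limits in ohms — are
  produced by the same procedures here but their numerical values on
  synthetic cohorts are not comparable to animal data.
- De-trending extrapolates a linear baseline fit across multi-hour
  spans; under strong exponential settling this slightly inflates
  late-step ΔZ (visible as earlier mean-channel detection), the same
  caution that applies to any trend-referenced bedside metric.
- The ANOM flags every event class on clean synthetic cohorts (focal
  events sit far above, global events far below the grand mean) — its
  decision limits are tight when within-event spread is small.
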