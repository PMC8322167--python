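# bim — intracranial bioimpedance monitoring analysis

`bim` implements the analysis chain of a multichannel tetrapolar
bioimpedance monitor for detecting and identifying **secondary brain
injury** at the bedside, together with a ground-truthed simulator of the
porcine injury protocol used to validate such a monitor.

Intracranial pressure (ICP), the clinical mainstay, rises with *any*
added intracranial volume and therefore cannot tell an ischemic mass
effect from an active bleed, nor a focal lesion from diffuse edema.
Tissue impedance can: blood is far more conductive than parenchyma
(≈0.7 S/m vs ≈0.2 S/m), so a hemorrhage *lowers* the impedance seen by
the electrodes near it while an ischemic/mass-effect lesion *raises* it.
Eight rotating scalp–intracranial electrode pairs give eight angular
sensitivity sectors, multiplexed 10 s each, each reporting |Z| at 50 Hz
from matched-filter demodulation of a 50 kHz carrier.

The package computes, per monitored event:

- **ΔZ** per channel — impedance change from the zero-volume reference
  (mean of the 80 s preceding the event) to the final-volume impedance,
  each step measured on the usable 10 s slot nearest the middle of its
  static-volume window;
- **volume-change detection** — first protocol step at which the
  de-trended mean-channel (or designated nearest-channel) |ΔZ| crosses a
  fixed 7.1 Ω threshold;
- **discriminatory index** `DI = ΔZ / ΔICP` — positive for
  high-impedance (ischemia-model) injury, negative for low-impedance
  (hemorrhagic) injury;
- **localization** — per-event channel maps `nΔZ ∈ [0, 1]`, averaged
  across subjects, classified focal-high-Z / focal-low-Z (with the
  culprit element) or global by 1/3–2/3 thresholds;
- **focal vs global statistics** — across-channel variance of ΔZ,
  compared by Levene's test, Welch's t on per-subject single-value
  variances, and an analysis of means (ANOM) of per-event standard
  deviations;
- **system characterization** — SNR (`20·log10(mean/std)`), linear
  calibration accuracy over known resistor loads, temporal coefficient
  of variation, and the paired-design sample-size/power calculation
  (noncentral-t).

## Worked example

Simulate a nine-subject cohort under the default injury protocol
(30 min baseline; balloon inflation 100 µL/5 min to 1.2 mL; mirrored
deflation; blood-analog injection 200 µL/5 min to 1.2 mL; a global
osmotic phase; a global terminal phase) and run the full analysis:

```python
from bim import InjuryScenario, run_cohort

results, _ = run_cohort(InjuryScenario(sample_rate_hz=5.0),
                        n_subjects=9, seed=1)
print(results.summary())
```

```
Cohort injury analysis — n = 9 subjects
========================================================
                 delta_icp_mmhg  mean_delta_z_ohm  subject_di  mean_pearson_r
phase
inflation                 8.370            27.532       3.337           0.997
deflation                -8.361           -18.820       2.288           0.250
hematoma                  8.364           -21.314      -2.588          -0.256
global_osmotic           -7.297            42.500      -5.890          -0.997
global_terminal         -11.251            41.649      -3.744          -0.999

Paired DI, inflation vs hematoma: 3.337 vs -2.588 Ω/mmHg (t = 19.23, p = 5.6e-08, n = 9)
Detection (mean-channel): 9/9 subjects at 0.32 ± 0.04 mL
Detection (closest-channel): 9/9 subjects at 0.20 ± 0.00 mL
Detection (non-detrended): 9/9 subjects at 0.40 ± 0.00 mL

Localization (cohort mean nΔZ classifier):
         inflation: focal_high_z, element 3
         deflation: focal_low_z, element 3
          hematoma: focal_low_z, element 3
    global_osmotic: global
   global_terminal: global

Focal vs global variance: Levene W = 309.0 (p = 1.9e-37); Welch t = 23.78, df = 8.0 (p = 1e-08)
ANOM flagged events: inflation, deflation, hematoma, global_osmotic, global_terminal
```

Reading the output: balloon inflation and blood injection both raise ICP
by ≈8 mmHg, but their DI signs differ (+3.3 vs −2.6 Ω/mmHg) — that sign
is what identifies the injury type. The mean-channel detector flags the
volume change at 0.32 mL of a 1.2 mL inclusion. All three focal events
localize to element 3, where the simulated inclusion sits; both global
events are correctly labelled global, and the variance statistics
separate focal from global decisively.

The same workflow is scriptable from the shell:

```bash
bim simulate --seed 42 --out rec/
bim preprocess --in rec/ --out rec_f/ --report quality.json
bim metrics --in rec_f/ --out metrics.json
bim localize --metrics metrics.json --out localization.json
bim power --mean-diff 0.003 --sd 0.002          # -> minimum n = 8 pairs
bim reproduce --seed 1 --subjects 9 --out repro/  # cohort + figures
```

## Layout

| module | contents |
| --- | --- |
| `bim.io` | domain types, recording bundles (CSV/JSON), protocol config |
| `bim.simulate` | scenario ground truth, envelope + carrier synthesis, cohorts |
| `bim.demod` | matched-filter amplitude extraction, V/I impedance series |
| `bim.preprocess` | CT masking, step-artifact detection, exclusions, de-trending |
| `bim.metrics` | event windows, ΔZ, DI, Pearson r, threshold detection |
| `bim.localize` | nΔZ maps, cohort means, focal/global classifier |
| `bim.variance_stats` | Levene, Welch, ANOM, variance summaries |
| `bim.characterize` | SNR, calibration, CV, paired power analysis |
| `bim.model` | `SubjectInjuryModel` / `CohortInjuryModel` and Results |
| `bim.cli` | `bim` command-line workflow |

See `docs/methods.md` for the models, defaults and their rationale.
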