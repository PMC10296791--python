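# cardioresp

Automatic detection of sleep respiratory events — normal breathing,
hypopnea, apnea, and the obstructive/central apnea subtypes — from
cardiopulmonary signals, with apnea–hypopnea index (AHI) severity
reporting. Built for sleep researchers and biomedical-signal engineers who
want a tested, scriptable pipeline rather than a black box.

## What it does

Overnight recordings carry an ECG channel (128 Hz) and oronasal airflow,
ribcage and abdomen effort channels (8 Hz). The pipeline:

1. **Preprocesses**: zero-phase 0.3-Hz Butterworth low-pass on airflow,
   cascaded-median-filter baseline removal on ECG, 10-s windowing.
2. **Extracts features** per window: airflow morphology (RF = 1/cycle,
   inspiratory duty cycle, volumes, slope); HRV time/frequency/Poincaré
   features from Pan–Tompkins R peaks (including pNN50 with the total
   RR-interval denominator); six entropies (Shannon, Rényi, Tsallis,
   transfer entropy EDR→RR, visibility-graph degree entropy, alphabet
   entropy); and cardiopulmonary coupling CPC(ω) = C_xy(ω)·|S_xy(ω)|²
   between the 4-Hz resampled RR tachogram and the QRS-slope-range
   ECG-derived respiration.
3. **Classifies** windows as N/H/A with gradient-boosted trees (decision
   tree and random forest also available), after Kruskal–Wallis +
   Benjamini–Hochberg feature screening, with TreeSHAP attribution.
4. **Subtypes apnea** by fusing the two effort leads into the 1-D series
   d_i = min_{j≠i} ‖(x_i,y_i) − (x_j,y_j)‖ — the distance from each state
   point of the rib/abdomen trajectory to its nearest other state point —
   and feeding 80-sample fused windows to an LSTM; the operating cutoff is
   chosen by Youden's J on the validation ROC.
5. **Reports AHI**: abnormal runs merge into events (≥ 10 s), AHI =
   events/hour, severity none/mild/moderate/severe at the 5/15/30
   events/h clinical bands.

A synthetic PSG generator (`cardioresp.synthetic`) produces annotated
recordings with the event signatures the classifiers rely on — airflow
collapse during apnea, persistent paradoxical effort in obstructive vs.
absent effort in central apnea, event-locked cyclic heart-rate variation —
so everything is testable offline. Recordings read/write EDF, WFDB and
CSV (`cardioresp.sigio`).

## Worked example

```python
import numpy as np
from cardioresp import SimConfig, EventSpec, generate_recording
from cardioresp.features import extract_features
from cardioresp.models import select_features, train_segment_classifier
from cardioresp.ahi import segments_to_events, compute_ahi
from cardioresp.types import SplitSpec

rec = generate_recording(SimConfig(
    record_length_s=600.0, seed=3,
    event_list=[EventSpec("hypopnea", 100.0, 20.0),
                EventSpec("obstructive_apnea", 250.0, 20.0),
                EventSpec("central_apnea", 400.0, 20.0)]))
tbl = extract_features(rec)                      # one row per 10-s window
print(tbl.groupby("label")[["rf", "insp_vol", "tp"]].mean().round(3))
report = compute_ahi(segments_to_events(list(tbl["label"])), rec.duration_s / 3600)
print(f"AHI = {report.ahi:.1f} ({report.severity})")
```

prints (airflow collapses and RR-spectrum power rises inside events):

```
          rf  insp_vol        tp
label
A      0.125     0.034  5311.928
H      0.250     0.406  1988.356
N      0.247     0.817  1115.889
AHI = 18.0 (moderate)
```

The same flow from the shell, end to end on a simulated cohort:

```
cardioresp simulate --out-dir runs/demo --seed 5
cardioresp features --out-dir runs/demo
cardioresp train    --out-dir runs/demo
cardioresp detect   --out-dir runs/demo
cardioresp subtype  --out-dir runs/demo
cardioresp ahi      --out-dir runs/demo
```

`ahi` prints one line per subject, e.g. `S2: AHI = 36.0 (severe)`, and
writes `ahi_report.json` / `screening.json`; every artifact carries a
`.meta.json` sidecar with the producing config hash and seed.

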