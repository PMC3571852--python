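# drowsefuse

Multimodal driver-drowsiness monitoring at desk scale: extract five
physiological/contextual indicators from raw sensor streams and fuse them
with a fuzzy Bayesian network (FBN) into a continuously updated vigilance
state and alert decision.

The package is aimed at researchers prototyping drowsiness-detection
pipelines who need the full chain — sensor parsing, feature extraction,
fusion, alerting, scoring — runnable offline on recorded or synthetic
sessions, without phone hardware.

## The model

Five indicators are extracted per tick (default 0.2 s):

| symbol | indicator | source |
|--------|-----------|--------|
| PR | PERCLOS — fraction of frames with the eye ≥ 80 % closed (P80) | face frames or an eye-openness CSV |
| HR | heart rate, 60 / mean RR interval | ECG, Pan–Tompkins-style R-peak detection |
| BP | blood-pressure surrogate, BP = a·PP − b | PPG peak-to-valley interval PP |
| SP | speed, SP = (√(x²+y²+z²) − C)·3.6 km/h, C = 9.80665 m/s² | three-axis accelerometer |
| TP | cabin temperature | temperature sensor, validated pass-through |

Each indicator is fuzzified through per-state membership functions and
normalized.  For the joint state (s₁,…,s₅) in the Cartesian product of
parent states, the weight is the product t-norm t = ∏ᵢ yᵢ(sᵢ), and the
fused fatigue probability pair is the CPT-weighted sum over all L
combinations:

    fatigue = ( Σ_p t_p · (1 − cpt_p),  Σ_p t_p · cpt_p )

With normalized memberships the t-norms sum to exactly 1, so
p_false + p_true = 1.  p_true is soft-binned into safe / warning /
dangerous (max-probability state reported), labeled by vigilance band
(awake 0.30–0.54, partial-sleep 0.60–0.75 with a rest advisory, alert
above 0.75; unmapped gaps are surfaced as indeterminate), and the alert
fires strictly above p_true = 0.75.  See `docs/methods.md` for defaults,
assumptions and limitations.

## Worked example

Generate a synthetic 240 s session (first half awake, second half drowsy),
run the pipeline and score it against the generator's ground truth:

```bash
drowsefuse synth --seed 3 --out session/
drowsefuse run --streams session/ --out out/
drowsefuse eval --records out/records.jsonl --truth session/manifest.json
```

which prints

```
session written to session/
1195 ticks, 562 alert ticks -> out/records.jsonl
class   total  true  false  true%  false%
awake     599   597      2   100%      0%
drowsy    596   587      9    98%      2%
tick accuracy: 99.1%
```

Reading: of the 599 ticks whose ground-truth label is awake, 597 were
predicted awake (p_true below the 0.60 partial-sleep edge); 587 of 596
drowsy ticks were predicted drowsy; 562 ticks exceeded the strict 0.75
alert threshold.  The same flow is available as a library:

```python
from drowsefuse import SessionSpec, synth_session, run_pipeline, evaluate
from drowsefuse.pipeline import SessionStreams, PipelineConfig
import numpy as np

session = synth_session(SessionSpec(duration=240.0, seed=3))
records = run_pipeline(SessionStreams.from_session(session),
                       cfg=PipelineConfig(perclos_window=10.0))
table = evaluate(records, session.truth.labels(np.array([r.t for r in records])))
print(table.aw_true_pct, table.dw_true_pct)   # -> 100 99
```

Real recordings plug in through the same CSV schemas (`timestamp,value`
for ECG/PPG, `timestamp,x,y,z` for the accelerometer,
`timestamp,celsius`, `timestamp,openness`, or a directory of PNG face
frames processed by `drowsefuse.vision.OpennessTracker`).

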