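# tremorkit

Tremor detection pipelines for 3D motion-capture kinematic data.

Tremor — an involuntary, rhythmic, oscillatory movement of a body part — is a
cardinal feature of Parkinson's disease and essential tremor, and clinical
assessment still relies on visual observation. Movement-disorder centers that
capture full-body optical motion-capture data (reflective markers tracked at
120 Hz, positions in mm) can instead detect tremor from the spectral content
of marker trajectories: pathological tremor concentrates in a narrow 4–12 Hz
band, voluntary movement lives below ~3 Hz, and optical jitter is broadband.

`tremorkit` implements six detection pipelines over per-extremity marker
trajectories, spanning the evolution from hand-tuned clinical heuristics to
generic machine-learned classifiers:

| id  | signal domain | features | classifier |
|-----|---------------|----------|------------|
| `a1r` | velocity (Savitzky–Golay derivative) | engineered spectral-peak descriptors, winner-take-all across markers | fixed rules |
| `a2r` | displacement amplitude (mm) | dominant peak of a max-aggregated single-sided FFT spectrum | fixed rules |
| `a1s` | velocity | same as `a1r` | SVM (RBF) |
| `a2s` | displacement | same as `a2r` | SVM (RBF) |
| `b1` | position magnitude | 61-point smoothed Welch PSD (0–20 Hz, 0.33 Hz bins) | SVM (RBF or linear) |
| `b2` | position magnitude | same 61-point PSD | XGBoost |

The rule classifiers encode clinical heuristics directly: `a1r` accepts a
velocity-spectrum peak only if it is narrow (3 dB bandwidth ≤ 2 Hz),
symmetric about its center, and at most 10 Hz; `a2r` accepts the dominant
amplitude-spectrum peak if it lies in [3.5, 10] Hz and reaches 0.1 mm.
Evaluation uses stratified 5-fold cross-validation with

    accuracy = (TP+TN)/(TP+TN+FP+FN)      precision = TP/(TP+FP)
    recall   = TP/(TP+FN)                  specificity = TN/(TN+FP)
    F1 = 2·precision·recall/(precision+recall)

plus ROC/PRC curves with AUROC/AUPRC for the trainable spectral pipelines.

Because clinical recordings are not redistributable, the package ships a
synthetic kinematic simulator (`tremorkit.simulate`) that generates labeled
extremity recordings with the same spectral structure — shared-frequency
sinusoidal tremor, low-frequency voluntary movement, white marker jitter,
metre-scale baseline offsets, clinical duration statistics — so every stage
is exercisable without any data download. See `docs/methods.md` for the
model, parameter defaults, and known limitations.

## Worked example

```python
import tremorkit as tk

# 400 labeled synthetic recordings, 32% tremor-present, amplitudes >= 0.5 mm
ds = tk.standard_benchmark(n=400, prevalence=0.32, seed=1)

# one tremor-present recording through the amplitude-domain rule pipeline
rec = ds.records[1]
feats = tk.extract_a2_for_recording(rec)
print(rec.extremity, rec.label)
print(f"peak {feats.F_CENTER:.2f} Hz, amplitude {feats.AMPLITUDE_MM:.2f} mm "
      f"-> {tk.classify_a2r(feats)}")

# cross-validated comparison of two pipelines
for pid in ("a2r", "b2"):
    res = tk.cross_validate(pid, ds.records, ds.labels, k=5, seed=1)
    print(f"{pid}: F1 = {res.mean['f1']:.3f} ({res.sd['f1']:.3f})")
```

prints

```
L_Prox_Arm present
peak 9.91 Hz, amplitude 0.41 mm -> present
a2r: F1 = 1.000 (0.000)
b2: F1 = 0.988 (0.011)
```

This recording carries a faint 9.9 Hz, ~0.5 mm tremor on the left upper
arm; the dominant aggregate-spectrum peak falls inside the accepted
[3.5, 10] Hz band and above the 0.1 mm threshold, so the rule classifier
calls it present. Cross-validated F1 is the mean (sample SD) over five stratified
folds; on this clean synthetic benchmark both the legacy rule pipeline and
the XGBoost pipeline are near ceiling — real clinical recordings are
substantially harder.

The same workflows are scriptable from the shell:

```sh
tremorkit simulate --n 100 --prevalence 0.32 --seed 7 --out data/
tremorkit detect   --pipeline a2r --input data/ --out predictions.csv
tremorkit train    --pipeline b2  --input data/ --model-out b2.joblib
tremorkit evaluate --pipeline b2  --input data/ --k 5 --seed 7 --out report.json
```

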