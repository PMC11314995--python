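# Methods

This note documents the signal models, the numerical choices behind each
pipeline, what the synthetic generator does and does not emulate, and the
design decisions taken where the underlying clinical algorithms left the
details open.

## Problem setting

Input data are 3D optical motion-capture marker trajectories: frames at
120 Hz, one (x, y, z) triplet in millimetres per marker, grouped onto 16
named body extremities (head, shoulders, thorax, pelvis, left/right hand,
distal/proximal arm, foot, distal/proximal leg). The task is binary: decide,
per extremity per recording, whether pathological tremor is present.
Clinician annotations use a 14-label free-text vocabulary; every size
qualifier ("very slight or very trace" through "severe", plus "present",
"intermittent" and the unsized "other" category) dichotomizes to *present*,
while "absent" and the dystonia/dyskinesia category dichotomize to *absent*
— dyskinetic and dystonic movements can resemble tremor but are not tremor.

Spectrally, tremor is a narrowband oscillation, typically 4–12 Hz and
nearly sinusoidal; voluntary movement concentrates below about 3 Hz;
optical marker jitter is broadband and becomes relatively stronger at high
frequencies. All six pipelines therefore reduce trajectories to spectral
descriptions and differ in which domain they analyze and how they classify.

## A1: velocity-domain peak features

Each marker axis is low-pass filtered at 20 Hz with a 4th-order Butterworth
applied forward–backward (zero phase), mean-centered, and differentiated
with a Savitzky–Golay derivative filter (order 3, window 7 samples ≈ 58 ms).
The window length was set so that the derivative's amplitude error stays
below 2% across the 4–10 Hz band accepted by the rules; an 11-sample window
would lose ~10% at 10 Hz. Per-axis Welch PSDs (Hamming window,
`min(480, n)` samples per segment, 50% overlap — 480 samples gives 0.25 Hz
bins, which places the 10 Hz decision boundary exactly on a bin) are
combined with the Euclidean norm `sqrt(Px² + Py² + Pz²)`, log-scaled,
smoothed with a Savitzky–Golay filter (order 3, 9 bins), and returned to
linear scale.

Peak characterization searches a configurable analysis band, default
3–20 Hz. The lower edge sits above the voluntary-movement band on purpose:
a large voluntary oscillation at 1–2 Hz produces a narrow, symmetric
velocity-spectrum peak that would pass every other rule, so admitting it
into the search would make pure voluntary movement indistinguishable from
tremor. Within the band:

- `F_CENTER`, `MAX_POWER`: location of the smoothed-PSD global maximum;
  the power (and the amplitude below) is read from the *unsmoothed* PSD in
  a ±4-bin neighborhood, because log-domain smoothing deflates narrow peaks.
- `LO_F`, `HI_F`, `BW`: log-interpolated −3 dB crossings on either side and
  their distance. A peak with no crossing inside the band yields
  `valid_peak = False`.
- `LO_POWER`, `HI_POWER`: smoothed log-PSD interpolated at symmetric
  one-bandwidth offsets from the midpoint of the two crossings. A pure
  sinusoid's leakage shape is symmetric about that midpoint, so the two
  values agree; a peak riding a sloped shoulder does not. (Powers *at* the
  crossings are −3 dB on both sides by construction, and powers at the
  first bin below threshold are hypersensitive to sub-bin frequency offsets
  on the steep leakage skirt — synthetic experiments showed 4–6 dB of
  spurious asymmetry for genuine tremor.)
- `AMPLITUDE_MM_P_S = sqrt(2 · P_peak · ENBW)`: the sinusoid-equivalent
  velocity amplitude, using the Welch window's equivalent noise bandwidth.
  Note that with tremor present on all three axes the combined-norm PSD is
  √3 larger than a single axis, so this reads 3^¼ × (2π f A) for a tremor
  of displacement amplitude A per axis.
- `RELATIVE_POWER`: trapezoidal power in [LO_F, HI_F] over total power.

The A1r rules accept a marker's peak as tremor iff it is valid, `BW ≤ 2 Hz`,
`|HI_POWER − LO_POWER| ≤ 3 dB` (the symmetry tolerance is configurable; the
source heuristic was never quantified), and `F_CENTER ≤ 10 Hz`. The
extremity verdict is winner-take-all: the features of the rule-passing
marker with the largest amplitude represent the extremity (ties break to
the lowest marker index); with no passing marker the verdict is absent and
the largest-amplitude valid peak is reported.

## A2: amplitude-domain aggregate spectrum

Each marker axis is high-pass filtered at 2 Hz (4th-order Butterworth,
forward–backward) to strip posture and drift, then converted to a
single-sided FFT amplitude spectrum (`2|DFT|/N`, mm units, no zero padding).
All x/y/z spectra of all markers on the extremity are combined bin-wise
with a maximum — the aggregate represents the most severe tremor at each
frequency — and smoothed with a Savitzky–Golay filter (order 3, 9 bins,
clamped at zero). Peaks are local maxima of the smoothed aggregate under
the common default definition (strictly greater than both neighbors,
plateaus taking the leftmost point); the dominant peak is the largest. Its
prominence and half-prominence width come from the standard peak-prominence
machinery; its *amplitude* is read from the raw aggregate around the
located bin, since Savitzky–Golay smoothing of the near-delta peak of a
sinusoid retains only ~26% of its height and the reported value is meant to
track the physical oscillation amplitude in mm (this also keeps the
0.1 mm decision threshold meaningful).

The A2r rule calls tremor present iff the dominant peak is valid,
`3.5 Hz ≤ F_CENTER ≤ 10 Hz` (boundaries inclusive — the source rule
discards peaks strictly outside the range), and `AMPLITUDE_MM ≥ 0.1 mm`.

## A1s / A2s: engineered features into an SVM

The same engineered feature rows (nine A1 descriptors, four A2 descriptors)
feed an RBF-kernel SVM. Rows whose extraction found no valid peak are
imputed with zeros plus a `NO_PEAK` indicator column, preserving the
"no peak found" information without dropping records. Features are
standardized to train-set mean/SD; C = 1 and `gamma = 'scale'` — no
hyperparameter search is performed anywhere in the package, mirroring the
untuned legacy setting. Probabilities come from cross-fitted Platt scaling
(`CalibratedClassifierCV(SVC(), ensemble=False, cv=5)`), and `predict` is
exactly `predict_proba[:, 1] ≥ 0.5`.

## B1 / B2: generic spectral features

Each marker's trajectory is reduced to its Euclidean distance from the
kinematic origin (one scalar per marker), bandpass filtered 1–20 Hz with a
linear-phase order-80 Hamming-window FIR, and decimated 120 → 40 Hz. The
constant 40-sample group delay is compensated by reflection padding and
valid-mode convolution, which preserves length (a 3.0 s recording still
yields the 120 samples needed below) and avoids edge ramps from the
metre-scale baseline. Note the FIR's ~5 Hz transition width means its 1 Hz
edge cannot null DC (|H(0)| ≈ 0.36); the residual is removed by per-segment
constant detrending in the Welch step. Spectra use 120-sample (3 s) Hamming
windows advanced by 10 samples (2.75 s overlap), a 120-point DFT, and a
circular Gaussian smoother of σ = 1 Hz (3 bins, truncated at ±4σ,
renormalized) applied to the two-sided PSD; the first 61 values (DC plus
positive frequencies at 40/120 = 0.333 Hz spacing up to 20 Hz) form the
feature vector, averaged across the extremity's markers.

B2 feeds the raw 61-point vectors to XGBoost (100 rounds, library-default
depth and learning rate, logloss evaluation metric, integer labels, fixed
seed). B1 feeds them to the SVM described above with one addition: a
log10 compression before standardization. PSD values span many orders of
magnitude, and an RBF margin on the raw power scale is dominated by the
heavy-tailed low-frequency bins — on the synthetic benchmark the raw-scale
SVM ranked classes almost perfectly (AUROC 0.98) while placing the decision
boundary poorly (F1 0.80); on the decibel-like scale both are near-perfect.
Decision trees are scale-invariant, so B2 is unaffected by this choice.

A documented geometric property of the magnitude projection: tremor
oscillating orthogonally to the marker's position vector is attenuated in
`|r(t)|`, so the B pipelines are origin-sensitive. This is inherent to the
design (and one reason the A pipelines remain available), not a bug; the
test suite pins it down quantitatively.

## Evaluation

Stratified 5-fold cross-validation at the (recording, extremity) record
level, shuffled deterministically from a seed; each test fold's class
counts are within one record of proportional. Metrics are computed from
confusion counts by their defining formulas, with 0/0 ratios reported as 0
and logged. Specificity uses the standard TN/(TN+FP); a
`specificity_as_printed` flag reproduces the TN/(TN+FN) variant that some
sources print, for auditing. Feature extraction runs once for all records
(it is unsupervised, so nothing leaks across folds); classifiers are refit
per fold — a no-op for the rule pipelines, whose across-fold variation
comes only from fold membership. ROC areas are trapezoidal; PRC areas use
step interpolation (average precision); mean ROC curves are vertically
averaged on a 101-point false-positive-rate grid with ±1 SD bands. Rule
pipelines emit degenerate {0, 1} scores and no curves by default (they have
no operating range); curves can be forced via `emit_curves=True`. Fold
SDs are sample SDs (n−1). An optional grouped-CV entry point is
deliberately out of scope: fold assignment at the record level matches the
evaluation protocol this package implements.

## Synthetic data generator

Per marker m and axis a the generated position (mm) is

    x(t) = baseline_a
         + Σ_k A_k sin(2π f_k t + φ_{m,a,k})          (voluntary, f_k < 3 Hz)
         + s_m A_t [sin(2π f_t t + ψ_{m,a}) + h sin(4π f_t t + ψ2)]  (tremor)
         + ε(t),  ε ~ N(0, jitter_sd²) white

with tremor frequency f_t shared across the extremity's markers, a
per-marker amplitude scale s_m ∈ [0.5, 1] (distal markers tremble most),
independent phases per marker and axis, and an optional second harmonic h.
Tremor is modeled as a (near-)pure sinusoid because neurologic tremor is
highly sinusoidal; voluntary movement as 1–3 summed sinusoids; jitter as
white Gaussian noise (no published jitter spectrum; white is the
conservative default). All randomness flows from a single root seed through
spawned per-recording streams, so datasets are bit-reproducible.

Dataset-level defaults emulate the clinical recording conditions:

- duration ~ N(27 s, 9 s) clipped to [3, 92] s at 120 Hz;
- three markers per extremity, extremity drawn uniformly from the 16 names;
- prevalence 0.32 (the positive fraction of the clinical annotation
  distribution), with exactly `round(n · prevalence)` positives;
- tremor frequency U[4, 10] Hz — the common parkinsonian/essential band,
  inside every pipeline's accepted range, so the benchmark measures
  detection capability rather than the rule pipelines' deliberate >10 Hz
  cutoff; the per-recording configuration accepts up to 12 Hz;
- tremor amplitude log-uniform 0.2–10 mm, straddling the 0.1 mm clinical
  threshold up to the ~1 cm clinical-scale anchor (the *standard benchmark*
  raises the floor to 0.5 mm);
- voluntary components at U[0.25, 1.25] Hz — typical goal-directed reaching
  rates — with half the recordings rest-like (component amplitudes ≤ 1 mm)
  and half movement-like (log-uniform 2–20 mm), so classifiers must reject
  voluntary motion, not merely detect energy;
- jitter SD U[0.02, 0.05] mm; baseline offsets at N(1000, 200) mm from the
  origin in a random direction.

What the generator does *not* emulate: task-specific trajectory shapes
(pointing paths, gait cycles), biomechanically articulated linkage between
extremities, amplitude-modulated or intermittent tremor, dystonic/
dyskinetic waveforms, marker occlusion and relabeling artifacts, and the
correlated (non-white) component of optical noise. Passing the synthetic
suite therefore demonstrates that each pipeline implements its intended
spectral computation and separates well-posed tremor from voluntary motion
and jitter — it does not certify clinical performance, where recordings
are substantially harder and rule pipelines are known to trade sensitivity
for specificity.

## Problem sizes and numerical conventions

The standard benchmark used by the test suite and the acceptance script is
n = 400 recordings at prevalence 0.32 with the 0.5 mm amplitude floor, a
size at which all six cross-validated pipelines run in well under a minute
while leaving ~26 positives in each test fold. Welch scaling is density
(power/Hz) throughout; any consistent scaling works for classification, the
choice is fixed for test stability. Zero PSD bins are floored at 1e-300
before log-scaling. TRC files follow the Motion Analysis tab-separated
dialect (three metadata lines, marker-name line, axis-label line, blank
line, then `Frame# Time` plus kinematic columns; trailing blank columns
tolerated; a `Units` header of `m` is converted to mm on read). Missing
samples become NaN on read and are linearly interpolated up to a 0.25 s
gap; markers with longer gaps are rejected with a warning — clinically
delivered files are already interpolated by staff, so this guards degraded
or synthetic inputs only. The CLI exposes `simulate`, `extract`, `train`,
`detect`, and `evaluate` subcommands (`train` exists so that `detect
--model` has a producer); exit code 2 flags configuration errors and 3
data errors, and every command writes a provenance JSON recording its
configuration and the package version.

## Known limitations

- The default marker-to-extremity map is an illustrative 60-marker montage;
  real deployments supply their own YAML/JSON map.
- The A2 pipeline characterizes a single dominant peak; two simultaneous
  tremor frequencies are not reported separately.
- A voluntary-movement component close to the 2 Hz high-pass corner with a
  large amplitude can out-compete a faint tremor peak in A2's aggregate
  spectrum; this mirrors the source heuristic's known recall limit.
- Decision thresholds sit at 0.5 and are not calibrated to any clinical
  operating point; the ROC/PRC machinery exposes the full operating range
  for the trainable pipelines.
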