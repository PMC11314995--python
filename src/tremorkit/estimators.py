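"""Scikit-learn style transformers and classifiers for the six pipelines.

Feature transformers turn lists of :class:`~tremorkit.trc.ExtremityRecording`
into numeric matrices; classifiers consume those matrices. The composed
pipelines are:

========  =========================================  =======================
id        features                                   classifier
========  =========================================  =======================
``a1r``   velocity-spectrum peak (winner-take-all)   fixed rules (no fit)
``a2r``   amplitude-spectrum aggregate peak          fixed rules (no fit)
``a1s``   same as a1r                                SVM, RBF kernel
``a2s``   same as a2r                                SVM, RBF kernel
``b1``    61-point smoothed PSD (marker average)     SVM, RBF/linear kernel
``b2``    61-point smoothed PSD (marker average)     XGBoost, logloss
========  =========================================  =======================

Engineered-feature rows with no valid spectral peak are imputed with zeros
plus a ``NO_PEAK`` indicator column so the SVMs keep the "no peak found"
information without dropping rows. Labels are integers (1 = tremor
present, 0 = absent). All estimators follow the scikit-learn contract
(``get_params``/``set_params``, ``fit``/``predict``/``predict_proba``,
fitted attributes with trailing underscores) and compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from ._errors import ConfigError, DataError
from .amplitude import A2_FEATURE_NAMES, A2Features, extract_a2_for_recording
from .spectral import SPECTRAL_FEATURE_NAMES, extremity_feature_vector
from .trc import LABEL_PRESENT, ExtremityRecording
from .velocity import (
    A1_FEATURE_NAMES,
    A1Features,
    classify_a1r,
    extract_a1_for_recording,
)

PIPELINE_IDS = ("a1r", "a2r", "a1s", "a2s", "b1", "b2")
NO_PEAK_FLAG = "NO_PEAK"

MODEL_FORMAT_VERSION = 1


def labels_to_int(labels: Sequence[str | int]) -> np.ndarray:
    """Map present/absent strings (or 0/1 ints) to a 0/1 integer array."""
    out = []
    for lab in labels:
        if isinstance(lab, str):
            out.append(1 if lab == LABEL_PRESENT else 0)
        else:
            out.append(int(lab))
    return np.asarray(out, dtype=int)


def handle_invalid_features(
    rows: Sequence[A1Features | A2Features], feature_names: Sequence[str]
) -> pd.DataFrame:
    """Impute no-peak feature rows with zeros and add a ``NO_PEAK`` flag.

    Valid rows pass through unchanged with flag 0; rows whose extraction
    found no usable spectral peak become all-zero with flag 1. The output
    never contains NaN.
    """
    mat = []
    for r in rows:
        if r.valid_peak:
            mat.append(list(r.as_row()) + [0.0])
        else:
            mat.append([0.0] * len(feature_names) + [1.0])
    df = pd.DataFrame(mat, columns=list(feature_names) + [NO_PEAK_FLAG])
    assert not df.isna().any().any()
    return df


class _RecordingTransformer(TransformerMixin, BaseEstimator):
    """Base for stateless recording->matrix transformers."""

    def fit(self, X, y=None):  # noqa: D102 - no state to fit
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[ExtremityRecording]) -> np.ndarray:
        return self._frame(X).to_numpy(float)

    def transform_frame(self, X: Sequence[ExtremityRecording]) -> pd.DataFrame:
        return self._frame(X)

    def _frame(self, X) -> pd.DataFrame:  # pragma: no cover - abstract
        raise NotImplementedError


class VelocityPeakFeatures(_RecordingTransformer):
    """A1 engineered features: winner-take-all velocity-spectrum peak.

    One row per recording holding the representative marker's nine
    engineered peak descriptors plus the ``NO_PEAK`` flag. The
    representative marker is the rule-passing marker with the largest
    tremor amplitude, falling back to the largest-amplitude valid peak.
    """

    def __init__(
        self,
        band_hz: tuple[float, float] = (3.0, 20.0),
        max_bandwidth_hz: float = 2.0,
        symmetry_tol_db: float = 3.0,
        max_center_freq_hz: float = 10.0,
    ):
        self.band_hz = band_hz
        self.max_bandwidth_hz = max_bandwidth_hz
        self.symmetry_tol_db = symmetry_tol_db
        self.max_center_freq_hz = max_center_freq_hz

    def _frame(self, X) -> pd.DataFrame:
        reps = []
        for rec in X:
            feats = extract_a1_for_recording(rec, band_hz=self.band_hz)
            _, rep = classify_a1r(
                feats,
                max_bandwidth_hz=self.max_bandwidth_hz,
                symmetry_tol_db=self.symmetry_tol_db,
                max_center_freq_hz=self.max_center_freq_hz,
            )
            reps.append(rep)
        return handle_invalid_features(reps, A1_FEATURE_NAMES)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(list(A1_FEATURE_NAMES) + [NO_PEAK_FLAG])


class AmplitudePeakFeatures(_RecordingTransformer):
    """A2 engineered features: dominant peak of the max-aggregated spectrum."""

    def __init__(self, corner_hz: float = 2.0, smooth_window: int = 9):
        self.corner_hz = corner_hz
        self.smooth_window = smooth_window

    def _frame(self, X) -> pd.DataFrame:
        rows = [
            extract_a2_for_recording(
                rec, corner_hz=self.corner_hz, smooth_window=self.smooth_window
            )
            for rec in X
        ]
        return handle_invalid_features(rows, A2_FEATURE_NAMES)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(list(A2_FEATURE_NAMES) + [NO_PEAK_FLAG])


class SpectralFeatures(_RecordingTransformer):
    """B-pipeline features: marker-averaged 61-point smoothed PSD vectors."""

    def _frame(self, X) -> pd.DataFrame:
        rows = [extremity_feature_vector(rec).values for rec in X]
        return pd.DataFrame(np.vstack(rows), columns=list(SPECTRAL_FEATURE_NAMES))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(SPECTRAL_FEATURE_NAMES)


class _RuleClassifierBase(ClassifierMixin, BaseEstimator):
    """Fixed-threshold rule classifier: fitting is a no-op.

    ``predict_proba`` emits degenerate {0, 1} scores; the decision has no
    tunable operating point.
    """

    def fit(self, X, y=None):
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = np.asarray(X).shape[1] if np.ndim(X) == 2 else 0
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        return self._apply_rules(np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        pred = self.predict(X)
        return np.column_stack([1.0 - pred, pred]).astype(float)

    def _apply_rules(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class A1RuleClassifier(_RuleClassifierBase):
    """A1r rules on the representative velocity-peak feature row.

    Present iff a valid peak exists (flag 0), the 3 dB bandwidth is at most
    2 Hz, border powers agree within the symmetry tolerance, and the center
    frequency is at most 10 Hz.
    """

    def __init__(
        self,
        max_bandwidth_hz: float = 2.0,
        symmetry_tol_db: float = 3.0,
        max_center_freq_hz: float = 10.0,
    ):
        self.max_bandwidth_hz = max_bandwidth_hz
        self.symmetry_tol_db = symmetry_tol_db
        self.max_center_freq_hz = max_center_freq_hz

    _cols = {k: i for i, k in enumerate(A1_FEATURE_NAMES)}

    def _apply_rules(self, X: np.ndarray) -> np.ndarray:
        c = self._cols
        no_peak = X[:, len(A1_FEATURE_NAMES)] > 0.5
        ok = (
            ~no_peak
            & (X[:, c["BW"]] <= self.max_bandwidth_hz)
            & (np.abs(X[:, c["HI_POWER"]] - X[:, c["LO_POWER"]]) <= self.symmetry_tol_db)
            & (X[:, c["F_CENTER"]] <= self.max_center_freq_hz)
        )
        return ok.astype(int)


class A2RuleClassifier(_RuleClassifierBase):
    """A2r rules: dominant peak in [3.5, 10] Hz with amplitude >= 0.1 mm."""

    def __init__(
        self,
        min_center_freq_hz: float = 3.5,
        max_center_freq_hz: float = 10.0,
        min_amplitude_mm: float = 0.1,
    ):
        self.min_center_freq_hz = min_center_freq_hz
        self.max_center_freq_hz = max_center_freq_hz
        self.min_amplitude_mm = min_amplitude_mm

    _cols = {k: i for i, k in enumerate(A2_FEATURE_NAMES)}

    def _apply_rules(self, X: np.ndarray) -> np.ndarray:
        c = self._cols
        no_peak = X[:, len(A2_FEATURE_NAMES)] > 0.5
        ok = (
            ~no_peak
            & (X[:, c["F_CENTER"]] >= self.min_center_freq_hz)
            & (X[:, c["F_CENTER"]] <= self.max_center_freq_hz)
            & (X[:, c["AMPLITUDE_MM"]] >= self.min_amplitude_mm)
        )
        return ok.astype(int)


class _ThresholdedClassifierBase(ClassifierMixin, BaseEstimator):
    """Trainable classifier whose predict thresholds predict_proba.

    Guarantees ``predict(X) == (predict_proba(X)[:, 1] >= threshold)``
    exactly, with the default threshold at 0.5.
    """

    threshold: float = 0.5

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = labels_to_int(y)
        if np.isnan(X).any():
            raise DataError("feature matrix contains NaN after imputation")
        if np.unique(y).size < 2:
            raise DataError("training labels contain a single class")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.model_ = self._build()
        self.model_.fit(X, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"feature count {X.shape[1]} does not match training schema "
                f"({self.n_features_in_})"
            )
        return self.model_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    def _build(self):  # pragma: no cover - abstract
        raise NotImplementedError


def _log10_eps(X: np.ndarray) -> np.ndarray:
    """Decibel-like compression for nonnegative power-scale features."""
    return np.log10(np.asarray(X, dtype=float) + 1e-12)


class SVMDetector(_ThresholdedClassifierBase):
    """Standardized SVM with cross-fitted Platt-scaled probabilities.

    Defaults mirror an untuned configuration: C = 1, ``gamma='scale'``
    (1 / (n_features * feature variance)), RBF kernel (linear available).
    With ``log_features=True`` (used for power-spectral inputs) features
    are log-compressed before standardization: PSD values span orders of
    magnitude and a kernel margin on the raw power scale is dominated by
    the heavy-tailed bins.
    """

    def __init__(
        self,
        kernel: str = "rbf",
        C: float = 1.0,
        gamma: str | float = "scale",
        standardize: bool = True,
        log_features: bool = False,
        threshold: float = 0.5,
        seed: int = 0,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.standardize = standardize
        self.log_features = log_features
        self.threshold = threshold
        self.seed = seed

    def _build(self):
        svc = CalibratedClassifierCV(
            SVC(kernel=self.kernel, C=self.C, gamma=self.gamma), ensemble=False, cv=5
        )
        steps = []
        if self.log_features:
            steps.append(("log", FunctionTransformer(_log10_eps)))
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(("svc", svc))
        return Pipeline(steps)


class XGBoostDetector(_ThresholdedClassifierBase):
    """Gradient-boosted trees with the logloss evaluation metric.

    Untuned defaults (100 rounds, library default depth and learning rate);
    label encoding is bypassed by passing integer labels directly.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        threshold: float = 0.5,
        seed: int = 0,
    ):
        self.n_estimators = n_estimators
        self.threshold = threshold
        self.seed = seed

    def _build(self):
        return XGBClassifier(
            n_estimators=self.n_estimators,
            eval_metric="logloss",
            random_state=self.seed,
            n_jobs=1,
            tree_method="hist",
        )


def make_detector(pipeline_id: str, seed: int = 0, **overrides) -> Pipeline:
    """Assemble a full detection pipeline (features -> classifier).

    ``overrides`` are forwarded as sklearn parameter overrides, e.g.
    ``make_detector("b1", clf__kernel="linear")``.
    """
    pid = pipeline_id.lower()
    if pid == "a1r":
        steps = [("features", VelocityPeakFeatures()), ("clf", A1RuleClassifier())]
    elif pid == "a2r":
        steps = [("features", AmplitudePeakFeatures()), ("clf", A2RuleClassifier())]
    elif pid == "a1s":
        steps = [("features", VelocityPeakFeatures()), ("clf", SVMDetector(seed=seed))]
    elif pid == "a2s":
        steps = [("features", AmplitudePeakFeatures()), ("clf", SVMDetector(seed=seed))]
    elif pid == "b1":
        steps = [
            ("features", SpectralFeatures()),
            ("clf", SVMDetector(log_features=True, seed=seed)),
        ]
    elif pid == "b2":
        steps = [("features", SpectralFeatures()), ("clf", XGBoostDetector(seed=seed))]
    else:
        raise ConfigError(f"unknown pipeline id {pipeline_id!r}; valid: {PIPELINE_IDS}")
    pipe = Pipeline(steps)
    if overrides:
        pipe.set_params(**overrides)
    return pipe


def is_rule_pipeline(pipeline_id: str) -> bool:
    return pipeline_id.lower() in ("a1r", "a2r")


def save_model(pipeline: Pipeline, pipeline_id: str, path: str | Path) -> None:
    """Persist a fitted pipeline with a format version stamp."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "pipeline_id": pipeline_id,
            "pipeline": pipeline,
        },
        path,
    )


def load_model(path: str | Path) -> tuple[Pipeline, str]:
    """Load a model written by :func:`save_model`; returns (pipeline, id)."""
    blob = joblib.load(path)
    if not isinstance(blob, dict) or blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise DataError(f"{path}: not a tremorkit model file (or unsupported version)")
    return blob["pipeline"], blob["pipeline_id"]
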