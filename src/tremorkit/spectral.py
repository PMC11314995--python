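"""Generic 61-point spectral feature vectors (B-pipeline preprocessing).

Each marker's 3D trajectory is reduced to its Euclidean distance from the
kinematic origin (one scalar signal per marker), bandpass filtered between
1 and 20 Hz with a linear-phase order-80 Hamming-window FIR, and decimated
from 120 Hz to 40 Hz. The spectrum is then estimated with Welch's method
using 120-sample (3 s) Hamming windows overlapping by 2.75 s (10-sample
hop) and a 120-point DFT, smoothed with a circular Gaussian kernel of
standard deviation 1 Hz, and truncated to the 61 one-sided values (DC plus
positive frequencies at 0.333 Hz spacing up to 20 Hz). The extremity
feature vector is the arithmetic mean over its markers.

Because the projection onto the position magnitude depends on where the
marker sits relative to the origin, tremor oscillating orthogonally to the
position vector is attenuated — a documented property of this design (and
a reason the A-pipelines stay available), not a bug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import firwin, welch

from ._errors import DataError
from .trc import ExtremityRecording

TARGET_RATE_HZ = 40.0
N_DFT = 120
N_FEATURES = 61
BIN_HZ = TARGET_RATE_HZ / N_DFT  # 0.333... Hz

SPECTRAL_FEATURE_NAMES = tuple(f"f{(i * BIN_HZ):05.2f}" for i in range(N_FEATURES))


@dataclass
class SpectralFeatureVector:
    """61 nonnegative smoothed PSD values on the 0-20 Hz grid."""

    values: np.ndarray
    freqs: np.ndarray
    n_markers_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.shape != (N_FEATURES,) or self.freqs.shape != (N_FEATURES,):
            raise DataError(f"spectral feature vector must have length {N_FEATURES}")


def marker_magnitude(trajectory_xyz: np.ndarray) -> np.ndarray:
    """Instantaneous distance from the kinematic origin, sqrt(x^2+y^2+z^2)."""
    x = np.asarray(trajectory_xyz, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise DataError("trajectory must have shape (n, 3)")
    if not np.isfinite(x).all():
        raise DataError("trajectory contains non-finite values")
    return np.linalg.norm(x, axis=1)


def fir_bandpass_taps(
    frame_rate: float = 120.0,
    band_hz: tuple[float, float] = (1.0, 20.0),
    order: int = 80,
) -> np.ndarray:
    """Linear-phase Hamming-window FIR bandpass coefficients (symmetric)."""
    return firwin(order + 1, list(band_hz), fs=frame_rate, pass_zero=False, window="hamming")


def bandpass_decimate(
    signal: np.ndarray,
    frame_rate: float = 120.0,
    band_hz: tuple[float, float] = (1.0, 20.0),
    order: int = 80,
    decimation: int = 3,
) -> tuple[np.ndarray, float]:
    """FIR bandpass then downsample by 3 (120 Hz -> 40 Hz).

    The constant group delay (order/2 samples) is compensated by
    reflection-padding and valid-mode convolution, which also avoids edge
    ramps from the large positional offset and preserves signal length; no
    separate anti-alias filter is needed since the passband ends at the new
    Nyquist frequency.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise DataError("signal must be 1-D")
    taps = fir_bandpass_taps(frame_rate, band_hz, order)
    pad = order // 2
    if x.shape[0] <= order + 1:
        raise DataError(f"signal too short for order-{order} FIR filtering")
    padded = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
    filtered = np.convolve(padded, taps, mode="valid")
    return filtered[::decimation], frame_rate / decimation


def _gaussian_kernel(sigma_bins: float, halfwidth_sigmas: float = 4.0) -> np.ndarray:
    k = int(np.ceil(halfwidth_sigmas * sigma_bins))
    g = np.exp(-0.5 * (np.arange(-k, k + 1) / sigma_bins) ** 2)
    return g / g.sum()


def welch_psd_smoothed(
    signal_40hz: np.ndarray,
    sample_rate: float = TARGET_RATE_HZ,
    smoothing_sigma_hz: float = 1.0,
) -> SpectralFeatureVector:
    """Welch PSD (120-point DFT, 0.25 s hop) with circular Gaussian smoothing.

    Requires at least one full 3 s window (120 samples at 40 Hz). The
    Gaussian kernel (sigma = 1 Hz = 3 bins, truncated at four sigmas,
    renormalized) is applied circularly to the two-sided PSD before the
    one-sided truncation to 61 values.
    """
    x = np.asarray(signal_40hz, dtype=float)
    if x.ndim != 1:
        raise DataError("signal must be 1-D")
    if x.shape[0] < N_DFT:
        raise DataError(
            f"need at least {N_DFT} samples ({N_DFT / sample_rate:g} s at "
            f"{sample_rate:g} Hz), got {x.shape[0]}"
        )
    freqs2, psd2 = welch(
        x,
        fs=sample_rate,
        window="hamming",
        nperseg=N_DFT,
        noverlap=N_DFT - 10,  # 3 s windows, 2.75 s overlap
        nfft=N_DFT,
        detrend="constant",
        return_onesided=False,
        scaling="density",
    )
    kernel = _gaussian_kernel(smoothing_sigma_hz / BIN_HZ)
    smoothed = convolve1d(psd2, kernel, mode="wrap")
    values = smoothed[:N_FEATURES]
    freqs = np.abs(freqs2[:N_FEATURES])  # index 60 is the Nyquist bin (+/-20 Hz)
    return SpectralFeatureVector(values=values, freqs=freqs, n_markers_averaged=1)


def marker_feature_vector(
    trajectory_xyz: np.ndarray, frame_rate: float = 120.0
) -> SpectralFeatureVector:
    """Magnitude -> bandpass/decimate -> smoothed Welch PSD for one marker."""
    mag = marker_magnitude(trajectory_xyz)
    decimated, rate = bandpass_decimate(mag, frame_rate)
    return welch_psd_smoothed(decimated, rate)


def extremity_feature_vector(recording: ExtremityRecording) -> SpectralFeatureVector:
    """Mean of the per-marker 61-point vectors of an extremity recording."""
    vectors = []
    errors = []
    for name in recording.marker_names:
        try:
            vectors.append(marker_feature_vector(recording.marker(name), recording.frame_rate))
        except DataError as exc:
            errors.append(f"{name}: {exc}")
    if not vectors:
        raise DataError("no marker long enough for spectral features: " + "; ".join(errors))
    values = np.mean([v.values for v in vectors], axis=0)
    return SpectralFeatureVector(
        values=values, freqs=vectors[0].freqs, n_markers_averaged=len(vectors)
    )
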