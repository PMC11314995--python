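"""Displacement-amplitude spectral features and the A2r rule classifier.

This pipeline works directly in the amplitude domain (mm) so that its
output is comparable to clinical magnitude cutoffs. Each axis of each
marker is zero-phase high-pass filtered (4th-order Butterworth, 2 Hz
corner) to remove posture and drift, converted to a single-sided FFT
amplitude spectrum, and all marker x/y/z spectra of the extremity are
combined bin-wise with a max so the aggregate represents the most severe
tremor at each frequency. After Savitzky-Golay smoothing, the dominant
local maximum is characterized (center frequency, amplitude, prominence,
half-prominence width). The rule classifier calls tremor present when the
dominant peak lies in [3.5, 10] Hz (inclusive) and its amplitude reaches
0.1 mm.

The peak is located on the smoothed aggregate, but its amplitude is read
from the raw aggregate around that location: smoothing deflates the
near-delta peak of a sinusoid, and the reported amplitude is meant to
track the physical oscillation amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks, peak_prominences, peak_widths, savgol_filter

from ._errors import DataError
from .trc import LABEL_ABSENT, LABEL_PRESENT, ExtremityRecording

A2_FEATURE_NAMES = ("F_CENTER", "AMPLITUDE_MM", "PROMINENCE", "WIDTH")


@dataclass
class A2Features:
    """Dominant-peak descriptors of the aggregate amplitude spectrum."""

    F_CENTER: float = 0.0
    AMPLITUDE_MM: float = 0.0
    PROMINENCE: float = 0.0
    WIDTH: float = 0.0
    valid_peak: bool = False

    def as_row(self) -> list[float]:
        return [getattr(self, k) for k in A2_FEATURE_NAMES]


def highpass_displacement(
    trajectory: np.ndarray,
    frame_rate: float,
    corner_hz: float = 2.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase high-pass (posture/drift removal) of displacement data."""
    x = np.asarray(trajectory, dtype=float)
    if not np.isfinite(x).all():
        raise DataError("trajectory contains non-finite values")
    min_len = 3 * (2 * order + 1)
    if x.shape[0] <= min_len:
        raise DataError(f"signal too short for high-pass filtering ({x.shape[0]} <= {min_len})")
    b, a = butter(order, corner_hz, btype="high", fs=frame_rate)
    return filtfilt(b, a, x, axis=0)


def single_sided_amplitude_spectrum(
    signal: np.ndarray, frame_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided FFT amplitude spectrum in signal units (mm).

    ``amplitude(f > 0) = 2 |DFT| / N`` (Nyquist and DC not doubled), so a
    bin-aligned sinusoid of amplitude A reads A at its frequency.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise DataError("signal must be 1-D")
    n = x.shape[0]
    amp = np.abs(np.fft.rfft(x)) / n
    amp[1:] *= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0
    return np.fft.rfftfreq(n, 1.0 / frame_rate), amp


def aggregate_max_spectrum(
    spectra: Sequence[tuple[np.ndarray, np.ndarray]],
    smooth_window: int = 9,
    smooth_polyorder: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin-wise maximum across marker/axis spectra, then smoothing.

    Returns ``(freqs, smoothed, raw)`` on the frequency grid of the first
    spectrum (others are interpolated onto it; within one recording all
    markers share a grid, this guards unequal lengths). The smoothed
    aggregate is clamped at zero because polynomial smoothing can overshoot
    below zero at sharp edges.
    """
    if not spectra:
        raise DataError("aggregate_max_spectrum requires at least one spectrum")
    freqs0 = np.asarray(spectra[0][0], dtype=float)
    stack = []
    for freqs, amp in spectra:
        freqs = np.asarray(freqs, dtype=float)
        amp = np.asarray(amp, dtype=float)
        if freqs.shape == freqs0.shape and np.allclose(freqs, freqs0):
            stack.append(amp)
        else:
            stack.append(np.interp(freqs0, freqs, amp))
    raw = np.max(np.vstack(stack), axis=0)
    if raw.shape[0] < smooth_window:
        smoothed = raw.copy()
    else:
        smoothed = np.clip(savgol_filter(raw, smooth_window, smooth_polyorder), 0.0, None)
    return freqs0, smoothed, raw


def find_dominant_peak(
    freqs: np.ndarray,
    aggregate: np.ndarray,
    raw_aggregate: np.ndarray | None = None,
    amplitude_halfwidth_bins: int = 4,
) -> A2Features:
    """Largest local maximum of the smoothed aggregate spectrum.

    Local maxima follow the common default peak definition (strictly greater
    than both neighbors, plateaus taking their leftmost point); prominence
    and half-prominence width come from the standard peak-prominence
    machinery on the smoothed spectrum. When ``raw_aggregate`` is given, the
    reported amplitude is the raw-spectrum maximum within
    ``amplitude_halfwidth_bins`` of the located peak (never below the
    smoothed height, preserving amplitude >= prominence).
    """
    freqs = np.asarray(freqs, dtype=float)
    agg = np.asarray(aggregate, dtype=float)
    if freqs.shape != agg.shape:
        raise DataError("freqs and aggregate must have equal shape")
    peaks, _ = find_peaks(agg)
    if peaks.size == 0:
        return A2Features(valid_peak=False)
    ipk = peaks[int(np.argmax(agg[peaks]))]
    prom = float(peak_prominences(agg, [ipk])[0][0])
    width_bins = float(peak_widths(agg, [ipk], rel_height=0.5)[0][0])
    df = float(freqs[1] - freqs[0]) if freqs.size > 1 else 0.0
    amp = float(agg[ipk])
    if raw_aggregate is not None:
        raw = np.asarray(raw_aggregate, dtype=float)
        sl = slice(max(ipk - amplitude_halfwidth_bins, 0), ipk + amplitude_halfwidth_bins + 1)
        amp = max(amp, float(np.max(raw[sl])))
    return A2Features(
        F_CENTER=float(freqs[ipk]),
        AMPLITUDE_MM=amp,
        PROMINENCE=prom,
        WIDTH=width_bins * df,
        valid_peak=True,
    )


def classify_a2r(
    features: A2Features,
    min_center_freq_hz: float = 3.5,
    max_center_freq_hz: float = 10.0,
    min_amplitude_mm: float = 0.1,
) -> str:
    """Frequency-band and amplitude-threshold rule on the dominant peak.

    Boundaries are inclusive-accept: peaks strictly below 3.5 Hz or above
    10 Hz are discarded; an amplitude of exactly 0.1 mm counts as present.
    """
    if (
        features.valid_peak
        and min_center_freq_hz <= features.F_CENTER <= max_center_freq_hz
        and features.AMPLITUDE_MM >= min_amplitude_mm
    ):
        return LABEL_PRESENT
    return LABEL_ABSENT


def extract_a2_for_recording(
    recording: ExtremityRecording,
    corner_hz: float = 2.0,
    smooth_window: int = 9,
    smooth_polyorder: int = 3,
) -> A2Features:
    """Full A2 feature extraction for one extremity recording."""
    spectra = []
    for name in recording.marker_names:
        filt = highpass_displacement(recording.marker(name), recording.frame_rate, corner_hz)
        for ax in range(3):
            spectra.append(single_sided_amplitude_spectrum(filt[:, ax], recording.frame_rate))
    freqs, smoothed, raw = aggregate_max_spectrum(spectra, smooth_window, smooth_polyorder)
    return find_dominant_peak(freqs, smoothed, raw_aggregate=raw)
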