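import numpy as np
import pytest

from tremorkit import SimulationConfig, simulate_extremity_recording, standard_benchmark


def make_tremor_recording(
    tremor_freq_hz=5.0,
    tremor_amp_mm=1.0,
    duration_s=20.0,
    jitter_sd_mm=0.0,
    voluntary=(),
    n_markers=1,
    marker_scale=1.0,
    baseline=(1000.0, 0.0, 0.0),
    extremity="R_Hand",
    seed=0,
    tremor_present=True,
):
    """Convenience constructor for controlled synthetic extremity recordings.

    ``voluntary`` is a sequence of (freq_hz, amp_mm) pairs; ``marker_scale``
    pins the per-marker tremor scale (1.0 = full amplitude on every marker).
    """
    vf = tuple(f for f, _ in voluntary)
    va = tuple(a for _, a in voluntary)
    cfg = SimulationConfig(
        duration_s=duration_s,
        tremor_present=tremor_present,
        tremor_freq_hz=tremor_freq_hz,
        tremor_amp_mm=tremor_amp_mm,
        voluntary_freqs_hz=vf,
        voluntary_amps_mm=va,
        jitter_sd_mm=jitter_sd_mm,
        baseline_offset_mm=baseline,
        marker_scale_range=(marker_scale, marker_scale),
        n_markers=n_markers,
        extremity=extremity,
        seed=seed,
    )
    return simulate_extremity_recording(cfg)


@pytest.fixture(scope="session")
def tremor_factory():
    return make_tremor_recording


@pytest.fixture(scope="session")
def benchmark():
    """The standard synthetic benchmark dataset (n=400, prevalence 0.32)."""
    return standard_benchmark(n=400, prevalence=0.32, seed=2026)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick dataset for classifier and evaluation plumbing tests."""
    from tremorkit import simulate_dataset

    return simulate_dataset(60, prevalence=0.35, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
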