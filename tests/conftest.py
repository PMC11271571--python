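import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

BASELINE_NA = 182.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace_with_dips(
    duration_s=1.0,
    sampling_rate_hz=20_000.0,
    baseline_na=BASELINE_NA,
    noise_sigma_na=0.0,
    dips=(),
    seed=0,
):
    """Constructed trace: flat baseline, optional noise, hand-placed dips.

    ``dips`` are (t0_s, amplitude_na, fwhm_ms, shape) with shape one of
    "cosine", "rect", "triangle".
    """
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    gen = np.random.default_rng(seed)
    samples = np.full(n, baseline_na, dtype=float)
    if noise_sigma_na > 0:
        samples += gen.normal(0.0, noise_sigma_na, n)
    for t0, amp, fwhm_ms, shape in dips:
        if shape == "cosine":
            w = 2.0 * fwhm_ms / 1000.0
            mask = np.abs(t - t0) <= w / 2.0
            samples[mask] -= 0.5 * amp * (1.0 + np.cos(2.0 * np.pi * (t[mask] - t0) / w))
        elif shape == "rect":
            half = fwhm_ms / 2000.0
            samples[(t >= t0 - half) & (t < t0 + half)] -= amp
        elif shape == "triangle":
            base = 2.0 * fwhm_ms / 1000.0  # fwhm_ms here is the half-base
            mask = np.abs(t - t0) <= base / 2.0
            samples[mask] -= amp * (1.0 - np.abs(t[mask] - t0) / (base / 2.0))
        else:  # pragma: no cover
            raise ValueError(shape)
    return samples
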