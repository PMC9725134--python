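import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fast",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def mf_oracle():
    """Independent median-frequency oracle.

    Cumulative periodogram of the whole record (no cycle segmentation,
    no band-pass filtering): the frequency where cumulative in-band
    power reaches half the total.
    """

    def _oracle(x, fs, band=(10.0, 250.0)):
        from scipy.signal import periodogram

        f, p = periodogram(x, fs)
        m = (f >= band[0]) & (f <= band[1])
        f, p = f[m], p[m]
        c = np.cumsum(p)
        half = c[-1] / 2.0
        i = int(np.searchsorted(c, half))
        if i == 0:
            return float(f[0])
        frac = (half - c[i - 1]) / (c[i] - c[i - 1])
        return float(f[i - 1] + frac * (f[i] - f[i - 1]))

    return _oracle


@pytest.fixture()
def small_session():
    """Two-condition synthetic session small enough for fast tests."""
    from gaitfatigue import SubjectSpec, simulate_session

    subject = SubjectSpec(
        subject_id="S01",
        affected_side="left",
        missing_channels=(("GasM", "left"), ("Sole", "left"), ("PerL", "left")),
    )
    return simulate_session(subject, n_strides=8, sampling_rate_hz=1000.0, seed=11)
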