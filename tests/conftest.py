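import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def simple_spectrum():
    from specdiff.io import Spectrum

    return Spectrum(
        mz=np.array([200.0, 300.0, 400.0, 500.0, 650.3]),
        intensity=np.array([100.0, 300.0, 50.0, 200.0, 400.0]),
        scan_id=1,
        precursor_mz=650.3,
    )


@pytest.fixture
def replicate_series_pair():
    """Two independent scan series of the same analyte, default generator."""
    from specdiff import simulate

    return simulate.replicate_pair(simulate.SyntheticConfig(seed=42))


@pytest.fixture
def isomer_series_pair():
    """Scan series of an analyte and of its planted isomer, default generator."""
    from specdiff import simulate

    a, b, fa_a, fa_b = simulate.isomer_pair(simulate.SyntheticConfig(seed=42))
    return a, b


def brute_observed_mean(int_a, int_b):
    """Independent pure-python oracle for the observed mean on matched channels."""
    sa, sb = float(sum(int_a)), float(sum(int_b))
    fa_a = [i / sa for i in int_a]
    fa_b = [i / sb for i in int_b]
    total = 0.0
    for a, b in zip(fa_a, fa_b):
        m = (a + b) / 2.0
        total += abs(a - b) / m if m > 0 else 0.0
    return total / len(fa_a)
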