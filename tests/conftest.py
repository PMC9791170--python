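import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import countdet as cd

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def spec():
    """Detector at the characterized operating point."""
    return cd.DetectorSpec(a=0.007, false_positive_rate=2.86e-6)


@pytest.fixture(scope="session")
def quiet_spec():
    """Detector with no dark counts, for clean statistics."""
    return cd.DetectorSpec(a=0.007, false_positive_rate=0.0)


@pytest.fixture(scope="session")
def printed_model():
    """Dose-response model fitted to the published (input, detected) pairs."""
    return cd.fit_dose_response([(16, 15), (34, 30), (78, 60)])


def detected_rate_se(a, x, n_pixels, duration):
    """Monte-Carlo standard error of the mean detected rate (eps).

    Detected counts per pixel are Binomial over duration/a windows with
    p = 1 - exp(-a x); the SE of the pixel-averaged rate follows.
    """
    n_windows = duration / a
    p = 1.0 - np.exp(-a * x)
    var_rate = n_windows * p * (1 - p) / duration ** 2
    return float(np.sqrt(var_rate / n_pixels))
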