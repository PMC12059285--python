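import pathlib

import pytest
from hypothesis import HealthCheck, settings

import barshadow as bs

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


NOISELESS = bs.DetectorSpec(aperture_mm=0.0, noise_cv=0.0)


@pytest.fixture(scope="session")
def geometry():
    """Default bore-type distance stack (SAD 85, B 20.473, C 3.65 cm)."""
    return bs.RADIXACT


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory) -> pathlib.Path:
    """A 10-repeat x 3-session synthetic study at default noise, fixed seed.

    Injected offsets: +0.42 mm (IEC-X), -0.36 mm (IEC-Y).
    """
    out = tmp_path_factory.mktemp("study") / "session"
    bs.generate_session(0.42, -0.36, n_repeats=10, n_sessions=3, seed=7, out_dir=out)
    return out


def noiseless_dip_center(offset_mm, level, method="local_linear_fit", bar_center_mm=0.0, **kw):
    """Dip center of a noiseless default-schedule simulated profile."""
    profile = bs.simulate_profile(
        bs.SourceSpec(offset_mm=offset_mm, fwhm_mm=0.0),
        level,
        bar_center_mm,
        NOISELESS,
        **kw,
    )
    return bs.find_dip_center(profile, method=method).center_mm
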