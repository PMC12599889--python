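import numpy as np
import pytest

from gaitpert.synthgait import (
    DEFAULT_SENSOR_SPECS,
    SensorSpec,
    default_archetypes,
    generate_cohort,
    generate_profile,
)
from gaitpert.windowing import WindowingConfig


@pytest.fixture(scope="session")
def profile():
    return generate_profile(1, 0)


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes(4.0)


@pytest.fixture(scope="session")
def wcfg():
    return WindowingConfig()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three participants, full 7-position protocol (smallest legal cohort)."""
    return generate_cohort(3, 42, amplitude_ratio=4.0)


@pytest.fixture(scope="session")
def cohort6():
    """Six participants: the smallest cohort that supports 70/15/15 splits."""
    return generate_cohort(6, 11, amplitude_ratio=4.0)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, tiny_cohort):
    """tiny_cohort saved once as a cohort directory (CSV + manifest)."""
    from gaitpert.interface import save_cohort

    root = tmp_path_factory.mktemp("cohort")
    save_cohort(tiny_cohort, root)
    return root


@pytest.fixture
def clean_spec():
    """Noise-free regular 100 Hz sensor for deterministic signal tests."""
    return SensorSpec("JP", 100.0, noise_sd=0.0, carry_noise_sd=0.0)
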