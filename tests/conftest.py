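import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chebutools.compound_library import load_library
from chebutools.msms_networking import MsmsSpectrum
from chebutools.synthetic_data import SyntheticDesign

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# constant-column / overlapping-peak warnings are expected in several tests
warnings.filterwarnings("ignore", message="dropping constant peaks")


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def library_by_id(library):
    return {rec.record_id: rec for rec in library}


@pytest.fixture(scope="session")
def design():
    return SyntheticDesign()


def spectrum_from_record(record, spectrum_id=None):
    """Build an MsmsSpectrum directly from a library record's printed
    fragment list (exact m/z, geometric intensity profile)."""
    frags = list(dict.fromkeys(record.fragments))
    intensity = 1000.0 * 0.75 ** np.arange(len(frags))
    return MsmsSpectrum(
        spectrum_id=spectrum_id or f"rec{record.record_id:03d}",
        precursor_mz=record.observed_mz,
        mz=np.asarray(frags),
        intensity=intensity,
        rt=record.rt_min,
    )
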