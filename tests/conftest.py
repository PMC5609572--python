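"""Shared fixtures: everything is generated by the synthetic beam model."""

import numpy as np
import pytest

from braggkit import beam, film, sobp


@pytest.fixture(scope="session")
def peak62():
    """Pristine 62 MeV Bragg curve at the default 0.05 mm grid."""
    return beam.pristine_bragg(62.0)


@pytest.fixture(scope="session")
def design10():
    """10-step flat-SOBP design over the width a 10-step family supports."""
    return sobp.design_sobp(62.0, 3.0, n_steps=10)


@pytest.fixture(scope="session")
def design16mm():
    """Auto-sized flat-SOBP design with a 16 mm plateau."""
    return sobp.design_sobp(62.0, 16.0)


@pytest.fixture(scope="session")
def cubic_curve():
    """A known, strictly increasing cubic netOD→dose calibration."""
    return film.CalibrationCurve(
        np.array([0.0, 9.0, 4.0, 11.0]),
        valid_dose_range=(0.25, 4.0),
        netod_span=(0.0, 0.55),
    )
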