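from dataclasses import replace

import numpy as np
import pytest

from phycospec import MATRIX_SPECS, Spectrum, WavelengthAxis, default_axis


@pytest.fixture(scope="session")
def axis() -> WavelengthAxis:
    return default_axis()


@pytest.fixture
def flat_spectrum(axis) -> Spectrum:
    return Spectrum(axis, np.full(axis.band_count, 0.6))


@pytest.fixture
def organic_noiseless():
    """Organic matrix with pixel noise switched off (deterministic optics)."""
    return replace(MATRIX_SPECS["organic"], noise_sd=0.0)


@pytest.fixture
def five_band_trough() -> Spectrum:
    """Worked 5-band trough: R=[0.8,0.75,0.5,0.72,0.78] on 600-640 nm."""
    return Spectrum(
        WavelengthAxis(np.array([600.0, 610.0, 620.0, 630.0, 640.0])),
        np.array([0.8, 0.75, 0.5, 0.72, 0.78]),
    )
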