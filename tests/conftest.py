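"""Shared fixtures: small detectors and phantoms sized for fast tests.

Simulations here use reduced detectors (129x129, 24 um sample pixels) and
short wavelength scans; the physics is scale-free, so the qualitative
depth/offset behaviour is unchanged.
"""

import numpy as np
import pytest

from orchid.phantom import (
    DEFAULT_OPTICS,
    DetectorModel,
    ScanPlan,
    stacked_dual_phantom,
    uniform_background_phantom,
)


@pytest.fixture(scope="session")
def small_detector() -> DetectorModel:
    return DetectorModel(
        n_rows=129, n_cols=129, pixel_pitch=24.0, magnification=1.0,
        dark_offset=50.0, read_noise_sigma=2.0, gain=1.0,
    )


@pytest.fixture(scope="session")
def tiny_detector() -> DetectorModel:
    return DetectorModel(
        n_rows=16, n_cols=16, pixel_pitch=24.0, magnification=1.0,
        dark_offset=50.0, read_noise_sigma=0.0, gain=2.0,
    )


@pytest.fixture(scope="session")
def single_spot_plan() -> ScanPlan:
    return ScanPlan.from_grid(
        10.0, 10.0, 1, 1, 1.0,
        lambda_start=800.0, lambda_stop=880.0, lambda_step=2.0,
        exposure=1.0, excitation_wavelength=785.0,
    )


@pytest.fixture(scope="session")
def stacked_2mm_spectrum(small_detector, single_spot_plan):
    """Offset spectrum of a noise-free 2+2 mm stacked dual-dye phantom."""
    import orchid
    from orchid.binning import OffsetBinningScheme
    from orchid.spectral import build_offset_spectrum

    phantom = stacked_dual_phantom(2.0)
    acq = orchid.simulate_scan(phantom, small_detector, single_spot_plan, noise="off", seed=0)
    scheme = OffsetBinningScheme.from_width(60.0, 4.0)
    return build_offset_spectrum(acq.frames_at_position(0), scheme)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
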