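import numpy as np
import pytest

from tpqc import synthetic
from tpqc.optics import ObjectiveSpec, ScanRelaySpec


@pytest.fixture(scope="session")
def reference_objective() -> ObjectiveSpec:
    """A 16x long-working-distance water-immersion objective."""
    return ObjectiveSpec(
        focal_length_mm=12.5,
        numerical_aperture=0.8,
        immersion_index=1.33,
        back_aperture_diameter_mm=20.0,
    )


@pytest.fixture(scope="session")
def reference_relay() -> ScanRelaySpec:
    """A 100 mm scan lens / 375 mm tube lens relay, +-10 deg scanner."""
    return ScanRelaySpec(
        scan_lens_focal_mm=100.0,
        tube_lens_focal_mm=375.0,
        scan_half_angle_deg=10.0,
        beam_diameter_at_pupil_mm=17.5,
    )


@pytest.fixture(scope="session")
def bead_phantom():
    """Default 38-bead phantom at peak SNR 20 (shared: generation is ~3 s)."""
    return synthetic.gen_bead_volume(seed=1)


@pytest.fixture(scope="session")
def single_noiseless_bead():
    return synthetic.gen_bead_volume(n_beads=1, peak_snr=None, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
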