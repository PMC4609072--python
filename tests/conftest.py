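"""Shared fixtures: the default therapy field and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import mcet
from mcet.experiments import DEFAULT_SCHEDULE, run_pressure_cohorts
from mcet.synthlesion import (
    JitterSpec,
    MicrolesionSet,
    StackSpec,
    TissueSlab,
    calibrate_scale_to_dose_response,
    render_sections,
)


@pytest.fixture(scope="session")
def default_field():
    """Pulsed field of the default 19-mm / 38-mm / 1.5-MHz transducer."""
    return mcet.compute_field()


@pytest.fixture(scope="session")
def default_slab():
    return TissueSlab()


@pytest.fixture(scope="session")
def calibrated_model(default_field, default_slab):
    """Lesion model calibrated to the 4.52 %/MPa observed dose-response."""
    return calibrate_scale_to_dose_response(default_field, default_slab)


@pytest.fixture(scope="session")
def pressure_cohorts(default_field, calibrated_model, default_slab):
    """Five simulated animals per cohort at 2.0 / 2.8 / 4.0 MPa."""
    return run_pressure_cohorts(
        default_field,
        calibrated_model,
        default_slab,
        DEFAULT_SCHEDULE,
        pressures_mpa=(2.0, 2.8, 4.0),
        n_animals=5,
        seed=1,
    )


def _section_lesion_cloud(seed: int = 3, n: int = 150) -> MicrolesionSet:
    """A lesion cloud confined to a thin band, for contiguous sectioning."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(-1.0, 1.0, size=(n, 2))
    z = rng.uniform(30.0, 30.35, size=n)
    sigma = 0.5
    vols = rng.lognormal(np.log(2.0e5) - sigma**2 / 2, sigma, size=n)
    return MicrolesionSet(np.column_stack([xy, z]), vols)


CONTIGUOUS_SPEC = StackSpec(
    n_sections=36,
    thickness_um=10.0,
    spacing_um=10.0,
    pixel_size_um=10.0,
    image_shape=(256, 256),
    z_start_mm=30.0,
)


@pytest.fixture(scope="session")
def band_lesions():
    return _section_lesion_cloud()


@pytest.fixture(scope="session")
def contiguous_stack(band_lesions, default_slab):
    """Jitter-free contiguous 10-um sections of the band cloud."""
    with np.errstate(all="ignore"):
        return render_sections(band_lesions, default_slab, CONTIGUOUS_SPEC, seed=5)


@pytest.fixture(scope="session")
def jittered_stack(band_lesions, default_slab):
    """Same cloud sectioned with +/-10 px, +/-3 deg placement jitter."""
    return render_sections(
        band_lesions,
        default_slab,
        CONTIGUOUS_SPEC,
        jitter_spec=JitterSpec(max_shift_px=10.0, max_angle_deg=3.0),
        seed=6,
    )
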