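import numpy as np
import pytest

from shagcarpet.phantom import PhantomSpec, make_phantom
from shagcarpet.signal_prep import scale_demean


@pytest.fixture(scope="session")
def rs_phantom():
    """Noiseless resting-state phantom: 400 voxels, 360 s at TR 0.72 s,
    delays spanning 4.5 s linearly."""
    spec = PhantomSpec(
        modality="rs",
        n_voxels=400,
        duration=360.0,
        tr=0.72,
        delay_model=("linear_span", 4.5),
        noise_sd=0.0,
        seed=3,
    )
    matrix, truth = make_phantom(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def rs_phantom_scaled(rs_phantom):
    spec, matrix, truth = rs_phantom
    return spec, scale_demean(matrix), truth


@pytest.fixture(scope="session")
def dsc_phantom():
    """Noiseless bolus-passage phantom: gamma-variate dips, TTP span 4.2 s."""
    spec = PhantomSpec(
        modality="dsc",
        n_voxels=100,
        duration=90.0,
        tr=1.5,
        delay_model=("linear_span", 4.2),
        noise_sd=0.0,
        seed=4,
        modality_params={"t0": 20.0, "tp": 4.0, "depth": 3.0, "baseline": 100.0},
    )
    matrix, truth = make_phantom(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def co2_phantom():
    """Noiseless CO2-challenge phantom: two-block protocol, 600 s at TR 1 s,
    delays spanning 5 s."""
    spec = PhantomSpec(
        modality="co2",
        n_voxels=120,
        duration=600.0,
        tr=1.0,
        delay_model=("linear_span", 5.0),
        noise_sd=0.0,
        seed=5,
    )
    matrix, truth = make_phantom(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def rs_carpet(rs_phantom_scaled):
    """Cropped delay-sorted carpet of the noiseless rs phantom."""
    from shagcarpet.delay_map import rs_delays
    from shagcarpet.shag import build_shag, crop_shag

    _, matrix, truth = rs_phantom_scaled
    dmap = rs_delays(matrix)
    return crop_shag(build_shag(matrix, dmap)), dmap, truth
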