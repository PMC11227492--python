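import numpy as np
import pytest

from elastomap import (
    EncodingModel,
    PlaneWaveSpec,
    VoxelGrid,
    encode_phase_series,
    plane_wave_field,
)

RHO = 1000.0  # kg/m^3
FREQ = 900.0  # Hz


@pytest.fixture(scope="session")
def fine_grid():
    """Grid fine enough (0.1 mm) for <1% Laplacian discretization error."""
    return VoxelGrid((32, 32, 32), (0.1, 0.1, 0.1))


@pytest.fixture(scope="session")
def plane_wave_recon_inputs(fine_grid):
    """Analytic shear plane wave in a homogeneous 5 + 1.5i kPa medium and
    its zero-noise encoded phase series."""
    G = 5000 + 1500j
    spec = PlaneWaveSpec(amplitude=(5.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0), frequency_hz=FREQ)
    field = plane_wave_field(fine_grid, spec, rho=RHO, G=G)
    series = encode_phase_series(field, EncodingModel(), seed=11)
    return G, field, series


def interior_mask(shape, margin):
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(margin, n - margin) for n in shape)
    m[sl] = True
    return m
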