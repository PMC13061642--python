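import numpy as np
import pytest

from lsom import (
    LsomPipeline,
    NoiseModel,
    OpticalConfig,
    compute_basis,
    preset,
)


@pytest.fixture(scope="session")
def basis_1d():
    return compute_basis(OpticalConfig(dim=1), 6)


@pytest.fixture(scope="session")
def basis_2d():
    return compute_basis(OpticalConfig(dim=2), 13)


@pytest.fixture(scope="session")
def pipeline_1d(basis_1d):
    """Noiseless calibrated 1D chain with two opposing TIR directions."""
    return LsomPipeline.calibrated(
        basis_1d, illuminations=preset("paper_1d").illuminations
    )


@pytest.fixture(scope="session")
def pipeline_2d(basis_2d):
    """Noiseless calibrated 2D chain with four TIR directions."""
    return LsomPipeline.calibrated(
        basis_2d, illuminations=preset("paper_2d").illuminations
    )


@pytest.fixture(scope="session")
def pipeline_1d_noisy(basis_1d):
    noise = NoiseModel(photons_per_submeasurement=1e4, poisson=True, seed=3)
    return LsomPipeline.calibrated(
        basis_1d,
        illuminations=preset("paper_1d").illuminations,
        noise=noise,
    )


def in_span_band_field(basis, c):
    """Band field of the exact modal superposition Σ c_i S_i."""
    from lsom import ComplexField

    samples = basis.band_modes() @ (basis.gammas * np.asarray(c, dtype=complex))
    return ComplexField(samples=samples, grid=basis.band_grid, plane="fourier")
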