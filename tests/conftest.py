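"""Shared small fixtures: kernels, phantoms and grids sized for fast tests."""

import warnings

import numpy as np
import pytest

import polardecon as pol
from polardecon.dipole_psf import DipolePSFBank
from polardecon.sphharm import BandLimit

warnings.filterwarnings("ignore", message="PSF support below 4 resolution units")


@pytest.fixture(scope="session")
def bl4():
    return BandLimit(4)


@pytest.fixture(scope="session")
def quad_grid():
    """Quadrature grid exact for products of two lmax=4 spectra."""
    return pol.gauss_legendre_grid(16)


@pytest.fixture(scope="session")
def small_cfg_a():
    return pol.OpticalConfig(na_det=1.1, shape=(9, 9, 9), view_axis="z")


@pytest.fixture(scope="session")
def small_cfg_b():
    return pol.OpticalConfig(na_det=0.67, shape=(9, 9, 9), view_axis="x")


@pytest.fixture(scope="session")
def epi_bank(small_cfg_a):
    """Widefield bank with detection along z and p̂ rotating in the
    transverse (xy) plane — the symmetric geometry where lake responses
    are exactly equal."""
    states = tuple(
        pol.PolarizationState("B", psi, 0.0) for psi in (0.0, 45.0, 90.0, 135.0)
    )
    kernels = np.stack(
        [pol.system_psf(small_cfg_a, s, "widefield") for s in states]
    )
    return DipolePSFBank(kernels, states, small_cfg_a.voxel, BandLimit(4))


@pytest.fixture(scope="session")
def dual_bank(small_cfg_a, small_cfg_b):
    """Dual-view diSPIM bank for the 6-modulation scheme (9³ kernels)."""
    return pol.psf_bank(small_cfg_a, small_cfg_b, pol.get_scheme("6V"))


@pytest.fixture(scope="session")
def dual_views(dual_bank):
    """(bank_A, bank_B) split of the dual bank."""
    scheme = pol.PolarizationScheme(tuple(dual_bank.states))
    idx_a = scheme.view_indices("A")
    idx_b = scheme.view_indices("B")
    return dual_bank.subset(idx_a), dual_bank.subset(idx_b)


@pytest.fixture(scope="session")
def small_shell():
    """16³ shell phantom with radial ODFs, kept clear of the volume edge."""
    return pol.make_phantom(
        pol.PhantomSpec("shell", (16, 16, 16), radius_vox=3.5, blur_sigma=1.0)
    )


@pytest.fixture(scope="session")
def small_shell_stack(small_shell, epi_bank):
    return pol.forward_project(small_shell, epi_bank)
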