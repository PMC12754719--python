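"""Vectorial dipole point-spread-function models.

A single fluorophore is an oscillating dipole: how brightly it excites
depends on the angle between its transition moment and the excitation
polarization (cos² law), and the image it casts depends on its orientation
relative to the detection pupil.  Both effects are band-limited on the
sphere, so each modulation's PSF is stored as a short stack of real-SH
spatial kernels H_{p̂,lm}(r): the image of an object with angular spectra
F_lm(r) is Σ_lm H_{p̂,lm} ⊛ F_lm.

The detection model follows the paraxial-vectorial pupil treatment:
aplanatic apodization, defocus phase, and the six dipole pupil field
components, combined into the 3×3 irradiance matrix and contracted with
l=1 Gaunt coefficients.  Excitation contributes only l ∈ {0,2}; detection
likewise, so system PSFs are band-limited at l=4 (15 channels).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property, lru_cache

import numpy as np
from scipy import fft as sfft
from scipy.spatial.transform import Rotation

from . import fourier
from .sphharm import (
    SQRT4PI,
    AngularSpectrum,
    BandLimit,
    gaunt_real,
    gaunt_tensor,
    real_sh_eval,
    wigner_matrix,
)

logger = logging.getLogger(__name__)

# Cartesian dipole component j ∈ {0,1,2} = {x,y,z} ↔ l=1 real SH order
_EPS = (1, -1, 0)


@dataclass(frozen=True)
class OpticalConfig:
    """One view's detection optics and light-sheet geometry.

    Lengths are in nanometres.  ``view_axis`` is the detection optical axis
    ('z' for view A, 'x' for the orthogonal view B of a diSPIM).
    """

    na_det: float = 1.1
    n0: float = 1.33
    wavelength: float = 525.0
    voxel: float = 130.0
    shape: tuple = (65, 65, 65)
    w0: float = 1200.0
    view_axis: str = "z"

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if self.na_det >= self.n0:
            raise ValueError("detection NA must be below the immersion index")
        if self.voxel <= 0 or self.w0 <= 0:
            raise ValueError("voxel pitch and sheet waist must be positive")
        if any(n % 2 == 0 or n < 1 for n in self.shape):
            raise ValueError("PSF support must be odd along every axis")
        if self.view_axis not in ("z", "x"):
            raise ValueError("view_axis must be 'z' (view A) or 'x' (view B)")

    @property
    def nu_c(self) -> float:
        """Detection cutoff parameter 2·NA/λ (the pupil edge is at νc/2)."""
        return 2.0 * self.na_det / self.wavelength

    @property
    def nu_m(self) -> float:
        """Medium frequency n0/λ."""
        return self.n0 / self.wavelength


@dataclass(frozen=True)
class PolarizationState:
    """One polarization modulation: view, transverse angle ψ, sheet tilt.

    The sheet propagation axis k̂ is the view's illumination axis rotated by
    ``tilt`` about the detection optical axis; the excitation polarization is
    p̂ = cosψ·ê1 + sinψ·ê2 with ê1 the unit component of the detection axis
    perpendicular to k̂ and ê2 = k̂ × ê1.
    """

    view: str = "A"
    psi: float = 0.0
    tilt: float = 0.0

    def __post_init__(self):
        if self.view not in ("A", "B"):
            raise ValueError("view must be 'A' or 'B'")

    @cached_property
    def geometry(self) -> dict:
        if self.view == "A":
            det = np.array([0.0, 0.0, 1.0])
            illum = np.array([1.0, 0.0, 0.0])
        else:
            det = np.array([1.0, 0.0, 0.0])
            illum = np.array([0.0, 0.0, 1.0])
        k_hat = Rotation.from_rotvec(det * np.deg2rad(self.tilt)).apply(illum)
        e1 = det - np.dot(det, k_hat) * k_hat
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(k_hat, e1)
        psi = np.deg2rad(self.psi)
        p_hat = np.cos(psi) * e1 + np.sin(psi) * e2
        return {"k_hat": k_hat, "p_hat": p_hat / np.linalg.norm(p_hat)}

    @property
    def p_hat(self) -> np.ndarray:
        return self.geometry["p_hat"]


# ---------------------------------------------------------------------------
# Excitation
# ---------------------------------------------------------------------------

def excitation_spectrum(
    p_hat: np.ndarray, bandlimit: BandLimit = BandLimit()
) -> AngularSpectrum:
    """Angular spectrum of the cos² photoselection function 3(p̂·ŝ)².

    P_lm(p̂) = 4π·Y_lm(p̂)·(δ_{l,0} + (2/5)·δ_{l,2}); the synthesized
    function peaks at 3 along p̂, vanishes perpendicular to it, and has
    spherical mean 1.
    """
    p = np.asarray(p_hat, dtype=float)
    if abs(np.linalg.norm(p) - 1.0) > 1e-6:
        raise ValueError("excitation axis p_hat must be a unit vector")
    coeffs = np.zeros(bandlimit.n_channels)
    for i, (l, m) in enumerate(bandlimit.channels):
        if l == 0:
            coeffs[i] = 4.0 * np.pi * real_sh_eval(l, m, p)
        elif l == 2:
            coeffs[i] = (8.0 * np.pi / 5.0) * real_sh_eval(l, m, p)
    return AngularSpectrum(coeffs, bandlimit)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def aplanatic_apodization(tau_abs: np.ndarray, config: OpticalConfig) -> np.ndarray:
    """Aplanatic pupil amplitude with a hard cutoff at the pupil edge νc/2."""
    inside = tau_abs < config.nu_c / 2.0
    s2 = np.clip((tau_abs / config.nu_m) ** 2, 0.0, 1.0 - 1e-12)
    return np.where(inside, (1.0 - s2) ** -0.25, 0.0)


def _pupil_fields(config: OpticalConfig):
    """Pupil grids: |τ|, azimuth, apodization and the six g_ij components."""
    nz, ny, nx = config.shape
    fy = sfft.fftfreq(ny, d=config.voxel)
    fx = sfft.fftfreq(nx, d=config.voxel)
    ty, tx = np.meshgrid(fy, fx, indexing="ij")
    tau_abs = np.hypot(tx, ty)
    phi = np.arctan2(ty, tx)
    A = aplanatic_apodization(tau_abs, config)
    s = np.clip(tau_abs / config.nu_m, 0.0, 1.0 - 1e-12)
    ct = np.sqrt(1.0 - s**2)  # cosine of the marginal-ray angle
    g = np.empty((2, 3) + tau_abs.shape)
    g[0, 0] = np.sin(phi) ** 2 + np.cos(phi) ** 2 * ct
    g[1, 1] = np.cos(phi) ** 2 + np.sin(phi) ** 2 * ct
    g[0, 1] = 0.5 * np.sin(2 * phi) * (ct - 1.0)
    g[1, 0] = g[0, 1]
    g[0, 2] = s * np.cos(phi)
    g[1, 2] = s * np.sin(phi)
    return tau_abs, A, g


@lru_cache(maxsize=8)
def _detection_spectrum_cached(config, bandlimit):
    return _detection_spectrum_impl(config, bandlimit)


def detection_spectrum(
    config: OpticalConfig, bandlimit: BandLimit = BandLimit()
) -> np.ndarray:
    return _detection_spectrum_cached(config, bandlimit).copy()


def _detection_spectrum_impl(
    config: OpticalConfig, bandlimit: BandLimit = BandLimit()
) -> np.ndarray:
    """Per-channel detection kernels H_lm^det(r), shape (C, z, y, x).

    Pupil fields β_ij per defocus plane (2D inverse FFT of A·Φ·g_ij), the
    Hermitian irradiance matrix B_jj' = Σ_i β_ij β*_ij', and the l=1×l=1
    Gaunt contraction; only l ∈ {0,2} channels are populated.  The bank is
    normalized so that the detection efficiency averaged over dipole
    orientations sums to 1 over the support (Σ_r H00 = 2√π).
    """
    nz, ny, nx = config.shape
    lateral_extent = min(ny, nx) * config.voxel
    if lateral_extent < 4.0 * config.wavelength / (2.0 * config.na_det):
        warnings.warn("PSF support below 4 resolution units; kernels may clip")
    tau_abs, A, g = _pupil_fields(config)
    zc = (np.arange(nz) - nz // 2) * config.voxel
    kz = np.sqrt(np.maximum(config.nu_m**2 - tau_abs**2, 0.0))
    C = bandlimit.n_channels
    out = np.zeros((C, nz, ny, nx))
    # Gaunt factors G(l,m,1,eps_j,1,eps_j') for the six independent (j,j')
    gaunt_jj = {}
    for i, (l, m) in enumerate(bandlimit.channels):
        if l > 2:
            continue
        for j in range(3):
            for jp in range(3):
                gaunt_jj[(i, j, jp)] = gaunt_real(l, m, 1, _EPS[j], 1, _EPS[jp])
    for iz, z in enumerate(zc):
        defocus = np.exp(1j * 2.0 * np.pi * z * kz)
        beta = sfft.ifft2(A * defocus * g, axes=(-2, -1))
        beta = sfft.fftshift(beta, axes=(-2, -1))
        B = np.einsum("ij...,ik...->jk...", beta, beta.conj())
        for (i, j, jp), gval in gaunt_jj.items():
            if gval != 0.0:
                out[i, iz] += gval * np.real(B[j, jp])
    out *= 4.0 * np.pi / 3.0
    total = out[0].sum()
    if total <= 0:
        raise RuntimeError("degenerate detection kernel")
    out *= SQRT4PI / total
    return out


def _rotate_kernels_y90(kernels: np.ndarray, bandlimit: BandLimit) -> np.ndarray:
    """Rotate a (C,z,y,x) kernel stack by +90° about y (ẑ → x̂), exactly.

    Channels mix through the real Wigner blocks; the spatial grid maps
    (z,y,x) → value at (x', y, z') with x' = −z, z' = x, a lattice motion.
    """
    W = wigner_matrix(np.array([0.0, 1.0, 0.0]), np.pi / 2.0, bandlimit).matrix()
    mixed = np.einsum("dc,c...->d...", W, kernels)
    return np.flip(np.swapaxes(mixed, -3, -1), axis=-3)


def system_psf(
    config: OpticalConfig,
    state: PolarizationState,
    modality: str = "spim",
    bandlimit: BandLimit = BandLimit(),
) -> np.ndarray:
    """Kernels H_{p̂,lm}(r) of one modulation, shape (C, z, y, x).

    widefield      : Gaunt product of detection and excitation spectra.
    spim           : widefield × Gaussian sheet envelope exp(−2z²/w0²).
    dispim_view2   : detection rotated 90° about y (optical axis → x̂),
                     envelope along x.
    """
    if modality not in ("widefield", "spim", "dispim_view2"):
        raise ValueError(f"unknown modality {modality!r}")
    det = detection_spectrum(config, bandlimit)
    if modality == "dispim_view2":
        if config.shape[0] != config.shape[2]:
            raise ValueError("rotated view needs matching z and x support")
        det = _rotate_kernels_y90(det, bandlimit)
    exc = excitation_spectrum(state.p_hat, bandlimit)
    mult = np.einsum("oab,b->oa", gaunt_tensor(bandlimit, bandlimit, bandlimit), exc.coeffs)
    kern = np.einsum("oa,a...->o...", mult, det)
    nz, ny, nx = kern.shape[-3:]
    if modality == "spim":
        z = (np.arange(nz) - nz // 2) * config.voxel
        kern *= np.exp(-2.0 * z**2 / config.w0**2)[None, :, None, None]
    elif modality == "dispim_view2":
        x = (np.arange(nx) - nx // 2) * config.voxel
        kern *= np.exp(-2.0 * x**2 / config.w0**2)[None, None, None, :]
    return kern


# ---------------------------------------------------------------------------
# PSF banks
# ---------------------------------------------------------------------------

@dataclass
class DipolePSFBank:
    """Per-modulation, per-channel spatial kernels with cached OTFs."""

    kernels: np.ndarray  # (P, C, kz, ky, kx), float32
    states: tuple
    voxel: float
    bandlimit: BandLimit = field(default_factory=BandLimit)

    def __post_init__(self):
        self.kernels = np.asarray(self.kernels, dtype=np.float32)
        if self.kernels.dtype.itemsize < 4:
            raise TypeError("kernels must be at least 32-bit float")
        if not np.all(np.isfinite(self.kernels)):
            raise ValueError("non-finite kernels")
        if self.kernels.shape[1] != self.bandlimit.n_channels:
            raise ValueError("kernel channel count does not match band limit")
        if self.kernels.shape[0] != len(self.states):
            raise ValueError("kernel count does not match states")
        self._otf_cache: dict = {}

    @property
    def n_modulations(self) -> int:
        return self.kernels.shape[0]

    @property
    def back_kernels(self) -> np.ndarray:
        """Matched back projector: the spatially flipped kernels."""
        return self.kernels[..., ::-1, ::-1, ::-1]

    def otfs(self, pshape: tuple) -> np.ndarray:
        """(P, C, freq) transfer functions on the padded grid (cached)."""
        key = tuple(pshape)
        if key not in self._otf_cache:
            self._otf_cache[key] = fourier.kernel_otfs(self.kernels, key)
        return self._otf_cache[key]

    def sensitivity_spectrum(self) -> AngularSpectrum:
        """Σ_p̂ Σ_r H_{p̂,lm}(r): the object-space sensitivity function."""
        coeffs = self.kernels.sum(axis=(0, 2, 3, 4)).astype(float)
        return AngularSpectrum(coeffs, self.bandlimit)

    def subset(self, indices) -> "DipolePSFBank":
        idx = list(indices)
        return DipolePSFBank(
            self.kernels[idx], tuple(self.states[i] for i in idx),
            self.voxel, self.bandlimit,
        )


def psf_bank(
    config_a: OpticalConfig | None,
    config_b: OpticalConfig | None,
    states,
    bandlimit: BandLimit = BandLimit(),
) -> DipolePSFBank:
    """Assemble the kernel bank for an ordered set of modulations.

    View-A states use ``config_a`` with the SPIM model (detection along ẑ);
    view-B states use ``config_b`` with the rotated dual-view model.
    """
    states = tuple(getattr(states, "states", states))
    if not states:
        raise ValueError("polarization scheme is empty")
    configs = {"A": config_a, "B": config_b}
    pitches = {c.voxel for c in (config_a, config_b) if c is not None}
    if len(pitches) > 1:
        raise ValueError("views must share the voxel pitch")
    kernels = []
    for state in states:
        cfg = configs[state.view]
        if cfg is None:
            raise ValueError(f"no optical config supplied for view {state.view}")
        modality = "spim" if state.view == "A" else "dispim_view2"
        kernels.append(system_psf(cfg, state, modality, bandlimit))
    voxel = next(iter(pitches))
    return DipolePSFBank(np.stack(kernels), states, voxel, bandlimit)
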