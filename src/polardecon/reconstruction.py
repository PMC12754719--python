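"""Inverse solvers for spatio-angular deconvolution.

The estimation target is an ``SHField``: a voxel grid of real-SH angular
spectra F_lm(r) (15 channels at the system band limit l ≤ 4, even).  The
primary solver is the efficient generalized Richardson–Lucy iteration
(eGRL), a multiplicative maximum-likelihood scheme restructured to run
entirely in the spatial-frequency × angular-spectrum domain:

    E_{k+1} = E_k ⊙ [ (i ⋄ h_back)  ⊘  (E_k ⋆ h ⋄ h_back) ]

where ⋆/⋄ are forward/backward projections through the dipole-PSF bank
(combined into one object-to-object operator), and ⊙/⊘ are per-voxel
band-limited spherical products and quotients (Gaunt contractions).  The
back-projected data and the combined kernel are precomputed outside the
loop.  Because both the numerator and denominator of the restructured
ratio carry the back-projector, the object-space sensitivity of the
explicit-orientation iteration cancels; a toggleable sensitivity division
is retained for the explicit formulation's sake but defaults off.

Baselines: the explicit-orientation GRL iteration (brute-force oracle on
small grids), the decoupled eGRL-p ablation, plain scalar Richardson–Lucy,
and a per-frequency Tikhonov-regularized SVD pseudoinverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import fourier
from .dipole_psf import DipolePSFBank
from .forward_model import PolarizedStack, forward_project
from .sphharm import (
    SQRT4PI,
    AngularSpectrum,
    BandLimit,
    SphereGrid,
    gaunt_tensor,
    multiplication_matrix,
    sh_basis_matrix,
    sh_divide_many,
    sh_multiply_many,
)

logger = logging.getLogger(__name__)

_CHUNK = 1 << 15  # voxels per per-voxel-solve block (float64 workspace)


@dataclass
class SHField:
    """Voxel grid of real-SH angular spectra, axis order (C, Z, Y, X)."""

    coeffs: np.ndarray
    bandlimit: BandLimit = field(default_factory=BandLimit)
    voxel: float = 130.0

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.float32)
        if self.coeffs.ndim != 4:
            raise ValueError("SHField coefficients must be (C, Z, Y, X)")
        if self.coeffs.shape[0] != self.bandlimit.n_channels:
            raise ValueError("channel count does not match band limit")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite SHField coefficients")

    @property
    def shape(self) -> tuple:
        return self.coeffs.shape[1:]

    def density(self) -> np.ndarray:
        return np.asarray(self.coeffs[0])

    def synthesize(self, grid: SphereGrid) -> np.ndarray:
        """Sample every voxel's ODF on the grid → (n_dirs, Z, Y, X)."""
        Y = sh_basis_matrix(self.bandlimit, grid)
        return np.einsum("jc,c...->j...", Y, self.coeffs.astype(np.float64))

    def copy(self) -> "SHField":
        return SHField(self.coeffs.copy(), self.bandlimit, self.voxel)


@dataclass
class ReconConfig:
    """Solver settings shared by the iterative reconstructions."""

    iterations: int = 10
    ridge: float = 1e-9          # relative ridge in the per-voxel solves
    density_floor: float = 1e-6  # freeze voxels below floor × max density
    seed: int = 0
    sensitivity_normalization: bool = False
    positivity_projection: bool = False

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("need at least one iteration")


def _as_lists(stacks, banks):
    if isinstance(stacks, PolarizedStack):
        stacks = [stacks]
    if isinstance(banks, DipolePSFBank):
        banks = [banks]
    stacks, banks = list(stacks), list(banks)
    if len(stacks) != len(banks):
        raise ValueError("need one kernel bank per stack")
    if not stacks:
        raise ValueError("empty stack list")
    shapes = {s.shape for s in stacks}
    if len(shapes) > 1:
        raise ValueError("per-view stacks must share their volume shape")
    bls = {b.bandlimit for b in banks}
    if len(bls) > 1:
        raise ValueError("per-view banks must share the band limit")
    return stacks, banks


# ---------------------------------------------------------------------------
# eGRL
# ---------------------------------------------------------------------------

class _ViewOperator:
    """Precomputed per-view pieces: back-projected data and OTF bank."""

    def __init__(self, stack: PolarizedStack, bank: DipolePSFBank, boundary: str = "pad"):
        self.vshape = stack.shape
        self.pshape = fourier.padded_shape(
            self.vshape, bank.kernels.shape[-3:], boundary
        )
        # double precision: the combined operator feeds multiplicative ratios
        self.otfs = fourier.kernel_otfs(
            bank.kernels.astype(np.float64), self.pshape
        )  # (P, C, freq)
        I = fourier.volume_rfft(stack.volumes.astype(np.float64), self.pshape)
        Edata = np.einsum("pcxyz,pxyz->cxyz", np.conj(self.otfs), I)
        self.backprojected = fourier.volume_irfft(Edata, self.pshape, self.vshape)
        self.sensitivity = bank.sensitivity_spectrum()

    def fp_bp(self, coeffs: np.ndarray) -> np.ndarray:
        """Object-to-object transform E ↦ (E ⋆ h) ⋄ h_back."""
        F = fourier.volume_rfft(coeffs.astype(np.float64), self.pshape)
        T = np.einsum("pcxyz,cxyz->pxyz", self.otfs, F)
        B = np.einsum("pcxyz,pxyz->cxyz", np.conj(self.otfs), T)
        return fourier.volume_irfft(B, self.pshape, self.vshape)


def _ratio_update(
    E_flat: np.ndarray,
    denom_flat: np.ndarray,
    numer_flat: np.ndarray,
    G: np.ndarray,
    config: ReconConfig,
    sens_inv: np.ndarray | None,
) -> np.ndarray:
    """One multiplicative update over flattened voxels (N, C)."""
    N, C = E_flat.shape
    dmax = float(denom_flat[:, 0].max())
    frozen = denom_flat[:, 0] <= config.density_floor * max(dmax, 1e-30)
    out = np.empty_like(E_flat)
    for i0 in range(0, N, _CHUNK):
        sl = slice(i0, min(i0 + _CHUNK, N))
        ratio = sh_divide_many(
            numer_flat[sl], denom_flat[sl], G, ridge_rel=config.ridge
        )
        if sens_inv is not None:
            ratio = ratio @ sens_inv.T
        out[sl] = sh_multiply_many(
            E_flat[sl].astype(np.float64), ratio, G
        ).astype(E_flat.dtype)
    out[frozen] = E_flat[frozen]
    out[:, 0] = np.maximum(out[:, 0], 0.0)
    return out


def _sensitivity_inverse(spectrum: AngularSpectrum) -> np.ndarray:
    """Inverse multiplication matrix of the unit-mean sensitivity function."""
    s = spectrum.coeffs / (spectrum.coeffs[0] / SQRT4PI)
    M = multiplication_matrix(AngularSpectrum(s, spectrum.bandlimit))
    return np.linalg.inv(M)


def egrl_reconstruct(
    stacks, banks, config: ReconConfig = ReconConfig(), boundary: str = "pad"
) -> SHField:
    """Efficient generalized Richardson–Lucy reconstruction.

    ``stacks``/``banks`` are per-view lists (or a single stack/bank); with
    two views the iteration alternates a view-A half-update then view-B
    within each iteration.  Initialization is the modulation/view-averaged
    raw data in the density channel with an isotropic angular part.
    """
    stacks, banks = _as_lists(stacks, banks)
    bl = banks[0].bandlimit
    C = bl.n_channels
    vshape = stacks[0].shape
    ops = [_ViewOperator(s, b, boundary) for s, b in zip(stacks, banks)]
    G = gaunt_tensor(bl, bl, bl)
    sens_inv = [
        _sensitivity_inverse(op.sensitivity) if config.sensitivity_normalization else None
        for op in ops
    ]
    E = np.zeros((C,) + vshape, dtype=np.float32)
    E[0] = np.mean([s.volumes.mean(axis=0) for s in stacks], axis=0)
    numer = [op.backprojected.reshape(C, -1).T for op in ops]
    for k in range(config.iterations):
        for v, op in enumerate(ops):
            denom = op.fp_bp(E).reshape(C, -1).T
            E_flat = _ratio_update(
                E.reshape(C, -1).T, denom, numer[v], G, config, sens_inv[v]
            )
            E = np.ascontiguousarray(E_flat.T.reshape((C,) + vshape))
            if not np.all(np.isfinite(E)):
                raise FloatingPointError(
                    f"non-finite estimate at iteration {k}, view {v}"
                )
    field_out = SHField(E, bl, voxel=banks[0].voxel)
    if config.positivity_projection:
        field_out = positivity_project(field_out)
    return field_out


def positivity_project(field: SHField, grid: SphereGrid | None = None) -> SHField:
    """Scale l>0 bands down per voxel until the sampled ODF is nonnegative."""
    from .sphharm import icosphere_grid

    if grid is None:
        grid = icosphere_grid()
    Y = sh_basis_matrix(field.bandlimit, grid)
    flat = field.coeffs.reshape(field.coeffs.shape[0], -1).T.astype(np.float64)
    iso = np.outer(flat[:, 0], Y[:, 0])
    aniso = flat[:, 1:] @ Y[:, 1:].T
    amin = aniso.min(axis=1)
    scale = np.ones(len(flat))
    bad = amin < -1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        scale[bad] = np.minimum(1.0, -iso[bad, 0] / amin[bad])
    scale = np.clip(scale, 0.0, 1.0)
    flat[:, 1:] *= scale[:, None]
    out = flat.T.reshape(field.coeffs.shape)
    return SHField(out.astype(np.float32), field.bandlimit, field.voxel)


# ---------------------------------------------------------------------------
# GRL oracle (explicit orientation grid)
# ---------------------------------------------------------------------------

def grl_reconstruct(
    stacks,
    banks,
    grid: SphereGrid,
    config: ReconConfig = ReconConfig(),
    boundary: str = "pad",
) -> np.ndarray:
    """Explicit-orientation MLEM iteration (the brute-force oracle).

    Returns the sampled object e(r, ŝ_j) with shape (n_dirs, Z, Y, X).
    Direct implementation of the multiplicative update with the
    object-space sensitivity constant 1/Σ_p̂∫h dr applied per orientation;
    guarded to small problems (≤ 32³ voxels × ≤ 200 orientations).
    """
    stacks, banks = _as_lists(stacks, banks)
    vshape = stacks[0].shape
    if np.prod(vshape) > 32**3 or len(grid) > 200:
        raise ValueError("GRL oracle limited to ≤ 32³ voxels × ≤ 200 orientations")
    bl = banks[0].bandlimit
    Y = sh_basis_matrix(bl, grid)  # (J, C)
    kernels = np.concatenate([b.kernels for b in banks], axis=0)
    vols = np.concatenate([s.volumes for s in stacks], axis=0).astype(np.float64)
    # sampled kernels h_p(r, ŝ_j); band-limit ripple clamped for MLEM
    h = np.einsum("jc,pc...->pj...", Y, kernels.astype(np.float64))
    h = np.clip(h, 0.0, None)
    pshape = fourier.padded_shape(vshape, h.shape[-3:], boundary)
    otf = fourier.kernel_otfs(h, pshape).astype(np.complex128)
    sens = h.sum(axis=(0, 2, 3, 4))  # s(ŝ_j)
    if np.any(sens <= 0):
        raise ValueError("zero sensitivity orientation on the grid")
    w = grid.weights
    # isotropic start with the modulation-averaged data as density (the same
    # initialization the spectral solver uses): f = F00·Y00
    e = np.broadcast_to(
        vols.mean(axis=0) / SQRT4PI, (len(grid),) + vshape
    ).astype(np.float64).copy()
    eps = 1e-12 * max(vols.max(), 1.0)
    for _ in range(config.iterations):
        Fh = fourier.volume_rfft(e, pshape)
        fwd = fourier.volume_irfft(
            np.einsum("j,pjxyz,jxyz->pxyz", w, otf, Fh), pshape, vshape
        )
        ratio = vols / np.maximum(fwd, eps)
        Rh = fourier.volume_rfft(ratio, pshape)
        upd = fourier.volume_irfft(
            np.einsum("pjxyz,pxyz->jxyz", np.conj(otf), Rh), pshape, vshape
        )
        e *= upd / sens[:, None, None, None]
        e = np.clip(e, 0.0, None)
    return e


# ---------------------------------------------------------------------------
# Scalar RL and the decoupled ablation
# ---------------------------------------------------------------------------

def rl_deconvolve(
    volume: np.ndarray, psf: np.ndarray, iterations: int = 10
) -> np.ndarray:
    """Standard multiplicative Richardson–Lucy with the flipped back projector."""
    volume = np.asarray(volume, dtype=np.float64)
    psf = np.asarray(psf, dtype=np.float64)
    ripple = 1e-6 * max(volume.max(), 1e-30)
    if volume.min() < -ripple or psf.min() < -1e-6 * max(psf.max(), 1e-30):
        raise ValueError("RL requires nonnegative image and PSF")
    volume = np.clip(volume, 0.0, None)
    psf = np.clip(psf, 0.0, None)
    pshape = fourier.padded_shape(volume.shape, psf.shape)
    otf = fourier.kernel_otfs(psf[None], pshape)[0].astype(np.complex128)
    est = np.full_like(volume, max(volume.mean(), 1e-30))
    eps = 1e-12 * max(volume.max(), 1.0)
    for _ in range(iterations):
        fwd = fourier.volume_irfft(
            otf * fourier.volume_rfft(est, pshape), pshape, volume.shape
        )
        ratio = volume / np.maximum(fwd, eps)
        upd = fourier.volume_irfft(
            np.conj(otf) * fourier.volume_rfft(ratio, pshape), pshape, volume.shape
        )
        est = np.clip(est * upd, 0.0, None)
    return est


def rl_deconvolve_multiview(
    volumes, psfs, iterations: int = 10
) -> np.ndarray:
    """Joint multi-view Richardson–Lucy: one half-update per view and
    iteration (flipped back projectors, flux-normalized PSFs)."""
    volumes = [np.asarray(v, dtype=np.float64) for v in volumes]
    ops = []
    for psf in psfs:
        psf = np.clip(np.asarray(psf, dtype=np.float64), 0.0, None)
        total = psf.sum()
        if total <= 0:
            raise ValueError("degenerate PSF")
        psf = psf / total
        pshape = fourier.padded_shape(volumes[0].shape, psf.shape)
        ops.append((fourier.kernel_otfs(psf[None], pshape)[0], pshape))
    est = np.mean(volumes, axis=0)
    eps = 1e-12 * max(v.max() for v in volumes)
    for _ in range(iterations):
        for vol, (otf, pshape) in zip(volumes, ops):
            fwd = fourier.volume_irfft(
                otf * fourier.volume_rfft(est, pshape), pshape, est.shape
            )
            ratio = vol / np.maximum(fwd, eps)
            upd = fourier.volume_irfft(
                np.conj(otf) * fourier.volume_rfft(ratio, pshape), pshape, est.shape
            )
            est = np.clip(est * upd, 0.0, None)
    return est


def egrlp_reconstruct(stacks, banks, config: ReconConfig = ReconConfig()) -> SHField:
    """Decoupled ablation: per-channel spatial RL, then voxel-wise angular MLEM.

    Stage 1 removes spatial blur from every polarization channel with the
    channel's density kernel; stage 2 treats the deconvolved voxels as
    independent and runs the band-limited multiplicative angular update
    with the spatially integrated kernels a_{p̂,lm} = Σ_r H_{p̂,lm}(r).
    """
    stacks, banks = _as_lists(stacks, banks)
    bl = banks[0].bandlimit
    C = bl.n_channels
    vshape = stacks[0].shape
    a_list, dec_list = [], []
    for stack, bank in zip(stacks, banks):
        a = bank.kernels.sum(axis=(2, 3, 4)).astype(np.float64)  # (P, C)
        for p in range(bank.n_modulations):
            psf = np.clip(bank.kernels[p, 0].astype(np.float64), 0.0, None)
            total = psf.sum()
            if total <= 0:
                raise ValueError("degenerate density kernel in eGRL-p stage 1")
            if stacks[0].volumes.max() == 0:
                dec = np.zeros(vshape)
            else:
                dec = rl_deconvolve(
                    stack.volumes[p], psf / total, iterations=config.iterations
                )
            a_list.append(a[p])
            dec_list.append(dec)
    A = np.stack(a_list)  # (Ptot, C)
    dec = np.stack(dec_list).reshape(len(a_list), -1)  # (Ptot, N)
    G = gaunt_tensor(bl, bl, bl)
    comb = A.T @ A  # (C, C)
    numer = (A.T @ dec).T  # (N, C)
    sens_inv = None
    if config.sensitivity_normalization:
        sens_inv = _sensitivity_inverse(AngularSpectrum(A.sum(axis=0), bl))
    E = np.zeros((np.prod(vshape, dtype=int), C))
    E[:, 0] = dec.mean(axis=0)
    for k in range(config.iterations):
        denom = E @ comb.T
        E = _ratio_update(E, denom, numer, G, config, sens_inv)
        if not np.all(np.isfinite(E)):
            raise FloatingPointError(f"non-finite estimate at iteration {k}")
    coeffs = E.T.reshape((C,) + vshape).astype(np.float32)
    return SHField(coeffs, bl, voxel=banks[0].voxel)


# ---------------------------------------------------------------------------
# SVD / Tikhonov baseline
# ---------------------------------------------------------------------------

class SVDOperator:
    """Per-frequency SVD of the modulation × channel system matrix.

    Factorized once; the Tikhonov filter s/(s²+η) is then applied for any η
    (used by the η grid search without refactorizing).
    """

    def __init__(self, stacks, banks, boundary: str = "pad"):
        stacks, banks = _as_lists(stacks, banks)
        self.bandlimit = banks[0].bandlimit
        self.voxel = banks[0].voxel
        self.vshape = stacks[0].shape
        kshape = tuple(
            max(b.kernels.shape[-3 + i] for b in banks) for i in range(3)
        )
        self.pshape = fourier.padded_shape(self.vshape, kshape, boundary)
        otfs = np.concatenate(
            [
                fourier.kernel_otfs(b.kernels.astype(np.float64), self.pshape)
                for b in banks
            ],
            axis=0,
        )
        data = np.concatenate([s.volumes for s in stacks], axis=0)
        I = fourier.volume_rfft(data.astype(np.float64), self.pshape)
        P, C = otfs.shape[:2]
        self.freq_shape = otfs.shape[2:]
        H = otfs.reshape(P, C, -1).transpose(2, 0, 1)  # (F, P, C)
        self.U, self.s, self.Vh = np.linalg.svd(H, full_matrices=False)
        self.proj = np.einsum(
            "fkp,pf->fk", np.conj(self.U).transpose(0, 2, 1), I.reshape(P, -1)
        )  # U^H Î per frequency

    def reconstruct(self, eta: float) -> SHField:
        if eta < 0:
            raise ValueError("eta must be nonnegative")
        filt = self.s / (self.s**2 + eta)
        Fh = np.einsum("fkc,fk->cf", np.conj(self.Vh), filt * self.proj)
        Fh = Fh.reshape((self.Vh.shape[-1],) + self.freq_shape)
        coeffs = fourier.volume_irfft(Fh, self.pshape, self.vshape)
        return SHField(coeffs.astype(np.float32), self.bandlimit, self.voxel)


def svd_reconstruct(stacks, banks, eta: float, boundary: str = "pad") -> SHField:
    """Tikhonov pseudoinverse F̂ = Σ_k s_k/(s_k²+η)·v_k (u_k·Î) per frequency."""
    return SVDOperator(stacks, banks, boundary).reconstruct(eta)


def eta_search(
    stacks,
    banks,
    ground_truth: SHField,
    etas: np.ndarray | None = None,
    grid: SphereGrid | None = None,
    boundary: str = "pad",
):
    """Grid-search the Tikhonov η maximizing PSIM against the ground truth.

    Default grid: 10^−8 … 10^0 in multiplicative steps of 10^0.1 (81
    values).  Ties within 1e-12 of the maximum resolve to the smallest η.
    Returns (best_eta, etas, scores).
    """
    from .analysis import peak_orientation_map, psim
    from .sphharm import icosphere_grid

    if etas is None:
        etas = 10.0 ** (np.arange(-80, 1) / 10.0)
    etas = np.asarray(etas, dtype=float)
    if etas.size == 0:
        raise ValueError("empty eta range")
    if grid is None:
        grid = icosphere_grid()
    op = SVDOperator(stacks, banks, boundary)
    gt_map = peak_orientation_map(ground_truth, grid)
    scores = np.empty(len(etas))
    for i, eta in enumerate(etas):
        rec = op.reconstruct(float(eta))
        scores[i] = psim(peak_orientation_map(rec, grid), gt_map)
    best = np.min(etas[scores >= scores.max() - 1e-12])
    return float(best), etas, scores


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def poisson_nll(stack: PolarizedStack, estimate: SHField, bank: DipolePSFBank) -> float:
    """Poisson negative log-likelihood (up to a data-only constant)."""
    fwd = forward_project(estimate, bank).volumes.astype(np.float64)
    data = stack.volumes.astype(np.float64)
    eps = 1e-12 * max(fwd.max(), 1.0)
    fwd = np.maximum(fwd, eps)
    return float(np.sum(fwd - data * np.log(fwd)))
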