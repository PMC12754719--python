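"""Polarization schemes, forward projection, noise and calibration.

The measurement model is a spatio-angular convolution: under modulation p̂
the camera sees i_p̂ = Σ_lm H_p̂,lm ⊛ F_lm, one 3D volume per modulation.
This module builds modulation schemes, projects SH-coefficient objects
through a kernel bank, injects Poisson noise at a target SNR, and applies
the lake-based gain calibration used for real instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import fourier
from .dipole_psf import DipolePSFBank, PolarizationState
from .sphharm import BandLimit

logger = logging.getLogger(__name__)


@dataclass
class PolarizationScheme:
    """Ordered list of polarization modulations."""

    states: tuple
    name: str = "custom"

    def __post_init__(self):
        self.states = tuple(self.states)
        if not self.states:
            raise ValueError("scheme must contain at least one modulation")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def per_view_counts(self) -> dict:
        counts = {"A": 0, "B": 0}
        for s in self.states:
            counts[s.view] += 1
        return counts

    def view_indices(self, view: str) -> list:
        return [i for i, s in enumerate(self.states) if s.view == view]


_PRESETS = {
    # per-view (psi list, tilt list); states are the cartesian product
    "sim42": (tuple(np.arange(7) * 180.0 / 7.0), (-15.0, 0.0, 15.0)),
    "18V": ((0.0, 60.0, 120.0), (-15.0, 0.0, 15.0)),
    "8V": ((0.0, 45.0, 90.0, 135.0), (0.0,)),
    "6V": ((0.0, 60.0, 120.0), (0.0,)),
}


def get_scheme(
    name: str | None = None,
    psis: tuple | None = None,
    tilts: tuple = (0.0,),
    views: tuple = ("A", "B"),
) -> PolarizationScheme:
    """Return a preset scheme or build one from explicit angle lists.

    Presets: ``sim42`` (21/view), ``18V`` (9/view), ``8V`` (4/view),
    ``6V`` (3/view).  Explicit ``psis``/``tilts`` override the preset.
    """
    if psis is None:
        if name is None or name not in _PRESETS:
            raise KeyError(f"unknown polarization scheme preset {name!r}")
        psis, tilts = _PRESETS[name]
    states = [
        PolarizationState(view=v, psi=float(psi), tilt=float(t))
        for v in views
        for t in tilts
        for psi in psis
    ]
    return PolarizationScheme(tuple(states), name=name or "custom")


@dataclass
class PolarizedStack:
    """Per-modulation intensity volumes i_p̂(r), axis order (P, Z, Y, X)."""

    volumes: np.ndarray
    scheme: PolarizationScheme
    voxel: float = 130.0
    alpha: float | None = None  # photon scale recorded by add_poisson_noise

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes)
        if self.volumes.dtype not in (np.float32, np.float64):
            self.volumes = self.volumes.astype(np.float32)
        if self.volumes.ndim != 4:
            raise ValueError("stack must be (modulation, Z, Y, X)")
        if self.volumes.shape[0] != len(self.scheme):
            raise ValueError("volume count does not match scheme length")
        vmin = float(self.volumes.min())
        if vmin < -1e-6 * max(float(self.volumes.max()), 1e-30):
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple:
        return self.volumes.shape[1:]

    def split_views(self) -> dict:
        """Per-view sub-stacks, preserving modulation order within a view."""
        out = {}
        for view in ("A", "B"):
            idx = self.scheme.view_indices(view)
            if idx:
                out[view] = (
                    idx,
                    PolarizedStack(
                        self.volumes[idx],
                        PolarizationScheme(
                            tuple(self.scheme.states[i] for i in idx),
                            name=f"{self.scheme.name}:{view}",
                        ),
                        self.voxel,
                    ),
                )
        return out


# ---------------------------------------------------------------------------
# Forward projection
# ---------------------------------------------------------------------------

def forward_project(
    obj,
    bank: DipolePSFBank,
    boundary: str = "pad",
    clamp: bool = True,
    double_precision: bool = False,
) -> PolarizedStack:
    """Project an SH-coefficient object into polarized intensity volumes.

    ``obj`` is anything with ``coeffs`` (C, Z, Y, X), ``bandlimit`` and
    ``voxel`` (an SHField).  Zero-padding by half the kernel support keeps
    wrap-around off the object; tiny negative FFT ripple is clamped.
    ``double_precision`` keeps the whole projection in float64 (round-trip
    exactness checks); the default single-precision path is cached.
    """
    coeffs = np.asarray(obj.coeffs)
    if obj.bandlimit != bank.bandlimit:
        raise ValueError("object and bank band limits differ")
    if abs(obj.voxel - bank.voxel) > 1e-9:
        raise ValueError("object and bank voxel pitches differ")
    vshape = coeffs.shape[1:]
    pshape = fourier.padded_shape(vshape, bank.kernels.shape[-3:], boundary)
    if double_precision:
        otfs = fourier.kernel_otfs(bank.kernels.astype(np.float64), pshape)
    else:
        otfs = bank.otfs(pshape)  # (P, C, freq)
    F = fourier.volume_rfft(
        coeffs.astype(np.float64 if double_precision else np.float32), pshape
    )
    I = np.einsum("pcf,cf->pf", otfs.reshape(otfs.shape[:2] + (-1,)),
                  F.reshape(F.shape[0], -1))
    I = I.reshape((otfs.shape[0],) + otfs.shape[2:])
    vols = fourier.volume_irfft(I, pshape, vshape)
    if not double_precision:
        vols = vols.astype(np.float32)
    if clamp:
        ripple_floor = -1e-6 * max(float(vols.max()), 1e-30)
        if vols.min() < ripple_floor:
            logger.info("forward projection produced negative intensities "
                        "beyond FFT ripple (min %.3e)", vols.min())
        vols = np.clip(vols, 0.0, None)
    scheme = PolarizationScheme(tuple(bank.states), name="bank")
    return PolarizedStack(vols, scheme, voxel=bank.voxel)


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def empirical_snr_db(noisy: np.ndarray, clean: np.ndarray) -> float:
    """SNR(dB) = 10·log10(mean(S²)/mean(N²)) with N the realized residual."""
    clean = np.asarray(clean, dtype=float)
    resid = np.asarray(noisy, dtype=float) - clean
    mn = np.mean(resid**2)
    if mn == 0.0:
        return np.inf
    return 10.0 * np.log10(np.mean(clean**2) / mn)


def add_poisson_noise(
    stack: PolarizedStack, target_snr_db: float, seed: int
) -> PolarizedStack:
    """Scale to photon counts hitting the target SNR in expectation, then
    draw one Poisson realization.

    For counts c ~ Poisson(αS) returned as c/α the expected residual power
    is mean(S)/α, so α = 10^(SNR/10)·mean(S)/mean(S²) exactly targets the
    requested SNR; the output is rescaled back to the input intensity scale
    with α recorded on the stack.
    """
    S = np.asarray(stack.volumes, dtype=np.float64)
    if not np.isfinite(target_snr_db):
        raise ValueError("target SNR must be finite")
    mean_s, mean_s2 = S.mean(), (S**2).mean()
    if mean_s2 == 0.0:
        raise ValueError("cannot add noise to an all-zero stack")
    alpha = 10.0 ** (target_snr_db / 10.0) * mean_s / mean_s2
    rng = np.random.default_rng(seed)
    counts = rng.poisson(alpha * S).astype(np.float64)
    out = PolarizedStack(counts / alpha, stack.scheme, stack.voxel)
    out.alpha = float(alpha)
    return out


# ---------------------------------------------------------------------------
# Calibration and bead mimicry
# ---------------------------------------------------------------------------

def lake_response(bank: DipolePSFBank, size: int | None = None) -> np.ndarray:
    """Per-modulation mean intensity of a uniform, isotropic unit object.

    The lake has F00 ≡ 1 and no higher bands; a cyclic forward projection
    of a small uniform volume is exactly constant, so the mean equals the
    analytic Σ_r H_p̂,00.
    """
    from .reconstruction import SHField

    if size is None:
        size = max(bank.kernels.shape[-3:])
    C = bank.bandlimit.n_channels
    coeffs = np.zeros((C, size, size, size), dtype=np.float32)
    coeffs[0] = 1.0
    lake = SHField(coeffs, bank.bandlimit, voxel=bank.voxel)
    stack = forward_project(lake, bank, boundary="wrap")
    return stack.volumes.mean(axis=(1, 2, 3)).astype(float)


def calibrate_stack(
    raw: PolarizedStack, g_cal: np.ndarray, g_lake: np.ndarray, p0: int = 0
) -> PolarizedStack:
    """Correct per-modulation instrument gains against the lake model:
    g_p = raw_p · (g_cal[p0]/g_cal[p]) · (g_lake[p]/g_lake[p0]).
    """
    g_cal = np.asarray(g_cal, dtype=float)
    g_lake = np.asarray(g_lake, dtype=float)
    P = len(raw.scheme)
    if g_cal.shape != (P,) or g_lake.shape != (P,):
        raise ValueError("calibration scalars must cover every modulation")
    if np.any(g_cal <= 0) or np.any(g_lake <= 0):
        raise ValueError("calibration scalars must be positive")
    factors = (g_cal[p0] / g_cal) * (g_lake / g_lake[p0])
    vols = raw.volumes * factors[:, None, None, None]
    n_clamped = int(np.sum(vols < 0))
    if n_clamped:
        logger.info("calibration clamped %d negative voxels", n_clamped)
        vols = np.clip(vols, 0.0, None)
    return PolarizedStack(vols, raw.scheme, raw.voxel)


def mimic_polarized_beads(
    bead_volumes: dict,
    scheme: PolarizationScheme,
    g_lake: np.ndarray,
    p0: int = 0,
    voxel: float = 130.0,
) -> PolarizedStack:
    """Synthesize a polarized stack from non-polarized bead volumes.

    Randomly oriented bead fluorophores respond to every modulation with the
    lake gain only: bead_{p,v}(r) = bead_v(r)·g_lake[p]/g_lake[p0].
    """
    g_lake = np.asarray(g_lake, dtype=float)
    if g_lake.shape != (len(scheme),):
        raise ValueError("need one lake scalar per modulation")
    if not (0 <= p0 < len(scheme)):
        raise ValueError("reference modulation out of range")
    vols = []
    for p, state in enumerate(scheme.states):
        if state.view not in bead_volumes:
            raise KeyError(f"missing bead volume for view {state.view}")
        vols.append(np.asarray(bead_volumes[state.view]) * (g_lake[p] / g_lake[p0]))
    return PolarizedStack(np.stack(vols), scheme, voxel)
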