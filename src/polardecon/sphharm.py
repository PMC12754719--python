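"""Real spherical harmonics machinery.

Everything angular in this package lives in one fixed convention:

* orthonormal real spherical harmonics, ``∫ Y_lm Y_l'm' dŝ = δ``;
* realification of the Condon–Shortley complex harmonics, giving the
  all-positive polynomial forms (``Y_{1,1} ∝ x``, ``Y_{2,-2} ∝ xy``, ...);
* channel ordering ``(0,0), (2,-2)…(2,2), (4,-4)…(4,4)`` for the even,
  band-limited spectra used throughout (15 channels at lmax=4).

Dipole emission intensity is antipodally symmetric, so orientation
distribution functions (ODFs) carry only even degrees; the imaging physics
band-limits them at l=4.  Odd degrees (l=1 enters the dipole pupil model)
are still available through :func:`real_sh_eval` and the Gaunt machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import sph_harm_y
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

SQRT4PI = 2.0 * np.sqrt(np.pi)
Y00 = 1.0 / SQRT4PI


# ---------------------------------------------------------------------------
# Band limits and channel bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandLimit:
    """Degree cutoff of an angular spectrum.

    Parameters
    ----------
    lmax : int
        Even maximum degree (default 4, the system band of the microscope).
    even_only : bool
        Keep only even degrees (dipole intensity is antipodally symmetric).
    """

    lmax: int = 4
    even_only: bool = True

    def __post_init__(self):
        if self.lmax < 0:
            raise ValueError("lmax must be >= 0")
        if self.even_only and self.lmax % 2 != 0:
            raise ValueError("even-only band limit requires an even lmax")

    @property
    def degrees(self) -> tuple[int, ...]:
        step = 2 if self.even_only else 1
        return tuple(range(0, self.lmax + 1, step))

    @property
    def channels(self) -> tuple[tuple[int, int], ...]:
        return tuple((l, m) for l in self.degrees for m in range(-l, l + 1))

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, l: int, m: int) -> int:
        return self.channels.index((l, m))


@dataclass
class AngularSpectrum:
    """Real SH coefficient vector of a single function on the sphere."""

    coeffs: np.ndarray
    bandlimit: BandLimit = field(default_factory=BandLimit)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.bandlimit.n_channels,):
            raise ValueError(
                f"expected {self.bandlimit.n_channels} coefficients, "
                f"got shape {self.coeffs.shape}"
            )
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite coefficients")

    def __getitem__(self, lm: tuple[int, int]) -> float:
        return float(self.coeffs[self.bandlimit.index(*lm)])


def unit_constant_spectrum(bandlimit: BandLimit = BandLimit()) -> AngularSpectrum:
    """Spectrum of the constant function 1 (coefficient 2√π in channel (0,0))."""
    c = np.zeros(bandlimit.n_channels)
    c[0] = SQRT4PI
    return AngularSpectrum(c, bandlimit)


# ---------------------------------------------------------------------------
# Sphere grids
# ---------------------------------------------------------------------------

@dataclass
class SphereGrid:
    """Discrete orientation samples with quadrature weights (steradians)."""

    directions: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("sphere grid directions must be unit vectors")
        if self.weights.shape != (len(self.directions),):
            raise ValueError("weights must align with directions")

    def __len__(self) -> int:
        return len(self.directions)


def gauss_legendre_grid(degree: int = 10) -> SphereGrid:
    """Gauss–Legendre (cosθ) × uniform-azimuth product grid.

    Exact (to machine precision) for spherical-polynomial integrands of
    total degree ≤ ``degree``; the default integrates products of two
    lmax=4 spectra exactly.
    """
    n = degree // 2 + 1
    x, w = leggauss(n)
    nphi = degree + 1
    phi = 2.0 * np.pi * np.arange(nphi) / nphi
    sin_t = np.sqrt(1.0 - x**2)
    dirs = np.stack(
        [
            np.outer(sin_t, np.cos(phi)),
            np.outer(sin_t, np.sin(phi)),
            np.outer(x, np.ones(nphi)),
        ],
        axis=-1,
    ).reshape(-1, 3)
    weights = np.repeat(w, nphi) * (2.0 * np.pi / nphi)
    return SphereGrid(dirs, weights)


@lru_cache(maxsize=8)
def _icosphere_vertices(subdivisions: int) -> tuple:
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return tuple(map(tuple, mesh.vertices))


def icosphere_grid(subdivisions: int = 3) -> SphereGrid:
    """Antipodally symmetric icosphere (642 vertices at subdivision 3).

    Near-uniform; intended for argmax searches over ODFs.  Weights are the
    uniform 4π/N approximation — use :func:`gauss_legendre_grid` when exact
    quadrature matters.
    """
    dirs = np.asarray(_icosphere_vertices(subdivisions), dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    weights = np.full(len(dirs), 4.0 * np.pi / len(dirs))
    return SphereGrid(dirs, weights)


def default_quadrature_grid(bandlimit: BandLimit = BandLimit()) -> SphereGrid:
    return gauss_legendre_grid(2 * bandlimit.lmax + 2)


# ---------------------------------------------------------------------------
# Evaluation / synthesis / analysis
# ---------------------------------------------------------------------------

def real_sh_eval(l: int, m: int, directions: np.ndarray) -> np.ndarray:
    """Evaluate the orthonormal real spherical harmonic Y_lm at unit vectors."""
    if abs(m) > l:
        raise ValueError(f"|m| = {abs(m)} exceeds degree l = {l}")
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(d, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("directions must be unit vectors (tolerance 1e-6)")
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    if m == 0:
        vals = np.real(sph_harm_y(l, 0, theta, phi))
    else:
        Y = sph_harm_y(l, abs(m), theta, phi)
        if m > 0:
            vals = np.sqrt(2.0) * (-1.0) ** m * np.real(Y)
        else:
            vals = np.sqrt(2.0) * (-1.0) ** (-m) * np.imag(Y)
    if np.ndim(directions) == 1:
        return float(vals[0])
    return vals


def sh_basis_matrix(bandlimit: BandLimit, grid: SphereGrid) -> np.ndarray:
    """Matrix Y of shape (n_directions, n_channels), Y[j, c] = Y_c(ŝ_j)."""
    return np.stack(
        [real_sh_eval(l, m, grid.directions) for l, m in bandlimit.channels],
        axis=1,
    )


def sh_synthesize(spectrum: AngularSpectrum, grid: SphereGrid) -> np.ndarray:
    """Sample f(ŝ_j) = Σ_c coeffs[c] Y_c(ŝ_j) on the grid."""
    Y = sh_basis_matrix(spectrum.bandlimit, grid)
    return Y @ spectrum.coeffs


def sh_analyze(
    samples: np.ndarray, grid: SphereGrid, bandlimit: BandLimit = BandLimit()
) -> AngularSpectrum:
    """Project sampled function values onto the band-limited basis."""
    samples = np.asarray(samples, dtype=float)
    if samples.shape != (len(grid),):
        raise ValueError("samples must align with grid directions")
    Y = sh_basis_matrix(bandlimit, grid)
    coeffs = Y.T @ (grid.weights * samples)
    return AngularSpectrum(coeffs, bandlimit)


# ---------------------------------------------------------------------------
# Gaunt coefficients (real basis)
# ---------------------------------------------------------------------------

def _real_to_complex_coeffs(m: int):
    """Expansion Y_lm^real = Σ c(μ) Y_l^μ over complex harmonics."""
    if m == 0:
        return ((0, 1.0),)
    am = abs(m)
    s = (-1.0) ** am
    if m > 0:
        return ((am, s / np.sqrt(2.0)), (-am, 1.0 / np.sqrt(2.0)))
    return ((am, -1j * s / np.sqrt(2.0)), (-am, 1j / np.sqrt(2.0)))


@lru_cache(maxsize=None)
def _complex_gaunt(l1, l2, l3, m1, m2, m3) -> float:
    from sympy.physics.wigner import gaunt

    return float(gaunt(l1, l2, l3, m1, m2, m3))


@lru_cache(maxsize=None)
def gaunt_real(l1: int, m1: int, l2: int, m2: int, l3: int, m3: int) -> float:
    """Real Gaunt coefficient ∫ Y_l1m1 Y_l2m2 Y_l3m3 dŝ (orthonormal basis)."""
    # selection rules keep the triple loop cheap
    if (l1 + l2 + l3) % 2 != 0:
        return 0.0
    if l3 < abs(l1 - l2) or l3 > l1 + l2:
        return 0.0
    val = 0.0 + 0.0j
    for mu1, c1 in _real_to_complex_coeffs(m1):
        for mu2, c2 in _real_to_complex_coeffs(m2):
            for mu3, c3 in _real_to_complex_coeffs(m3):
                if mu1 + mu2 + mu3 != 0:
                    continue
                val += c1 * c2 * c3 * _complex_gaunt(l1, l2, l3, mu1, mu2, mu3)
    if abs(val.imag) > 1e-12:  # pragma: no cover - convention sanity check
        raise AssertionError("real Gaunt coefficient came out complex")
    return float(val.real)


@dataclass
class GauntTable:
    """Sparse map (l,m,l',m',l'',m'') → real Gaunt coefficient."""

    lmax: int
    entries: dict

    def get(self, l1, m1, l2, m2, l3, m3) -> float:
        return self.entries.get((l1, m1, l2, m2, l3, m3), 0.0)


@lru_cache(maxsize=8)
def gaunt_table(lmax: int) -> GauntTable:
    """All non-zero real Gaunt coefficients with every degree ≤ lmax."""
    if lmax < 0:
        raise ValueError("lmax must be >= 0")
    pairs = [(l, m) for l in range(lmax + 1) for m in range(-l, l + 1)]
    entries = {}
    for i1, (l1, m1) in enumerate(pairs):
        for i2, (l2, m2) in enumerate(pairs):
            if i2 < i1:
                continue
            for i3, (l3, m3) in enumerate(pairs):
                if i3 < i2:
                    continue
                g = gaunt_real(l1, m1, l2, m2, l3, m3)
                if g != 0.0:
                    # store all permutations; the integrand is symmetric
                    for key in {
                        (l1, m1, l2, m2, l3, m3),
                        (l1, m1, l3, m3, l2, m2),
                        (l2, m2, l1, m1, l3, m3),
                        (l2, m2, l3, m3, l1, m1),
                        (l3, m3, l1, m1, l2, m2),
                        (l3, m3, l2, m2, l1, m1),
                    }:
                        entries[key] = g
    return GauntTable(lmax=lmax, entries=entries)


@lru_cache(maxsize=32)
def gaunt_tensor(
    out_bl: BandLimit, a_bl: BandLimit = BandLimit(), b_bl: BandLimit = BandLimit()
) -> np.ndarray:
    """Dense contraction tensor G[out, a, b] for band-limited products."""
    G = np.zeros((out_bl.n_channels, a_bl.n_channels, b_bl.n_channels))
    for i, (l1, m1) in enumerate(out_bl.channels):
        for j, (l2, m2) in enumerate(a_bl.channels):
            for k, (l3, m3) in enumerate(b_bl.channels):
                G[i, j, k] = gaunt_real(l1, m1, l2, m2, l3, m3)
    return G


# ---------------------------------------------------------------------------
# Spectrum products and quotients
# ---------------------------------------------------------------------------

def sh_multiply(
    a: AngularSpectrum, b: AngularSpectrum, out_bandlimit: BandLimit | None = None
) -> AngularSpectrum:
    """Band-limited pointwise product of two spherical functions."""
    if out_bandlimit is None:
        out_bandlimit = a.bandlimit
    G = gaunt_tensor(out_bandlimit, a.bandlimit, b.bandlimit)
    coeffs = np.einsum("oab,a,b->o", G, a.coeffs, b.coeffs)
    return AngularSpectrum(coeffs, out_bandlimit)


def multiplication_matrix(b: AngularSpectrum, bandlimit: BandLimit | None = None) -> np.ndarray:
    """Matrix M with (b·f)_lm = Σ M_{lm,l'm'} f_{l'm'} (truncated product)."""
    if bandlimit is None:
        bandlimit = b.bandlimit
    G = gaunt_tensor(bandlimit, bandlimit, b.bandlimit)
    return np.einsum("oab,b->oa", G, b.coeffs)


def sh_divide(
    numer: AngularSpectrum,
    denom: AngularSpectrum,
    ridge: float | None = None,
    cond_threshold: float = 1e12,
) -> AngularSpectrum:
    """Solve M(denom) x = numer, the band-limited deconvolution of a product.

    The denominator's mean (channel (0,0)) is floored at a small positive
    value and a scaled ridge is added before solving; a badly conditioned
    system falls back to a stronger ridge solve with a log message.
    """
    bl = numer.bandlimit
    d = denom.coeffs.copy()
    floor = 1e-6 * max(abs(d[0]), 1.0)
    if d[0] < floor:
        d = d.copy()
        d[0] = floor
    M = multiplication_matrix(AngularSpectrum(d, denom.bandlimit), bl)
    lam = (1e-9 * np.trace(M) / M.shape[0]) if ridge is None else ridge
    Mr = M + lam * np.eye(M.shape[0])
    if np.linalg.cond(Mr) > cond_threshold:
        logger.warning("sh_divide: ill-conditioned system, increasing ridge")
        Mr = M + (abs(lam) + 1e-6 * abs(np.trace(M)) / M.shape[0]) * np.eye(M.shape[0])
    x = np.linalg.solve(Mr, numer.coeffs)
    return AngularSpectrum(x, bl)


def sh_multiply_many(a: np.ndarray, b: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Batched product: a (N,Ca), b (N,Cb), G (Co,Ca,Cb) → (N,Co)."""
    Co, Ca, Cb = G.shape
    Mb = (G.reshape(Co * Ca, Cb) @ b.T).T.reshape(-1, Co, Ca)
    return np.einsum("noa,na->no", Mb, a)


def sh_divide_many(
    numer: np.ndarray,
    denom: np.ndarray,
    G: np.ndarray,
    ridge_rel: float = 1e-9,
) -> np.ndarray:
    """Batched solve of M(denom) x = numer per row (float64 accumulation)."""
    numer = np.asarray(numer, dtype=np.float64)
    denom = np.asarray(denom, dtype=np.float64)
    Co, Ca, Cb = G.shape
    M = (G.reshape(Co * Ca, Cb) @ denom.T).T.reshape(-1, Co, Ca)
    tr = np.einsum("nii->n", M)
    lam = ridge_rel * np.abs(tr) / Co + 1e-300
    M[:, np.arange(Co), np.arange(Co)] += lam[:, None]
    return np.linalg.solve(M, numer[..., None])[..., 0]


# ---------------------------------------------------------------------------
# Real Wigner rotations
# ---------------------------------------------------------------------------

@dataclass
class WignerMatrix:
    """Block-diagonal real rotation of SH coefficients, one block per degree."""

    bandlimit: BandLimit
    blocks: dict

    def matrix(self) -> np.ndarray:
        C = self.bandlimit.n_channels
        B = np.zeros((C, C))
        off = 0
        for l in self.bandlimit.degrees:
            n = 2 * l + 1
            B[off : off + n, off : off + n] = self.blocks[l]
            off += n
        return B

    def apply(self, coeffs: np.ndarray) -> np.ndarray:
        """Rotate spectra; coeffs has channels on the last axis."""
        return coeffs @ self.matrix().T


def wigner_real_rotation(l: int, axis: np.ndarray, angle: float) -> np.ndarray:
    """Real Wigner block B for degree l: rotated-function coefficients are
    B @ original coefficients, for the active rotation by `angle` about `axis`.

    Computed by exact quadrature of Y_lm(ŝ)·Y_lm'(R⁻¹ŝ): the integrand is a
    spherical polynomial of degree 2l, so the Gauss–Legendre grid integrates
    it to machine precision.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ValueError("rotation axis must be a unit vector")
    axis = axis / norm
    if l == 0:
        return np.ones((1, 1))
    grid = gauss_legendre_grid(2 * l + 2)
    R = Rotation.from_rotvec(axis * angle).as_matrix()
    dirs_r = grid.directions @ R  # row-wise R⁻¹ ŝ
    Ym = np.stack([real_sh_eval(l, m, grid.directions) for m in range(-l, l + 1)])
    Ymr = np.stack([real_sh_eval(l, m, dirs_r) for m in range(-l, l + 1)])
    return (Ym * grid.weights) @ Ymr.T


def wigner_matrix(
    axis: np.ndarray, angle: float, bandlimit: BandLimit = BandLimit()
) -> WignerMatrix:
    blocks = {l: wigner_real_rotation(l, axis, angle) for l in bandlimit.degrees}
    return WignerMatrix(bandlimit, blocks)
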