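"""ODF-derived maps and reconstruction-quality metrics.

Maps: density (F00), peak orientation (per-voxel ODF argmax), principal
orientation (axis maximizing the axial projection Σ|ŝ·ŝ'|f(ŝ')),
generalized fractional anisotropy, and the order parameter ⟨P₂(ŝ·n̂)⟩
against a reference axis.  Orientation comparisons are axial throughout
(ŝ ≡ −ŝ), so dot products appear as absolute values and representative
axes live on the z ≥ 0 hemisphere.

Metrics: global-statistics SSIM for density volumes, PSIM (mean axial dot
of peak orientations), ONCC (mean per-voxel Pearson correlation of ODF
samples), OSIM (1 − mean squared ODF sample difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .sphharm import SQRT4PI, BandLimit, SphereGrid, icosphere_grid, sh_basis_matrix

_GFA_MASK_THRESHOLD = 0.02
_DENSITY_MASK_REL = 1e-3


@dataclass
class OrientationMap:
    """Unit axis per voxel (axial semantics) with a validity mask."""

    axes: np.ndarray  # (3, Z, Y, X), components (x, y, z)
    mask: np.ndarray  # (Z, Y, X) bool

    def __post_init__(self):
        self.axes = np.asarray(self.axes, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.axes.shape[0] != 3 or self.axes.shape[1:] != self.mask.shape:
            raise ValueError("axes must be (3, Z, Y, X) aligned with mask")


@dataclass
class ScalarMap:
    values: np.ndarray
    name: str = "density"


def _hemisphere(axes: np.ndarray) -> np.ndarray:
    """Flip axes into the representative hemisphere z ≥ 0 (ties: y, then x)."""
    a = axes.copy()
    z, y, x = a[2], a[1], a[0]
    flip = (z < 0) | ((z == 0) & (y < 0)) | ((z == 0) & (y == 0) & (x < 0))
    a[:, flip] *= -1.0
    return a


def density_map(field) -> ScalarMap:
    """Orientation-independent fluorophore density: the (0,0) channel."""
    return ScalarMap(np.asarray(field.coeffs[0], dtype=float), name="density")


def gfa_map(field) -> ScalarMap:
    """Generalized fractional anisotropy √(1 − F00²/Σ F_lm²), 0 for empty voxels."""
    c = np.asarray(field.coeffs, dtype=np.float64)
    total = np.sum(c**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gfa = np.sqrt(np.clip(1.0 - c[0] ** 2 / total, 0.0, 1.0))
    gfa[total == 0] = 0.0
    return ScalarMap(gfa, name="gfa")


def _valid_mask(field) -> np.ndarray:
    dens = np.asarray(field.coeffs[0])
    gfa = gfa_map(field).values
    dmax = float(dens.max()) if dens.size else 0.0
    return (gfa >= _GFA_MASK_THRESHOLD) & (dens > _DENSITY_MASK_REL * max(dmax, 1e-30))


def peak_orientation_map(field, grid: SphereGrid | None = None) -> OrientationMap:
    """Per-voxel ODF argmax over the (antipodal) grid; near-flat voxels masked."""
    if grid is None:
        grid = icosphere_grid()
    Y = sh_basis_matrix(field.bandlimit, grid)
    C = field.coeffs.shape[0]
    flat = np.asarray(field.coeffs, dtype=np.float64).reshape(C, -1)
    idx = np.argmax(Y @ flat, axis=0)
    axes = grid.directions[idx].T.reshape((3,) + field.coeffs.shape[1:])
    mask = _valid_mask(field)
    axes = _hemisphere(axes)
    axes[:, ~mask] = np.nan
    return OrientationMap(axes, mask)


def principal_orientation_map(field, grid: SphereGrid | None = None) -> OrientationMap:
    """Axis maximizing the axial projection Σ_ŝ' |ŝ·ŝ'| f(ŝ') over the grid."""
    if grid is None:
        grid = icosphere_grid()
    Y = sh_basis_matrix(field.bandlimit, grid)
    proj = np.abs(grid.directions @ grid.directions.T)  # (J, J)
    C = field.coeffs.shape[0]
    flat = np.asarray(field.coeffs, dtype=np.float64).reshape(C, -1)
    samples = Y @ flat  # (J, N)
    idx = np.argmax(proj @ samples, axis=0)
    axes = grid.directions[idx].T.reshape((3,) + field.coeffs.shape[1:])
    mask = _valid_mask(field)
    axes = _hemisphere(axes)
    axes[:, ~mask] = np.nan
    return OrientationMap(axes, mask)


def op_map(field, n_hat: np.ndarray) -> ScalarMap:
    """Order parameter ⟨P₂(ŝ·n̂)⟩ of each voxel's ODF.

    Computed from the l=2 band via the addition theorem; the prefactor is
    calibrated so a delta ODF parallel to n̂ scores exactly 1 (isotropic 0,
    perpendicular −1/2).
    """
    n_hat = np.asarray(n_hat, dtype=float)
    if abs(np.linalg.norm(n_hat) - 1.0) > 1e-6:
        raise ValueError("reference axis must be a unit vector")
    bl: BandLimit = field.bandlimit
    from .sphharm import real_sh_eval

    c = np.asarray(field.coeffs, dtype=np.float64)
    num = np.zeros(c.shape[1:])
    for i, (l, m) in enumerate(bl.channels):
        if l == 2:
            num += c[i] * real_sh_eval(2, m, n_hat)
    dens = c[0]
    prefactor = (4.0 * np.pi / 5.0) / SQRT4PI
    with np.errstate(invalid="ignore", divide="ignore"):
        op = prefactor * num / dens
    op[dens <= _DENSITY_MASK_REL * max(float(dens.max()), 1e-30)] = np.nan
    return ScalarMap(op, name="op")


def op_vs_distance(op: ScalarMap, structure_mask: np.ndarray):
    """Mean OP binned by integer-voxel Euclidean distance from a structure.

    Returns (distances, mean OP, counts); bin 0 is the structure itself.
    """
    mask = np.asarray(structure_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure mask")
    dist = ndimage.distance_transform_edt(~mask)
    bins = np.round(dist).astype(int)
    values = np.asarray(op.values, dtype=float)
    good = np.isfinite(values)
    nbins = int(bins[good].max()) + 1 if good.any() else 1
    sums = np.bincount(bins[good], weights=values[good], minlength=nbins)
    counts = np.bincount(bins[good], minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    d = np.arange(nbins)
    keep = counts > 0
    return d[keep], means[keep], counts[keep]


# ---------------------------------------------------------------------------
# Quality metrics
# ---------------------------------------------------------------------------

def ssim(a, b, windowed: bool = False) -> float:
    """Structural similarity of two density volumes.

    Default: the global-statistics form (means, variances and covariance
    over the whole volume with the usual small constants).  ``windowed``
    switches to the common sliding-window SSIM for cross-checks.
    """
    av = np.asarray(getattr(a, "values", a), dtype=np.float64)
    bv = np.asarray(getattr(b, "values", b), dtype=np.float64)
    if av.shape != bv.shape:
        raise ValueError("density maps must share their shape")
    if windowed:
        from skimage.metrics import structural_similarity

        rng = max(av.max(), bv.max()) - min(av.min(), bv.min())
        return float(structural_similarity(av, bv, data_range=max(rng, 1e-30)))
    rng = max(av.max(), bv.max()) - min(av.min(), bv.min())
    rng = max(rng, 1e-30)
    c1, c2 = (0.01 * rng) ** 2, (0.03 * rng) ** 2
    mu_a, mu_b = av.mean(), bv.mean()
    var_a, var_b = av.var(), bv.var()
    cov = np.mean((av - mu_a) * (bv - mu_b))
    return float(
        (2 * mu_a * mu_b + c1)
        * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


def psim(a: OrientationMap, b: OrientationMap) -> float:
    """Mean axial dot product |â·b̂| of peak orientations over shared voxels."""
    mask = a.mask & b.mask
    if not mask.any():
        raise ValueError("orientation maps share no valid voxels")
    dots = np.abs(np.sum(a.axes[:, mask] * b.axes[:, mask], axis=0))
    return float(np.mean(np.clip(dots, 0.0, 1.0)))


def _odf_samples(field, grid: SphereGrid):
    Y = sh_basis_matrix(field.bandlimit, grid)
    C = field.coeffs.shape[0]
    return Y @ np.asarray(field.coeffs, dtype=np.float64).reshape(C, -1)  # (J, N)


def oncc(a, b, grid: SphereGrid | None = None) -> float:
    """Mean per-voxel Pearson correlation of the two sampled ODFs."""
    if grid is None:
        grid = icosphere_grid()
    if a.coeffs.shape != b.coeffs.shape:
        raise ValueError("fields must share shape and band limit")
    fa, fb = _odf_samples(a, grid), _odf_samples(b, grid)
    fa = fa - fa.mean(axis=0)
    fb = fb - fb.mean(axis=0)
    va = np.sqrt(np.mean(fa**2, axis=0))
    vb = np.sqrt(np.mean(fb**2, axis=0))
    good = (va > 1e-30) & (vb > 1e-30)
    if not good.any():
        raise ValueError("no voxel with ODF variance in both fields")
    corr = np.mean(fa[:, good] * fb[:, good], axis=0) / (va[good] * vb[good])
    return float(np.mean(corr))


def osim(a, b, grid: SphereGrid | None = None) -> float:
    """1 − mean squared difference of the sampled ODFs (1 on identical inputs)."""
    if grid is None:
        grid = icosphere_grid()
    if a.coeffs.shape != b.coeffs.shape:
        raise ValueError("fields must share shape and band limit")
    fa, fb = _odf_samples(a, grid), _odf_samples(b, grid)
    return float(1.0 - np.mean((fa - fb) ** 2))


def axis_proportions(omap: OrientationMap) -> np.ndarray:
    """Fraction of orientation energy on the x, y, z axes (radar-chart stat).

    Mean squared component per Cartesian axis over valid voxels; sums to 1.
    """
    v = omap.axes[:, omap.mask]
    if v.size == 0:
        raise ValueError("no valid orientations")
    return np.mean(v**2, axis=1)
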