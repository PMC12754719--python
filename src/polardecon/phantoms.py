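"""Synthetic spatio-angular ground-truth objects.

Each phantom is an ``SHField`` whose per-voxel ODF is a band-limited
"delta" pointing along a geometrically meaningful local axis — radial for
shells, spheres and vesicles, tangential for helices.  Orientations are
axial (ŝ ≡ −ŝ): only even degrees are populated, which is what dipole
emission can encode.  Truncated deltas ring negative on the sphere, so the
anisotropy scale is capped at a per-bandlimit positivity bound.

Returned fields carry two extra attributes used by recovery tests:
``true_axes`` (3, Z, Y, X; NaN where no orientation is defined) and
``structure_mask`` (bool volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.special import eval_legendre

from .reconstruction import SHField
from .sphharm import Y00, BandLimit, real_sh_eval

_SUPERSAMPLE = 3  # sub-voxel rasterization factor for thin curved structures


@dataclass
class PhantomSpec:
    """Geometry + angular parameters of one synthetic object."""

    kind: str
    shape: tuple = (64, 64, 64)
    voxel: float = 130.0
    seed: int = 0
    gfa_scale: float | None = None  # None → 0.75 × positivity bound
    density: float = 1.0
    bandlimit: BandLimit = field(default_factory=BandLimit)
    # shell / GUV
    radius_vox: float = 30.0
    blur_sigma: float = 2.0
    # spheres
    n_spheres: int = 8
    density_range: tuple = (500.0, 900.0)
    sphere_radius_range: tuple = (2.0, 6.0)
    # helices
    helix_radius_nm: float = 600.0
    pitch_nm: float = 1000.0
    inner_space_nm: float = 554.0
    gfa_ramp: bool = False

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        if self.voxel <= 0 or any(n < 1 for n in self.shape):
            raise ValueError("invalid phantom geometry")

    def resolved_gfa_scale(self) -> float:
        bound = positivity_bound(self.bandlimit)
        if self.gfa_scale is None:
            return 0.75 * bound
        if self.gfa_scale > bound + 1e-9:
            import warnings

            warnings.warn(
                f"gfa_scale {self.gfa_scale:.3f} exceeds the positivity "
                f"bound {bound:.3f}; the band-limited ODF will go negative"
            )
        return self.gfa_scale


@lru_cache(maxsize=8)
def positivity_bound(bandlimit: BandLimit = BandLimit()) -> float:
    """Largest l>0 scale keeping the band-limited delta ODF nonnegative.

    By rotational symmetry the bound follows from the Legendre sum
    1 + t·Σ_{l>0}(2l+1)P_l(cosθ) ≥ 0 over θ.
    """
    ct = np.cos(np.linspace(0.0, np.pi, 20001))
    g = np.zeros_like(ct)
    for l in bandlimit.degrees:
        if l > 0:
            g += (2 * l + 1) * eval_legendre(l, ct)
    gmin = g.min()
    if gmin >= 0:
        return np.inf
    return float(-1.0 / gmin)


def delta_odf_spectrum(
    axis: np.ndarray,
    gfa_scale: float = 1.0,
    bandlimit: BandLimit = BandLimit(),
):
    """Band-limited delta along ``axis``: F_lm = Y_lm(axis), l>0 × gfa_scale."""
    from .sphharm import AngularSpectrum

    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
        raise ValueError("axis must be a unit vector")
    coeffs = np.array(
        [
            real_sh_eval(l, m, axis) * (1.0 if l == 0 else gfa_scale)
            for l, m in bandlimit.channels
        ]
    )
    return AngularSpectrum(coeffs, bandlimit)


def _assemble_field(
    density: np.ndarray,
    axes: np.ndarray,
    gfa_scale,
    spec: PhantomSpec,
) -> SHField:
    """Build (C, Z, Y, X) coefficients from density, axes and GFA scale.

    ``axes`` is (3, Z, Y, X) with NaN where no orientation is defined
    (those voxels stay isotropic); ``gfa_scale`` may be a volume (ramps).
    """
    bl = spec.bandlimit
    C = bl.n_channels
    coeffs = np.zeros((C,) + spec.shape, dtype=np.float32)
    coeffs[0] = density
    valid = np.isfinite(axes[0]) & (density > 0)
    if np.any(valid):
        v = axes[:, valid].T  # (N, 3)
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        g = gfa_scale[valid] if np.ndim(gfa_scale) else gfa_scale
        rho = density[valid]
        for i, (l, m) in enumerate(bl.channels):
            if l == 0:
                continue
            coeffs[i, valid] = rho * g * real_sh_eval(l, m, v) / Y00
    out = SHField(coeffs, bl, voxel=spec.voxel)
    out.true_axes = axes
    out.structure_mask = valid
    return out


def _voxel_centers(shape):
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    return zz, yy, xx


# ---------------------------------------------------------------------------
# Radial phantoms
# ---------------------------------------------------------------------------

def _radial_shell(spec: PhantomSpec, blur: float, thickness: float = 1.0) -> SHField:
    if 2 * spec.radius_vox >= min(spec.shape):
        raise ValueError("shell radius exceeds the volume")
    zz, yy, xx = _voxel_centers(spec.shape)
    center = (np.array(spec.shape) - 1) / 2.0
    d = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    density = (np.abs(d - spec.radius_vox) < thickness / 2.0).astype(float)
    density *= spec.density
    if blur > 0:
        density = ndimage.gaussian_filter(density, sigma=blur)
    # radial axes stored as Cartesian (x, y, z) components per voxel
    with np.errstate(invalid="ignore", divide="ignore"):
        axes = np.stack(
            [(xx - center[2]) / d, (yy - center[1]) / d, (zz - center[0]) / d]
        )
    axes[:, density <= 1e-3 * density.max()] = np.nan
    return _assemble_field(density, axes, spec.resolved_gfa_scale(), spec)


def _spheres(spec: PhantomSpec) -> SHField:
    rng = np.random.default_rng(spec.seed)
    density = np.zeros(spec.shape)
    axes = np.full((3,) + spec.shape, np.nan)
    owner_dist = np.full(spec.shape, np.inf)
    zz, yy, xx = _voxel_centers(spec.shape)
    rmin, rmax = spec.sphere_radius_range
    for _ in range(spec.n_spheres):
        radius = rng.uniform(rmin, rmax)
        d0 = rng.uniform(*spec.density_range)
        margin = radius + 1
        center = [rng.uniform(margin, n - 1 - margin) for n in spec.shape]
        d = np.sqrt(
            (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        )
        inside = d <= radius
        sigma = radius / 2.0
        density[inside] += d0 * np.exp(-(d[inside] ** 2) / (2 * sigma**2))
        take = inside & (d < owner_dist) & (d > 1e-9)
        owner_dist[take] = d[take]
        for k, comp in enumerate(((xx - center[2]), (yy - center[1]), (zz - center[0]))):
            axes[k][take] = comp[take] / d[take]
    return _assemble_field(density, axes, spec.resolved_gfa_scale(), spec)


# ---------------------------------------------------------------------------
# Helical phantoms
# ---------------------------------------------------------------------------

def _helix_curve(axis_dir, center_vox, radius_vox, pitch_vox, length_vox, phase=0.0):
    """Sample points and unit tangents of one helix (voxel units)."""
    axis_dir = np.asarray(axis_dir, dtype=float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    # orthonormal frame
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis_dir)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis_dir, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis_dir, u)
    n_turns = length_vox / pitch_vox
    n_pts = max(int(600 * max(n_turns, 1.0)), 400)
    t = np.linspace(-n_turns * np.pi, n_turns * np.pi, n_pts) + phase
    along = (t - phase) * pitch_vox / (2 * np.pi)
    pts = (
        np.asarray(center_vox)[None, :]
        + along[:, None] * axis_dir[None, :]
        + radius_vox * (np.cos(t)[:, None] * u[None, :] + np.sin(t)[:, None] * v[None, :])
    )
    tang = (
        (pitch_vox / (2 * np.pi)) * axis_dir[None, :]
        + radius_vox * (-np.sin(t)[:, None] * u[None, :] + np.cos(t)[:, None] * v[None, :])
    )
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return pts, tang


def _rasterize_curves(spec: PhantomSpec, curves) -> SHField:
    """Supersampled splat of curve points, box-downsampled to the voxel grid."""
    ss = _SUPERSAMPLE
    fine_shape = tuple(n * ss for n in spec.shape)
    fine = np.zeros(fine_shape, dtype=np.float32)
    all_pts, all_tang = [], []
    for pts, tang in curves:
        # pts in coarse-voxel coordinates (z, y, x order)
        fine_idx = np.round(pts * ss + (ss - 1) / 2.0).astype(int)
        ok = np.all((fine_idx >= 0) & (fine_idx < np.array(fine_shape)), axis=1)
        fine[tuple(fine_idx[ok].T)] = 1.0
        all_pts.append(pts[ok])
        all_tang.append(tang[ok])
    if not all_pts or not any(len(p) for p in all_pts):
        raise ValueError("helix geometry falls outside the volume")
    density = fine.reshape(
        spec.shape[0], ss, spec.shape[1], ss, spec.shape[2], ss
    ).mean(axis=(1, 3, 5)).astype(float)
    density *= spec.density
    pts = np.concatenate(all_pts)
    tang = np.concatenate(all_tang)
    tree = cKDTree(pts)
    axes = np.full((3,) + spec.shape, np.nan)
    mask = density > 0
    vox = np.argwhere(mask).astype(float)
    if len(vox):
        _, nearest = tree.query(vox)
        t = tang[nearest]  # (N,3) in (z,y,x) component order
        for k in range(3):  # store as (x, y, z)
            axes[k][mask] = t[:, 2 - k]
    # GFA ramp along z ("bottom to top"), if requested
    if spec.gfa_ramp:
        bound = positivity_bound(spec.bandlimit)
        z = np.arange(spec.shape[0], dtype=float) / max(spec.shape[0] - 1, 1)
        gfa = (0.1 + 0.85 * z)[:, None, None] * bound * np.ones(spec.shape)
    else:
        gfa = spec.resolved_gfa_scale()
    return _assemble_field(density, axes, gfa, spec)


def _single_helix(spec: PhantomSpec) -> SHField:
    r = spec.helix_radius_nm / spec.voxel
    p = spec.pitch_nm / spec.voxel
    center = (np.array(spec.shape, dtype=float) - 1) / 2.0
    length = spec.shape[2] * 0.9  # run along x; axis given in (z,y,x) order
    curve = _helix_curve([0.0, 0.0, 1.0], center, r, p, length)
    return _rasterize_curves(spec, [curve])


def _triple_helix(spec: PhantomSpec) -> SHField:
    """Three single helices along the x, y, z axes, spaced along x."""
    r = spec.helix_radius_nm / spec.voxel
    p = spec.pitch_nm / spec.voxel
    nz, ny, nx = spec.shape
    cz, cy = (nz - 1) / 2.0, (ny - 1) / 2.0
    box = min(20.0, nx / 3.0 - 1.0, nz - 2.0, ny - 2.0)
    centers_x = [(i + 0.5) * nx / 3.0 for i in range(3)]
    axes_zyx = [[0, 0, 1.0], [0, 1.0, 0], [1.0, 0, 0]]  # x-, y-, z-aligned
    curves = [
        _helix_curve(a, [cz, cy, cx0], r, p, box)
        for a, cx0 in zip(axes_zyx, centers_x)
    ]
    return _rasterize_curves(spec, curves)


def _double_helix(spec: PhantomSpec) -> SHField:
    """Two strands on one cylinder (axis z) with an axial center-to-center
    gap of ``inner_space_nm`` set by the phase offset 2π·inner/pitch."""
    r = spec.helix_radius_nm / spec.voxel
    p = spec.pitch_nm / spec.voxel
    nz, ny, nx = spec.shape
    center = (np.array(spec.shape, dtype=float) - 1) / 2.0
    dphi = 2 * np.pi * spec.inner_space_nm / spec.pitch_nm
    length = nz * 0.95
    axis_z = [1.0, 0, 0]  # (z,y,x) component order
    c1 = _helix_curve(axis_z, center, r, p, length, phase=0.0)
    c2 = _helix_curve(axis_z, center, r, p, length, phase=dphi)
    return _rasterize_curves(spec, [c1, c2])


_KINDS = {}


def make_phantom(spec: PhantomSpec) -> SHField:
    """Generate the phantom described by ``spec`` (deterministic in seed)."""
    kind = spec.kind.lower()
    if kind == "shell":
        return _radial_shell(spec, blur=spec.blur_sigma)
    if kind == "guv":
        return _radial_shell(spec, blur=min(spec.blur_sigma, 1.0), thickness=2.0)
    if kind == "spheres":
        return _spheres(spec)
    if kind == "helix":
        return _single_helix(spec)
    if kind == "triple_helix":
        return _triple_helix(spec)
    if kind == "double_helix":
        return _double_helix(spec)
    raise ValueError(f"unknown phantom kind {spec.kind!r}")
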