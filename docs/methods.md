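# Methods

## Model

A fluorophore is treated as an oscillating dipole with a fixed transition
moment ŝ during the exposure. Two angular factors enter the measurement:

* **Photoselection.** Under linearly polarized excitation along p̂ the
  excitation probability is ∝ (p̂·ŝ)². Its angular spectrum is exact in
  the even real spherical harmonics with l ≤ 2:
  `P_lm(p̂) = 4π·Y_lm(p̂)·(δ_l0 + (2/5)δ_l2)`; the synthesized function is
  3(p̂·ŝ)², peaking at 3 with spherical mean 1.
* **Vectorial detection.** The pupil fields of the three dipole components
  are propagated plane-by-plane with the aplanatic apodization
  `A(τ) = (1 − (|τ|/ν_m)²)^(−1/4)` inside the coherent cutoff
  |τ| < NA/λ and the defocus phase `exp(i2π z √(ν_m² − |τ|²))`, with
  ν_m = n0/λ. The six pupil dipole components use the standard vectorial
  forms; the axial-dipole terms scale with
  sinθ = |τ|/ν_m. Squaring gives the 3×3 Hermitian
  irradiance matrix `B_jj'(r)`, which an l=1×l=1 Gaunt contraction maps to
  the detection angular spectra `H_lm^det(r)`; only l ∈ {0, 2} survive.
  (A bare |τ| in the axial-dipole terms would be dimensionally
  inconsistent — the normalized frequency is the physical quantity.)

System kernels are band-limited spherical products (Gaunt contractions) of
detection and excitation spectra — nonzero only for even l ≤ 4, hence 15
channels. Light-sheet geometries multiply by the Gaussian sheet envelope
`exp(−2 d²/w0²)` with d the distance along the detection axis (the sheet
is assumed not to broaden over the field of view). The orthogonal second
view of a dual-view system is the canonical kernel rotated 90° about y:
real Wigner blocks on the channels and an exact lattice motion on the
grid.

Everything angular uses one convention: orthonormal real spherical
harmonics obtained from the Condon–Shortley complex basis by the standard
realification (all-positive polynomial forms: Y_{1,1} ∝ x, Y_{2,−2} ∝ xy,
…), with channel ordering (0,0), (2,−2)…(2,2), (4,−4)…(4,4). Real Gaunt
coefficients are computed analytically (complex Gaunt via Wigner-3j plus
the real↔complex unitary transform) and verified in the tests against
Gauss–Legendre sphere quadrature of the triple products. Wigner rotation
blocks are computed by exact quadrature of Y_lm(ŝ)Y_lm'(R⁻¹ŝ) — the
integrand is a spherical polynomial, so the Gauss–Legendre grid integrates
it to machine precision.

## Solvers

**eGRL** (primary). The explicit-orientation maximum-likelihood iteration
for Poisson data is restructured into the frequency × angular-spectrum
domain: precompute the back-projected data `b = Σ_p h̄_p ⊛ i_p` and the
combined object-to-object operator `A = Σ_p h̄_p ⊛ h_p ⊛ ·`; then iterate
`E ← E ⊙ (b ⊘ A E)` with per-voxel band-limited spherical products (⊙)
and quotients (⊘, a 15×15 linear solve per voxel built from the Gaunt
tensor). Because numerator and denominator both carry the back-projector,
the object-space sensitivity constant of the explicit formulation cancels
here; applying it anyway double-boosts poorly sensed orientations and
diverges, so the `sensitivity_normalization` toggle defaults off (the
explicit-orientation GRL keeps it, where it is required). Dual-view data
alternate one half-update per view per iteration, view A first. Voxels
whose forward-backward density falls below `density_floor × max` are
frozen for that update (the per-voxel system is singular in empty space);
the solves carry a relative ridge of 1e-9·trace/dim; only the density
channel is clamped at zero (full ODF positivity projection is available
as an optional post-step). Products of two l ≤ 4 spectra are truncated
back to l ≤ 4: the system operator has no content beyond it.

The restructured update is ISRA-like — its division sits in back-projected
object space, whereas the explicit-orientation GRL divides in measurement
space before back-projecting. The two share fixed points on consistent
data (the perfect-data fixed point holds to ~1e-7) and both converge
toward the truth with monotonically improving data fit, but their
transients differ at the ~10% level on small phantoms; they are *similar*,
not numerically identical.

**GRL oracle.** Direct explicit-orientation implementation on a sphere
grid (Gauss–Legendre, ≤ 200 orientations) for volumes up to 32³; used as
the brute-force reference. Kernels sampled on the grid are clamped at the
(≤ 1e-6 relative) band-limit ripple to preserve the nonnegativity the
multiplicative update assumes.

**eGRL-p ablation.** Stage 1: per-polarization-channel scalar RL with the
channel's density kernel. Stage 2: voxel-independent angular MLEM with the
spatially integrated kernels a_{p,lm} = Σ_r H_{p,lm}(r) — the same
update algebra with the convolution replaced by a constant matrix. With a
spatially delta PSF the two stages reduce exactly to eGRL (verified).
When the PSF mixes differently oriented structures, the pixel-wise stage
cannot unmix them and the ODFs flatten toward isotropy relative to the
joint solver — the behaviour the ablation exists to demonstrate.

**SVD/Tikhonov baseline.** Per spatial frequency, the modulation × channel
matrix H(ν) is factorized once; the Tikhonov filter s/(s²+η) is applied
for any η without refactorizing, which makes the η grid search (default
10⁻⁸…10⁰, step 10^0.1, PSIM-scored against ground truth, ties to the
smallest η) cheap. Note a physical rank limit: polarized excitation spans
only l ≤ 2 per view, so the per-frequency rank is at most 6 per view (12
dual-view) — the full 15-channel band is never fully determined at any
single frequency, and exact η→0 recovery holds only for l ≤ 2 objects.
The iterative solvers regularize the undetermined subspace implicitly;
the pseudoinverse instead biases peak orientations toward the axis
orthogonal to both optical axes (reproduced in the tests).

## Forward simulation

Convolutions zero-pad by half the kernel support per axis (FFT-friendly
lengths) and crop back; a cyclic (`wrap`) mode exists for exactness checks
and uniform-lake responses, where it is exact. Tiny negative FFT ripple
(≤ 1e-6 of the maximum) is clamped. Poisson noise at a target SNR uses
the closed-form photon scale α = 10^(SNR/10)·mean(S)/mean(S²) (for counts
c ~ Poisson(αS) returned as c/α the expected residual power is mean(S)/α),
then draws one seeded realization; the tests verify the realized SNR to
±0.3 dB at ≥10⁵ voxels. Lake calibration follows the gain-ratio correction
g = raw·(g_cal(p0)/g_cal(p))·(g_lake(p)/g_lake(p0)); bead mimicry scales
non-polarized bead volumes by lake gains.

## Phantoms

Per-voxel ODFs are band-limited deltas: F_lm ∝ Y_lm(axis) for even l with
the l > 0 bands scaled by `gfa_scale`. Truncated deltas ring negative;
the sharp positivity bound per band limit follows from the Legendre sum
1 + t·Σ_{l>0}(2l+1)P_l(cosθ) ≥ 0 (≈ 0.286 at lmax 4) and the default
anisotropy is 75% of it. Geometries: Gaussian-smoothed spherical shells
and vesicles with radial/normal axes; random Gaussian-profile spheres
(seeded; radius 2–6 voxels, central density 500–900, σ = radius/2);
helices with 600 nm coil radius rasterized by 3× supersampling and box
down-sampling, tangential axes from the nearest curve point; the triple
helix (three axis-aligned helices spaced along x); and DNA-like double
helices — two strands on one cylinder whose axial center-to-center gap
(the "inner space", 554 or 478 nm) is set by the phase offset
2π·inner/pitch, with a linear bottom-to-top GFA ramp. Generated fields
carry the analytic axes and structure masks used by the recovery tests.

What the generator does *not* emulate: labeling density statistics,
background/autofluorescence, camera offsets and read noise, refractive
aberrations, or registration error between views. Tests passing on these
phantoms validate the operator algebra and solver behaviour, not
robustness to those real-data effects.

## Analysis

Density is the (0,0) channel. Peak orientation is the per-voxel ODF
argmax over an antipodally symmetric icosphere (642 vertices); principal
orientation maximizes the axial projection Σ|ŝ·ŝ'|f(ŝ') (the plain inner
product vanishes for even ODFs, so the axial form is used). Orientation
maps mask near-flat voxels (GFA < 0.02 or density < 1e-3 of max) and
report representative axes on the z ≥ 0 hemisphere. GFA is
√(1 − F00²/ΣF²). The order parameter is ⟨P₂(ŝ·n̂)⟩ computed from the l=2
band via the addition theorem; the prefactor is fixed by the calibration
anchor that a delta ODF parallel to n̂ scores exactly 1 (isotropic 0,
perpendicular −1/2). SSIM is the global-statistics form by default (a windowed
variant is behind a flag); PSIM averages axial dot products of peak
orientations; ONCC/OSIM compare sampled ODFs (grid recorded with the
value, since both depend on it).

## Pipeline

Large volumes are tiled by exactly-fitting cores with a halo of 10% of
the core per face (clamped at edges), reconstructed per padded chunk and
blended with separable linear ramps that cross-fade over each *shared*
overlap interval — an exact partition of unity by construction. Interior
agreement with the whole-volume reconstruction improves monotonically as
the halo approaches the PSF half-width.

The motion experiment translates the object rigidly per modulation
(frequency-domain sub-voxel shifts; the phantom is embedded with a free
margin so nothing wraps around the periodic grid) using a zero-mean drift
profile — a common offset of the whole sequence is a global translation
that registration removes, not reconstruction bias — with the two views
interleaved in the acquisition order. On the triple-helix phantom the
PSIM loss is ≈ 5% at 260 nm accumulated drift and grows steeply beyond
(≈ 35% just under 1 µm): the phantom's orientation field decorrelates on
the ~250 nm scale, so its tolerance to drift is intrinsically tighter
than that of cellular structures that vary over micrometres.

## Problem sizes and numerics

Benchmarks run at desk scale: 64³ voxels × 12 modulations for the
double-helix density study, 22×22×64 (padded to 30×30×80 for the drift
margin) for the motion study, 33³-voxel kernels at 130 nm pitch, 10
iterations — each study completes in minutes on one CPU core. Kernels and
fields are stored float32; the solver's operator, per-voxel solves and
all acceptance-critical paths accumulate in float64. FFT grids use
`next_fast_len` padded lengths. All randomness flows through explicit
seeds.

## Known limitations

* The angular problem is underdetermined per frequency (rank ≤ 12 of 15
  dual-view); anisotropy is systematically underestimated at practical
  iteration counts, and l = 4 structure is recovered only partially.
* Multiplicative solvers converge slowly near convergence; the default 10
  iterations trade resolution for time as in common practice.
* Spatially varying PSFs, aberrations and view-registration error are out
  of scope; stacks are assumed registered to a common 130 nm grid.
* The preset polarization schemes are documented constructions with the
  stated cardinalities (ψ × tilt products per view), fully overridable;
  they are not instrument-calibrated state tables.
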