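# polardecon

Spatio-angular deconvolution for polarized fluorescence microscopy:
joint reconstruction of the 3D **density** and **orientation** distributions
of fluorophores from polarization-modulated image stacks.

## The problem

Fluorophores are dipoles. How brightly one emits under polarized excitation
p̂ depends on the angle between p̂ and its transition moment ŝ (cos² law),
and the image it casts depends on its orientation relative to the detection
pupil. A polarized microscope therefore measures, for each modulation p̂, a
blurred *joint* projection of where the emitters are and how they are
oriented:

    i_p̂(r) = ∫∫ h_p̂(r − r′, ŝ) f(r′, ŝ) dŝ dr′

where `f(r, ŝ)` is the spatio-angular distribution (per-voxel orientation
distribution functions, ODFs) and `h_p̂` the dipole point-spread function.
Dipole emission is antipodally symmetric and the optics are angularly
band-limited, so every angular object lives in the real even spherical
harmonics with l ≤ 4 — 15 coefficients per voxel. In that representation
the model becomes a multi-channel convolution,
`I_p̂(ν) = Σ_lm H_p̂,lm(ν) F_lm(ν)`, which this package inverts.

## The solver

The primary solver is the **efficient generalized Richardson–Lucy (eGRL)**
iteration, a multiplicative maximum-likelihood scheme restructured to run
entirely in the spatial-frequency × angular-spectrum domain:

    E_{k+1} = E_k ⊙ [ (i ⋄ h_back) ⊘ (E_k ⋆ h ⋄ h_back) ]

with ⋆/⋄ forward/backward projections through a precomputed kernel bank,
and ⊙/⊘ per-voxel band-limited spherical products and quotients (Gaunt
contractions). Dual-view geometries alternate per-view half-updates.
Baselines: the explicit-orientation GRL oracle, a decoupled two-stage
ablation (eGRL-p), plain scalar Richardson–Lucy, and a per-frequency
SVD/Tikhonov pseudoinverse with an η grid search.

Around the solvers: vectorial dipole-PSF models (polarized excitation ×
aplanatic vectorial detection; wide-field, light-sheet and dual-view
geometries), polarization schemes, Poisson noise at a target SNR, lake
calibration, synthetic phantoms (shells, spheres, helices, double helices,
vesicles), ODF analysis maps (density, peak/principal orientation, GFA,
order parameter) and the SSIM/PSIM/ONCC/OSIM quality metrics, plus a
chunk–reconstruct–blend pipeline for large volumes and a CLI.

## Worked example

```python
import numpy as np
import polardecon as pol

# dual-view optics: 1.1 NA detection (view A), 0.67 NA (view B)
cfg_a = pol.OpticalConfig(na_det=1.1, shape=(33, 33, 33), view_axis="z")
cfg_b = pol.OpticalConfig(na_det=0.67, shape=(33, 33, 33), view_axis="x")
scheme = pol.get_scheme("6V")                      # 3 modulations per view
bank = pol.psf_bank(cfg_a, cfg_b, scheme)
bank_a = bank.subset(scheme.view_indices("A"))
bank_b = bank.subset(scheme.view_indices("B"))

# shell phantom with membrane-normal dipoles, simulated acquisition
shell = pol.make_phantom(pol.PhantomSpec("shell", (32, 32, 32),
                                         radius_vox=9.0, density=100.0))
stacks = [pol.add_poisson_noise(pol.forward_project(shell, b), 20.0, seed=v)
          for v, b in enumerate((bank_a, bank_b))]

rec = pol.egrl_reconstruct(stacks, [bank_a, bank_b],
                           pol.ReconConfig(iterations=10))
gt_map = pol.peak_orientation_map(shell)
print("SSIM :", round(pol.ssim(pol.density_map(shell), pol.density_map(rec)), 3))
print("PSIM :", round(pol.psim(pol.peak_orientation_map(rec), gt_map), 3))
print("GFA  :", round(float(np.median(
    pol.gfa_map(rec).values[shell.structure_mask])), 3))
```

prints

```
SSIM : 0.992
PSIM : 0.888
GFA  : 0.289
```

— the density channel closely matches the ground truth (SSIM 0.99 at 20 dB
noise), the reconstructed peak orientations agree with the radial surface
normals (mean axial dot product 0.89 on the icosphere grid), and the shell
voxels come out clearly anisotropic (ground-truth GFA here is 0.63; ten
multiplicative iterations recover part of that anisotropy, and more
iterations sharpen it further).

The same flow is available from the shell:

```sh
polardecon simulate --kind double_helix --shape 64,64,64 --scheme 6V --out run/
polardecon reconstruct --stack run/stack.tif --bank run/bank.tif \
    --method egrl --iters 10 --out run/rec.tif
polardecon analyze --field run/rec.tif --maps density,peak,gfa --out run/maps/
polardecon metrics --gt run/ground_truth.tif --pred run/rec.tif
```

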