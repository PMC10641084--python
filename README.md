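# bpfscope

Joint, gradient-based design of **binary phase filters** (concentric 0/π
rings in a microscope pupil) together with a **deconvolution network**, so
that the two in combination deliver sharp, high-contrast images over an
extended depth of field (EDoF) — without refocusing, and with an element
simple enough to fabricate by single-step photolithography.

## Who this is for

Computational-microscopy researchers and optical engineers who want to

- simulate a wide-field fluorescence microscope with an arbitrary
  ring-structured pupil phase filter,
- co-optimize the ring phases and a restoration network end-to-end on
  synthetic (or their own) training scenes,
- quantify depth-of-field with an SSIM-threshold protocol, and
- export a manufacturable ring table and etch depth for the finished design.

## The model in brief

A planar object `I_T` defocused by `z` is imaged as

    I = I_T ⊗ h(·; Φ, ψ) + η,        ψ = z·NA² / (2 λ n_medium),

where the incoherent PSF is the squared magnitude of the Fourier transform
of the pupil,

    h = |F{ circ(ρ) · exp(iΦ(ρ)) · exp(−i 2π ψ ρ²) }|²,

`ρ` the pupil radius normalized to the cutoff NA/λ, and `η` additive
Gaussian noise (σ = 0.05 on the [0, 1]-normalized image). The filter is a
vector of K ring phases `φ̄`. During training the phases are continuous; a
septic penalty

    P(φ) = φ⁷/7 − 2π²φ⁵/5 + π⁴φ³/3,    P′(φ) = φ²(φ−π)²(φ+π)²

with saddle points at {−π, 0, π} steers them toward binary values. The
joint objective is

    L = RMSE( N(I(φ̄, ψ); W_net), I_T ) + α · ‖P′(φ̄)‖₂ ,

minimized by gradient descent over both `φ̄` and the network weights
`W_net`, with the penalty weight α grown geometrically every epoch so that
the design is binary when training ends. Depth of field is measured as the
axial interval around focus over which the mean SSIM of reconstructed
images stays ≥ 0.900, and is compared against the clear-aperture value

    DoF_clear = n λ / NA² + n e / (M · NA).

The optical stage, its analytic gradients and the encoder–decoder network
are implemented in pure numpy (a small reverse-mode autodiff engine ships
with the package), so the whole pipeline runs on one CPU.

## Worked example

```python
import numpy as np
from bpfscope.config import OpticalConfig
from bpfscope.design import binarize, etch_depth, init_phase, ring_phase_map
from bpfscope.metrics import dof_clear, psf_fwhm
from bpfscope.optics import compute_psf, make_pupil_grid, pupil_function, z_to_psi

cfg = OpticalConfig()          # 0.75 NA, 525 nm, 33.3x, 6.5 um camera pixels
print(f"clear-aperture DoF : {dof_clear(cfg):.2f} um")
print(f"psi at z = 9.96 um : {z_to_psi(9.96, cfg):.3f}")

fine = OpticalConfig(grid_size=256, pupil_diameter_px=64)
grid = make_pupil_grid(fine)
airy = compute_psf(pupil_function(np.zeros_like(grid.rho), grid), 0.0, grid)
print(f"in-focus FWHM      : {psf_fwhm(airy, fine.image_pitch):.3f} um "
      f"(0.51 lambda/NA = {0.51 * cfg.wavelength / cfg.na:.3f} um)")

design = binarize(init_phase("axicon", 16, np.pi).phases)
print(f"binary rings (pi=1): {(design.binary_phases / np.pi).astype(int)}")
print(f"etch depth in N-BK7: {etch_depth(525.0, 1.5157):.0f} nm")
```

prints

```
clear-aperture DoF : 1.19 um
psi at z = 9.96 um : 5.336
in-focus FWHM      : 0.347 um (0.51 lambda/NA = 0.357 um)
binary rings (pi=1): [0 0 0 0 0 0 0 0 1 1 1 1 1 1 1 1]
etch depth in N-BK7: 509 nm
```

i.e. the analytic depth of field of the reference microscope is 1.19 µm, a
defocus of ±9.96 µm corresponds to ψ = ±5.34, the simulated in-focus PSF
width matches the diffraction estimate within 3 %, and a π step in N-BK7
glass at 525 nm requires a 509 nm etch.

A full desk-scale design run (the same one the acceptance suite executes —
16 rings, 64×64 scenes, 300 optimizer steps, a few minutes on one CPU):

```bash
bpfscope make-data --out data --n-train 64 --n-val 8 --n-test 8 --seed 1
bpfscope design --config examples/desk.yaml --scenes data/train --out runs/desk
bpfscope evaluate --checkpoint runs/desk/checkpoint.npz --zmin -8 --zmax 8 \
    --zstep 0.5 --out runs/desk/eval
bpfscope export-mask --checkpoint runs/desk/checkpoint.npz --out runs/desk/mask.json
```

`evaluate` writes per-depth RMSE/SSIM curves (CSV) and a JSON summary with
the SSIM-threshold DoF estimate and its ratio to the clear aperture.

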