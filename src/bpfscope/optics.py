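"""Scalar Fourier-optics forward model.

The pupil is sampled on an N×N grid with a circular aperture of diameter
``pupil_diameter_px``; the radial coordinate ρ is normalized so ρ = 1 on the
aperture edge (the physical cutoff NA/λ). The incoherent PSF at defocus
parameter ψ is

    h(x', y'; ψ) = | F{ circ(ρ) · exp(iΦ(ρ)) · exp(−i 2π ψ ρ²) } |²

with ψ = z · NA² / (2 λ n_medium). Orthonormal FFTs are used throughout so a
phase-only pupil conserves energy exactly (Parseval): the raw PSF sums to the
pupil pixel count for every phase map and every ψ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .config import OpticalConfig

__all__ = [
    "PupilGrid",
    "DefocusSpec",
    "PSFStack",
    "SceneSample",
    "z_to_psi",
    "psi_to_z",
    "make_pupil_grid",
    "pupil_function",
    "compute_psf",
    "forward_image",
    "bin_to_camera",
    "save_psf_stack",
    "load_psf_stack",
]


# ---------------------------------------------------------------------------
# defocus parameter


def z_to_psi(z: float | np.ndarray, cfg: OpticalConfig) -> float | np.ndarray:
    """Convert axial defocus z (µm) to the dimensionless defocus parameter ψ.

    ψ = z · NA² / (2 λ n_medium); linear in z.
    """
    return z * cfg.na**2 / (2.0 * cfg.wavelength * cfg.n_medium)


def psi_to_z(psi: float | np.ndarray, cfg: OpticalConfig) -> float | np.ndarray:
    """Inverse of :func:`z_to_psi`."""
    return psi * 2.0 * cfg.wavelength * cfg.n_medium / cfg.na**2


# ---------------------------------------------------------------------------
# pupil grid


@dataclass
class PupilGrid:
    """Normalized radial coordinate and aperture mask on the FFT grid."""

    rho: np.ndarray
    circ_mask: np.ndarray
    grid_size: int
    pupil_diameter_px: int

    @property
    def mask_count(self) -> int:
        return int(self.circ_mask.sum())


@dataclass
class DefocusSpec:
    """An axial defocus distance together with its defocus parameter."""

    z: float
    psi: float

    @classmethod
    def from_z(cls, z: float, cfg: OpticalConfig) -> "DefocusSpec":
        return cls(z=z, psi=float(z_to_psi(z, cfg)))


def make_pupil_grid(cfg: OpticalConfig) -> PupilGrid:
    """Build the pupil-plane sampling grid.

    The grid center sits at pixel (N//2, N//2), matching ``fftshift``
    conventions, and ρ reaches exactly 1 at radius D/2 from that center.
    """
    cfg.validate()
    n = cfg.grid_size
    d = cfg.pupil_diameter_px
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    rho = np.hypot(yy - c, xx - c) / (d / 2.0)
    circ_mask = (rho <= 1.0).astype(float)
    return PupilGrid(rho=rho, circ_mask=circ_mask, grid_size=n,
                     pupil_diameter_px=d)


def pupil_function(phase_map: np.ndarray, grid: PupilGrid) -> np.ndarray:
    """Phase-only complex pupil P = circ(ρ) · exp(iΦ(ρ)).

    The magnitude is exactly the aperture mask; only the phase carries design
    information.
    """
    phase_map = np.asarray(phase_map, dtype=float)
    if phase_map.shape != grid.rho.shape:
        raise ValueError(
            f"phase map shape {phase_map.shape} != grid shape {grid.rho.shape}"
        )
    return grid.circ_mask * np.exp(1j * phase_map)


def defocus_factor(psi: float, grid: PupilGrid) -> np.ndarray:
    """Quadratic defocus phase term exp(−i 2π ψ ρ²)."""
    return np.exp(-2j * np.pi * psi * grid.rho**2)


def compute_psf(
    pupil: np.ndarray,
    psi: float,
    grid: PupilGrid,
    normalize: bool = True,
) -> np.ndarray:
    """Incoherent PSF |F{P · exp(−i2πψρ²)}|², centered on the grid.

    With ``normalize`` (default) the PSF is scaled to unit total energy, which
    makes image intensity independent of defocus after convolution. Without
    it the total equals the pupil pixel count (orthonormal FFT + phase-only
    pupil).
    """
    q = pupil * defocus_factor(psi, grid)
    amp = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(q), norm="ortho"))
    h = np.abs(amp) ** 2
    if normalize:
        h = h / h.sum()
    return h


# ---------------------------------------------------------------------------
# PSF stacks


@dataclass
class PSFStack:
    """Intensity PSFs over a set of defocus parameters on a known pitch."""

    psi_values: np.ndarray
    psfs: np.ndarray  # (len(psi_values), H, W), each unit energy
    pitch: float      # image-plane pixel size, µm

    def __post_init__(self) -> None:
        self.psi_values = np.asarray(self.psi_values, dtype=float)
        self.psfs = np.asarray(self.psfs, dtype=float)
        if self.psfs.ndim != 3 or len(self.psfs) != len(self.psi_values):
            raise ValueError("psfs must be (n_psi, H, W) aligned to psi_values")

    @classmethod
    def from_design(cls, phase_map, psi_values, grid, pitch) -> "PSFStack":
        pupil = pupil_function(phase_map, grid)
        psfs = np.stack([compute_psf(pupil, p, grid) for p in psi_values])
        return cls(psi_values=np.asarray(psi_values, float), psfs=psfs,
                   pitch=pitch)


@dataclass
class SceneSample:
    """A ground-truth scene with its defocus and simulated measurement."""

    ground_truth: np.ndarray
    z: float
    intermediate: np.ndarray | None = None
    noise_sigma: float = 0.0


# ---------------------------------------------------------------------------
# image formation


def _odd_crop(psf: np.ndarray) -> np.ndarray:
    """Crop an even-sized, center-at-N//2 PSF to odd support, re-normalized.

    Odd support makes 'same'-size convolution alignment unambiguous.
    """
    out = psf
    if out.shape[0] % 2 == 0:
        out = out[1:, :]
    if out.shape[1] % 2 == 0:
        out = out[:, 1:]
    s = out.sum()
    if s > 0:
        out = out / s
    return out


def forward_image(
    ground_truth: np.ndarray,
    psf: np.ndarray,
    sigma: float = 0.05,
    rng: np.random.Generator | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Simulate the intermediate (measured) image.

    The scene is convolved with the PSF using reflective padding, min–max
    normalized to [0, 1], then additive Gaussian noise of standard deviation
    ``sigma`` is applied. The noisy result is *not* clipped; clip on export
    only.
    """
    img = np.asarray(ground_truth, dtype=float)
    kern = _odd_crop(np.asarray(psf, dtype=float))
    if kern.shape[0] > 2 * img.shape[0] + 1 or kern.shape[1] > 2 * img.shape[1] + 1:
        raise ValueError(
            f"psf support {kern.shape} too large for image {img.shape}"
        )
    py, px = kern.shape[0] // 2, kern.shape[1] // 2
    padded = np.pad(img, ((py, py), (px, px)), mode="reflect")
    blurred = fftconvolve(padded, kern, mode="valid")
    if normalize:
        lo, hi = blurred.min(), blurred.max()
        if hi > lo:
            blurred = (blurred - lo) / (hi - lo)
        else:
            blurred = np.zeros_like(blurred)
    if sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        blurred = blurred + rng.normal(0.0, sigma, size=blurred.shape)
    return blurred


# ---------------------------------------------------------------------------
# camera-pitch resampling


def _bin_matrix(n_in: int, pitch_in: float, n_out: int, pitch_out: float) -> np.ndarray:
    """Area-weighted 1-D rebinning matrix (energy conserving).

    Row j holds the fractional overlap of output pixel j with each input
    pixel, with both grids sharing a common center.
    """
    center_in = n_in / 2.0
    center_out = n_out / 2.0
    b = np.zeros((n_out, n_in))
    for j in range(n_out):
        lo = (j - center_out) * pitch_out
        hi = lo + pitch_out
        # overlapping input pixel range
        i0 = int(np.floor(lo / pitch_in + center_in))
        i1 = int(np.ceil(hi / pitch_in + center_in))
        for i in range(max(i0, 0), min(i1, n_in)):
            a = (i - center_in) * pitch_in
            bnd = a + pitch_in
            ov = min(hi, bnd) - max(lo, a)
            if ov > 0:
                b[j, i] = ov / pitch_in
    return b


def bin_to_camera(psf: np.ndarray, cfg: OpticalConfig,
                  n_out: int | None = None) -> np.ndarray:
    """Resample a PSF from the simulation pitch to the camera pitch e/M.

    Area-weighted binning: total energy is conserved to numerical precision.
    """
    pitch_in = cfg.image_pitch
    pitch_out = cfg.camera_pitch
    if n_out is None:
        n_out = int(np.floor(psf.shape[0] * pitch_in / pitch_out))
    b_row = _bin_matrix(psf.shape[0], pitch_in, n_out, pitch_out)
    b_col = _bin_matrix(psf.shape[1], pitch_in, n_out, pitch_out)
    return b_row @ psf @ b_col.T


# ---------------------------------------------------------------------------
# PSF stack I/O (HDF5 with metadata, or multi-page TIFF + JSON sidecar)


def save_psf_stack(stack: PSFStack, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("psfs", data=stack.psfs)
            fh.create_dataset("psi_values", data=stack.psi_values)
            fh.attrs["pitch_um"] = stack.pitch
    else:
        import tifffile

        tifffile.imwrite(path, stack.psfs.astype(np.float32),
                         photometric="minisblack")
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "psi_values": stack.psi_values.tolist(),
                    "pitch_um": stack.pitch,
                    "units": {"pitch": "um", "psi": "dimensionless"},
                },
                fh,
                indent=2,
            )


def load_psf_stack(path: str | Path) -> PSFStack:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as fh:
            return PSFStack(
                psi_values=fh["psi_values"][...],
                psfs=fh["psfs"][...],
                pitch=float(fh.attrs["pitch_um"]),
            )
    import tifffile

    psfs = tifffile.imread(path).astype(float)
    if psfs.ndim == 2:
        psfs = psfs[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    return PSFStack(psi_values=np.asarray(meta["psi_values"], float),
                    psfs=psfs, pitch=float(meta["pitch_um"]))
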