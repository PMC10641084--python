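"""Seeded synthetic scenes and phantoms.

The training corpus the design pipeline expects is a large set of textured
micrographs rich in high-frequency content. The generator here emulates that
statistical structure rather than any particular tissue: a random-phase
texture with a power-law radial power spectrum (default exponent −1.5),
composited with elliptical blobs and curvilinear filaments, min–max
normalized to [0, 1]. Bead fields emulate sub-resolution fluorescent
microspheres (default diameter 0.175 µm) used to probe the PSF.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import OpticalConfig
from .optics import PupilGrid, compute_psf, forward_image, make_pupil_grid, \
    pupil_function, z_to_psi

__all__ = [
    "SceneSpec",
    "BeadFieldSpec",
    "gen_texture_scene",
    "gen_bead_field",
    "gen_multiplane_scene",
    "forward_multiplane",
    "make_dataset",
]


@dataclass
class SceneSpec:
    """Statistical description of a synthetic ground-truth scene."""

    size: int = 64
    spectrum_exponent: float = -1.5
    mix_texture: float = 0.4
    mix_blobs: float = 0.35
    mix_filaments: float = 0.25
    smoothing_px: float = 0.6
    seed: int = 0


@dataclass
class BeadFieldSpec:
    """A field of sub-resolution point emitters at known positions."""

    n_beads: int = 5
    bead_diameter: float = 0.175   # µm, FWHM of the rendered spot
    z_positions: tuple = (0.0,)    # µm
    size: int = 128
    intensity: float = 1.0
    min_separation_factor: float = 3.0  # × PSF FWHM
    seed: int = 0


# ---------------------------------------------------------------------------
# texture scenes


def _power_law_texture(n: int, exponent: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Random-phase field whose radial power spectrum follows f^exponent."""
    white = rng.normal(size=(n, n))
    spec = np.fft.fft2(white)
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0 / n  # avoid div by zero; DC handled below
    envelope = f ** (exponent / 2.0)
    envelope[0, 0] = 0.0
    tex = np.real(np.fft.ifft2(spec * envelope))
    return tex


def _blobs(n: int, rng: np.random.Generator, count: int | None = None) -> np.ndarray:
    """Sum of random anisotropic Gaussian bumps (cell-body-like blobs)."""
    if count is None:
        count = max(3, n // 10)
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    img = np.zeros((n, n))
    for _ in range(count):
        cy, cx = rng.uniform(0, n, 2)
        sy, sx = rng.uniform(n / 40, n / 8, 2)
        angle = rng.uniform(0, np.pi)
        amp = rng.uniform(0.3, 1.0)
        ct, st = np.cos(angle), np.sin(angle)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        img += amp * np.exp(-(u**2 / (2 * sx**2) + v**2 / (2 * sy**2)))
    return img


def _filaments(n: int, rng: np.random.Generator,
               count: int | None = None) -> np.ndarray:
    """Curvilinear structures drawn as smoothed random walks."""
    from scipy.ndimage import gaussian_filter

    if count is None:
        count = max(2, n // 16)
    img = np.zeros((n, n))
    for _ in range(count):
        pos = rng.uniform(0, n, 2)
        heading = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        for _ in range(3 * n):
            iy, ix = int(pos[0]) % n, int(pos[1]) % n
            img[iy, ix] += amp
            heading += rng.normal(0, 0.3)
            pos += np.array([np.sin(heading), np.cos(heading)])
    return gaussian_filter(img, sigma=max(1.0, n / 128))


def gen_texture_scene(spec: SceneSpec) -> np.ndarray:
    """Generate one band-limited textured scene in [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    parts = []

    def norm01(a):
        lo, hi = a.min(), a.max()
        return (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)

    parts.append(spec.mix_texture
                 * norm01(_power_law_texture(n, spec.spectrum_exponent, rng)))
    parts.append(spec.mix_blobs * norm01(_blobs(n, rng)))
    parts.append(spec.mix_filaments * norm01(_filaments(n, rng)))
    out = sum(parts)
    if spec.smoothing_px > 0:
        # acquisition band limit of the emulated corpus: ground truths come
        # from a finite-NA microscope, so pixel-scale detail is suppressed
        from scipy.ndimage import gaussian_filter

        out = gaussian_filter(out, spec.smoothing_px)
    return norm01(out)


# ---------------------------------------------------------------------------
# bead phantoms


def _render_gaussian_spot(img: np.ndarray, y: float, x: float,
                          sigma_px: float, amp: float) -> None:
    n = img.shape[0]
    half = max(3, int(np.ceil(4 * sigma_px)))
    y0, x0 = int(round(y)), int(round(x))
    ys = slice(max(y0 - half, 0), min(y0 + half + 1, n))
    xs = slice(max(x0 - half, 0), min(x0 + half + 1, n))
    yy, xx = np.mgrid[ys, xs].astype(float)
    img[ys, xs] += amp * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma_px**2)
    )


def gen_bead_field(spec: BeadFieldSpec, cfg: OpticalConfig):
    """Render per-z bead planes at sub-pixel positions.

    Returns ``(planes, table)`` where ``planes`` maps z (µm) to an image of
    rendered beads (before imaging through the PSF) and ``table`` is a pandas
    DataFrame of ground-truth bead positions. Beads are Gaussian spots whose
    FWHM equals the physical bead diameter; positions closer than
    ``min_separation_factor`` × the diffraction FWHM are rejected and
    resampled.
    """
    import pandas as pd

    lam_over = 0.51 * cfg.wavelength / cfg.na  # diffraction FWHM, µm
    if spec.bead_diameter >= cfg.wavelength / (2 * cfg.na):
        raise ValueError(
            "bead diameter must stay below λ/(2NA) to act as a PSF probe"
        )
    pitch = cfg.image_pitch
    n = spec.size
    min_sep_px = spec.min_separation_factor * lam_over / pitch
    sigma_px = spec.bead_diameter / (2.0 * np.sqrt(2.0 * np.log(2.0))) / pitch
    rng = np.random.default_rng(spec.seed)

    margin = max(8.0, 4 * sigma_px + 4)
    positions: list[tuple[float, float]] = []
    attempts = 0
    while len(positions) < spec.n_beads:
        attempts += 1
        if attempts > 2000 * spec.n_beads:
            raise ValueError(
                f"cannot place {spec.n_beads} beads with separation "
                f"{min_sep_px:.1f} px in a {n}x{n} field"
            )
        cand = (rng.uniform(margin, n - margin),
                rng.uniform(margin, n - margin))
        if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep_px
               for p in positions):
            positions.append(cand)

    z_assign = [spec.z_positions[i % len(spec.z_positions)]
                for i in range(spec.n_beads)]
    planes = {z: np.zeros((n, n)) for z in spec.z_positions}
    rows = []
    for (y, x), z in zip(positions, z_assign):
        _render_gaussian_spot(planes[z], y, x, sigma_px, spec.intensity)
        rows.append({"y_px": y, "x_px": x, "z_um": z,
                     "y_um": y * pitch, "x_um": x * pitch})
    table = pd.DataFrame(rows)
    return planes, table


# ---------------------------------------------------------------------------
# multi-plane scenes


def gen_multiplane_scene(specs: list[tuple[SceneSpec, float]]):
    """Generate a stack of (scene, z) planes at distinct depths."""
    zs = [z for _, z in specs]
    if len(set(zs)) != len(zs):
        raise ValueError("z values must be distinct")
    return [(gen_texture_scene(s), z) for s, z in specs]


def forward_multiplane(planes: list[tuple[np.ndarray, float]],
                       phase_map: np.ndarray, cfg: OpticalConfig,
                       sigma: float = 0.0,
                       rng: np.random.Generator | None = None,
                       normalize: bool = True) -> np.ndarray:
    """Incoherent sum of per-plane convolutions with each depth's PSF."""
    grid = make_pupil_grid(cfg)
    pupil = pupil_function(phase_map, grid)
    total = None
    for img, z in planes:
        psf = compute_psf(pupil, float(z_to_psi(z, cfg)), grid)
        contrib = forward_image(img, psf, sigma=0.0, normalize=False)
        total = contrib if total is None else total + contrib
    if normalize:
        lo, hi = total.min(), total.max()
        total = (total - lo) / (hi - lo) if hi > lo else np.zeros_like(total)
    if sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        total = total + rng.normal(0.0, sigma, size=total.shape)
    return total


# ---------------------------------------------------------------------------
# dataset materialization


def make_dataset(n_train: int = 22000, n_val: int = 2200, n_test: int = 820,
                 spec: SceneSpec = SceneSpec(), seed: int = 0,
                 out_dir: str | Path = "data",
                 augment_train: bool = True):
    """Write disjoint seeded train/val/test splits as TIFFs plus a manifest.

    Per-image seeds derive deterministically from ``seed``; rotation/flip
    augmentation (recorded in the manifest) applies to the training split
    only. Returns the manifest DataFrame.
    """
    import pandas as pd
    import tifffile

    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split counts must be >= 0")
    out = Path(out_dir)
    rows = []
    master = np.random.default_rng(seed)
    counter = 0
    for split, count in (("train", n_train), ("val", n_val), ("test", n_test)):
        sub = out / split
        sub.mkdir(parents=True, exist_ok=True)
        for _ in range(count):
            img_seed = int(master.integers(2**31))
            s = SceneSpec(size=spec.size,
                          spectrum_exponent=spec.spectrum_exponent,
                          mix_texture=spec.mix_texture,
                          mix_blobs=spec.mix_blobs,
                          mix_filaments=spec.mix_filaments,
                          seed=img_seed)
            img = gen_texture_scene(s)
            aug = "none"
            if split == "train" and augment_train:
                k = int(master.integers(4))
                flip = bool(master.integers(2))
                img = np.rot90(img, k)
                if flip:
                    img = img[:, ::-1]
                aug = f"rot{90 * k}" + ("+flip" if flip else "")
            name = f"{split}_{counter:06d}.tif"
            tifffile.imwrite(sub / name,
                             np.ascontiguousarray(img).astype(np.float32))
            rows.append({"file": f"{split}/{name}", "split": split,
                         "seed": img_seed, "augmentation": aug})
            counter += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
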