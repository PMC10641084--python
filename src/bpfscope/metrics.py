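"""Image metrics and the depth-of-field measurement protocol.

The DoF of a filtered system is operationalized as the axial interval around
focus over which the mean SSIM of reconstructed images stays at or above a
threshold (default 0.900). SSIM here is the global-statistics formula

    SSIM = (2 μ_T μ_Î + C₁)(2 σ_TÎ + C₂) /
           ((μ_T² + μ_Î² + C₁)(σ_T² + σ_Î² + C₂))

with C₁ = 1e−4 and C₂ = 9e−4 — computed from whole-image moments, not a
sliding window (a windowed variant is available behind a flag). The analytic
clear-aperture DoF n·λ/NA² + n·e/(M·NA) serves as the normalizer for
extension ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import EvalConfig, OpticalConfig
from .optics import compute_psf, forward_image, make_pupil_grid, \
    pupil_function, z_to_psi
from .train import rmse_loss

__all__ = [
    "MetricsReport",
    "FitError",
    "ssim",
    "dof_clear",
    "depth_response",
    "estimate_dof",
    "fwhm_fit",
    "psf_fwhm",
    "michelson_contrast",
]


class FitError(RuntimeError):
    """Raised when a profile fit fails to converge."""


def ssim(reference: np.ndarray, estimate: np.ndarray,
         cfg: EvalConfig | None = None, windowed: bool = False) -> float:
    """Structural similarity between two images on a common [0, 1] scale."""
    if cfg is None:
        cfg = EvalConfig()
    a = np.asarray(reference, float)
    b = np.asarray(estimate, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(a, b, data_range=1.0))
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    c1, c2 = cfg.c1, cfg.c2
    return float(
        (2 * mu_a * mu_b + c1) * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


def dof_clear(cfg: OpticalConfig) -> float:
    """Analytic clear-aperture depth of field (µm).

    DoF = n·λ/NA² + n·e/(M·NA): a wave term plus a geometric pixel term.
    """
    return (cfg.n_medium * cfg.wavelength / cfg.na**2
            + cfg.n_medium * cfg.pixel_pitch / (cfg.magnification * cfg.na))


@dataclass
class MetricsReport:
    """Per-depth metric curves and derived DoF summaries."""

    z_grid: np.ndarray
    rmse_mean: np.ndarray
    rmse_sem: np.ndarray
    ssim_mean: np.ndarray
    ssim_sem: np.ndarray
    dof_estimate: float = 0.0
    dof_ratio: float = float("nan")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "z_um": self.z_grid,
            "rmse_mean": self.rmse_mean, "rmse_sem": self.rmse_sem,
            "ssim_mean": self.ssim_mean, "ssim_sem": self.ssim_sem,
        })


def depth_response(
    phase_map: np.ndarray,
    reconstruct,
    scenes: list[np.ndarray],
    optical_cfg: OpticalConfig,
    eval_cfg: EvalConfig,
    noise_sigma: float = 0.05,
    z_grid: np.ndarray | None = None,
) -> MetricsReport:
    """Simulate, reconstruct and score scenes across a defocus grid.

    ``phase_map`` is the per-pixel pupil phase (zeros for a clear aperture);
    ``reconstruct`` maps an intermediate image to a restored image (use
    ``lambda im: im`` for no post-processing). Noise realizations derive
    from ``eval_cfg.seed``. Returns mean and standard error of RMSE/SSIM
    per z, with the SSIM-threshold DoF estimate filled in.
    """
    if not scenes:
        raise ValueError("scene set is empty")
    if z_grid is None:
        z_grid = eval_cfg.z_grid()
    grid = make_pupil_grid(optical_cfg)
    pupil = pupil_function(phase_map, grid)
    rng = np.random.default_rng(eval_cfg.seed)
    n_z, n_s = len(z_grid), len(scenes)
    rmse_all = np.zeros((n_z, n_s))
    ssim_all = np.zeros((n_z, n_s))
    for i, z in enumerate(z_grid):
        psf = compute_psf(pupil, float(z_to_psi(z, optical_cfg)), grid)
        for j, scene in enumerate(scenes):
            inter = forward_image(scene, psf, sigma=noise_sigma, rng=rng)
            restored = reconstruct(inter)
            rmse_all[i, j] = rmse_loss(scene, restored)
            ssim_all[i, j] = ssim(scene, restored, eval_cfg)
    sem = lambda a: a.std(axis=1, ddof=1) / np.sqrt(n_s) if n_s > 1 \
        else np.zeros(n_z)
    report = MetricsReport(
        z_grid=np.asarray(z_grid, float),
        rmse_mean=rmse_all.mean(axis=1), rmse_sem=sem(rmse_all),
        ssim_mean=ssim_all.mean(axis=1), ssim_sem=sem(ssim_all),
    )
    report.dof_estimate = estimate_dof(report.z_grid, report.ssim_mean,
                                       eval_cfg)
    return report


def estimate_dof(z_grid: np.ndarray, ssim_means: np.ndarray,
                 cfg: EvalConfig | None = None,
                 threshold: float | None = None) -> float:
    """SSIM-threshold DoF: length of the maximal contiguous interval around
    z = 0 with mean SSIM ≥ threshold; crossings located by linear
    interpolation between grid samples. Returns 0 when even the in-focus
    SSIM falls below threshold.
    """
    thr = threshold if threshold is not None else (
        cfg.ssim_thr if cfg is not None else 0.900
    )
    z = np.asarray(z_grid, float)
    s = np.asarray(ssim_means, float)
    i0 = int(np.argmin(np.abs(z)))
    if s[i0] < thr:
        return 0.0

    def cross(direction: int) -> float:
        i = i0
        while 0 <= i + direction < len(z) and s[i + direction] >= thr:
            i += direction
        j = i + direction
        if j < 0 or j >= len(z):
            return z[i]  # threshold never crossed within the grid
        # linear interpolation between (z[i], s[i]) and (z[j], s[j])
        frac = (s[i] - thr) / (s[i] - s[j])
        return z[i] + frac * (z[j] - z[i])

    return float(cross(+1) - cross(-1))


def fwhm_fit(profile: np.ndarray, positions: np.ndarray | None = None) -> float:
    """FWHM of a single-peaked profile by least-squares Gaussian fit.

    Fits amplitude·exp(−(x−x₀)²/(2σ²)) + offset and returns 2√(2 ln 2)·σ in
    the units of ``positions`` (pixels when omitted). Non-convergence raises
    :class:`FitError` rather than silently defaulting.
    """
    from scipy.optimize import curve_fit

    y = np.asarray(profile, float)
    x = np.arange(y.size, dtype=float) if positions is None \
        else np.asarray(positions, float)

    def gauss(xx, amp, x0, sigma, off):
        return amp * np.exp(-((xx - x0) ** 2) / (2 * sigma**2)) + off

    peak = int(np.argmax(y))
    amp0 = y[peak] - y.min()
    if amp0 <= 0:
        raise FitError("profile has no peak above baseline")
    # moment-based width start
    w = np.clip(y - y.min(), 0, None)
    sigma0 = np.sqrt(np.sum(w * (x - x[peak]) ** 2) / np.sum(w)) or (x[1] - x[0])
    try:
        popt, _ = curve_fit(gauss, x, y,
                            p0=[amp0, x[peak], sigma0, y.min()],
                            maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    sigma = abs(popt[2])
    return float(2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma)


def psf_fwhm(psf: np.ndarray, pitch: float) -> float:
    """FWHM (µm) of a PSF: Gaussian fits through the peak along both axes,
    averaged."""
    peak = np.unravel_index(np.argmax(psf), psf.shape)
    prof_y = psf[:, peak[1]]
    prof_x = psf[peak[0], :]
    pos_y = np.arange(psf.shape[0]) * pitch
    pos_x = np.arange(psf.shape[1]) * pitch
    return 0.5 * (fwhm_fit(prof_y, pos_y) + fwhm_fit(prof_x, pos_x))


def michelson_contrast(profile: np.ndarray) -> float:
    """(max − min)/(max + min) of a non-negative intensity profile."""
    p = np.asarray(profile, float)
    if np.any(p < 0):
        raise ValueError("profile must be non-negative")
    hi, lo = p.max(), p.min()
    if hi + lo == 0:
        raise ValueError("all-zero profile has undefined contrast")
    return float((hi - lo) / (hi + lo))
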