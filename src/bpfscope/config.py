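"""Configuration objects for the imaging model, training and evaluation.

All lengths are in micrometres unless a field name says otherwise (etch depth
is handled in nanometres by :mod:`bpfscope.design`, mirroring common usage).
Configs are plain dataclasses validated eagerly; :func:`load_config` and
:func:`save_config` round-trip a single YAML document and reject unknown keys
so that typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "OpticalConfig",
    "TrainConfig",
    "EvalConfig",
    "RunConfig",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Raised when a configuration value is missing, unknown or non-physical."""


@dataclass
class OpticalConfig:
    """Physical parameters of the microscope plus the simulation grid.

    Parameters
    ----------
    na : numerical aperture of the objective (dimensionless, > 0).
    wavelength : design / emission wavelength in µm.
    magnification : effective system magnification (objective × relay).
    pixel_pitch : camera pixel size in µm (at the camera, i.e. divide by
        ``magnification`` for the object-plane pitch).
    n_medium : refractive index of the imaging medium (≥ 1).
    grid_size : FFT grid side N in pixels.
    pupil_diameter_px : sampled pupil diameter D within the grid. The
        image-plane sampling pitch is ``wavelength * D / (2 * na * N)``; the
        default ``D = N // 2`` gives λ/(4·NA), twice Nyquist.
    seed : master seed from which every stochastic component derives.
    """

    na: float = 0.75
    wavelength: float = 0.525
    magnification: float = 20.0 * 300.0 / 180.0
    pixel_pitch: float = 6.5
    n_medium: float = 1.0
    grid_size: int = 64
    pupil_diameter_px: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pupil_diameter_px is None:
            self.pupil_diameter_px = self.grid_size // 2
        self.validate()

    def validate(self) -> None:
        if self.na <= 0:
            raise ConfigError(f"na must be > 0 (numerical aperture), got {self.na}")
        if self.wavelength <= 0:
            raise ConfigError(
                f"wavelength must be > 0 µm, got {self.wavelength}"
            )
        if self.magnification <= 0:
            raise ConfigError(
                f"magnification must be > 0, got {self.magnification}"
            )
        if self.pixel_pitch <= 0:
            raise ConfigError(
                f"pixel_pitch must be > 0 µm, got {self.pixel_pitch}"
            )
        if self.n_medium < 1:
            raise ConfigError(
                f"n_medium must be >= 1 (refractive index), got {self.n_medium}"
            )
        if self.grid_size < 8:
            raise ConfigError(f"grid_size must be >= 8 px, got {self.grid_size}")
        if self.pupil_diameter_px > self.grid_size:
            raise ConfigError(
                "pupil_diameter_px must not exceed grid_size "
                f"({self.pupil_diameter_px} > {self.grid_size})"
            )
        if self.pupil_diameter_px < 4:
            raise ConfigError(
                f"pupil_diameter_px must be >= 4 px, got {self.pupil_diameter_px}"
            )

    @property
    def image_pitch(self) -> float:
        """Image-plane sampling pitch δx in µm (object-space units)."""
        return self.wavelength * self.pupil_diameter_px / (
            2.0 * self.na * self.grid_size
        )

    @property
    def camera_pitch(self) -> float:
        """Camera pixel pitch referred to object space, e/M in µm."""
        return self.pixel_pitch / self.magnification

    def nyquist_ok(self) -> bool:
        """True when the PSF-accuracy sampling criterion δx ≤ λ/(4·NA) holds."""
        return self.image_pitch <= self.wavelength / (4.0 * self.na) + 1e-12


@dataclass
class TrainConfig:
    """Hyper-parameters of the joint phase/network optimization.

    ``psi_max`` defaults to the defocus parameter corresponding to half the
    target depth-of-field, i.e. ψ(target_dof_factor · DoF_clear / 2); set it
    explicitly to override. ``finetune_steps`` continues network-only training
    on the binarized design after the annealed joint phase.
    """

    k_rings: int = 64
    target_dof_factor: float = 16.0
    alpha0: float = 1e-6
    alpha_growth: float = 10.0
    epochs: int = 10
    steps_per_epoch: int = 24
    batch_size: int = 4
    learning_rate: float = 2e-3
    phase_learning_rate: float = 2e-2
    noise_sigma: float = 0.05
    psi_max: float | None = None
    net_depth: int = 3
    net_base_channels: int = 16
    finetune_steps: int = 60
    phase_optimizer: str = "adam"
    lr_schedule: str = "cosine"
    ema_decay: float = 0.0
    init_kind: str = "axicon"
    init_param: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.k_rings < 1:
            raise ConfigError(f"k_rings must be >= 1, got {self.k_rings}")
        if self.alpha0 <= 0:
            raise ConfigError(f"alpha0 must be > 0, got {self.alpha0}")
        if self.alpha_growth < 1:
            raise ConfigError(
                f"alpha_growth must be >= 1, got {self.alpha_growth}"
            )
        if self.epochs < 1:
            raise ConfigError(f"epochs must be >= 1, got {self.epochs}")
        if self.psi_max is not None and self.psi_max <= 0:
            raise ConfigError(f"psi_max must be > 0, got {self.psi_max}")
        if self.noise_sigma < 0:
            raise ConfigError(
                f"noise_sigma must be >= 0, got {self.noise_sigma}"
            )
        if self.batch_size < 1:
            raise ConfigError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.phase_optimizer not in ("gd", "adam"):
            raise ConfigError(
                f"phase_optimizer must be 'gd' or 'adam', got {self.phase_optimizer!r}"
            )
        if self.lr_schedule not in ("cosine", "constant"):
            raise ConfigError(
                f"lr_schedule must be 'cosine' or 'constant', got {self.lr_schedule!r}"
            )
        if not 0.0 <= self.ema_decay < 1.0:
            raise ConfigError(
                f"ema_decay must lie in [0, 1), got {self.ema_decay}"
            )


@dataclass
class EvalConfig:
    """Evaluation protocol: SSIM constants, threshold and the defocus grid."""

    ssim_thr: float = 0.900
    c1: float = 1e-4
    c2: float = 9e-4
    z_min: float = -12.0
    z_max: float = 12.0
    z_step: float = 0.1
    dataset_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.ssim_thr < 1:
            raise ConfigError(
                f"ssim_thr must lie in (0, 1), got {self.ssim_thr}"
            )
        if self.z_step <= 0:
            raise ConfigError(f"z_step must be > 0 µm, got {self.z_step}")
        if abs(self.z_min + self.z_max) > 1e-9:
            raise ConfigError(
                "z grid must be symmetric about 0 "
                f"(z_min={self.z_min}, z_max={self.z_max})"
            )
        if self.dataset_size < 1:
            raise ConfigError(
                f"dataset_size must be >= 1, got {self.dataset_size}"
            )

    def z_grid(self):
        import numpy as np

        n = int(round(self.z_max / self.z_step))
        return np.arange(-n, n + 1) * self.z_step


@dataclass
class RunConfig:
    """Everything one run needs: optics + training + evaluation + paths."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    output_dir: str = "runs"
    scene_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        # one top-level seed deterministically drives every module
        self.optics.seed = self.seed
        self.train.seed = self.seed
        self.eval.seed = self.seed


_SECTIONS = {"optics": OpticalConfig, "train": TrainConfig, "eval": EvalConfig}


def _build(cls, data: dict[str, Any], where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{where}'; "
            f"valid keys: {sorted(known)}"
        )
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a RunConfig from a YAML (or JSON) document."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    top_known = {"optics", "train", "eval", "output_dir", "scene_dir", "seed"}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; valid: {sorted(top_known)}"
        )
    kwargs: dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        if section in raw:
            kwargs[section] = _build(cls, raw[section] or {}, section)
    for key in ("output_dir", "scene_dir", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config next to a run's outputs."""
    doc = {
        "optics": dataclasses.asdict(cfg.optics),
        "train": dataclasses.asdict(cfg.train),
        "eval": dataclasses.asdict(cfg.eval),
        "output_dir": cfg.output_dir,
        "scene_dir": cfg.scene_dir,
        "seed": cfg.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
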