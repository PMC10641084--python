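"""Binary-phase-filter parameterization and binarization machinery.

A design is a vector of K ring phases φ̄ on concentric annuli of the unit
pupil. During optimization the phases are continuous in [−π, π]; a septic
penalization polynomial with saddle points at {−π, 0, π},

    P(φ) = φ⁷/7 − 2π²φ⁵/5 + π⁴φ³/3,   P'(φ) = φ²(φ−π)²(φ+π)²,

steers them toward the binary wells, and the feature loss ‖P'(φ̄)‖₂ vanishes
exactly when every ring is binary. The finished filter carries only phases
0 and π and can be fabricated by single-step etching of depth
d = λ₀ / (2(n_substrate − n_air)).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .optics import PupilGrid

__all__ = [
    "PhaseVector",
    "BPFDesign",
    "FabricationSpec",
    "wrap_phase",
    "penalize",
    "penalty_gradient",
    "penalty_curvature",
    "bpf_feature_loss",
    "binarize",
    "init_phase",
    "equal_width_edges",
    "ring_index_map",
    "ring_phase_map",
    "cpm_phase_map",
    "etch_depth",
    "phase_at_wavelength",
    "export_design",
    "load_design",
]


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phases to [−π, π]; values already in range pass through exactly."""
    arr = np.asarray(phi, dtype=float)
    wrapped = np.mod(arr + np.pi, 2.0 * np.pi) - np.pi
    # mod maps odd multiples of +π to −π; keep +π representable
    wrapped = np.where(np.isclose(np.mod(arr - np.pi, 2.0 * np.pi), 0.0)
                       & (arr > 0), np.pi, wrapped)
    out = np.where(np.abs(arr) <= np.pi, arr, wrapped)
    if np.isscalar(phi):
        return float(out)
    return out


@dataclass
class PhaseVector:
    """K continuous ring phases, kept wrapped to [−π, π]."""

    phases: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.atleast_1d(np.asarray(self.phases, dtype=float))
        if self.phases.ndim != 1 or self.phases.size < 1:
            raise ValueError("phases must be a 1-D vector with K >= 1")
        self.phases = np.asarray(wrap_phase(self.phases))

    @property
    def k_rings(self) -> int:
        return self.phases.size


@dataclass
class BPFDesign:
    """A binarized design: ring phases in {0, π} plus the ring geometry."""

    binary_phases: np.ndarray
    ring_edges: np.ndarray
    design_wavelength: float = 0.525  # µm

    def __post_init__(self) -> None:
        self.binary_phases = np.atleast_1d(np.asarray(self.binary_phases, float))
        self.ring_edges = np.asarray(self.ring_edges, dtype=float)
        ok = np.all(np.isclose(self.binary_phases, 0.0)
                    | np.isclose(self.binary_phases, np.pi))
        if not ok:
            raise ValueError("binary_phases must each be exactly 0 or π")
        if self.ring_edges.size != self.binary_phases.size + 1:
            raise ValueError("need K+1 ring edges for K rings")
        if not (np.all(np.diff(self.ring_edges) > 0)
                and np.isclose(self.ring_edges[0], 0.0)
                and np.isclose(self.ring_edges[-1], 1.0)):
            raise ValueError("ring_edges must increase strictly from 0 to 1")

    @property
    def k_rings(self) -> int:
        return self.binary_phases.size

    @property
    def etched_flags(self) -> np.ndarray:
        return np.isclose(self.binary_phases, np.pi)


@dataclass
class FabricationSpec:
    """Physical fabrication parameters for a binarized design."""

    etch_depth_nm: float
    ring_edges_physical_mm: np.ndarray
    etched_flags: np.ndarray
    substrate_index: float
    air_index: float = 1.0
    design_wavelength_nm: float = 525.0


# ---------------------------------------------------------------------------
# penalization machinery


def penalize(phases: PhaseVector | np.ndarray) -> np.ndarray:
    """Septic penalization P(φ) = φ⁷/7 − 2π²φ⁵/5 + π⁴φ³/3 (elementwise)."""
    phi = phases.phases if isinstance(phases, PhaseVector) else np.asarray(phases, float)
    return phi**7 / 7.0 - 2.0 * np.pi**2 * phi**5 / 5.0 + np.pi**4 * phi**3 / 3.0


def penalty_gradient(phases: PhaseVector | np.ndarray) -> np.ndarray:
    """P'(φ) = φ²(φ−π)²(φ+π)²: non-negative, zero exactly at {−π, 0, π}."""
    phi = phases.phases if isinstance(phases, PhaseVector) else np.asarray(phases, float)
    return phi**2 * (phi - np.pi) ** 2 * (phi + np.pi) ** 2


def penalty_curvature(phases: PhaseVector | np.ndarray) -> np.ndarray:
    """P''(φ) = 2φ(φ²−π²)(3φ²−π²), the derivative of :func:`penalty_gradient`."""
    phi = phases.phases if isinstance(phases, PhaseVector) else np.asarray(phases, float)
    return 2.0 * phi * (phi**2 - np.pi**2) * (3.0 * phi**2 - np.pi**2)


def bpf_feature_loss(phases: PhaseVector | np.ndarray) -> float:
    """Euclidean norm of P'(φ̄); zero iff every ring phase is in {−π, 0, π}."""
    return float(np.linalg.norm(penalty_gradient(phases)))


def binarize(phases: PhaseVector | np.ndarray, threshold: float = np.pi / 2,
             ring_edges: np.ndarray | None = None,
             design_wavelength: float = 0.525) -> BPFDesign:
    """Map continuous phases to {0, π}: π where |φ| ≥ threshold, else 0.

    Idempotent on already-binary inputs (|φ| = π maps to π, 0 stays 0).
    """
    if not 0 < threshold < np.pi:
        raise ValueError(f"threshold must lie in (0, π), got {threshold}")
    phi = phases.phases if isinstance(phases, PhaseVector) else np.atleast_1d(np.asarray(phases, float))
    binary = np.where(np.abs(phi) >= threshold, np.pi, 0.0)
    if ring_edges is None:
        ring_edges = equal_width_edges(binary.size)
    return BPFDesign(binary_phases=binary, ring_edges=ring_edges,
                     design_wavelength=design_wavelength)


# ---------------------------------------------------------------------------
# ring geometry and initializers


def equal_width_edges(k: int) -> np.ndarray:
    """Equal radial width edges ρ_k = k/K, k = 0..K."""
    return np.linspace(0.0, 1.0, k + 1)


def ring_centers(edges: np.ndarray) -> np.ndarray:
    return 0.5 * (edges[:-1] + edges[1:])


def init_phase(kind: str, k: int, param: float | np.ndarray | None = None,
               edges: np.ndarray | None = None) -> PhaseVector:
    """Initialize K ring phases.

    kind='axicon'    : φ_k = wrap(a · ρ̄_k), conical profile linear in radius;
                       default slope a = 2π·K/8 (≈ K/8 wrapped cycles).
    kind='spherical' : φ_k = wrap(c · (6ρ̄_k⁴ − 6ρ̄_k² + 1)), the primary
                       spherical-aberration radial profile; default c = 2π.
    kind='zernike'   : param is a coefficient vector over even radial orders
                       (n = 0, 2, 4, ...) of the rotationally symmetric
                       Zernike radial polynomials R_n^0(ρ̄).
    kind='custom'    : param is the K phase values directly.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if edges is None:
        edges = equal_width_edges(k)
    centers = ring_centers(np.asarray(edges, float))
    if kind == "axicon":
        a = 2.0 * np.pi * k / 8.0 if param is None else float(param)
        return PhaseVector(wrap_phase(a * centers))
    if kind == "spherical":
        c = 2.0 * np.pi if param is None else float(param)
        return PhaseVector(wrap_phase(c * (6 * centers**4 - 6 * centers**2 + 1)))
    if kind == "zernike":
        coeffs = np.atleast_1d(np.asarray(param, float))
        phi = np.zeros_like(centers)
        for i, c in enumerate(coeffs):
            phi += c * _zernike_radial(2 * i, centers)
        return PhaseVector(wrap_phase(phi))
    if kind == "custom":
        vals = np.atleast_1d(np.asarray(param, float))
        if vals.size != k:
            raise ValueError(f"custom init needs {k} values, got {vals.size}")
        return PhaseVector(vals)
    raise ValueError(f"unknown init kind {kind!r}")


def _zernike_radial(n: int, rho: np.ndarray) -> np.ndarray:
    """Rotationally symmetric Zernike radial polynomial R_n^0."""
    from math import comb

    out = np.zeros_like(rho)
    for s in range(n // 2 + 1):
        out += ((-1) ** s * comb(n - s, s) * comb(n - 2 * s, n // 2 - s)
                * rho ** (n - 2 * s))
    return out


def ring_index_map(grid: PupilGrid, edges: np.ndarray) -> np.ndarray:
    """Per-pixel ring index (0-based); −1 outside the pupil (ρ ≥ 1).

    Half-open convention: a pixel with ρ exactly on interior edge ρ_k belongs
    to ring k+1 (1-based), i.e. the outer ring.
    """
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, grid.rho, side="right") - 1
    idx = np.clip(idx, 0, edges.size - 2)
    idx[grid.rho >= 1.0] = -1
    # ρ exactly 1 is still inside the aperture; assign to the outermost ring
    idx[np.isclose(grid.rho, 1.0)] = edges.size - 2
    return idx


def ring_phase_map(design: PhaseVector | BPFDesign, grid: PupilGrid,
                   edges: np.ndarray | None = None) -> np.ndarray:
    """Expand ring phases to a per-pixel pupil phase map."""
    if isinstance(design, BPFDesign):
        phases = design.binary_phases
        edges = design.ring_edges
    else:
        phases = design.phases if isinstance(design, PhaseVector) else np.atleast_1d(np.asarray(design, float))
        if edges is None:
            edges = equal_width_edges(phases.size)
    idx = ring_index_map(grid, edges)
    out = np.where(idx >= 0, np.asarray(phases, float)[np.maximum(idx, 0)], 0.0)
    return out


def cpm_phase_map(grid: PupilGrid, strength: float = 20.0 * np.pi) -> np.ndarray:
    """Cubic phase mask α(x³ + y³) on normalized pupil coordinates.

    The classical wavefront-coding baseline; not a binary design.
    """
    n = grid.grid_size
    c = n // 2
    r = grid.pupil_diameter_px / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    x = (xx - c) / r
    y = (yy - c) / r
    return strength * (x**3 + y**3) * grid.circ_mask


# ---------------------------------------------------------------------------
# fabrication


def etch_depth(lambda0_nm: float, n_substrate: float,
               n_air: float = 1.0) -> float:
    """Etch depth (nm) for a π step: d = λ₀ / (2(n_substrate − n_air))."""
    if n_substrate <= n_air:
        raise ValueError(
            f"n_substrate ({n_substrate}) must exceed n_air ({n_air})"
        )
    return lambda0_nm / (2.0 * (n_substrate - n_air))


def phase_at_wavelength(spec: FabricationSpec, lambda_nm: float,
                        n_at_lambda: float | None = None) -> float:
    """Phase step (rad) the etched rings impart at wavelength λ.

    φ(λ) = 2π d (n(λ) − n_air) / λ; equals π at the design wavelength by
    construction. Without a supplied index the design-wavelength substrate
    index is reused (dispersion ignored).
    """
    if lambda_nm <= 0:
        raise ValueError("wavelength must be positive")
    n = spec.substrate_index if n_at_lambda is None else n_at_lambda
    return 2.0 * np.pi * spec.etch_depth_nm * (n - spec.air_index) / lambda_nm


def make_fabrication_spec(design: BPFDesign, pupil_radius_mm: float,
                          n_substrate: float = 1.5157,
                          n_air: float = 1.0) -> FabricationSpec:
    lam_nm = design.design_wavelength * 1e3
    return FabricationSpec(
        etch_depth_nm=etch_depth(lam_nm, n_substrate, n_air),
        ring_edges_physical_mm=design.ring_edges * pupil_radius_mm,
        etched_flags=design.etched_flags,
        substrate_index=n_substrate,
        air_index=n_air,
        design_wavelength_nm=lam_nm,
    )


# ---------------------------------------------------------------------------
# design file I/O


def export_design(design: BPFDesign, path: str | Path,
                  pupil_radius_mm: float = 5.0,
                  n_substrate: float = 1.5157,
                  metadata: dict | None = None) -> FabricationSpec:
    """Write a design as JSON (full spec) plus a CSV ring table.

    The JSON round-trips losslessly through :func:`load_design`; the CSV has
    one data row per ring (index, inner/outer radius in mm, etched flag).
    """
    path = Path(path)
    spec = make_fabrication_spec(design, pupil_radius_mm, n_substrate)
    doc = {
        "format": "bpfscope-design-v1",
        "k_rings": int(design.k_rings),
        "binary_phases_rad": design.binary_phases.tolist(),
        "ring_edges_normalized": design.ring_edges.tolist(),
        "design_wavelength_um": design.design_wavelength,
        "pupil_radius_mm": pupil_radius_mm,
        "etch_depth_nm": spec.etch_depth_nm,
        "substrate_index": n_substrate,
        "units": {
            "binary_phases": "rad",
            "ring_edges": "normalized pupil radius",
            "design_wavelength": "um",
            "etch_depth": "nm",
        },
        "metadata": metadata or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
    csv_path = path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ring", "inner_radius_mm", "outer_radius_mm", "etched"])
        for i in range(design.k_rings):
            writer.writerow([
                i + 1,
                f"{design.ring_edges[i] * pupil_radius_mm:.6f}",
                f"{design.ring_edges[i + 1] * pupil_radius_mm:.6f}",
                int(design.etched_flags[i]),
            ])
    return spec


def load_design(path: str | Path) -> BPFDesign:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "bpfscope-design-v1":
        raise ValueError(f"{path}: not a bpfscope design file")
    return BPFDesign(
        binary_phases=np.asarray(doc["binary_phases_rad"], float),
        ring_edges=np.asarray(doc["ring_edges_normalized"], float),
        design_wavelength=float(doc["design_wavelength_um"]),
    )
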