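"""Joint optimization of ring phases and the deconvolution network.

The end-to-end loss is

    L = RMSE( N(I(φ̄, ψ); W_net), I_T ) + α · L_BPF(φ̄)

with the penalty weight α annealed geometrically across epochs so the ring
phases are driven into the binary wells {−π, 0, π} by the end of training.
Gradients through the reconstruction network come from the autodiff engine;
gradients through the optical stage (ring phases → pupil → PSF →
convolution → min–max normalization) are applied analytically, which keeps
the optical forward model plain numpy. Both are verified against finite
differences in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from . import autodiff as ad
from .autodiff import Tensor
from .config import OpticalConfig, TrainConfig
from .design import (
    BPFDesign,
    PhaseVector,
    binarize,
    bpf_feature_loss,
    equal_width_edges,
    init_phase,
    penalty_curvature,
    penalty_gradient,
    ring_index_map,
    wrap_phase,
)
from .network import (
    NetworkDescriptor,
    NetworkWeights,
    build_network,
    network_forward,
)
from .optics import make_pupil_grid, z_to_psi

__all__ = [
    "TrainingDivergence",
    "TrainHistory",
    "rmse_loss",
    "alpha_schedule",
    "sample_defocus",
    "e2e_loss",
    "train_joint",
    "Adam",
]


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite; carries the offending step."""


def rmse_loss(target: np.ndarray, estimate: np.ndarray) -> float:
    """Root-mean-square error (1/√NP)·‖I_T − Î‖₂ between two images."""
    target = np.asarray(target, float)
    estimate = np.asarray(estimate, float)
    if target.shape != estimate.shape:
        raise ValueError(
            f"shape mismatch: {target.shape} vs {estimate.shape}"
        )
    return float(np.sqrt(np.mean((target - estimate) ** 2)))


def alpha_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Geometric penalty schedule α(epoch) = α₀ · growth^epoch."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.alpha0 * cfg.alpha_growth ** epoch


def sample_defocus(cfg: TrainConfig, rng: np.random.Generator,
                   n: int, psi_max: float | None = None) -> np.ndarray:
    """Draw ψ ~ Uniform[−ψ_max, ψ_max] independently per batch element."""
    pm = psi_max if psi_max is not None else cfg.psi_max
    if pm is None or pm <= 0:
        raise ValueError("psi_max must be set and positive")
    return rng.uniform(-pm, pm, size=n)


# ---------------------------------------------------------------------------
# differentiable optical stage (analytic VJPs)


def _fft_centered(q: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(q), norm="ortho"))


def _fft_centered_adjoint(y: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(y), norm="ortho"))


@dataclass
class _OpticsContext:
    """Cached per-sample intermediates for the optics backward pass."""

    q: np.ndarray
    amp: np.ndarray
    h_crop: np.ndarray
    e_crop: float
    crop: tuple[int, int]
    padded: np.ndarray
    blurred_raw: np.ndarray
    lo: float
    hi: float
    argmin: tuple
    argmax: tuple


def _optics_forward(gt: np.ndarray, theta: np.ndarray, psi: float,
                    mask: np.ndarray, rho2: np.ndarray
                    ) -> tuple[np.ndarray, _OpticsContext]:
    """Scene → normalized blurred image for one sample, caching intermediates."""
    q = mask * np.exp(1j * (theta - 2.0 * np.pi * psi * rho2))
    amp = _fft_centered(q)
    h_raw = np.abs(amp) ** 2
    r0 = 1 if h_raw.shape[0] % 2 == 0 else 0
    c0 = 1 if h_raw.shape[1] % 2 == 0 else 0
    h_crop = h_raw[r0:, c0:]
    e_crop = float(h_crop.sum())
    kern = h_crop / e_crop
    py, px = kern.shape[0] // 2, kern.shape[1] // 2
    padded = np.pad(gt, ((py, py), (px, px)), mode="reflect")
    blurred = fftconvolve(padded, kern, mode="valid")
    lo, hi = float(blurred.min()), float(blurred.max())
    argmin = np.unravel_index(np.argmin(blurred), blurred.shape)
    argmax = np.unravel_index(np.argmax(blurred), blurred.shape)
    if hi > lo:
        out = (blurred - lo) / (hi - lo)
    else:
        out = np.zeros_like(blurred)
    ctx = _OpticsContext(q=q, amp=amp, h_crop=h_crop, e_crop=e_crop,
                         crop=(r0, c0), padded=padded, blurred_raw=blurred,
                         lo=lo, hi=hi, argmin=argmin, argmax=argmax)
    return out, ctx


def _optics_backward(g_out: np.ndarray, ctx: _OpticsContext,
                     ring_idx: np.ndarray, k_rings: int) -> np.ndarray:
    """Propagate dL/d(normalized image) back to dL/dφ̄ for one sample."""
    s = ctx.hi - ctx.lo
    if s <= 0:
        return np.zeros(k_rings)
    g_blur = g_out / s
    blurred = ctx.blurred_raw
    g_lo = float(np.sum(g_out * (blurred - ctx.hi)) / s**2)
    g_hi = float(-np.sum(g_out * (blurred - ctx.lo)) / s**2)
    g_blur = g_blur.copy()
    g_blur[ctx.argmin] += g_lo
    g_blur[ctx.argmax] += g_hi
    # convolution adjoint: dL/dkern = flip(correlate_valid(padded, g_blur))
    corr = fftconvolve(ctx.padded, g_blur[::-1, ::-1], mode="valid")
    g_kern = corr[::-1, ::-1]
    # unit-energy normalization adjoint (quotient rule over the crop support)
    g_hc = g_kern / ctx.e_crop - np.sum(g_kern * ctx.h_crop) / ctx.e_crop**2
    g_hraw = np.zeros(ctx.q.shape)
    r0, c0 = ctx.crop
    g_hraw[r0:, c0:] = g_hc
    # |FFT|² adjoint through the centered orthonormal transform
    gq = _fft_centered_adjoint(g_hraw * ctx.amp)
    g_theta = 2.0 * np.real(np.conj(gq) * 1j * ctx.q)
    valid = ring_idx >= 0
    return np.bincount(ring_idx[valid],
                       weights=g_theta[valid], minlength=k_rings)


# ---------------------------------------------------------------------------
# end-to-end loss


def _mean_per_sample(x: Tensor) -> Tensor:
    """Mean over all but the batch axis; returns a (B,) tensor."""
    axes = tuple(range(1, x.data.ndim))
    n = int(np.prod([x.data.shape[a] for a in axes]))
    out = Tensor(x.data.mean(axis=axes), parents=(x,))

    def backward(g):
        expanded = g.reshape(g.shape + (1,) * len(axes))
        x._accumulate(np.broadcast_to(expanded / n, x.data.shape).copy())

    out._backward = backward
    return out


def e2e_loss(
    phases: PhaseVector | np.ndarray,
    weights: NetworkWeights,
    scenes: list[np.ndarray],
    psis: np.ndarray,
    alpha: float,
    cfg: OpticalConfig,
    noises: list[np.ndarray] | None = None,
    ring_edges: np.ndarray | None = None,
    return_grads: bool = False,
):
    """End-to-end loss L = mean-batch RMSE(N(I), I_T) + α·L_BPF(φ̄).

    With ``return_grads`` also returns (dL/dφ̄, {name: dL/dW}) and a dict of
    the loss components. Noise realizations may be supplied explicitly so the
    loss is a deterministic function of its arguments.
    """
    phi = phases.phases if isinstance(phases, PhaseVector) else np.atleast_1d(np.asarray(phases, float))
    k = phi.size
    if ring_edges is None:
        ring_edges = equal_width_edges(k)
    grid = make_pupil_grid(cfg)
    ring_idx = ring_index_map(grid, ring_edges)
    mask = grid.circ_mask
    rho2 = grid.rho**2
    theta = np.where(ring_idx >= 0, phi[np.maximum(ring_idx, 0)], 0.0)

    contexts = []
    noisy_batch = []
    targets = []
    for i, scene in enumerate(scenes):
        gt = np.asarray(scene, float)
        out, ctx = _optics_forward(gt, theta, float(psis[i]), mask, rho2)
        if noises is not None:
            out = out + noises[i]
        contexts.append(ctx)
        noisy_batch.append(out)
        targets.append(gt)

    dtype = next(iter(weights.params.values())).dtype
    x = Tensor(np.stack(noisy_batch)[:, None].astype(dtype),
               requires_grad=True)
    param_tensors = {k_: Tensor(v, requires_grad=return_grads)
                     for k_, v in weights.params.items()}
    pred = network_forward(x, weights, param_tensors)
    tgt = Tensor(np.stack(targets)[:, None].astype(dtype))
    per_sample_mse = _mean_per_sample((pred - tgt).square())
    loss_rmse = ad.mean(ad.sqrt(per_sample_mse))

    l_bpf = bpf_feature_loss(phi)
    total = loss_rmse.item() + alpha * l_bpf
    if not np.isfinite(total):
        raise TrainingDivergence(
            f"non-finite loss (rmse={loss_rmse.item()}, l_bpf={l_bpf})"
        )
    parts = {"rmse": loss_rmse.item(), "l_bpf": l_bpf, "alpha": alpha}
    if not return_grads:
        return total, parts

    loss_rmse.backward()
    g_phi = np.zeros(k)
    g_x = x.grad.astype(float)
    for i, ctx in enumerate(contexts):
        g_phi += _optics_backward(g_x[i, 0], ctx, ring_idx, k)
    if l_bpf > 0:
        g_phi += alpha * penalty_gradient(phi) * penalty_curvature(phi) / l_bpf
    g_params = {k_: (t.grad if t.grad is not None else np.zeros_like(t.data))
                for k_, t in param_tensors.items()}
    return total, parts, g_phi, g_params


# ---------------------------------------------------------------------------
# optimizer and history


class Adam:
    """Adam for dicts of arrays, with an optional per-step lr multiplier."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict, grads: dict, lr_scale: float = 1.0) -> None:
        self.t += 1
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g, dtype=float)
                self.v[key] = np.zeros_like(g, dtype=float)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g**2
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            params[key] = params[key] - (
                lr_scale * self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(params[key].dtype)


@dataclass
class TrainHistory:
    """Per-step training records."""

    steps: list[int] = field(default_factory=list)
    epoch: list[int] = field(default_factory=list)
    loss_rmse: list[float] = field(default_factory=list)
    loss_bpf: list[float] = field(default_factory=list)
    alpha: list[float] = field(default_factory=list)
    well_distance: list[float] = field(default_factory=list)
    phase: list[str] = field(default_factory=list)

    def record(self, step, epoch, rmse, l_bpf, alpha, phi, phase="joint"):
        self.steps.append(step)
        self.epoch.append(epoch)
        self.loss_rmse.append(rmse)
        self.loss_bpf.append(l_bpf)
        self.alpha.append(alpha)
        self.well_distance.append(mean_well_distance(phi))
        self.phase.append(phase)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "step": self.steps, "epoch": self.epoch,
            "loss_rmse": self.loss_rmse, "loss_bpf": self.loss_bpf,
            "alpha": self.alpha, "well_distance": self.well_distance,
            "phase": self.phase,
        })


def mean_well_distance(phi: np.ndarray) -> float:
    """Mean distance of the ring phases to the nearest well in {−π, 0, π}."""
    wells = np.array([-np.pi, 0.0, np.pi])
    return float(np.mean(np.min(np.abs(
        np.asarray(phi, float)[:, None] - wells[None, :]), axis=1)))


# ---------------------------------------------------------------------------
# the joint loop


def _augment(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    img = np.rot90(img, k=int(rng.integers(4)))
    if rng.integers(2):
        img = img[:, ::-1]
    return np.ascontiguousarray(img)


def train_joint(
    dataset,
    optical_cfg: OpticalConfig,
    cfg: TrainConfig,
) -> tuple[BPFDesign, NetworkWeights, TrainHistory]:
    """Run the annealed joint optimization.

    ``dataset`` is a sequence of ground-truth images in [0, 1] (all the same
    square size, divisible by 2^depth). Returns the binarized design, the
    final network weights (fine-tuned on the binarized filter when
    ``cfg.finetune_steps`` > 0) and the full step-by-step history. Fully
    deterministic under ``cfg.seed``.
    """
    from .metrics import dof_clear

    rng = np.random.default_rng(cfg.seed)
    dataset = [np.asarray(im, float) for im in dataset]
    if not dataset:
        raise ValueError("dataset is empty")

    k = cfg.k_rings
    edges = equal_width_edges(k)
    pv = init_phase(cfg.init_kind, k, cfg.init_param, edges)
    phi = pv.phases.copy()

    psi_max = cfg.psi_max
    if psi_max is None:
        psi_max = float(z_to_psi(
            cfg.target_dof_factor * dof_clear(optical_cfg) / 2.0, optical_cfg
        ))

    desc = NetworkDescriptor(depth=cfg.net_depth,
                             base_channels=cfg.net_base_channels)
    weights = build_network(desc, seed=cfg.seed)

    opt_phi = Adam(cfg.phase_learning_rate) \
        if cfg.phase_optimizer == "adam" else None
    opt_net = Adam(cfg.learning_rate)
    history = TrainHistory()
    step = 0
    total_steps = cfg.epochs * cfg.steps_per_epoch + cfg.finetune_steps

    def net_lr_scale() -> float:
        if cfg.lr_schedule == "constant" or total_steps <= 1:
            return 1.0
        # cosine decay to a 10% floor over the whole run
        frac = step / (total_steps - 1)
        return 0.1 + 0.9 * 0.5 * (1.0 + np.cos(np.pi * frac))

    # Polyak (exponential moving) average of the network parameters; the
    # averaged weights are what the run returns
    ema = ({k: v.copy() for k, v in weights.params.items()}
           if cfg.ema_decay > 0 else None)

    def ema_update() -> None:
        if ema is None:
            return
        d = cfg.ema_decay
        for k, v in weights.params.items():
            ema[k] = (d * ema[k] + (1.0 - d) * v).astype(v.dtype)

    def draw_batch():
        idx = rng.integers(len(dataset), size=cfg.batch_size)
        scenes = [_augment(dataset[i], rng) for i in idx]
        psis = sample_defocus(cfg, rng, cfg.batch_size, psi_max)
        noises = [rng.normal(0.0, cfg.noise_sigma, size=s.shape)
                  if cfg.noise_sigma > 0 else np.zeros_like(s)
                  for s in scenes]
        return scenes, psis, noises

    for epoch in range(cfg.epochs):
        alpha = alpha_schedule(epoch, cfg)
        for _ in range(cfg.steps_per_epoch):
            scenes, psis, noises = draw_batch()
            try:
                _, parts, g_phi, g_params = e2e_loss(
                    phi, weights, scenes, psis, alpha, optical_cfg,
                    noises=noises, ring_edges=edges, return_grads=True,
                )
            except TrainingDivergence as exc:
                raise TrainingDivergence(
                    f"diverged at step {step} (epoch {epoch}): {exc}"
                ) from exc
            if opt_phi is None:
                # plain gradient descent on the ring phases; step capped so a
                # huge late-epoch penalty gradient cannot overshoot the wells
                step_phi = cfg.phase_learning_rate * g_phi
                step_phi = np.clip(step_phi, -0.3, 0.3)
                phi = np.asarray(wrap_phase(phi - step_phi))
            else:
                box = {"phi": phi}
                opt_phi.step(box, {"phi": g_phi})
                phi = np.asarray(wrap_phase(box["phi"]))
            opt_net.step(weights.params, g_params, net_lr_scale())
            ema_update()
            history.record(step, epoch, parts["rmse"], parts["l_bpf"],
                           alpha, phi)
            step += 1

    design = binarize(phi, ring_edges=edges,
                      design_wavelength=optical_cfg.wavelength)

    # network-only fine-tune on the binarized filter
    phi_bin = design.binary_phases
    for _ in range(cfg.finetune_steps):
        scenes, psis, noises = draw_batch()
        _, parts, _, g_params = e2e_loss(
            phi_bin, weights, scenes, psis, 0.0, optical_cfg,
            noises=noises, ring_edges=edges, return_grads=True,
        )
        opt_net.step(weights.params, g_params, net_lr_scale())
        ema_update()
        history.record(step, cfg.epochs, parts["rmse"], parts["l_bpf"],
                       0.0, phi_bin, phase="finetune")
        step += 1

    if ema is not None:
        weights = NetworkWeights(weights.descriptor, ema)
    return design, weights, history
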