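"""Full-frame reconstruction: patch-wise network inference and a classical
Wiener-deconvolution baseline.

Large frames are processed in overlapping tiles (default patch 576 px,
10 % overlap); tile outputs are blended with separable linear feathering
whose weights form a partition of unity, so an identity network returns the
input exactly, seams included. Multichannel images are reconstructed
channel-by-channel with the same single-wavelength-trained network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkWeights, apply_network

__all__ = ["TileLayout", "reconstruct_patch", "reconstruct_tiled",
           "wiener_deconvolve"]


@dataclass
class TileLayout:
    """Tiling of a frame into overlapping square patches."""

    patch_size: int = 576
    overlap: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 0.5:
            raise ValueError(f"overlap must lie in [0, 0.5), got {self.overlap}")

    def origins(self, length: int) -> list[int]:
        """Tile origins along one axis covering [0, length)."""
        p = self.patch_size
        if length <= p:
            return [0]
        stride = max(1, int(round(p * (1.0 - self.overlap))))
        starts = list(range(0, length - p, stride))
        starts.append(length - p)
        return sorted(set(starts))


def reconstruct_patch(image: np.ndarray,
                      weights: NetworkWeights) -> np.ndarray:
    """Run the reconstruction network on one patch (deterministic)."""
    img = np.asarray(image, float)
    return apply_network(img, weights)


def _feather_window(p: int, margin: int) -> np.ndarray:
    """1-D weight with linear ramps of ``margin`` samples at both ends.

    Overlapping tiles placed on a fixed stride give ramps that sum to one
    across a seam (partition of unity).
    """
    w = np.ones(p)
    if margin > 0:
        ramp = (np.arange(margin) + 1.0) / (margin + 1.0)
        w[:margin] = ramp
        w[-margin:] = ramp[::-1]
    return w


def reconstruct_tiled(image: np.ndarray, weights: NetworkWeights,
                      layout: TileLayout | None = None,
                      reconstruct=None) -> np.ndarray:
    """Reconstruct a full frame patch-wise with feathered blending.

    Frames smaller than one patch are reflect-padded up to the patch size and
    cropped back afterwards. ``reconstruct`` overrides the per-patch function
    (defaults to the network).
    """
    if layout is None:
        layout = TileLayout()
    img = np.asarray(image, float)
    if img.ndim == 3:  # channels last: process independently
        return np.stack(
            [reconstruct_tiled(img[..., c], weights, layout, reconstruct)
             for c in range(img.shape[-1])], axis=-1)
    if reconstruct is None:
        reconstruct = lambda patch: reconstruct_patch(patch, weights)

    p = layout.patch_size
    h, w = img.shape
    pad_h = max(0, p - h)
    pad_w = max(0, p - w)
    if pad_h or pad_w:
        img = np.pad(img, ((0, pad_h), (0, pad_w)), mode="reflect")
    hh, ww = img.shape
    margin = int(round(p * layout.overlap))
    win = _feather_window(p, margin)
    window = np.outer(win, win)
    num = np.zeros((hh, ww))
    den = np.zeros((hh, ww))
    rows = layout.origins(hh)
    cols = layout.origins(ww)
    for r in rows:
        for c in cols:
            patch = reconstruct(img[r:r + p, c:c + p])
            num[r:r + p, c:c + p] += window * patch
            den[r:r + p, c:c + p] += window
    # dividing by the accumulated weights turns the feather windows into an
    # exact partition of unity, seams and borders included
    out = num / den
    return out[:h, :w]


def wiener_deconvolve(image: np.ndarray, psf: np.ndarray,
                      nsr: float = 0.0) -> np.ndarray:
    """Frequency-domain Wiener filter H*/(|H|² + nsr).

    The PSF (unit energy, centered on its grid) is embedded at the image
    size; ``nsr`` is the scalar noise-to-signal power ratio (0 gives the
    exact inverse wherever the OTF does not vanish).
    """
    if nsr < 0:
        raise ValueError(f"nsr must be >= 0, got {nsr}")
    img = np.asarray(image, float)
    kern = np.asarray(psf, float)
    h, w = img.shape
    big = np.zeros((h, w))
    kh, kw = kern.shape
    if kh > h or kw > w:
        raise ValueError("psf larger than image")
    # place PSF center at the array origin
    cy, cx = kh // 2, kw // 2
    big[:kh, :kw] = kern
    big = np.roll(big, (-cy, -cx), axis=(0, 1))
    otf = np.fft.fft2(big)
    spec = np.fft.fft2(img)
    denom = np.abs(otf) ** 2 + nsr
    denom = np.where(denom == 0, np.inf, denom)
    est = np.conj(otf) / denom * spec
    return np.real(np.fft.ifft2(est))
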