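"""Guided-filter refinement: feathering a hard mask into a soft one.

The guided filter is a linear-in-guidance edge-preserving filter: within
each window the output is an affine function a*I + b of the guidance
image I, with coefficients chosen by ridge regression of the input p on
I.  Averaging the per-window coefficients yields an O(n) algorithm built
entirely from box means.  Applied to a binary canopy mask with the
multispectral composite as guidance, it produces a grayscale mask whose
boundary follows canopy texture; an adaptive threshold turns it back
into a hard mask when needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_local, threshold_otsu
from skimage.transform import resize


@dataclass
class SoftMask:
    """Grayscale canopy mask in [0, 1] with its filtering provenance."""

    values: np.ndarray
    radius: int
    epsilon: float
    guidance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("soft mask values must lie in [0, 1]")


def box_mean(image: np.ndarray, r: int) -> np.ndarray:
    """Mean over the (2r+1)^2 window, clipped at borders, via integral image.

    Border windows are normalised by their actual pixel count, so a
    constant image maps to itself everywhere.
    """
    image = np.asarray(image, dtype=np.float64)
    if r < 1:
        raise ValueError("radius must be >= 1")
    H, W = image.shape
    if r >= H and r >= W:
        raise ValueError(f"radius {r} exceeds both image dimensions {H}x{W}")
    cs = np.zeros((H + 1, W + 1))
    cs[1:, 1:] = image.cumsum(axis=0).cumsum(axis=1)
    r0 = np.clip(np.arange(H) - r, 0, H)
    r1 = np.clip(np.arange(H) + r + 1, 0, H)
    c0 = np.clip(np.arange(W) - r, 0, W)
    c1 = np.clip(np.arange(W) + r + 1, 0, W)
    S = cs[np.ix_(r1, c1)] - cs[np.ix_(r0, c1)] - cs[np.ix_(r1, c0)] + cs[np.ix_(r0, c0)]
    counts = (r1 - r0)[:, None] * (c1 - c0)[None, :]
    return S / counts


def _guided_filter_single(p: np.ndarray, I: np.ndarray, r: int, epsilon: float) -> np.ndarray:
    mu_I = box_mean(I, r)
    mu_p = box_mean(p, r)
    corr_I = box_mean(I * I, r)
    corr_Ip = box_mean(I * p, r)
    var_I = corr_I - mu_I * mu_I
    cov_Ip = corr_Ip - mu_I * mu_p
    a = cov_Ip / (var_I + epsilon)
    b = mu_p - a * mu_I
    return box_mean(a, r) * I + box_mean(b, r)


def guided_filter(
    p: np.ndarray,
    I: np.ndarray,
    r: int = 8,
    epsilon: float = 1e-3,
    clip: bool = True,
) -> SoftMask:
    """Filter ``p`` guided by ``I`` (single- or multi-channel).

    With a multi-channel guidance each channel is used as an independent
    scalar guide and the outputs averaged.  If the guidance has a larger
    spatial shape than ``p`` (e.g. a high-resolution reference image),
    ``p`` is bilinearly upsampled to match before filtering.  The raw
    filter output is linear in ``p``; ``clip`` snaps it into [0, 1] for
    use as a soft mask.
    """
    p = np.asarray(p, dtype=np.float64)
    I = np.asarray(I, dtype=np.float64)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if I.shape[:2] != p.shape:
        if I.shape[0] >= p.shape[0] and I.shape[1] >= p.shape[1]:
            p = resize(p, I.shape[:2], order=1, anti_aliasing=False)
        else:
            raise ValueError(f"guidance shape {I.shape[:2]} incompatible with input {p.shape}")
    if I.ndim == 2:
        q = _guided_filter_single(p, I, r, epsilon)
        desc = "single-channel"
    elif I.ndim == 3:
        q = np.mean(
            [_guided_filter_single(p, I[:, :, c], r, epsilon) for c in range(I.shape[2])],
            axis=0,
        )
        desc = f"{I.shape[2]}-channel mean"
    else:
        raise ValueError("guidance must be 2-D or 3-D")
    if clip:
        q = np.clip(q, 0.0, 1.0)
    return SoftMask(values=q, radius=r, epsilon=epsilon, guidance=desc)


def guided_filter_raw(p: np.ndarray, I: np.ndarray, r: int = 8, epsilon: float = 1e-3) -> np.ndarray:
    """Unclipped filter output (exactly linear in ``p``)."""
    p = np.asarray(p, dtype=np.float64)
    I = np.asarray(I, dtype=np.float64)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if I.ndim == 2:
        return _guided_filter_single(p, I, r, epsilon)
    return np.mean(
        [_guided_filter_single(p, I[:, :, c], r, epsilon) for c in range(I.shape[2])], axis=0
    )


def adaptive_threshold(
    soft: SoftMask | np.ndarray,
    method: str = "otsu",
    window: int | None = None,
) -> np.ndarray:
    """Binarise a soft mask.

    ``otsu`` (default) picks the global histogram threshold; ``local``
    compares each pixel against a Gaussian-weighted local mean over a
    window of 2r+1 pixels (r from the soft mask's provenance unless
    ``window`` is given).  A constant mask has no threshold: returns
    all-background with a warning.
    """
    values = soft.values if isinstance(soft, SoftMask) else np.asarray(soft, dtype=np.float64)
    if values.min() < 0 or values.max() > 1:
        raise ValueError("soft mask must lie in [0, 1]")
    if np.ptp(values) == 0:
        warnings.warn("constant soft mask: threshold undefined, returning all-background")
        return np.zeros_like(values, dtype=np.uint8)
    if method == "otsu":
        t = threshold_otsu(values)
        return (values > t).astype(np.uint8)
    if method == "local":
        if window is None:
            r = soft.radius if isinstance(soft, SoftMask) else 8
            window = 2 * r + 1
        if window % 2 == 0:
            window += 1
        t = threshold_local(values, block_size=window, method="gaussian")
        return (values > t).astype(np.uint8)
    raise ValueError(f"unknown threshold method {method!r}")
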