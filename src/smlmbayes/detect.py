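"""Spot candidate detection and background estimation.

A candidate is any pixel that is the brightest within an Airy-disk radius of
itself (circular Euclidean neighborhood).  No further pre-selection happens:
every locally brightest spot, signal or noise, is handed to the PSF fitter,
and true/false classification is deferred to the histogram thresholding
stage.

Background is estimated per pixel as the local minimum of the
Gaussian-smoothed frame over a (6 h_f + 1) square, which tracks slow
background structure while ignoring diffraction-limited spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .camera import OpticsDerived, PhotoelectronFrame

__all__ = [
    "SpotCandidate",
    "BackgroundFrame",
    "find_local_maxima",
    "estimate_background",
    "circular_footprint",
]


@dataclass(frozen=True)
class SpotCandidate:
    """A locally brightest pixel and the background estimate under it."""

    i_peak: int
    j_peak: int
    frame_index: int
    peak_value: float
    bg_estimate: float


@dataclass(frozen=True)
class BackgroundFrame:
    """Per-pixel background photoelectron estimate for one frame."""

    values: np.ndarray


def circular_footprint(radius: float) -> np.ndarray:
    """Boolean disk of pixels within Euclidean distance ``radius`` of center."""
    r = int(np.ceil(radius))
    ii, jj = np.mgrid[-r : r + 1, -r : r + 1]
    return (ii * ii + jj * jj) <= radius * radius


def gaussian_kernel(s0_px: float, h_f: int) -> np.ndarray:
    """Truncated 2D Gaussian smoothing kernel, unit sum over its support.

    Support is (2 h_f + 1) square; normalization to unit sum makes the
    smoothing exactly preserve constant frames despite the truncation.
    """
    ii, jj = np.mgrid[-h_f : h_f + 1, -h_f : h_f + 1]
    k = np.exp(-(ii * ii + jj * jj) / (2.0 * s0_px * s0_px))
    return k / k.sum()


def find_local_maxima(frame: PhotoelectronFrame, optics: OpticsDerived,
                      background: BackgroundFrame | None = None) -> list[SpotCandidate]:
    """Find every pixel that is maximal within an Airy radius of itself.

    Plateaus (ties within the neighborhood) yield one candidate per
    8-connected plateau component, the lexicographically smallest (i, j),
    so the result is deterministic.  Candidates closer than ``h_f`` to any
    border are dropped: their fit window would not fit inside the frame.

    If ``background`` is given its value at each peak is recorded on the
    candidate; otherwise ``bg_estimate`` is 0.
    """
    vals = frame.values
    foot = circular_footprint(optics.r_airy_px)
    local_max = vals >= ndimage.maximum_filter(vals, footprint=foot, mode="nearest")

    # Adjacent tied maxima form plateaus of equal value; keep one per component.
    labels, n_lab = ndimage.label(local_max, structure=np.ones((3, 3), dtype=int))
    out: list[SpotCandidate] = []
    h, w = vals.shape
    hf = optics.h_f
    if n_lab == 0:
        return out
    # lexicographically first pixel of each labeled component
    flat_idx = ndimage.minimum_position(
        np.arange(vals.size).reshape(vals.shape), labels=labels,
        index=np.arange(1, n_lab + 1),
    )
    for (i, j) in flat_idx:
        i, j = int(i), int(j)
        if i < hf or j < hf or i >= h - hf or j >= w - hf:
            continue
        bg = float(background.values[i, j]) if background is not None else 0.0
        out.append(SpotCandidate(i_peak=i, j_peak=j, frame_index=frame.frame_index,
                                 peak_value=float(vals[i, j]), bg_estimate=bg))
    return out


def estimate_background(frame: PhotoelectronFrame, optics: OpticsDerived) -> BackgroundFrame:
    """Estimate the per-pixel background of a frame.

    The frame is smoothed with a truncated Gaussian of width ``s0`` (edge
    replication at the borders, so no artificial dark rim), then each pixel's
    background is the minimum of the smoothed image over the (6 h_f + 1)
    square centered on it, clipped at the frame borders.
    """
    kern = gaussian_kernel(optics.s0_px, optics.h_f)
    smoothed = ndimage.convolve(frame.values, kern, mode="nearest")
    size = 6 * optics.h_f + 1
    bg = ndimage.minimum_filter(smoothed, size=size, mode="nearest")
    return BackgroundFrame(values=bg)
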