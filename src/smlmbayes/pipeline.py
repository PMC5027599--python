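"""End-to-end movie analysis: detect, fit, prune, threshold, select.

This is the library-level driver behind the ``analyze`` command.  Per frame
it converts ADU to photoelectrons, estimates the background, fits every
locally brightest spot and suppresses duplicates; the pooled photoelectron
counts of all frames then go through minimum-error thresholding to split
true from false emitters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .camera import CameraOptics, OpticsDerived, derive_optics, to_photoelectrons
from .detect import estimate_background, find_local_maxima
from .fitpsf import EmitterFit, fit_spots, prune_close_spots
from .render import ReliabilityCurve, reliability_curve
from .threshold import (CharacteristicHistogram, ThresholdResult, build_histogram,
                        find_threshold, select_emitters)

__all__ = ["AnalysisResult", "analyze_movie", "analyze_frame", "fits_to_table"]

log = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Everything the movie analysis produces."""

    fits: list[EmitterFit]           # all retained potential emitters
    accepted: list[EmitterFit]
    rejected: list[EmitterFit]
    histogram: CharacteristicHistogram
    threshold: ThresholdResult | None  # None under a manual threshold
    threshold_value: float
    reliability: ReliabilityCurve | None
    cam: CameraOptics
    optics: OpticsDerived
    n_fit_failures: int


def analyze_frame(frame_adu: np.ndarray, cam: CameraOptics, optics: OpticsDerived,
                  frame_index: int = 0) -> tuple[list[EmitterFit], int]:
    """Run detection, background estimation, fitting and pruning on one frame.

    Returns the pruned fits and the number of failed fits (excluded).
    """
    pe = to_photoelectrons(frame_adu, cam, frame_index=frame_index)
    bg = estimate_background(pe, optics)
    cands = find_local_maxima(pe, optics, background=bg)
    fits = fit_spots(pe, cands, optics)
    good = [f for f in fits if f.converged]
    n_fail = len(fits) - len(good)
    pruned = prune_close_spots(good, optics)
    log.info("frame %d: %d candidates, %d fit failures, %d after pruning",
             frame_index, len(cands), n_fail, len(pruned))
    return pruned, n_fail


def analyze_movie(movie: np.ndarray, cam: CameraOptics, *, model: str = "wldm",
                  n_levels: int | None = None,
                  manual_threshold: float | None = None) -> AnalysisResult:
    """Analyze a full ADU movie (frames, H, W) and threshold the results.

    ``manual_threshold`` bypasses the automatic search (a value of 1 keeps
    every positive-count fit; useful for exporting the full table).
    """
    movie = np.asarray(movie)
    if movie.ndim == 2:
        movie = movie[None]
    optics = derive_optics(cam)
    all_fits: list[EmitterFit] = []
    n_fail = 0
    for t in range(movie.shape[0]):
        fits, nf = analyze_frame(movie[t], cam, optics, frame_index=t)
        all_fits.extend(fits)
        n_fail += nf

    n_psf = [f.n_psf for f in all_fits]
    hist = build_histogram(n_psf, n_levels=n_levels)
    result = None
    curve = None
    if manual_threshold is None:
        result = find_threshold(hist, model)
        thr = result.threshold
        curve = reliability_curve(result)
    else:
        thr = float(manual_threshold)
    accepted, rejected = select_emitters(all_fits, result if result is not None else thr)
    log.info("movie: %d potential emitters, threshold %.1f, %d accepted / %d rejected",
             len(all_fits), thr, len(accepted), len(rejected))
    return AnalysisResult(fits=all_fits, accepted=accepted, rejected=rejected,
                          histogram=hist, threshold=result, threshold_value=thr,
                          reliability=curve, cam=cam, optics=optics,
                          n_fit_failures=n_fail)


def fits_to_table(fits: list[EmitterFit], cam: CameraOptics,
                  curve: ReliabilityCurve | None = None) -> pd.DataFrame:
    """Tabulate fits as frame, x_nm, y_nm, n_psf, n_b (+ reliability).

    Coordinates follow the export convention: nm with the origin at the
    outer corner of pixel (0, 0), x along columns.
    """
    p = cam.pixel_size_sample_nm
    df = pd.DataFrame({
        "frame": [f.frame_index for f in fits],
        "x_nm": [(f.x0 + 0.5) * p for f in fits],
        "y_nm": [(f.y0 + 0.5) * p for f in fits],
        "n_psf": [f.n_psf for f in fits],
        "n_b": [f.n_b for f in fits],
    })
    if curve is not None and len(df):
        df["reliability"] = curve.r(df["n_psf"].to_numpy())
    elif curve is not None:
        df["reliability"] = pd.Series(dtype=float)
    return df
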