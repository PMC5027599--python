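"""Emitter reliability and image rendering.

From the fitted false/true densities the expected number of false and true
emitters at a characteristic value x is

    NF(x) = total · P_false · f_false(x | θ0)
    NT(x) = total · P_true  · f_true(x | θ1)

and the reliability of an emitter — its posterior probability of being a
true emitter — is R(x) = NT(x) / (NF(x) + NT(x)).

Rendering: super-resolution images are 2D histograms of the accepted
localizations on a fine grid (optionally smoothed into Gaussian blobs), and
the reliability map holds the max-normalized per-pixel mean reliability of
*all* potential emitters, accepted or not, which makes under-supported
structures visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy import ndimage

from .camera import CameraOptics
from .threshold import ThresholdResult, get_model

__all__ = ["ReliabilityCurve", "RenderedImage", "reliability_curve",
           "render_superres", "render_reliability_map", "positions_nm"]


@dataclass(frozen=True)
class ReliabilityCurve:
    """Reliability R and expected-count curves NF/NT on the raw axis."""

    result: ThresholdResult
    total: int

    def _log_nf_nt(self, raw) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        res = self.result
        g = np.atleast_1d(np.asarray(res.histogram.to_gray(raw), dtype=float))
        model = get_model(res.model_name)
        with np.errstate(divide="ignore", invalid="ignore"):
            lf = model.logpdf_false(g, res.theta_false) + np.log(res.p_false)
            lt = model.logpdf_true(g, res.theta_true) + np.log(res.p_true)
        return g, lf + np.log(self.total), lt + np.log(self.total)

    def nf(self, raw) -> np.ndarray:
        """Expected number of false emitters at characteristic value(s)."""
        return np.exp(self._log_nf_nt(raw)[1])

    def nt(self, raw) -> np.ndarray:
        """Expected number of true emitters at characteristic value(s)."""
        return np.exp(self._log_nf_nt(raw)[2])

    def r(self, raw) -> np.ndarray:
        """Reliability R = NT / (NF + NT), evaluated stably in log space.

        Where both densities underflow to zero the value is taken from the
        side of the fitted-mean midpoint (the density-ratio limit: 1 above
        the crossing, 0 below).
        """
        g, lnf, lnt = self._log_nf_nt(raw)
        with np.errstate(invalid="ignore"):
            out = expit(lnt - lnf)
        bad = ~np.isfinite(lnt - lnf)
        if np.any(bad):
            res = self.result
            model = get_model(res.model_name)
            x = res.histogram.centers_gray
            m0 = float(x[np.argmax(model.logpdf_false(x, res.theta_false))])
            m1 = float(x[np.argmax(model.logpdf_true(x, res.theta_true))])
            mid = 0.5 * (m0 + m1)
            out = np.where(bad, (g > mid).astype(float), out)
        return out

    def __call__(self, raw) -> np.ndarray:
        return self.r(raw)


def reliability_curve(result: ThresholdResult, total: int | None = None) -> ReliabilityCurve:
    """Build the reliability curve from a threshold-search result."""
    if total is None:
        total = result.histogram.total
    return ReliabilityCurve(result=result, total=int(total))


@dataclass(frozen=True)
class RenderedImage:
    """A rendered 2D image with its grid geometry.

    ``origin_nm`` is the (x, y) position of the outer corner of rendered
    pixel (0, 0); rendered pixel (r, c) covers the half-open square
    ``[origin + (c, r)·px, origin + (c+1, r+1)·px)``.
    """

    values: np.ndarray
    render_pixel_nm: float
    origin_nm: tuple[float, float]
    kind: str


def positions_nm(fits, cam: CameraOptics) -> np.ndarray:
    """Fitted (x, y) positions in sample-plane nm, shape (n, 2).

    Pixel i spans [i·p_eff, (i+1)·p_eff) nm, so the nm coordinate of a
    sub-pixel position is (pos_px + 0.5) · p_eff.
    """
    p = cam.pixel_size_sample_nm
    return np.array([[(f.x0 + 0.5) * p, (f.y0 + 0.5) * p] for f in fits], dtype=float).reshape(-1, 2)


def _grid(xy: np.ndarray, render_pixel_nm: float,
          extent_nm: tuple[float, float] | None,
          origin_nm: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    if extent_nm is None:
        if xy.size == 0:
            extent_nm = (render_pixel_nm, render_pixel_nm)
        else:
            extent_nm = (float(xy[:, 0].max()) - origin_nm[0] + render_pixel_nm,
                         float(xy[:, 1].max()) - origin_nm[1] + render_pixel_nm)
    nx = max(int(np.ceil(extent_nm[0] / render_pixel_nm)), 1)
    ny = max(int(np.ceil(extent_nm[1] / render_pixel_nm)), 1)
    xe = origin_nm[0] + np.arange(nx + 1) * render_pixel_nm
    ye = origin_nm[1] + np.arange(ny + 1) * render_pixel_nm
    return xe, ye


def render_superres(fits, cam: CameraOptics, render_pixel_nm: float = 10.0, *,
                    extent_nm: tuple[float, float] | None = None,
                    origin_nm: tuple[float, float] = (0.0, 0.0),
                    blur_sigma_px: float | None = None) -> RenderedImage:
    """Render accepted localizations as a 2D count histogram.

    Bins are half-open ``[lo, hi)``; total intensity equals the number of
    localizations inside the grid.  With ``blur_sigma_px`` set, the count
    image is smoothed into Gaussian blobs of that sigma (in render pixels)
    for visual parity with conventional renderers.
    """
    xy = positions_nm(fits, cam) if not isinstance(fits, np.ndarray) else fits
    if xy.shape[0] == 0:
        import warnings

        warnings.warn("no localizations to render; returning an all-zero image")
    xe, ye = _grid(xy, render_pixel_nm, extent_nm, origin_nm)
    img, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=(ye, xe))
    if blur_sigma_px:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    return RenderedImage(values=img, render_pixel_nm=render_pixel_nm,
                         origin_nm=origin_nm, kind="localization-density")


def render_reliability_map(all_fits, curve: ReliabilityCurve, cam: CameraOptics,
                           render_pixel_nm: float = 10.0, *,
                           extent_nm: tuple[float, float] | None = None,
                           origin_nm: tuple[float, float] = (0.0, 0.0)) -> RenderedImage:
    """Render the max-normalized mean reliability of all potential emitters.

    Every fitted candidate (accepted or rejected) contributes R(n_psf) to
    the rendered pixel it falls in; each pixel holds the mean of its
    contributions, empty pixels are 0, and the map is normalized by its
    maximum.
    """
    xy = positions_nm(all_fits, cam)
    rel = curve.r(np.array([f.n_psf for f in all_fits], dtype=float)) if all_fits else np.empty(0)
    xe, ye = _grid(xy, render_pixel_nm, extent_nm, origin_nm)
    if xy.shape[0]:
        rsum, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=(ye, xe), weights=rel)
        cnt, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=(ye, xe))
    else:
        rsum = np.zeros((len(ye) - 1, len(xe) - 1))
        cnt = np.zeros_like(rsum)
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, rsum / np.maximum(cnt, 1), 0.0)
    peak = mean.max()
    if peak > 0:
        mean = mean / peak
    return RenderedImage(values=mean, render_pixel_nm=render_pixel_nm,
                         origin_nm=origin_nm, kind="reliability")
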