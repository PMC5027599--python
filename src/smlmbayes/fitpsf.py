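"""Fixed-width 2D Gaussian PSF fitting of spot candidates.

The in-focus PSF is modeled as a 2D Gaussian of fixed width ``s0`` on a
constant local background:

    model(x, y) = n_psf / (2 π s0²) · exp(−((x−x0)² + (y−y0)²) / (2 s0²)) + n_b

with free parameters (x0, y0, n_psf, n_b); ``n_psf`` is the integrated
photoelectron count of the spot, the selection characteristic used for
thresholding.  Each candidate is fitted on the (2 h_f + 1) square window
centered on its peak pixel by least squares in two passes: an unweighted
pass, then a refit weighted by the inverse fitted model value (the Poisson
variance of each pixel, floored at one photoelectron), which brings the
position estimate to maximum-likelihood efficiency at low photon counts.
``weighted=False`` gives the plain unweighted fit.

Two fitting entry points are provided: :func:`fit_psf` fits one candidate
with SciPy's Levenberg–Marquardt solver, and :func:`fit_spots` runs a
vectorized Levenberg–Marquardt over all windows of a frame at once (the two
agree to solver tolerance; the batched path is what the movie pipeline
uses, since a movie routinely produces tens of thousands of candidates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .camera import OpticsDerived, PhotoelectronFrame
from .detect import SpotCandidate

__all__ = ["EmitterFit", "initial_guess", "fit_psf", "fit_spots", "prune_close_spots"]

N_PSF_FLOOR = 1.0   # smallest admissible starting integrated count
WEIGHT_FLOOR = 1.0  # variance floor (photoelectrons) for the weighted pass


@dataclass(frozen=True)
class EmitterFit:
    """One fitted spot candidate.

    ``x0`` is the sub-pixel column position and ``y0`` the row position,
    both in camera pixels.  ``converged`` is False for fits that diverged,
    left the window, or ended with non-positive integrated count; such fits
    are excluded from the photoelectron histogram.
    """

    frame_index: int
    x0: float
    y0: float
    n_psf: float
    n_b: float
    converged: bool
    residual_norm: float


def initial_guess(candidate: SpotCandidate, optics: OpticsDerived) -> tuple[float, float, float, float]:
    """Starting values (x0, y0, n_b, n_psf) for the nonlinear fit.

    Position starts at the integer peak pixel, background at the estimated
    background under the peak, and the integrated count at
    ``2 π s0² (peak − n_b)`` — the amplitude-to-integral conversion of the
    Gaussian model — floored at a small positive value.
    """
    n_b = candidate.bg_estimate
    amp = candidate.peak_value - n_b
    n_psf = max(2.0 * np.pi * optics.s0_px ** 2 * amp, N_PSF_FLOOR)
    return float(candidate.j_peak), float(candidate.i_peak), float(n_b), float(n_psf)


def _window(frame: PhotoelectronFrame, candidate: SpotCandidate, h_f: int) -> np.ndarray:
    i, j = candidate.i_peak, candidate.j_peak
    h, w = frame.values.shape
    if i < h_f or j < h_f or i + h_f >= h or j + h_f >= w:
        raise ValueError("fit window extends outside the frame")
    return frame.values[i - h_f : i + h_f + 1, j - h_f : j + h_f + 1]


def _model(p, jj, ii, inv2s2, norm):
    x0, y0, a, b = p
    return a * norm * np.exp(-((jj - x0) ** 2 + (ii - y0) ** 2) * inv2s2) + b


def fit_psf(frame: PhotoelectronFrame, candidate: SpotCandidate, optics: OpticsDerived,
            weighted: bool = True) -> EmitterFit:
    """Fit one candidate with SciPy's Levenberg–Marquardt least squares."""
    h_f = optics.h_f
    s0 = optics.s0_px
    win = _window(frame, candidate, h_f)
    jj, ii = np.meshgrid(
        np.arange(candidate.j_peak - h_f, candidate.j_peak + h_f + 1, dtype=float),
        np.arange(candidate.i_peak - h_f, candidate.i_peak + h_f + 1, dtype=float),
    )
    jj = jj.ravel()
    ii = ii.ravel()
    data = win.ravel()
    inv2s2 = 1.0 / (2.0 * s0 * s0)
    norm = 1.0 / (2.0 * np.pi * s0 * s0)

    def solve(p0, sw):
        def resid(p):
            return sw * (_model(p, jj, ii, inv2s2, norm) - data)

        def jac(p):
            x0, y0, a, b = p
            k = np.exp(-((jj - x0) ** 2 + (ii - y0) ** 2) * inv2s2)
            g = norm * k
            return np.stack([sw * a * g * (jj - x0) / (s0 * s0),
                             sw * a * g * (ii - y0) / (s0 * s0),
                             sw * g, sw], axis=1)

        return least_squares(resid, x0=p0, jac=jac, method="lm",
                             xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=200)

    gx, gy, gb, ga = initial_guess(candidate, optics)
    res = solve([gx, gy, ga, gb], np.ones_like(data))
    if weighted and np.isfinite(res.x).all():
        w = 1.0 / np.maximum(_model(res.x, jj, ii, inv2s2, norm), WEIGHT_FLOOR)
        res = solve(res.x, np.sqrt(w))
    fx, fy, fa, fb = res.x
    inside = (abs(fx - candidate.j_peak) <= h_f) and (abs(fy - candidate.i_peak) <= h_f)
    ok = bool(res.success) and fa > 0 and inside and np.isfinite(res.x).all()
    return EmitterFit(frame_index=candidate.frame_index, x0=float(fx), y0=float(fy),
                      n_psf=float(fa), n_b=float(fb), converged=ok,
                      residual_norm=float(2.0 * res.cost))


def _lm_batch(data, jj, ii, p0, sw, s0, *, xtol, ftol, max_iter):
    """Vectorized Levenberg–Marquardt for the fixed-width Gaussian model.

    ``data``, ``jj``, ``ii``, ``sw`` are (spots, pixels); ``p0`` is
    (spots, 4) ordered (x0, y0, n_psf, n_b).  Damping is per spot; steps
    that do not reduce a spot's weighted cost are rejected and its damping
    increased.  Returns (params, cost, failed) where ``failed`` marks spots
    whose damping diverged.
    """
    inv2s2 = 1.0 / (2.0 * s0 * s0)
    norm = 1.0 / (2.0 * np.pi * s0 * s0)
    m, npix = data.shape
    p = p0.copy()

    def resid(pp):
        kexp = np.exp(-((jj - pp[:, 0:1]) ** 2 + (ii - pp[:, 1:2]) ** 2) * inv2s2)
        return kexp, sw * (pp[:, 2:3] * norm * kexp + pp[:, 3:4] - data)

    kexp, r = resid(p)
    cost = np.einsum("ij,ij->i", r, r)
    lam = np.full(m, 1e-3)
    active = np.ones(m, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        pa = p[idx]
        g = norm * kexp[idx] * sw[idx]
        dx = jj[idx] - pa[:, 0:1]
        dy = ii[idx] - pa[:, 1:2]
        J = np.empty((len(idx), npix, 4))
        J[:, :, 0] = pa[:, 2:3] * g * dx / (s0 * s0)
        J[:, :, 1] = pa[:, 2:3] * g * dy / (s0 * s0)
        J[:, :, 2] = g
        J[:, :, 3] = sw[idx]
        JtJ = np.einsum("spi,spj->sij", J, J)
        Jtr = np.einsum("spi,sp->si", J, r[idx])
        A = JtJ.copy()
        diag = np.maximum(np.abs(np.diagonal(JtJ, axis1=1, axis2=2)), 1e-12)
        A[:, np.arange(4), np.arange(4)] += lam[idx][:, None] * diag
        try:
            step = np.linalg.solve(A, -Jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(A[s], -Jtr[s], rcond=None)[0]
                             for s in range(len(idx))])
        p_new = pa + step
        k_new = np.exp(-((jj[idx] - p_new[:, 0:1]) ** 2 + (ii[idx] - p_new[:, 1:2]) ** 2) * inv2s2)
        r_new = sw[idx] * (p_new[:, 2:3] * norm * k_new + p_new[:, 3:4] - data[idx])
        c_new = np.einsum("ij,ij->i", r_new, r_new)
        improved = c_new <= cost[idx]

        acc = idx[improved]
        p[acc] = p_new[improved]
        kexp[acc] = k_new[improved]
        r[acc] = r_new[improved]
        step_small = np.max(np.abs(step), axis=1) < xtol * (1.0 + np.max(np.abs(pa), axis=1))
        cost_small = (cost[idx] - c_new) < ftol * (1.0 + cost[idx])
        done = improved & (step_small | cost_small)
        cost[acc] = c_new[improved]
        lam[acc] = np.maximum(lam[acc] / 3.0, 1e-12)
        rej = idx[~improved]
        lam[rej] *= 4.0
        active[idx[done]] = False
        active[idx[lam[idx] > 1e10]] = False

    failed = lam > 1e10
    return p, cost, failed


def fit_spots(frame: PhotoelectronFrame, candidates: list[SpotCandidate],
              optics: OpticsDerived, *, weighted: bool = True, xtol: float = 1e-8,
              ftol: float = 1e-8, max_iter: int = 200) -> list[EmitterFit]:
    """Fit all candidates of a frame with a vectorized Levenberg–Marquardt.

    All windows share the same shape and model, so the normal equations of
    every spot are assembled and solved simultaneously.  Results agree with
    :func:`fit_psf` to solver tolerance.
    """
    if not candidates:
        return []
    h_f = optics.h_f
    s0 = optics.s0_px
    m = len(candidates)
    npix = (2 * h_f + 1) ** 2

    off = np.arange(-h_f, h_f + 1, dtype=float)
    djj, dii = np.meshgrid(off, off)
    ipk = np.array([c.i_peak for c in candidates])
    jpk = np.array([c.j_peak for c in candidates])
    jj = jpk[:, None] + djj.ravel()[None, :]
    ii = ipk[:, None] + dii.ravel()[None, :]
    data = np.empty((m, npix))
    p0 = np.empty((m, 4))
    for k, c in enumerate(candidates):
        data[k] = _window(frame, c, h_f).ravel()
        gx, gy, gb, ga = initial_guess(c, optics)
        p0[k] = (gx, gy, ga, gb)

    ones = np.ones_like(data)
    p, cost, failed = _lm_batch(data, jj, ii, p0, ones, s0,
                                xtol=xtol, ftol=ftol, max_iter=max_iter)
    if weighted:
        inv2s2 = 1.0 / (2.0 * s0 * s0)
        norm = 1.0 / (2.0 * np.pi * s0 * s0)
        kexp = np.exp(-((jj - p[:, 0:1]) ** 2 + (ii - p[:, 1:2]) ** 2) * inv2s2)
        mu = p[:, 2:3] * norm * kexp + p[:, 3:4]
        sw = 1.0 / np.sqrt(np.maximum(mu, WEIGHT_FLOOR))
        bad = ~np.isfinite(p).all(axis=1)
        sw[bad] = 1.0
        p2 = np.where(np.isfinite(p).all(axis=1)[:, None], p, p0)
        p, cost, failed2 = _lm_batch(data, jj, ii, p2, sw, s0,
                                     xtol=xtol, ftol=ftol, max_iter=max_iter)
        failed |= failed2

    fits: list[EmitterFit] = []
    for k, c in enumerate(candidates):
        fx, fy, fa, fb = p[k]
        inside = (abs(fx - c.j_peak) <= h_f) and (abs(fy - c.i_peak) <= h_f)
        ok = bool(np.isfinite(p[k]).all() and fa > 0 and inside and not failed[k])
        fits.append(EmitterFit(frame_index=c.frame_index, x0=float(fx), y0=float(fy),
                               n_psf=float(fa), n_b=float(fb), converged=ok,
                               residual_norm=float(cost[k])))
    return fits


def prune_close_spots(fits: list[EmitterFit], optics: OpticsDerived) -> list[EmitterFit]:
    """Suppress fits closer than ``s0`` to a brighter fit (one frame).

    Greedy largest-first suppression on fitted sub-pixel centers: fits are
    visited in descending ``n_psf`` order (ties broken on position for
    determinism) and kept only if no already-kept fit lies within ``s0``
    pixels.  Idempotent; never increases the count.
    """
    if not fits:
        return []
    s0 = optics.s0_px
    order = sorted(range(len(fits)),
                   key=lambda k: (-fits[k].n_psf, fits[k].y0, fits[k].x0))
    kept_xy: list[tuple[float, float]] = []
    kept: list[EmitterFit] = []
    s0sq = s0 * s0
    for k in order:
        f = fits[k]
        if any((f.x0 - x) ** 2 + (f.y0 - y) ** 2 <= s0sq for x, y in kept_xy):
            continue
        kept_xy.append((f.x0, f.y0))
        kept.append(f)
    kept.sort(key=lambda f: (f.frame_index, f.y0, f.x0))
    return kept
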