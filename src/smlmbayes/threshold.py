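"""Unsupervised Bayesian threshold determination on a characteristic histogram.

All fitted candidates — true emitters and noise spots alike — are pooled into
a histogram of a scalar selection characteristic (by default the integrated
photoelectron count ``n_psf``).  Because no pre-selection is applied, the
histogram is bimodal: a large low-count mode of false emitters and a smaller
high-count mode of true emitters.  The optimal cut between them is found by
generalized minimum-error thresholding: for every candidate gray level ``T``
the two sides of the histogram are fitted with a parametric false/true
density pair, and the threshold minimizing the classification-error criterion

    J(T) = − Σ_{i∈{0,1}} Σ_{x∈R_iT} h(x) · [ log P_iT + log f_i(x | θ_iT) ]

is selected, where ``R_0T = {0..T}``, ``R_1T = {T+1..N−1}``, ``P_iT`` is the
histogram mass fraction on side ``i`` and ``f_i`` the side density with
parameters ``θ_iT`` estimated from that side alone.  This is the
Kittler–Illingworth minimum-error construction generalized to arbitrary
density families.

Two density pairs are provided: Gaussian–Gaussian (``ggdm``, the
central-limit default) and Weibull–Lognormal (``wldm``, matching the
right-skewed photon statistics of single-fluorophore emission).  The module
is characteristic-agnostic: any scalar per-emitter quantity with a bimodal
false/true structure can be thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gamma as gamma_fn

from .fitpsf import EmitterFit

__all__ = [
    "CharacteristicHistogram",
    "DistributionModel",
    "GaussianGaussianModel",
    "WeibullLognormalModel",
    "ThresholdResult",
    "build_histogram",
    "gmet_criterion",
    "find_threshold",
    "select_emitters",
    "get_model",
    "InsufficientDataError",
    "NotBimodalError",
]

MIN_VALUES = 10
MIN_SIDE_LEVELS = 5  # nonzero gray levels required on each side of a candidate T


class InsufficientDataError(ValueError):
    """Too few characteristic values to build a meaningful histogram."""


class NotBimodalError(RuntimeError):
    """No valid threshold candidate: the histogram is not separably bimodal."""


@dataclass(frozen=True)
class CharacteristicHistogram:
    """Quantized histogram of a selection characteristic.

    Gray level ``L`` covers raw values in ``[lo + L·width, lo + (L+1)·width)``;
    the gray-axis coordinate of a level is its bin center ``L + 0.5`` (the
    half-level shift also keeps logarithms finite at level 0).
    """

    counts: np.ndarray
    n_levels: int
    lo: float
    width: float
    total: int

    def to_gray(self, raw: np.ndarray | float) -> np.ndarray | float:
        """Map raw characteristic values to continuous gray-axis coordinates."""
        return (np.asarray(raw, dtype=float) - self.lo) / self.width

    def to_raw(self, gray: np.ndarray | float) -> np.ndarray | float:
        """Map continuous gray-axis coordinates back to raw units."""
        return self.lo + np.asarray(gray, dtype=float) * self.width

    @property
    def centers_gray(self) -> np.ndarray:
        return np.arange(self.n_levels, dtype=float) + 0.5

    @property
    def centers_raw(self) -> np.ndarray:
        return self.to_raw(self.centers_gray)


def build_histogram(values, n_levels: int | None = None) -> CharacteristicHistogram:
    """Quantize characteristic values into ``N`` gray levels.

    When ``n_levels`` is not given, ``N = min(ceil(max), count)``: near
    unit-width bins for photoelectron counts, but never more levels than
    contributing spots.  Values below 0 extend the range downwards.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < MIN_VALUES:
        raise InsufficientDataError(f"need at least {MIN_VALUES} values, got {vals.size}")
    vmax = float(vals.max())
    lo = min(0.0, float(vals.min()))
    if n_levels is None:
        n_levels = int(min(np.ceil(vmax), vals.size))
    if n_levels < 2:
        raise InsufficientDataError("histogram needs at least 2 gray levels")
    width = (vmax - lo) / n_levels
    if width <= 0:
        raise InsufficientDataError("characteristic values are all identical")
    levels = np.clip(np.floor((vals - lo) / width).astype(int), 0, n_levels - 1)
    counts = np.bincount(levels, minlength=n_levels).astype(np.int64)
    return CharacteristicHistogram(counts=counts, n_levels=n_levels, lo=lo,
                                   width=width, total=int(vals.size))


# ---------------------------------------------------------------------------
# distribution models


class DistributionModel:
    """A false/true density pair with per-side estimators on the gray axis."""

    name = "abstract"

    def fit_false(self, x: np.ndarray, w: np.ndarray) -> tuple:
        raise NotImplementedError

    def fit_true(self, x: np.ndarray, w: np.ndarray) -> tuple:
        raise NotImplementedError

    def logpdf_false(self, x: np.ndarray, theta: tuple) -> np.ndarray:
        raise NotImplementedError

    def logpdf_true(self, x: np.ndarray, theta: tuple) -> np.ndarray:
        raise NotImplementedError


def _wmean_std(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    s = w.sum()
    mu = float((w * x).sum() / s)
    var = float((w * (x - mu) ** 2).sum() / s)
    return mu, np.sqrt(var)


class GaussianGaussianModel(DistributionModel):
    """Gaussian densities on both sides (moment estimators)."""

    name = "ggdm"

    def _fit(self, x, w):
        mu, sd = _wmean_std(x, w)
        return (mu, sd)

    fit_false = _fit
    fit_true = _fit

    def _logpdf(self, x, theta):
        mu, sd = theta
        return stats.norm.logpdf(x, loc=mu, scale=sd)

    logpdf_false = _logpdf
    logpdf_true = _logpdf


def _weibull_mle(x: np.ndarray, w: np.ndarray, max_iter: int = 50,
                 tol: float = 1e-10) -> tuple[float, float]:
    """Weighted Weibull (shape k, scale lam) fit.

    Newton iteration on the profile-likelihood equation for the shape; if it
    fails to converge the method-of-moments shape is used instead.  Requires
    x > 0 (gray bin centers are ≥ 0.5).
    """
    s = w.sum()
    # work on y = x / max(x): the shape equation is scale-invariant and
    # y**k cannot overflow for large k
    xmax = float(x.max())
    y = x / xmax
    ly = np.log(y)
    mean_ly = float((w * ly).sum() / s)
    mu, sd = _wmean_std(x, w)
    # moment start: k from the coefficient of variation (Justus approximation)
    cv = sd / mu if mu > 0 else 1.0
    k_mom = float(np.clip(cv ** -1.086 if cv > 0 else 1.0, 0.05, 50.0))
    k = k_mom

    converged = False
    for _ in range(max_iter):
        yk = np.power(y, k)
        a = float((w * yk).sum())
        b = float((w * yk * ly).sum())
        c = float((w * yk * ly * ly).sum())
        if a <= 0:
            break
        g = b / a - 1.0 / k - mean_ly
        gp = (c * a - b * b) / (a * a) + 1.0 / (k * k)
        step = g / gp
        k_new = float(np.clip(k - step, 0.05, 50.0))
        if abs(k_new - k) < tol * (1.0 + k):
            k = k_new
            converged = True
            break
        k = k_new
    if converged:
        yk = np.power(y, k)
        lam = xmax * float(((w * yk).sum() / s) ** (1.0 / k))
    else:
        k = k_mom
        lam = mu / float(gamma_fn(1.0 + 1.0 / k))
    return k, lam


class WeibullLognormalModel(DistributionModel):
    """Weibull false side, lognormal true side.

    The false-side Weibull absorbs the sharply right-skewed noise-spot
    counts; the lognormal matches the photon-count statistics of single
    fluorophores.
    """

    name = "wldm"

    def fit_false(self, x, w):
        return _weibull_mle(x, w)

    def fit_true(self, x, w):
        mu, sd = _wmean_std(np.log(x), w)
        return (mu, sd)

    def logpdf_false(self, x, theta):
        k, lam = theta
        return stats.weibull_min.logpdf(x, k, scale=lam)

    def logpdf_true(self, x, theta):
        mu, sd = theta
        return stats.lognorm.logpdf(x, sd, scale=np.exp(mu))


_MODELS = {"ggdm": GaussianGaussianModel, "wldm": WeibullLognormalModel}


def get_model(name: str) -> DistributionModel:
    try:
        return _MODELS[name.lower()]()
    except KeyError:
        raise ValueError(f"unknown distribution model {name!r}; choose from {sorted(_MODELS)}")


# ---------------------------------------------------------------------------
# criterion and threshold search


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the minimum-error threshold search."""

    threshold: float           # raw characteristic units, half-level convention
    t_star: int                # optimal gray level
    theta_false: tuple
    theta_true: tuple
    p_false: float
    p_true: float
    criterion_trace: np.ndarray  # J(T) per gray level, NaN where invalid
    model_name: str
    histogram: CharacteristicHistogram


def gmet_criterion(hist: CharacteristicHistogram, t: int, model: DistributionModel):
    """Evaluate the minimum-error criterion ``J(T)`` at one gray level.

    Returns ``(J, theta_false, theta_true, p_false, p_true)``, or ``None`` if
    the candidate is invalid (a side with fewer than 5 populated levels or
    zero variance).  Empty gray levels contribute nothing (0·log ≡ 0).
    """
    counts = hist.counts
    n = hist.n_levels
    if not (0 <= t < n - 1):
        return None
    x = hist.centers_gray
    w0 = counts[: t + 1].astype(float)
    w1 = counts[t + 1 :].astype(float)
    x0 = x[: t + 1]
    x1 = x[t + 1 :]
    nz0 = w0 > 0
    nz1 = w1 > 0
    if nz0.sum() < MIN_SIDE_LEVELS or nz1.sum() < MIN_SIDE_LEVELS:
        return None
    x0, w0 = x0[nz0], w0[nz0]
    x1, w1 = x1[nz1], w1[nz1]
    if _wmean_std(x0, w0)[1] <= 0 or _wmean_std(x1, w1)[1] <= 0:
        return None
    m0 = w0.sum()
    m1 = w1.sum()
    p0 = m0 / hist.total
    p1 = m1 / hist.total
    theta0 = model.fit_false(x0, w0)
    theta1 = model.fit_true(x1, w1)
    lp0 = model.logpdf_false(x0, theta0)
    lp1 = model.logpdf_true(x1, theta1)
    if not (np.all(np.isfinite(lp0)) and np.all(np.isfinite(lp1))):
        return None
    j = -((w0 * (np.log(p0) + lp0)).sum() + (w1 * (np.log(p1) + lp1)).sum())
    return float(j), theta0, theta1, float(p0), float(p1)


def find_threshold(hist: CharacteristicHistogram, model: DistributionModel | str) -> ThresholdResult:
    """Exhaustively minimize ``J(T)`` over all valid gray levels.

    The returned raw-unit threshold uses the half-level convention
    ``lo + (T* + 0.5)·width`` so that "characteristic ≥ threshold" selection
    is unambiguous (for unit-width photoelectron bins this is the familiar
    xxx.5 form).

    Raises
    ------
    NotBimodalError
        If no gray level admits a valid two-sided fit — the histogram does
        not separate into two distinguishable groups.
    """
    if isinstance(model, str):
        model = get_model(model)
    n = hist.n_levels
    trace = np.full(n, np.nan)
    results = {}
    for t in range(n - 1):
        out = gmet_criterion(hist, t, model)
        if out is None:
            continue
        trace[t] = out[0]
        results[t] = out
    if not results:
        raise NotBimodalError(
            "no valid threshold candidate: false/true groups are not "
            "distinguishable in this histogram (need >= "
            f"{MIN_SIDE_LEVELS} populated levels with spread on each side)"
        )
    jmin = np.nanmin(trace)
    first = int(np.nanargmin(trace))
    # Empty gray levels between the modes leave J(T) exactly flat: every cut
    # through the gap classifies the observed data identically.  Break the
    # tie inside the contiguous argmin plateau at the Bayes crossing of the
    # fitted component densities (fallback: plateau midpoint).
    t_hi = first
    while t_hi + 1 in results and np.isclose(trace[t_hi + 1], jmin, rtol=1e-12, atol=0.0):
        t_hi += 1
    t_star = first
    if t_hi > first:
        t_star = _plateau_tie_break(results[first], model, first, t_hi)
    j, theta0, theta1, p0, p1 = results[t_star]
    return ThresholdResult(threshold=float(hist.to_raw(t_star + 0.5)), t_star=t_star,
                           theta_false=theta0, theta_true=theta1, p_false=p0, p_true=p1,
                           criterion_trace=trace, model_name=model.name, histogram=hist)


def _plateau_tie_break(out, model: DistributionModel, t_lo: int, t_hi: int) -> int:
    """Pick the plateau level closest to the fitted-model Bayes crossing."""
    from scipy.optimize import brentq

    _, theta0, theta1, p0, p1 = out

    def g(x):
        xa = np.array([x])
        return float(np.log(p0) + model.logpdf_false(xa, theta0)[0]
                     - np.log(p1) - model.logpdf_true(xa, theta1)[0])

    lo, hi = t_lo + 0.5, t_hi + 1.5
    mid = (t_lo + t_hi) // 2
    try:
        if g(lo) > 0 and g(hi) < 0:
            crossing = brentq(g, lo, hi)
            return int(np.clip(round(crossing - 0.5), t_lo, t_hi))
    except (ValueError, FloatingPointError):
        pass
    return mid


def select_emitters(fits: list[EmitterFit], threshold: "ThresholdResult | float") -> tuple[list[EmitterFit], list[EmitterFit]]:
    """Partition fits into (accepted, rejected) by ``n_psf ≥ threshold``.

    ``threshold`` may be a :class:`ThresholdResult` or a manual raw-unit
    value (a manual threshold of 1 keeps every positive-count fit, which is
    how the full table for reliability mapping is exported).
    """
    thr = threshold.threshold if isinstance(threshold, ThresholdResult) else float(threshold)
    accepted = [f for f in fits if f.n_psf >= thr]
    rejected = [f for f in fits if f.n_psf < thr]
    return accepted, rejected
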