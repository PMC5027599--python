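import numpy as np
import pytest

import smlmbayes as sb
from smlmbayes.detect import SpotCandidate
from smlmbayes.fitpsf import (EmitterFit, fit_psf, fit_spots, initial_guess,
                              prune_close_spots)

from conftest import make_spot_frame


def cand(i, j, peak, bg=0.0):
    return SpotCandidate(i_peak=i, j_peak=j, frame_index=0, peak_value=peak, bg_estimate=bg)


def test_initial_guess_amplitude_to_integral(optics):
    # peak 10 above background: n_psf = 2*pi*s0^2*10
    x0, y0, n_b, n_psf = initial_guess(cand(7, 12, 15.0, bg=5.0), optics)
    assert (x0, y0, n_b) == (12.0, 7.0, 5.0)
    assert n_psf == pytest.approx(2 * np.pi * optics.s0_px ** 2 * 10, rel=1e-12)
    assert n_psf == pytest.approx(114.3, abs=0.2)


def test_initial_guess_floors_zero_amplitude(optics):
    assert initial_guess(cand(5, 5, 4.0, bg=4.0), optics)[3] == 1.0
    assert initial_guess(cand(5, 5, 1.0, bg=4.0), optics)[3] == 1.0


@pytest.mark.parametrize("fitter", ["single", "batch"])
def test_noiseless_model_spot_recovered_exactly(optics, rng, fitter):
    for _ in range(10):
        x0 = 10 + rng.uniform(-0.5, 0.5)
        y0 = 8 + rng.uniform(-0.5, 0.5)
        n_psf = rng.uniform(100, 3000)
        n_b = rng.uniform(0, 20)
        frame = make_spot_frame(optics, (21, 21), x0, y0, n_psf, n_b)
        c = cand(8, 10, frame.values[8, 10], bg=n_b)
        if fitter == "single":
            f = fit_psf(frame, c, optics)
        else:
            f = fit_spots(frame, [c], optics)[0]
        assert f.converged
        assert f.x0 == pytest.approx(x0, abs=1e-6)
        assert f.y0 == pytest.approx(y0, abs=1e-6)
        assert f.n_psf == pytest.approx(n_psf, rel=1e-6)
        assert f.n_b == pytest.approx(n_b, abs=1e-6)


def test_batch_fitter_matches_scipy_fitter_on_noisy_spots(optics, rng):
    frames, cands = [], []
    for _ in range(25):
        x0 = 10 + rng.uniform(-0.5, 0.5)
        y0 = 10 + rng.uniform(-0.5, 0.5)
        frame = make_spot_frame(optics, (21, 21), x0, y0, rng.uniform(400, 2000), 10.0)
        noisy = sb.PhotoelectronFrame(rng.poisson(frame.values).astype(float), 0)
        frames.append(noisy)
        cands.append(cand(10, 10, noisy.values[10, 10], bg=10.0))
    for frame, c in zip(frames, cands):
        f1 = fit_psf(frame, c, optics)
        f2 = fit_spots(frame, [c], optics)[0]
        assert f1.converged and f2.converged
        assert f2.x0 == pytest.approx(f1.x0, abs=5e-4)
        assert f2.y0 == pytest.approx(f1.y0, abs=5e-4)
        assert f2.n_psf == pytest.approx(f1.n_psf, rel=5e-3)


def test_flat_window_is_not_retained(optics):
    frame = sb.PhotoelectronFrame(np.full((21, 21), 5.0), 0)
    f = fit_spots(frame, [cand(10, 10, 5.0, bg=5.0)], optics)[0]
    assert (not f.converged) or f.n_psf < 2.0


def test_out_of_bounds_window_raises(optics):
    frame = sb.PhotoelectronFrame(np.zeros((10, 10)), 0)
    with pytest.raises(ValueError):
        fit_psf(frame, cand(1, 1, 1.0), optics)


def test_fit_is_translation_equivariant(optics):
    base = make_spot_frame(optics, (31, 31), 10.3, 9.6, 800.0, 6.0)
    f1 = fit_spots(base, [cand(10, 10, base.values[10, 10], 6.0)], optics)[0]
    shifted = sb.PhotoelectronFrame(np.roll(base.values, (5, 7), axis=(0, 1)), 0)
    f2 = fit_spots(shifted, [cand(15, 17, shifted.values[15, 17], 6.0)], optics)[0]
    assert f2.x0 - f1.x0 == pytest.approx(7.0, abs=1e-8)
    assert f2.y0 - f1.y0 == pytest.approx(5.0, abs=1e-8)


def fitlike(x0, y0, n_psf):
    return EmitterFit(frame_index=0, x0=x0, y0=y0, n_psf=n_psf, n_b=0.0,
                      converged=True, residual_norm=0.0)


def brute_force_suppression(fits, s0):
    order = sorted(range(len(fits)), key=lambda k: (-fits[k].n_psf, fits[k].y0, fits[k].x0))
    kept = []
    for k in order:
        f = fits[k]
        if all((f.x0 - g.x0) ** 2 + (f.y0 - g.y0) ** 2 > s0 * s0 for g in kept):
            kept.append(f)
    return {id(f) for f in kept}


def test_prune_keeps_brightest_of_close_pair(optics):
    s0 = optics.s0_px
    a, b = fitlike(10.0, 10.0, 900.0), fitlike(10.0 + 0.5 * s0, 10.0, 700.0)
    kept = prune_close_spots([a, b], optics)
    assert kept == [a]


def test_prune_keeps_distant_pair(optics):
    s0 = optics.s0_px
    a, b = fitlike(10.0, 10.0, 900.0), fitlike(10.0 + 3 * s0, 10.0, 700.0)
    assert len(prune_close_spots([a, b], optics)) == 2


def test_prune_matches_brute_force_and_is_idempotent(optics, rng):
    for _ in range(20):
        fits = [fitlike(rng.uniform(0, 12), rng.uniform(0, 12), rng.uniform(10, 1000))
                for _ in range(rng.integers(2, 50))]
        kept = prune_close_spots(fits, optics)
        assert {id(f) for f in kept} == brute_force_suppression(fits, optics.s0_px)
        assert len(kept) <= len(fits)
        again = prune_close_spots(kept, optics)
        assert {id(f) for f in again} == {id(f) for f in kept}
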