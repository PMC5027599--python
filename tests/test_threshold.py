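import numpy as np
import pytest
from scipy import stats

import smlmbayes as sb
from smlmbayes.fitpsf import EmitterFit
from smlmbayes.threshold import (CharacteristicHistogram, InsufficientDataError,
                                 NotBimodalError, build_histogram, find_threshold,
                                 get_model, gmet_criterion, select_emitters)


def test_default_level_count_is_capped_by_value_count():
    h = build_histogram([1.2, 2.7, 3.1] * 4)  # 12 values, max 3.1
    assert h.n_levels == 4  # min(ceil(3.1)=4, 12)
    h2 = build_histogram(list(np.linspace(1, 500.2, 1000)))
    assert h2.n_levels == 501


def test_histogram_counts_are_conserved(rng):
    vals = rng.lognormal(5.0, 0.6, size=2000)
    h = build_histogram(vals)
    assert h.counts.sum() == h.total == 2000


def test_histogram_requires_enough_values():
    with pytest.raises(InsufficientDataError):
        build_histogram([1.0, 2.0, 3.0])


def test_bin_map_round_trip(rng):
    h = build_histogram(rng.uniform(0, 300, size=500), n_levels=128)
    g = h.to_gray([10.0, 150.0])
    assert np.allclose(h.to_raw(g), [10.0, 150.0])


def two_cluster_histogram():
    counts = np.zeros(101, dtype=int)
    counts[8:13] = 40   # false cluster around level 10, mass 200
    counts[88:93] = 40  # true cluster around level 90, mass 200
    return CharacteristicHistogram(counts=counts, n_levels=101, lo=0.0, width=1.0,
                                   total=int(counts.sum()))


def test_equal_mass_sides_give_half_priors():
    h = two_cluster_histogram()
    out = gmet_criterion(h, 50, get_model("ggdm"))
    assert out is not None
    _, _, _, p0, p1 = out
    assert p0 == pytest.approx(0.5)
    assert p1 == pytest.approx(0.5)
    assert p0 + p1 == pytest.approx(1.0)


def test_criterion_side_too_small_is_invalid():
    h = two_cluster_histogram()
    assert gmet_criterion(h, 9, get_model("ggdm")) is None  # only 2 levels below


def test_appending_empty_levels_leaves_criterion_unchanged():
    h = two_cluster_histogram()
    ext = CharacteristicHistogram(counts=np.concatenate([h.counts, [0, 0, 0]]),
                                  n_levels=h.n_levels + 3, lo=h.lo, width=h.width,
                                  total=h.total)
    m = get_model("ggdm")
    for t in (20, 50, 80):
        assert gmet_criterion(ext, t, m)[0] == pytest.approx(gmet_criterion(h, t, m)[0])


def test_threshold_is_argmin_of_independent_reevaluation(rng):
    vals = np.concatenate([rng.normal(100, 15, 4000), rng.normal(500, 60, 6000)])
    h = build_histogram(vals[vals > 0])
    for model in ("ggdm", "wldm"):
        res = find_threshold(h, model)
        m = get_model(model)
        js = {t: out[0] for t in range(h.n_levels - 1)
              if (out := gmet_criterion(h, t, m)) is not None}
        jmin = min(js.values())
        assert js[res.t_star] == pytest.approx(jmin, rel=1e-12)
        assert res.criterion_trace[res.t_star] == pytest.approx(js[res.t_star])
        assert res.p_false + res.p_true == pytest.approx(1.0)


def test_ggdm_threshold_near_bayes_crossing_of_two_gaussians(rng):
    from scipy.optimize import brentq

    vals = np.concatenate([rng.normal(100, 15, 4000), rng.normal(500, 60, 6000)])
    h = build_histogram(vals[vals > 0])
    res = find_threshold(h, "ggdm")
    crossing = brentq(lambda x: 0.4 * stats.norm.pdf(x, 100, 15)
                      - 0.6 * stats.norm.pdf(x, 500, 60), 100, 500)
    assert res.threshold > 100 and res.threshold < 500
    assert abs(res.threshold - crossing) <= 40  # coarse; the exact band is in acceptance


def test_wldm_recovers_lognormal_parameters(rng):
    vals = np.concatenate([rng.weibull(1.5, 4000) * 120.0,
                           rng.lognormal(6.3, 0.35, 6000)])
    h = build_histogram(vals)
    res = find_threshold(h, "wldm")
    mu, sd = res.theta_true
    mu_raw = mu + np.log(h.width)  # gray-axis fit back to raw units
    assert mu_raw == pytest.approx(6.3, rel=0.05)
    assert sd == pytest.approx(0.35, rel=0.05)
    k, lam = res.theta_false
    assert k == pytest.approx(1.5, rel=0.25)
    assert lam * h.width == pytest.approx(120.0, rel=0.25)


def test_unseparable_histogram_raises_not_bimodal():
    counts = np.zeros(6, dtype=int)
    counts[2] = 50
    counts[3] = 50
    h = CharacteristicHistogram(counts=counts, n_levels=6, lo=0.0, width=1.0, total=100)
    with pytest.raises(NotBimodalError):
        find_threshold(h, "ggdm")


def test_unknown_model_name_rejected():
    with pytest.raises(ValueError):
        get_model("gamma-gamma")


def fitlike(n_psf):
    return EmitterFit(frame_index=0, x0=1.0, y0=1.0, n_psf=n_psf, n_b=0.0,
                      converged=True, residual_norm=0.0)


def test_select_emitters_partitions_by_threshold():
    fits = [fitlike(v) for v in (0.5, 1.0, 5.0, 99.0, 400.0)]
    acc, rej = select_emitters(fits, 100.0)
    assert [f.n_psf for f in acc] == [400.0]
    assert len(acc) + len(rej) == len(fits)
    # manual threshold of 1 keeps every positive-count fit
    acc1, _ = select_emitters(fits, 1.0)
    assert [f.n_psf for f in acc1] == [1.0, 5.0, 99.0, 400.0]
    # threshold above the maximum keeps nothing
    assert select_emitters(fits, 1e6)[0] == []
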