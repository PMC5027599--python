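import itertools

import numpy as np
import pandas as pd
import pytest

from smlmbayes.evaluate import fwhm_tolerance_nm, match_localizations


def table(xy, frame=0):
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    return pd.DataFrame({"frame": frame, "x_nm": xy[:, 0], "y_nm": xy[:, 1]})


def brute_force_best_matching(ref, rec, tol):
    """Enumerate all one-to-one matchings: max pairs, then min total distance."""
    d = np.sqrt(((ref[:, None, :] - rec[None, :, :]) ** 2).sum(-1))
    feas = [(i, j) for i in range(len(ref)) for j in range(len(rec)) if d[i, j] <= tol]
    best = (0, 0.0)
    for size in range(min(len(ref), len(rec)), -1, -1):
        found = None
        for combo in itertools.combinations(feas, size):
            ri = [p[0] for p in combo]
            ci = [p[1] for p in combo]
            if len(set(ri)) < size or len(set(ci)) < size:
                continue
            dist = sum(d[i, j] for i, j in combo)
            if found is None or dist < found:
                found = dist
        if found is not None:
            return size, found
    return 0, 0.0


def test_identical_tables_match_perfectly(rng):
    xy = rng.uniform(0, 1000, size=(30, 2))
    rep = match_localizations(table(xy), table(xy), tolerance_nm=50.0)
    assert rep.jaccard == rep.precision == rep.recall == 1.0
    assert rep.rmsd_nm == 0.0


def test_metric_arithmetic_for_partial_overlap():
    # 10 reference points, 8 reconstructed: 6 within tolerance, 2 far off
    ref = np.array([[100.0 * k, 0.0] for k in range(10)])
    rec = np.vstack([ref[:6] + [3.0, 4.0], [[5000.0, 5000.0], [6000.0, 6000.0]]])
    rep = match_localizations(table(ref), table(rec), tolerance_nm=20.0)
    assert (rep.tp, rep.fp, rep.fn) == (6, 2, 4)
    assert rep.jaccard == pytest.approx(0.5)
    assert rep.precision == pytest.approx(0.75)
    assert rep.recall == pytest.approx(0.6)
    assert rep.rmsd_nm == pytest.approx(5.0)  # 3-4-5 triangle offsets


def test_matching_equals_brute_force_enumeration(rng):
    for _ in range(15):
        n_ref = int(rng.integers(1, 7))
        n_rec = int(rng.integers(1, 7))
        ref = rng.uniform(0, 60, size=(n_ref, 2))
        rec = rng.uniform(0, 60, size=(n_rec, 2))
        tol = 25.0
        rep = match_localizations(table(ref), table(rec), tolerance_nm=tol)
        tp_bf, dist_bf = brute_force_best_matching(ref, rec, tol)
        assert rep.tp == tp_bf
        assert sum(d for _, _, d in rep.pairs) == pytest.approx(dist_bf, abs=1e-9)
        assert all(d <= tol for _, _, d in rep.pairs)


def test_matched_pairs_are_one_to_one(rng):
    ref = rng.uniform(0, 200, size=(12, 2))
    rec = rng.uniform(0, 200, size=(15, 2))
    rep = match_localizations(table(ref), table(rec), tolerance_nm=80.0)
    assert len({p[0] for p in rep.pairs}) == len(rep.pairs)
    assert len({p[1] for p in rep.pairs}) == len(rep.pairs)
    assert rep.tp + rep.fp == 15
    assert rep.tp + rep.fn == 12


def test_jaccard_never_exceeds_precision_or_recall(rng):
    for _ in range(10):
        ref = rng.uniform(0, 300, size=(rng.integers(2, 20), 2))
        rec = rng.uniform(0, 300, size=(rng.integers(2, 20), 2))
        rep = match_localizations(table(ref), table(rec), tolerance_nm=60.0)
        assert rep.jaccard <= min(rep.precision, rep.recall) + 1e-12


def test_metrics_invariant_under_rigid_translation(rng):
    ref = rng.uniform(0, 500, size=(15, 2))
    rec = ref[:10] + rng.normal(0, 5, size=(10, 2))
    r1 = match_localizations(table(ref), table(rec), tolerance_nm=30.0)
    shift = np.array([123.4, -56.7])
    r2 = match_localizations(table(ref + shift), table(rec + shift), tolerance_nm=30.0)
    assert (r1.tp, r1.fp, r1.fn) == (r2.tp, r2.fp, r2.fn)
    assert r1.rmsd_nm == pytest.approx(r2.rmsd_nm)


def test_true_positives_monotone_in_tolerance(rng):
    ref = rng.uniform(0, 400, size=(20, 2))
    rec = rng.uniform(0, 400, size=(25, 2))
    tps = [match_localizations(table(ref), table(rec), tolerance_nm=t).tp
           for t in (10, 30, 60, 120, 240, 480)]
    assert tps == sorted(tps)


def test_per_frame_matching_keeps_frames_apart():
    xy = [[0.0, 0.0]]
    ref = table(xy, frame=0)
    rec = table(xy, frame=1)
    rep = match_localizations(ref, rec, tolerance_nm=100.0)
    assert rep.tp == 0 and rep.fp == 1 and rep.fn == 1
    rep_global = match_localizations(ref, rec, tolerance_nm=100.0, per_frame=False)
    assert rep_global.tp == 1


def test_missing_columns_are_an_input_error():
    bad = pd.DataFrame({"x_nm": [1.0], "y_nm": [2.0]})  # no frame column
    good = table([[0.0, 0.0]])
    with pytest.raises(ValueError):
        match_localizations(bad, good, tolerance_nm=10.0)
    with pytest.raises(ValueError):
        match_localizations(pd.DataFrame({"x_nm": [1.0]}), good, tolerance_nm=10.0)


def test_fwhm_tolerance_value(optics, cam):
    tol = fwhm_tolerance_nm(optics.s0_px, cam.pixel_size_sample_nm)
    assert tol == pytest.approx(2.3548 * optics.s0_px * 70.0, rel=1e-4)
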