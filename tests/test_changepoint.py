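import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ownflow.changepoint import (
    GROUP_MEAN,
    INDIVIDUAL,
    EffectSeries,
    best_line_sse,
    find_changepoints,
    individual_changepoints,
    onset_changepoint,
    ownership_effect,
    rate_of_change_report,
    result_landmarks,
    segment_sse,
    smooth_moving_average,
)
from ownflow.data_model import (
    CONDITIONS,
    POST,
    RH_ASYNC,
    RH_SYNC,
    STIM,
    mask_dataset_post_gap,
    read_ratings,
)
from ownflow.synthetic import TrajectoryParams, trajectory

from conftest import ratings_frame


def make_effect(values, phase=STIM, start=1):
    values = np.asarray(values, dtype=float)
    times = np.arange(start, start + len(values))
    return EffectSeries(level=GROUP_MEAN, phase=phase, times=times, values=values)


# ------------------------------------------------------------ effect signal


def test_effect_zero_when_conditions_identical():
    per = {
        f"p{i}": {c: np.full(240, 300.0) for c in CONDITIONS} for i in range(3)
    }
    ds = read_ratings(ratings_frame(per))
    eff = ownership_effect(ds, GROUP_MEAN, STIM)
    assert np.allclose(eff.values, 0.0)
    assert len(eff.values) == 120


def test_effect_two_participant_hand_computed():
    sync = {"p1": np.arange(1.0, 241.0), "p2": np.full(240, 100.0)}
    asyn = {"p1": np.full(240, 10.0), "p2": np.full(240, 20.0)}
    per = {
        pid: {
            RH_SYNC: sync[pid],
            RH_ASYNC: asyn[pid],
            "wood_sync": np.zeros(240),
            "wood_async": np.zeros(240),
        }
        for pid in ("p1", "p2")
    }
    ds = read_ratings(ratings_frame(per))
    eff = ownership_effect(ds, GROUP_MEAN, STIM)
    # per-second mean of sync minus mean of async, checked on first 10 s
    expected = (np.arange(1.0, 11.0) + 100.0) / 2 - 15.0
    assert np.allclose(eff.values[:10], expected)
    ind = ownership_effect(ds, INDIVIDUAL, STIM, participant_id="p1")
    assert np.allclose(ind.values[:10], np.arange(1.0, 11.0) - 10.0)


def test_effect_masked_seconds_absent():
    per = {"p1": {c: np.full(240, 50.0) for c in CONDITIONS}}
    ds = mask_dataset_post_gap(read_ratings(ratings_frame(per)), 10)
    eff = ownership_effect(ds, GROUP_MEAN, POST)
    assert eff.times[0] == 11  # phase-relative; 1..10 are masked
    assert len(eff.times) == 110


def test_effect_requires_both_conditions():
    per = {"p1": {RH_SYNC: np.full(240, 50.0)}}
    ds = read_ratings(ratings_frame(per))
    with pytest.raises(ValueError, match="rh_async"):
        ownership_effect(ds, GROUP_MEAN, STIM)


def test_effect_tracks_planted_group_curve(planted_cohort):
    from ownflow.data_model import exclude_nonresponders

    ds, truth = planted_cohort
    ds, _ = exclude_nonresponders(ds)
    eff = ownership_effect(ds, GROUP_MEAN, STIM)
    # planted plateau gives a net effect near 320 points late in stimulation
    late = eff.values[eff.times >= 100].mean()
    assert late == pytest.approx(320.0, abs=40.0)


# ------------------------------------------------------------ smoothing


def test_smooth_constant_unchanged():
    eff = smooth_moving_average(make_effect(np.full(50, 7.0)), 5)
    assert np.allclose(eff.values, 7.0)
    assert eff.smoothed and eff.window_s == 5


def test_smooth_impulse_manual_convolution():
    eff = smooth_moving_average(
        make_effect([0, 0, 0, 0, 0, 10, 0, 0, 0, 0, 0]), 5
    )
    expected = np.zeros(11)
    expected[3:8] = 2.0
    assert np.allclose(eff.values, expected)


def test_smooth_window_one_is_identity():
    v = np.random.default_rng(0).normal(size=30)
    eff = smooth_moving_average(make_effect(v), 1)
    assert np.allclose(eff.values, v)


def test_smooth_edge_truncation():
    eff = smooth_moving_average(make_effect([6.0, 0.0, 0.0, 0.0, 0.0, 0.0]), 5)
    assert eff.values[0] == pytest.approx(2.0)  # first ceil(5/2)=3 samples
    assert eff.values[1] == pytest.approx(1.5)  # first 4 samples


def test_smooth_even_window_rejected():
    with pytest.raises(ValueError):
        smooth_moving_average(make_effect(np.zeros(10)), 4)


@given(st.lists(st.floats(-1000, 1000), min_size=3, max_size=60))
@settings(max_examples=60, deadline=None)
def test_smooth_never_widens_range(values):
    eff = make_effect(values)
    sm = smooth_moving_average(eff, 5)
    assert sm.values.min() >= eff.values.min() - 1e-9
    assert sm.values.max() <= eff.values.max() + 1e-9


# ------------------------------------------------------------ segment fits


def test_segment_collinear_zero_sse():
    t = np.arange(1, 21)
    fit = segment_sse(t, 3.0 * t + 2.0, 0, 19)
    assert fit.sse == pytest.approx(0.0, abs=1e-9)
    assert fit.slope == pytest.approx(3.0)
    assert fit.intercept == pytest.approx(2.0)


def test_segment_closed_form_three_points():
    fit = segment_sse([0, 1, 2], [0.0, 1.0, 0.0], 0, 2)
    assert fit.slope == pytest.approx(0.0)
    assert fit.intercept == pytest.approx(1.0 / 3.0)
    assert fit.sse == pytest.approx(2.0 / 3.0)


def test_segment_too_short():
    with pytest.raises(ValueError):
        segment_sse([1, 2, 3], [1.0, 2.0, 3.0], 1, 1)


def test_prefix_statistics_match_direct_lstsq():
    rng = np.random.default_rng(11)
    t = np.arange(1, 101)
    v = rng.normal(0, 50, 100) + 0.5 * t
    for _ in range(100):
        i = int(rng.integers(0, 98))
        j = int(rng.integers(i + 1, 100))
        fit = segment_sse(t, v, i, j)
        # independent route: polynomial least squares on the slice
        coeffs = np.polyfit(t[i : j + 1], v[i : j + 1], 1)
        resid = v[i : j + 1] - np.polyval(coeffs, t[i : j + 1])
        assert fit.slope == pytest.approx(coeffs[0], abs=1e-8)
        assert fit.intercept == pytest.approx(coeffs[1], abs=1e-6)
        assert fit.sse == pytest.approx(float(np.sum(resid**2)), abs=1e-6)


# ------------------------------------------------------------ changepoints


def brute_force(series, k, msl=3):
    """Independent exhaustive search using direct per-slice least squares."""

    def sse(i, j):
        tt = series.times[i : j + 1].astype(float)
        vv = series.values[i : j + 1]
        A = np.vstack([tt, np.ones_like(tt)]).T
        resid = vv - A @ np.linalg.lstsq(A, vv, rcond=None)[0]
        return float(resid @ resid)

    n = len(series.values)
    tie_tol = 1e3 * np.finfo(float).eps * max(float(np.sum(series.values**2)), 1.0)
    best = (np.inf, ())
    if k == 1:
        cuts = [(c,) for c in range(msl - 1, n - msl)]
    else:
        cuts = [
            (c1, c2)
            for c1 in range(msl - 1, n - 2 * msl)
            for c2 in range(c1 + msl, n - msl)
        ]
    for cs in cuts:
        bounds = [-1, *cs, n - 1]
        total = sum(sse(a + 1, b) for a, b in zip(bounds[:-1], bounds[1:]))
        if not np.isfinite(best[0]):
            best = (total, cs)
            continue
        tol = max(1e-9 * best[0], tie_tol)
        if total < best[0] - tol:
            best = (total, cs)
        elif total < best[0] + tol:
            best = (min(best[0], total), cs)
    return best


def test_noiseless_three_segments_recovered():
    t = np.arange(1, 31).astype(float)
    v = np.where(t <= 10, t, np.where(t <= 20, 10.0, 10.0 - (t - 20)))
    res = find_changepoints(make_effect(v), 2)
    assert res.changepoint_times == [10, 20]
    assert res.total_sse == pytest.approx(0.0, abs=1e-9)
    assert len(res.segments) == 3
    assert res.segments[0].slope == pytest.approx(1.0)
    assert res.segments[1].slope == pytest.approx(0.0, abs=1e-9)
    assert res.segments[2].slope == pytest.approx(-1.0)


@pytest.mark.parametrize("k", [1, 2])
@pytest.mark.parametrize("seed", range(10))
def test_matches_brute_force(k, seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(12, 45))
    eff = make_effect(rng.normal(0, 10, n) + np.linspace(0, rng.uniform(-50, 50), n))
    res = find_changepoints(eff, k)
    oracle_sse, oracle_cuts = brute_force(eff, k)
    assert tuple(res.changepoint_indices) == oracle_cuts
    assert res.total_sse == pytest.approx(oracle_sse, rel=1e-7, abs=1e-7)


def test_sse_monotone_in_k():
    rng = np.random.default_rng(5)
    eff = make_effect(rng.normal(0, 10, 60))
    sse0 = best_line_sse(eff)
    sse1 = find_changepoints(eff, 1).total_sse
    sse2 = find_changepoints(eff, 2).total_sse
    assert sse2 <= sse1 + 1e-9 <= sse0 + 2e-9


def test_total_sse_is_sum_of_segment_sses():
    rng = np.random.default_rng(8)
    eff = make_effect(rng.normal(0, 10, 50))
    res = find_changepoints(eff, 2)
    assert res.total_sse == pytest.approx(sum(s.sse for s in res.segments))
    assert all(
        s.end_idx - s.start_idx + 1 >= 3 for s in res.segments
    )


def test_changepoint_errors():
    eff = make_effect(np.arange(8.0))
    with pytest.raises(ValueError):
        find_changepoints(eff, 2)  # 8 < 3*3
    with pytest.raises(ValueError):
        find_changepoints(eff, 0)
    with pytest.raises(ValueError):
        find_changepoints(make_effect(np.arange(100.0)), 3)


@given(
    knots=st.tuples(st.integers(5, 20), st.integers(10, 25)),
    slopes=st.tuples(
        st.integers(1, 8), st.integers(-8, -1), st.integers(2, 9)
    ),
)
@settings(max_examples=40, deadline=None)
def test_noiseless_identifiability(knots, slopes):
    # piecewise-linear with distinct integer slopes and segments >= 5
    len1, len2 = knots
    s1, s2, s3 = slopes
    n = len1 + len2 + 12
    t = np.arange(1, n + 1).astype(float)
    v = np.empty(n)
    v[:len1] = s1 * t[:len1]
    v[len1 : len1 + len2] = v[len1 - 1] + s2 * (t[len1 : len1 + len2] - t[len1 - 1])
    v[len1 + len2 :] = v[len1 + len2 - 1] + s3 * (
        t[len1 + len2 :] - t[len1 + len2 - 1]
    )
    res = find_changepoints(make_effect(v), 2)
    assert res.total_sse == pytest.approx(0.0, abs=1e-6)
    assert res.changepoint_times == [len1, len1 + len2]


# ------------------------------------------------------------ individual level


def _dataset_from_sync_async(sync_map, async_map):
    per = {}
    for pid in sync_map:
        per[pid] = {
            RH_SYNC: sync_map[pid],
            RH_ASYNC: async_map[pid],
            "wood_sync": np.zeros(240),
            "wood_async": np.zeros(240),
        }
    return read_ratings(ratings_frame(per))


def test_individual_stationary_yields_none():
    flat = np.full(240, 200.0)
    ds = _dataset_from_sync_async({"p1": flat}, {"p1": flat})
    res = individual_changepoints(ds, STIM)
    assert res["p1"] is None
    assert onset_changepoint(res["p1"]) is None


def test_individual_perfect_line_yields_none():
    # nonconstant but exactly linear: no changepoint distinguishes anything
    sync = np.concatenate([np.linspace(0, 600, 120), np.zeros(120)])
    ds = _dataset_from_sync_async({"p1": sync}, {"p1": np.zeros(240)})
    res = individual_changepoints(ds, STIM, smooth=False)
    assert res["p1"] is None


def test_individual_noiseless_exact_recovery():
    params = TrajectoryParams(noise_sd=0.0, quantize=False)
    sync = trajectory(params, RH_SYNC, gain=1.0).rating
    ds = _dataset_from_sync_async({"p1": sync}, {"p1": np.zeros(240)})
    res = individual_changepoints(ds, STIM, smooth=False)
    assert res["p1"].changepoint_times == [19, 87]
    assert onset_changepoint(res["p1"]) == 19


def test_individual_noisy_onset_median_recovery():
    # planted onsets at 23 s; median recovered onset within +/-2 s
    params = TrajectoryParams(
        onset_latency_s=23.0, rise_rate=9.0, slow_rate=2.0, noise_sd=20.0
    )
    onsets = []
    for seed in range(30):
        sync = trajectory(params, RH_SYNC, seed=seed, gain=1.0).rating
        ds = _dataset_from_sync_async({"p1": sync}, {"p1": np.zeros(240)})
        res = individual_changepoints(ds, STIM)
        onsets.append(onset_changepoint(res["p1"]))
    assert abs(np.median([o for o in onsets if o is not None]) - 23) <= 2


# ------------------------------------------------------------ landmarks


def test_rate_of_change_report():
    marks = [(0, 0.0), (19, 180.47), (87, 319.87), (120, 312.75)]
    rep = rate_of_change_report(marks)
    assert [r["delta"] for r in rep] == pytest.approx([180.47, 139.40, -7.12])
    assert [r["duration_s"] for r in rep] == [19, 68, 33]
    with pytest.raises(ValueError):
        rate_of_change_report([(0, 1.0)])
    with pytest.raises(ValueError):
        rate_of_change_report([(5, 1.0), (5, 2.0)])


def test_result_landmarks_noiseless():
    t = np.arange(1, 31).astype(float)
    v = np.where(t <= 10, t, np.where(t <= 20, 10.0, 10.0 - (t - 20)))
    eff = make_effect(v)
    res = find_changepoints(eff, 2)
    marks = result_landmarks(eff, res)
    assert marks[0] == pytest.approx((1.0, 1.0))
    assert marks[1] == pytest.approx((10.0, 10.0))
    assert marks[2] == pytest.approx((20.0, 10.0))
    assert marks[3] == pytest.approx((30.0, 0.0))
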