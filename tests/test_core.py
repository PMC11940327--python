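"""Episode segmentation, point construction and slope-fit tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

from chemoreflex import (
    AnalysisError,
    BreathSeries,
    InsufficientDataError,
    beats_from_times,
    fit_slope,
    post_point_hr,
    post_point_ventilation,
    pre_point,
    run_hr_slope,
    run_hvr,
    segment_episodes,
    smooth_hr,
)
from chemoreflex.core import HypoxicEpisode, ResponsePoint, best_consecutive_mean

from conftest import make_flat_recording


def _recording_with_spo2(spo2, fs=50.0, n2=((260.0, 280.0),)):
    rec = make_flat_recording(duration=len(spo2) / fs, fs=fs, n2_intervals=n2)
    rec.spo2 = np.asarray(spo2, dtype=float)
    return rec


class TestSegmentEpisodes:
    def test_v_shaped_desaturation_nadir(self):
        fs, a, b = 50.0, 260.0, 280.0
        n = int(400 * fs)
        t = np.arange(n) / fs
        spo2 = np.full(n, 96.0)
        t_nadir = b + 22.0
        # symmetric V shape dipping to 78 % at 22 s after the admin end
        mask = (t > b) & (t < b + 44.0)
        spo2[mask] = 96.0 - (18.0 * (1 - np.abs(t[mask] - t_nadir) / 22.0))
        rec = _recording_with_spo2(spo2, fs=fs, n2=((a, b),))
        (ep,) = segment_episodes(rec)
        assert ep.valid
        assert ep.nadir_spo2 == pytest.approx(78.0, abs=0.05)
        assert ep.nadir_time == pytest.approx(t_nadir, abs=0.05)

    def test_flat_spo2_flagged_no_desaturation(self):
        rec = make_flat_recording()
        (ep,) = segment_episodes(rec)
        assert not ep.valid
        assert ep.nadir_spo2 == pytest.approx(96.0)
        assert any("no desaturation" in r for r in ep.reasons)

    def test_tied_minima_take_earliest(self):
        fs, b = 50.0, 280.0
        n = int(400 * fs)
        spo2 = np.full(n, 96.0)
        i1 = int((b + 10) * fs)
        i2 = int((b + 30) * fs)
        spo2[i1] = spo2[i2] = 80.0
        rec = _recording_with_spo2(spo2, fs=fs)
        (ep,) = segment_episodes(rec)
        assert ep.nadir_time == pytest.approx((b + 10), abs=0.05)

    def test_spacing_violation_flagged_not_dropped(self):
        rec = make_flat_recording(
            duration=700.0, n2_intervals=((260.0, 280.0), (350.0, 360.0))
        )
        eps = segment_episodes(rec)
        assert len(eps) == 2
        assert not eps[1].valid
        assert any("spacing" in r for r in eps[1].reasons)

    def test_nadir_search_is_halfopen_after_admin_end(self):
        """The minimum exactly at n2_end is outside the search window."""
        fs, b = 50.0, 280.0
        n = int(400 * fs)
        spo2 = np.full(n, 96.0)
        spo2[int(b * fs)] = 70.0  # at the boundary: excluded
        spo2[int((b + 5) * fs)] = 80.0
        rec = _recording_with_spo2(spo2, fs=fs)
        (ep,) = segment_episodes(rec)
        assert ep.nadir_spo2 == pytest.approx(80.0)


class TestPrePoint:
    def test_constant_window_means(self):
        rec = make_flat_recording()
        ep = HypoxicEpisode(0, 260.0, 280.0, nadir_time=290.0, nadir_spo2=80.0)
        times = np.arange(0.0, 400.0, 4.0)
        values = np.full(len(times), 11.0)
        pt = pre_point(ep, rec, times, values)
        assert (pt.spo2, pt.response) == (pytest.approx(96.0), pytest.approx(11.0))
        assert pt.role == "pre"

    def test_linear_ramp_averages_to_midpoint(self):
        fs = 50.0
        n = int(400 * fs)
        t = np.arange(n) / fs
        spo2 = np.full(n, 96.0)
        win = (t >= 200.0) & (t < 260.0)
        spo2[win] = 95.0 + 2.0 * (t[win] - 200.0) / 60.0  # 95 -> 97 over the window
        rec = _recording_with_spo2(spo2, fs=fs)
        ep = HypoxicEpisode(0, 260.0, 280.0, nadir_time=290.0, nadir_spo2=80.0)
        pt = pre_point(ep, rec, np.array([230.0]), np.array([11.0]))
        assert pt.spo2 == pytest.approx(96.0, abs=1e-3)

    def test_truncated_window_is_an_error(self):
        rec = make_flat_recording(n2_intervals=((30.0, 50.0),))
        ep = HypoxicEpisode(0, 30.0, 50.0, nadir_time=60.0, nadir_spo2=80.0)
        with pytest.raises(InsufficientDataError):
            pre_point(ep, rec, np.array([20.0]), np.array([11.0]))

    def test_no_events_in_window_is_an_error(self):
        rec = make_flat_recording()
        ep = HypoxicEpisode(0, 260.0, 280.0, nadir_time=290.0, nadir_spo2=80.0)
        with pytest.raises(InsufficientDataError):
            pre_point(ep, rec, np.array([10.0]), np.array([11.0]))


def _breaths(times, vdots):
    times = np.asarray(times, dtype=float)
    vdots = np.asarray(vdots, dtype=float)
    br = np.full(len(times), 15.0)
    return BreathSeries(
        pd.DataFrame(
            {"t_breath": times, "vt": vdots / br, "br": br, "vdot": vdots}
        )
    )


class TestPostPoints:
    def _episode_and_beats(self, nadir_time=300.0):
        ep = HypoxicEpisode(0, 260.0, 280.0, nadir_time=nadir_time, nadir_spo2=78.0)
        beats = smooth_hr(beats_from_times(np.arange(0.0, 400.0, 1.0)))
        return ep, beats

    def test_best_consecutive_triple(self):
        ep, beats = self._episode_and_beats()
        times = 295.0 + np.arange(6) * 2.0
        breaths = _breaths(times, [10.0, 12.0, 18.0, 20.0, 19.0, 13.0])
        pt = post_point_ventilation(ep, breaths, beats)
        assert pt.response == pytest.approx((18 + 20 + 19) / 3.0)
        assert pt.spo2 == pytest.approx(78.0)

    def test_constant_ventilation(self):
        ep, beats = self._episode_and_beats()
        breaths = _breaths(295.0 + np.arange(8) * 2.0, [11.0] * 8)
        assert post_point_ventilation(ep, breaths, beats).response == pytest.approx(11.0)

    def test_exactly_three_breaths(self):
        ep, beats = self._episode_and_beats()
        breaths = _breaths([298.0, 302.0, 306.0], [9.0, 14.0, 12.0])
        pt = post_point_ventilation(ep, breaths, beats)
        assert pt.response == pytest.approx(35.0 / 3.0)

    def test_too_few_breaths_excluded(self):
        ep, beats = self._episode_and_beats()
        breaths = _breaths([298.0, 302.0], [9.0, 14.0])
        with pytest.raises(InsufficientDataError):
            post_point_ventilation(ep, breaths, beats)

    def test_hr_post_point_is_window_max(self):
        ep, beats = self._episode_and_beats()
        hr = beats.data["hr_smooth"].to_numpy()
        t = beats.t
        in_win = (t >= 295.0) & (t <= 320.0)
        hr[in_win] = [62, 65, 71, 70] * 6 + [62, 65]
        beats.data["hr_smooth"] = hr
        pt = post_point_hr(ep, beats)
        assert pt.response == pytest.approx(71.0)

    def test_all_window_beats_excluded(self):
        ep, beats = self._episode_and_beats()
        hr = beats.data["hr_smooth"].to_numpy()
        hr[(beats.t >= 290.0) & (beats.t <= 330.0)] = np.nan
        beats.data["hr_smooth"] = hr
        with pytest.raises(InsufficientDataError):
            post_point_hr(ep, beats)

    def test_noiseless_hr_point_matches_closed_form(self, noiseless_recording):
        """Post-point HR = baseline + Gh * (baseline SpO2 - nadir SpO2)."""
        rec, truth = noiseless_recording
        res = run_hr_slope(rec)
        posts = res.points[res.points["role"] == "post"]
        expected = 62.0 + truth.gh * (96.0 - posts["spo2"])
        np.testing.assert_allclose(posts["response"], expected, rtol=2e-3)


class TestBestConsecutiveMeanOracle:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(3, 15)
            vals = rng.normal(10.0, 3.0, size=n)
            brute = max(vals[i : i + 3].mean() for i in range(n - 2))
            assert best_consecutive_mean(vals, 3) == pytest.approx(brute)


def _points(pairs, roles=None):
    pts = []
    for i, (s, r) in enumerate(pairs):
        role = roles[i] if roles else ("pre" if i % 2 == 0 else "post")
        pts.append(ResponsePoint(spo2=s, response=r, role=role, episode=i // 2))
    return pts


class TestFitSlope:
    def test_two_episode_hand_case(self):
        pts = _points([(96.0, 11.0), (76.0, 19.0), (96.0, 11.0), (76.0, 19.0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_slope(pts, "ventilation", min_episodes=2)
        assert res.slope_magnitude == pytest.approx(0.40)
        assert res.raw_ols_slope == pytest.approx(-0.40)
        assert res.n_points == 4

    def test_flat_response_zero_slope(self):
        pts = _points([(96.0, 11.0), (76.0, 11.0)] * 3)
        res = fit_slope(pts, "ventilation")
        assert res.slope_magnitude == 0.0
        assert res.r_squared == 0.0

    def test_affine_equivariance(self):
        rng = np.random.default_rng(5)
        pairs = [(s, 11 + 0.4 * (96 - s) + rng.normal()) for s in rng.uniform(70, 96, 12)]
        base = fit_slope(_points(pairs), "ventilation")
        shifted = fit_slope(_points([(s, r + 7.5) for s, r in pairs]), "ventilation")
        scaled = fit_slope(_points([(s, r * 3.0) for s, r in pairs]), "ventilation")
        assert shifted.slope_magnitude == pytest.approx(base.slope_magnitude)
        assert shifted.intercept == pytest.approx(base.intercept + 7.5)
        assert scaled.slope_magnitude == pytest.approx(3.0 * base.slope_magnitude)

    def test_on_line_episode_deletion_invariance(self):
        """Removing an episode lying exactly on the fit leaves it unchanged."""
        rng = np.random.default_rng(6)
        pairs = [(s, 11 + 0.4 * (96 - s) + rng.normal()) for s in rng.uniform(70, 96, 12)]
        res = fit_slope(_points(pairs), "ventilation")
        a, b = res.raw_ols_slope, res.intercept
        extra = [(95.0, a * 95.0 + b), (75.0, a * 75.0 + b)]
        res2 = fit_slope(_points(pairs + extra), "ventilation")
        assert res2.raw_ols_slope == pytest.approx(a, abs=1e-12)
        assert res2.intercept == pytest.approx(b, abs=1e-10)

    def test_min_episode_floor(self):
        pts = _points([(96.0, 11.0), (76.0, 19.0)] * 2)
        with pytest.raises(InsufficientDataError):
            fit_slope(pts, "ventilation", min_episodes=3)

    def test_identical_spo2_undefined(self):
        pts = _points([(96.0, 11.0), (96.0, 19.0)] * 3)
        with pytest.raises(AnalysisError):
            fit_slope(pts, "ventilation")

    def test_paradoxical_response_warns_not_clamps(self):
        pts = _points([(96.0, 19.0), (76.0, 11.0)] * 3)
        with pytest.warns(UserWarning, match="paradoxical"):
            res = fit_slope(pts, "ventilation")
        assert res.slope_magnitude < 0


class TestPipelines:
    def test_hvr_deterministic(self, fast_recording):
        rec, _ = fast_recording
        a = run_hvr(rec).slope_magnitude
        b = run_hvr(rec).slope_magnitude
        assert a == pytest.approx(b, abs=1e-12)

    def test_noiseless_recovery(self, noiseless_recording, noiseless_config):
        rec, truth = noiseless_recording
        hvr = run_hvr(rec)
        hr = run_hr_slope(rec)
        assert hvr.slope_magnitude == pytest.approx(truth.gv, rel=0.05)
        assert hr.slope_magnitude == pytest.approx(truth.gh, rel=0.05)
        assert hvr.r_squared > 0.99

    def test_af_like_recording_refused_for_hr(self):
        rng = np.random.default_rng(8)
        rec = make_flat_recording(duration=700.0, n2_intervals=((610.0, 630.0),))
        rec.beat_times = np.cumsum(rng.uniform(0.4, 1.2, size=900))
        with pytest.raises(AnalysisError, match="irregular rhythm"):
            run_hr_slope(rec)

    def test_qc_log_covers_every_episode(self, fast_recording, fast_config):
        rec, _ = fast_recording
        res = run_hvr(rec)
        assert len(res.qc) == fast_config.n_admins
        assert res.qc["used"].sum() == res.n_episodes
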