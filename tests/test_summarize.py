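"""Aggregation, head activity, zone occupancy and agreement statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_pose, make_report, make_tracks
from eyeuse.errors import ConsistencyError, InsufficientDataError
from eyeuse.fieldscore import SCORE_COLUMNS, score_video
from eyeuse.headgeom import SECTOR_LABELS, VisualFieldConfig
from eyeuse.summarize import (
    Zone,
    aggregate_scores,
    compare_with_manual,
    head_activity,
    tracking_accuracy,
    zone_occupancy,
)
from eyeuse.synth import SynthParams, generate_session
from eyeuse.trackio import SessionConfig

_COLS = list(SCORE_COLUMNS.values())
CANON = ((-1.0, 0.0), (1.0, 0.0), (0.0, 1.0))


def _table(rows_by_sector, stimulus_id="s"):
    """Build a score table from a list of dicts {sector_column: value}."""
    rows = []
    for i, r in enumerate(rows_by_sector):
        row = {"frame": i, "stimulus_id": stimulus_id, "valid_flag": r is not None}
        for c in _COLS:
            row[c] = np.nan if r is None else r.get(c, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


class TestAggregateScores:
    def test_all_lateral_left(self):
        t = _table([{"lateral_left": 1.0}] * 30)
        s = aggregate_scores(t, fps=30.0)
        assert s.durations["lateral_left"] == pytest.approx(1.0)
        assert s.proportions["lateral_left"] == pytest.approx(1.0)
        assert s.laterality_index == pytest.approx(-1.0)

    def test_balanced_use_has_zero_laterality(self):
        t = _table([{"lateral_left": 1.0}, {"lateral_right": 1.0}] * 5)
        assert aggregate_scores(t, fps=10.0).laterality_index == pytest.approx(0.0)

    def test_totals_match_ground_truth_sums_exactly(self):
        p = SynthParams(n_frames=200, landmark_noise_sd=0.0, outlier_rate=0.0, seed=6)
        tracks, gt, _ = generate_session(p)
        cfg = SessionConfig(field_angles=VisualFieldConfig(), stimuli=p.stimuli,
                            fps=p.fps)
        scores = score_video(tracks, cfg)
        s = aggregate_scores(scores, p.fps)
        for c in _COLS:
            assert s.totals[c] == gt[c].sum()

    def test_proportions_sum_to_one(self):
        p = SynthParams(n_frames=100, seed=9)
        _, gt, _ = generate_session(p)
        s = aggregate_scores(gt, p.fps)
        assert sum(s.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_laterality_antisymmetric_under_mirroring(self):
        p = SynthParams(n_frames=150, seed=12)
        _, gt, _ = generate_session(p)
        mirrored = gt.rename(columns={
            "frontal_left": "frontal_right", "frontal_right": "frontal_left",
            "lateral_left": "lateral_right", "lateral_right": "lateral_left",
            "blind_left": "blind_right", "blind_right": "blind_left"})
        a = aggregate_scores(gt, p.fps).laterality_index
        b = aggregate_scores(mirrored, p.fps).laterality_index
        assert b == pytest.approx(-a, abs=1e-12)


class TestHeadActivity:
    def test_stationary_head(self):
        tracks = make_tracks([CANON] * 10)
        per_pair, summary = head_activity(tracks, make_report(tracks))
        assert summary["path_length"] == 0.0
        assert summary["mean_heading_change"] == 0.0
        assert summary["n_pairs"] == 9

    def test_translation_path_length(self):
        frames = [tuple((x + 3.0 * i, y) for x, y in CANON) for i in range(10)]
        _, summary = head_activity(make_tracks(frames))
        assert summary["path_length"] == pytest.approx(27.0)

    def test_pure_rotation(self):
        """Head rotating 5 deg/frame about a fixed origin: zero displacement,
        constant 5 deg/frame heading change."""
        def rot(p, deg):
            c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
            return (c * p[0] - s * p[1], s * p[0] + c * p[1])

        frames = [tuple(rot(p, 5.0 * i) for p in CANON) for i in range(12)]
        per_pair, summary = head_activity(make_tracks(frames))
        assert summary["path_length"] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(per_pair["heading_change"], 5.0, atol=1e-9)

    def test_gaps_skipped_not_interpolated(self):
        frames = [tuple((x + 3.0 * i, y) for x, y in CANON) for i in range(10)]
        tracks = make_tracks(frames)
        low = np.zeros(10, bool)
        low[5] = True
        _, summary = head_activity(tracks, make_report(tracks, low_likelihood=low))
        # pairs (4,5) and (5,6) are dropped; the 4->6 gap is not bridged
        assert summary["n_pairs"] == 7
        assert summary["path_length"] == pytest.approx(21.0)

    def test_too_few_valid_frames_warns(self):
        tracks = make_tracks([CANON] * 3)
        low = np.array([True, True, False])
        with pytest.warns(UserWarning):
            per_pair, summary = head_activity(
                tracks, make_report(tracks, low_likelihood=low))
        assert summary["n_pairs"] == 0 and per_pair.empty


class TestZoneOccupancy:
    def test_all_frames_in_one_zone(self):
        tracks = make_tracks([CANON] * 50)  # eye midpoint at (0, 0)
        zones = [Zone("A", -10, -10, 10, 10), Zone("B", 10, -10, 30, 10)]
        occ = zone_occupancy(tracks, make_report(tracks), zones, fps=25.0)
        assert occ == {"A": 2.0, "B": 0.0}

    def test_shared_edge_counted_once(self):
        # eye midpoint exactly at x=10, the shared edge: min-inclusive rule
        frames = [((9.0, 0.0), (11.0, 0.0), (10.0, 1.0))]
        tracks = make_tracks(frames)
        zones = [Zone("A", 0, -10, 10, 10), Zone("B", 10, -10, 20, 10)]
        occ = zone_occupancy(tracks, make_report(tracks), zones, fps=1.0)
        assert occ == {"A": 0.0, "B": 1.0}

    def test_matches_brute_force_on_random_walk(self):
        p = SynthParams(n_frames=400, position_walk_sd=20.0, seed=21)
        tracks, _, _ = generate_session(p)
        report = make_report(tracks)
        zones = [Zone("left", 0, 0, 640, 1400), Zone("right", 640, 0, 1400, 1400)]
        occ = zone_occupancy(tracks, report, zones, fps=p.fps)
        mid = tracks.eye_midpoints()
        for z in zones:
            count = sum(
                1 for x, y in mid
                if z.x_min <= x < z.x_max and z.y_min <= y < z.y_max
            )
            assert occ[z.id] == pytest.approx(count / p.fps)


class TestAgreement:
    @pytest.fixture
    def auto(self):
        p = SynthParams(n_frames=60, seed=14)
        _, gt, _ = generate_session(p)
        return gt

    def test_identical_tables_perfect_correlation(self, auto):
        """Scoring that never disagrees with the coder gives r = 1 in every
        sector with any variance."""
        for res in compare_with_manual(auto, auto):
            if not np.isnan(res.r):
                assert res.r == pytest.approx(1.0, abs=1e-12)
                assert res.p <= 0.05

    def test_anticorrelated_series(self):
        vals = ([{"frontal_left": 1.0}, {"lateral_left": 1.0}] * 5)
        auto = _table(vals)
        manual = auto.copy()
        manual["frontal_left"] = 1.0 - auto["frontal_left"]
        res = {r.sector: r for r in compare_with_manual(auto, manual)}
        assert res["FL"].r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_formula(self, auto):
        """r equals cov(x,y)/(sd_x sd_y) computed from scratch, to 1e-12."""
        rng = np.random.default_rng(15)
        manual = auto.copy()
        for c in _COLS:
            manual[c] = np.clip(manual[c] + rng.normal(0, 0.1, len(manual)), 0, 1)
        results = {r.sector: r for r in compare_with_manual(auto, manual)}
        for label in SECTOR_LABELS:
            c = SCORE_COLUMNS[label]
            x, y = auto[c].to_numpy(), manual[c].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                assert np.isnan(results[label].r)
                continue
            xc, yc = x - x.mean(), y - y.mean()
            expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert results[label].r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_reported_as_missing(self):
        t = _table([{"lateral_left": 1.0}] * 10)
        res = {r.sector: r for r in compare_with_manual(t, t)}
        assert np.isnan(res["LL"].r)  # constant series: undefined, not 0
        assert np.isnan(res["FL"].r)

    def test_spearman_supported(self, auto):
        for res in compare_with_manual(auto, auto, method="spearman"):
            assert res.method == "spearman"
            if not np.isnan(res.r):
                assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_per_subject_scope(self, auto):
        a = auto.copy()
        a["subject"] = np.where(a["frame"] < 30, "c1", "c2")
        res = compare_with_manual(a, a)
        scopes = {(r.scope, r.subject) for r in res}
        assert ("pooled", None) in scopes
        assert ("per-subject", "c1") in scopes and ("per-subject", "c2") in scopes

    def test_mismatched_frames_rejected(self, auto):
        with pytest.raises(ConsistencyError):
            compare_with_manual(auto, auto.iloc[:-1])

    def test_too_few_frames_rejected(self):
        t = _table([{"lateral_left": 1.0}, None, None])
        with pytest.raises(InsufficientDataError):
            compare_with_manual(t, t)


class TestTrackingAccuracy:
    def test_identical_tables(self):
        t = _table([{"lateral_left": 1.0}] * 8)
        assert tracking_accuracy(t, t) == 1.0

    def test_one_of_four_frames_differs(self):
        t = _table([{"lateral_left": 1.0}] * 4)
        m = t.copy()
        m.loc[0, "lateral_left"] = 0.75
        m.loc[0, "frontal_left"] = 0.25
        assert tracking_accuracy(t, m) == 0.75

    def test_matches_brute_force_row_comparison(self):
        rng = np.random.default_rng(16)
        p = SynthParams(n_frames=80, seed=17)
        _, auto, _ = generate_session(p)
        manual = auto.copy()
        relabel = rng.random(len(manual)) < 0.3
        manual.loc[relabel, "frontal_left"] = 0.33
        expected = sum(
            1.0 for i in range(len(auto))
            if all(abs(auto.loc[i, c] - manual.loc[i, c]) <= 1e-9 for c in _COLS)
        ) / len(auto)
        assert tracking_accuracy(auto, manual) == pytest.approx(expected)

    def test_validity_mismatch_counts_as_disagreement(self):
        t = _table([{"lateral_left": 1.0}] * 4)
        m = t.copy()
        m.loc[1, _COLS] = np.nan
        m.loc[1, "valid_flag"] = False
        assert tracking_accuracy(t, m) == 0.75
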