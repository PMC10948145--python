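"""Event matching, NN analysis, cumulative correlation, TRA, quality score."""

import numpy as np
import pytest

from apodetect.evaluation import (
    MatchConfig,
    QualityRanges,
    combine_quality_components,
    cumulative_correlation,
    estimate_snr,
    match_events,
    nn_analysis,
    temporal_offsets,
    tra_score,
    video_quality_score,
)
from apodetect.io import Timelapse


def events(*xyt):
    return [tuple(map(float, e)) for e in xyt]


class TestMatchEvents:
    def test_identical_sets_give_perfect_scores(self):
        truth = events((10, 10, 5), (50, 50, 9), (80, 20, 30))
        r = match_events(truth, truth)
        assert r.tpr == 1.0 and r.fpr == 0.0
        assert (r.spatial_errors == 0).all() and (r.temporal_offsets == 0).all()

    def test_no_predictions(self):
        r = match_events([], events((5, 5, 1)))
        assert r.tpr == 0.0 and r.fpr == 0.0

    def test_empty_truth_leaves_tpr_undefined(self):
        r = match_events(events((5, 5, 1)), [])
        assert r.tpr is None and r.fpr == 1.0

    def test_out_of_radius_prediction_is_a_false_positive(self):
        r = match_events(events((40, 0, 5)), events((10, 0, 5)),
                         MatchConfig(spatial_radius=20))
        assert r.tpr == 0.0 and r.fpr == 1.0

    def test_matching_is_one_to_one(self):
        truth = events((10, 10, 5))
        preds = events((11, 10, 5), (9, 10, 5))
        r = match_events(preds, truth)
        assert len(r.matches) == 1 and r.fpr == 0.5

    def test_tpr_shrinks_with_the_spatial_radius(self, rng):
        truth = [(float(x), float(y), int(t)) for x, y, t in
                 zip(rng.uniform(0, 200, 30), rng.uniform(0, 200, 30),
                     rng.integers(0, 50, 30))]
        preds = [(x + float(rng.normal(0, 8)), y + float(rng.normal(0, 8)), t)
                 for x, y, t in truth]
        tprs = [match_events(preds, truth, MatchConfig(spatial_radius=r)).tpr
                for r in (40, 20, 10, 5)]
        assert tprs == sorted(tprs, reverse=True)


class TestNNAnalysis:
    def test_three_four_five_triangle(self):
        out = nn_analysis(events((0, 0, 0)), events((3, 4, 0)), (64, 64))
        assert out["distances"][0] == pytest.approx(5.0)

    def test_identical_points_have_zero_distance(self):
        e = events((5, 5, 0), (20, 30, 3))
        assert (nn_analysis(e, e, (64, 64))["distances"] == 0).all()

    def test_matches_pairwise_min_oracle(self, rng):
        P = rng.uniform(0, 100, (20, 2))
        G = rng.uniform(0, 100, (15, 2))
        preds = [(x, y, 0) for x, y in P]
        truth = [(x, y, 0) for x, y in G]
        got = nn_analysis(preds, truth, (100, 100))["distances"]
        oracle = [min(np.hypot(px - gx, py - gy) for gx, gy in G) for px, py in P]
        np.testing.assert_allclose(got, oracle)

    def test_baseline_uses_same_count(self, rng):
        preds = events((10, 10, 0), (20, 20, 0))
        out = nn_analysis(preds, events((50, 50, 0)), (200, 200), seed=1)
        assert len(out["baseline_distances"]) == len(preds)


class TestTemporalAndCumulative:
    def test_offsets_are_signed_pred_minus_truth(self):
        r = match_events(events((10, 10, 7)), events((10, 10, 5)))
        np.testing.assert_array_equal(temporal_offsets(r), [2.0])

    def test_identical_curves_correlate_perfectly(self):
        e = events((1, 1, 2), (2, 2, 5), (3, 3, 9))
        assert cumulative_correlation(e, e, T=12) == pytest.approx(1.0)

    def test_zero_variance_curve_is_undefined(self):
        truth = events((1, 1, 2), (2, 2, 5))
        assert np.isnan(cumulative_correlation([], truth, T=8))

    def test_matches_textbook_formula(self, rng):
        pred = [(0, 0, int(t)) for t in rng.integers(0, 30, 12)]
        truth = [(0, 0, int(t)) for t in rng.integers(0, 30, 15)]
        got = cumulative_correlation(pred, truth, T=30)
        from apodetect.pipeline import cumulative_counts
        a = cumulative_counts([t for _, _, t in pred], 30).astype(float)
        b = cumulative_counts([t for _, _, t in truth], 30).astype(float)
        expect = (((a - a.mean()) * (b - b.mean())).sum()
                  / np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()))
        assert got == pytest.approx(expect)


def straight_track(tid, x0, y0, t0, n, dx=2.0):
    return [(tid, t0 + k, x0 + dx * k, y0) for k in range(n)]


class TestTra:
    def test_identical_tracks_score_one(self):
        truth = [straight_track(0, 10, 10, 0, 5), straight_track(1, 60, 60, 2, 6)]
        assert tra_score(truth, truth) == 1.0

    def test_track_ids_are_irrelevant(self):
        truth = [straight_track(0, 10, 10, 0, 5), straight_track(1, 60, 60, 2, 6)]
        relabeled = [straight_track(7, 10, 10, 0, 5), straight_track(3, 60, 60, 2, 6)]
        assert tra_score(relabeled, truth) == 1.0

    def test_empty_prediction_scores_zero(self):
        truth = [straight_track(0, 10, 10, 0, 5)]
        assert tra_score([], truth) == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            tra_score([straight_track(0, 1, 1, 0, 3)], [])

    def test_hand_enumerated_missing_node_case(self):
        """Truth: one 5-node track (4 edges).  Prediction misses the middle
        node, so its 4 nodes carry edges (t0,t1), (t1,t3), (t3,t4).
        Costs: 1 FN node (10) + 2 missing truth edges (2 x 1.5) + 1
        redundant predicted edge (1) = 14; empty cost = 5*10 + 4*1.5 = 56;
        TRA = 1 - 14/56 = 0.75."""
        truth = [straight_track(0, 10, 10, 0, 5)]
        pred = [[(0, t, 10 + 2.0 * t, 10) for t in (0, 1, 3, 4)]]
        assert tra_score(pred, truth) == pytest.approx(1 - 14 / 56)


class TestQualityScore:
    IDEAL = {"cell_count": 11.0, "snr": 12.5, "signal_fluctuation": 0.0,
             "min_cell_distance": 36.6, "saturation": 0.0}
    WORST = {"cell_count": 163.0, "snr": 5.3, "signal_fluctuation": 0.5,
             "min_cell_distance": 5.8, "saturation": 0.2}

    def test_ideal_components_score_one(self):
        score, _ = combine_quality_components(self.IDEAL)
        assert score == 1.0

    def test_worst_components_score_zero(self):
        score, _ = combine_quality_components(self.WORST)
        assert score == 0.0

    def test_more_cells_strictly_lower_the_score(self):
        mid = dict(self.IDEAL, cell_count=60.0)
        worse = dict(mid, cell_count=120.0)
        assert combine_quality_components(worse)[0] < combine_quality_components(mid)[0]

    def test_movie_level_score_in_unit_interval(self):
        from apodetect.synth import SynthConfig, generate
        sm = generate(SynthConfig(H=128, W=128, T=20, n_cells=20, n_apoptoses=3,
                                  seed=2))
        score, parts = video_quality_score(sm.movie)
        assert 0 <= score <= 1
        assert set(parts["normalized"]) == set(self.IDEAL)


class TestEstimateSnr:
    def test_noise_free_blob_hits_the_ceiling(self):
        frames = np.zeros((4, 64, 64), dtype=np.uint8)
        frames[:, 28:36, 28:36] = 200
        assert estimate_snr(Timelapse(frames=frames)) == 100.0

    def test_pure_noise_matches_truncated_normal_oracle(self, rng):
        from scipy import stats
        from skimage.filters import threshold_otsu

        mu, sd = 120.0, 12.0
        frames = np.clip(rng.normal(mu, sd, (6, 128, 128)).round(), 0, 255
                         ).astype(np.uint8)
        got = estimate_snr(Timelapse(frames=frames))
        # oracle: analytic foreground mean / robust background SD for a
        # normal split at the observed threshold
        t = threshold_otsu(frames[np.unique(np.linspace(0, 5, 10).astype(int))]
                           .astype(np.float64).ravel())
        a = (t - mu) / sd
        fg_mean = mu + sd * stats.norm.pdf(a) / stats.norm.sf(a)
        lower = stats.truncnorm(-np.inf, a, loc=mu, scale=sd)
        med = lower.ppf(0.5)
        # MAD of the truncated normal, found numerically
        from scipy.optimize import brentq
        mad = brentq(lambda m: (lower.cdf(med + m) - lower.cdf(med - m)) - 0.5,
                     1e-6, 5 * sd)
        expect = fg_mean / (1.4826 * mad)
        assert got == pytest.approx(expect, rel=0.1)

    def test_constant_movie_has_no_signal(self):
        frames = np.full((3, 32, 32), 7, dtype=np.uint8)
        assert estimate_snr(Timelapse(frames=frames)) == 0.0
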