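"""Discriminant training, reports, duration constraints, stream detection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neuroloop.classifier import (EVENT, NON_EVENT, DurationConstraints,
                                  DetectorPhase, LabeledSegment,
                                  LinearBoundary, apply_duration_constraints,
                                  cross_validate, detect_stream,
                                  margin_histogram, roc, train_fisher)


def _gauss_segments(rng, mean, n, label, cov=None):
    cov = np.eye(len(mean)) if cov is None else cov
    x = rng.multivariate_normal(mean, cov, size=n)
    return LabeledSegment(x, label)


class TestTrainFisher:
    def test_isotropic_case_recovers_symmetric_direction(self, rng):
        ev = _gauss_segments(rng, [10, 10], 400, EVENT)
        ne = _gauss_segments(rng, [0, 0], 400, NON_EVENT)
        b = train_fisher([ev], [ne])
        w = b.weights / np.linalg.norm(b.weights)
        assert w == pytest.approx([1 / np.sqrt(2)] * 2, abs=0.05)
        assert b.margin(np.array([10.0, 10.0])) > 0
        assert b.margin(np.array([0.0, 0.0])) < 0

    def test_direction_matches_angular_grid_oracle(self, rng):
        # brute-force maximization of the Fisher ratio over directions
        cov = np.array([[2.0, 1.2], [1.2, 1.5]])
        x1 = rng.multivariate_normal([3, 1], cov, size=30)
        x0 = rng.multivariate_normal([0, 0], cov, size=30)
        b = train_fisher([LabeledSegment(x1, EVENT)],
                         [LabeledSegment(x0, NON_EVENT)], ridge=1e-6)

        def fisher_ratio(w):
            m1, m0 = x1.mean(0), x0.mean(0)
            sw = ((x1 - m1).T @ (x1 - m1)) + ((x0 - m0).T @ (x0 - m0))
            num = float(w @ (m1 - m0)) ** 2
            return num / float(w @ sw @ w)

        angles = np.linspace(0, np.pi, 20001)
        best = max(fisher_ratio(np.array([np.cos(a), np.sin(a)]))
                   for a in angles)
        assert fisher_ratio(b.weights) == pytest.approx(best, rel=0.01)

    def test_matches_sklearn_lda_direction(self, rng):
        # independent implementation cross-check
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis").LinearDiscriminantAnalysis
        x1 = rng.multivariate_normal([5, 2], np.eye(2), size=200)
        x0 = rng.multivariate_normal([0, 0], np.eye(2), size=200)
        b = train_fisher([LabeledSegment(x1, EVENT)],
                         [LabeledSegment(x0, NON_EVENT)], ridge=1e-9)
        lda = sklearn_lda(solver="eigen").fit(
            np.vstack([x1, x0]), [1] * 200 + [0] * 200)
        w_ours = b.weights / np.linalg.norm(b.weights)
        w_ref = lda.coef_.ravel() / np.linalg.norm(lda.coef_)
        assert abs(float(w_ours @ w_ref)) == pytest.approx(1.0, abs=1e-3)

    def test_plant_fixture_fully_separated(self, ad_classifier):
        boundary, _, ev_segs, ne_segs = ad_classifier
        for s in ev_segs:
            assert (boundary.margin(s.usable) > 0).all()
        for s in ne_segs:
            assert (boundary.margin(s.usable) < 0).all()

    def test_empty_class_rejected(self, rng):
        ne = _gauss_segments(rng, [0, 0], 10, NON_EVENT)
        with pytest.raises(ValueError):
            train_fisher([], [ne])

    def test_discard_mask_excluded_from_training(self):
        # poisoned samples behind the mask must not influence the boundary
        x1 = np.array([[10.0, 10.0]] * 20 + [[-100.0, -100.0]] * 5)
        mask = np.array([False] * 20 + [True] * 5)
        x0 = np.array([[0.0, 0.0]] * 20)
        b = train_fisher([LabeledSegment(x1, EVENT, discard_mask=mask)],
                         [LabeledSegment(x0, NON_EVENT)])
        assert b.margin(np.array([10.0, 10.0])) > 0

    def test_serialization_round_trip(self, ad_classifier):
        boundary = ad_classifier[0]
        again = LinearBoundary.from_json(boundary.to_json())
        assert np.array_equal(again.weights, boundary.weights)
        assert again.bias == boundary.bias
        assert again.feature_labels == boundary.feature_labels


class TestReports:
    def test_histogram_zero_overlap_when_separated(self, rng):
        ev = _gauss_segments(rng, [20, 20], 300, EVENT)
        ne = _gauss_segments(rng, [0, 0], 300, NON_EVENT)
        b = train_fisher([ev], [ne])
        h = margin_histogram(b, [ev, ne])
        assert int(h[EVENT].sum()) == 300 and int(h[NON_EVENT].sum()) == 300
        assert not np.any((h[EVENT] > 0) & (h[NON_EVENT] > 0))

    def test_plant_fixture_margin_overlap_below_1pct(self, ad_classifier):
        boundary, _, ev_segs, ne_segs = ad_classifier
        h = margin_histogram(boundary, ev_segs + ne_segs)
        overlap = int(np.minimum(h[EVENT], h[NON_EVENT]).sum())
        total = int(h[EVENT].sum() + h[NON_EVENT].sum())
        assert overlap < 0.01 * total

    def test_roc_endpoints_and_monotonicity(self, rng):
        ev = _gauss_segments(rng, [2, 0], 500, EVENT)
        ne = _gauss_segments(rng, [0, 0], 500, NON_EVENT)
        b = train_fisher([ev], [ne])
        table = roc(b, [ev, ne],
                    thresholds=np.concatenate(([-np.inf],
                                               np.linspace(-20, 20, 81),
                                               [np.inf])))
        assert table.tp_pct.iloc[0] == 100 and table.fp_pct.iloc[0] == 100
        assert table.tp_pct.iloc[-1] == 0 and table.fp_pct.iloc[-1] == 0
        assert (np.diff(table.tp_pct) <= 0).all()
        assert (np.diff(table.fp_pct) <= 0).all()

    def test_uninformative_margins_give_chance_auc(self, rng):
        # identical class distributions: ROC area ~ 0.5
        ev = _gauss_segments(rng, [0, 0], 1000, EVENT)
        ne = _gauss_segments(rng, [0, 0], 1000, NON_EVENT)
        b = LinearBoundary(weights=np.array([1.0, 0.5]), bias=0.0)
        table = roc(b, [ev, ne])
        auc = -np.trapezoid(table.tp_pct / 100, table.fp_pct / 100)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_cross_validation_close_to_training(self, ad_classifier):
        boundary, _, ev_segs, ne_segs = ad_classifier
        cv = cross_validate(ev_segs, ne_segs, k=5, seed=0)
        assert cv["sensitivity_pct"] >= 95.0
        assert cv["specificity_pct"] >= 95.0

    def test_suppression_vs_resting_cross_validated(self):
        from neuroloop.session import train_suppression_classifier
        _, ev, ne = train_suppression_classifier(seed=0)
        cv = cross_validate(ev, ne, k=5, seed=1)
        acc = (cv["sensitivity_pct"] + cv["specificity_pct"]) / 2
        assert acc > 95.0


class TestDurationConstraints:
    def test_assertion_index_forced_by_onset_count(self):
        phases, asserts = apply_duration_constraints(
            [1, 1, 0, 1, 1, 1], DurationConstraints(onset_count=3))
        assert asserts == [5]
        assert phases[0] is DetectorPhase.PRE_DETECTION
        assert phases[2] is DetectorPhase.IDLE

    def test_onset_one_asserts_on_first_event_sample(self):
        decisions = [0] * 10 + [1] * 5
        _, asserts = apply_duration_constraints(
            decisions, DurationConstraints(onset_count=1))
        # one 5 Hz sample after the last non-event sample = 200 ms
        assert asserts == [10]
        assert asserts[0] / 5.0 - 9 / 5.0 == pytest.approx(0.2)

    def test_singleton_spikes_filtered(self):
        decisions = [0, 1, 0, 0, 1, 0, 1, 0]
        _, asserts = apply_duration_constraints(
            decisions, DurationConstraints(onset_count=2))
        assert asserts == []

    def test_termination_hysteresis(self):
        c = DurationConstraints(onset_count=1, termination_count=3)
        phases, asserts = apply_duration_constraints(
            [1, 0, 0, 1, 0, 0, 0, 1], c)
        assert asserts == [0, 7]  # short gaps do not clear; 3 zeros do
        assert phases[6] is DetectorPhase.IDLE

    @given(st.lists(st.booleans(), max_size=60),
           st.integers(1, 4), st.integers(1, 4))
    def test_never_more_detections_than_raw_runs_nor_earlier(
            self, decisions, onset, term):
        c = DurationConstraints(onset_count=onset, termination_count=term)
        _, asserts = apply_duration_constraints(decisions, c)
        arr = np.array(decisions, dtype=bool)
        raw_run_starts = int(np.sum(np.diff(
            np.concatenate(([False], arr)).astype(int)) == 1))
        assert len(asserts) <= raw_run_starts
        if asserts:
            first_event = int(np.argmax(arr))
            assert asserts[0] >= first_event


class TestDetectStream:
    def test_single_ad_episode_detected_near_onset(self, ad_classifier):
        from neuroloop.plant import Plant, StimInput, STIM_OFF
        from neuroloop.session import _SensedChain, _power_features
        boundary, constraints, _, _ = ad_classifier
        plant = Plant(seed=42)
        chain = _SensedChain(plant.params, np.random.default_rng(43))
        pre = _power_features(plant, chain, STIM_OFF, 10.0)
        t_onset = plant.clock
        during = _power_features(plant, chain, StimInput(True, 1.8), 6.0)
        feats = np.vstack([pre, during])
        events, trace = detect_stream(boundary, constraints, feats)
        assert len(events) == 1
        assert abs(events[0].onset_t - t_onset) <= 0.6

    def test_all_resting_stream_no_detections(self, ad_classifier):
        from neuroloop.plant import Plant, STIM_OFF
        from neuroloop.session import _SensedChain, _power_features
        boundary, constraints, _, _ = ad_classifier
        plant = Plant(seed=44)
        chain = _SensedChain(plant.params, np.random.default_rng(45))
        feats = _power_features(plant, chain, STIM_OFF, 120.0)
        events, _ = detect_stream(boundary, constraints, feats)
        assert events == []

    def test_constant_event_input_asserts_once(self, ad_classifier):
        boundary, constraints, _, _ = ad_classifier
        feats = np.tile([900.0, 10.0], (50, 1))
        events, trace = detect_stream(boundary, constraints, feats)
        assert len(events) == 1
        assert events[0].clear_t is None  # never cleared

    def test_dimensionality_mismatch_rejected(self, ad_classifier):
        boundary, constraints, _, _ = ad_classifier
        with pytest.raises(ValueError):
            detect_stream(boundary, constraints, np.zeros((10, 3)))
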