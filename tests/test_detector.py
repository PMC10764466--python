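"""High-chaos detector: class grouping, pruning rules, candidate logic."""

import numpy as np
import pandas as pd
import pytest

from chaosaudio import classmap
from chaosaudio.detector import (
    ClassMapError,
    build_group_map,
    detect_high_chaos,
    evaluate_detector,
    filter_topk_confidence,
    prune_cry_babble,
    prune_whitenoise_vehicle,
    run_detector,
)
from chaosaudio.features import FrameSeries, ParticipantStats, frame_rmse

from conftest import SR, make_segment


def preds(*pairs):
    return pd.DataFrame(
        [{"segment_id": "P1:0", "class_name": c, "confidence": v} for c, v in pairs]
    )


@pytest.fixture(scope="module")
def gmap():
    return build_group_map(classmap.default_class_table())


STATS = ParticipantStats("P1", mean_rmse=0.05)


class TestGroupMap:
    def test_low_quality_class_absent(self, gmap):
        assert "Battle cry" not in gmap.group  # quality 0.30 <= 33% threshold

    def test_excluded_class_absent(self, gmap):
        assert "Eruption" not in gmap.group

    def test_children_shouting_mapped_high(self, gmap):
        assert gmap.group["Children shouting"] == "high"
        assert gmap.is_high("Screaming")

    def test_white_noise_mapped_non_high(self, gmap):
        assert gmap.group["White noise"] == "non_high"

    def test_empty_table_gives_empty_map(self):
        empty = classmap.default_class_table().iloc[0:0]
        assert len(build_group_map(empty)) == 0

    def test_missing_group_assignment_names_class(self):
        df = classmap.default_class_table().copy()
        df.loc[df["class_name"] == "Piano", "chaos_group"] = "???"
        with pytest.raises(ClassMapError, match="Piano"):
            build_group_map(df)

    def test_quality_threshold_boundary_is_exclusive(self):
        df = pd.DataFrame(
            {
                "class_name": ["A", "B"],
                "quality_estimate": [0.33, 0.34],
                "excluded": [False, False],
                "chaos_group": ["high", "high"],
            }
        )
        m = build_group_map(df)
        assert "A" not in m.group and "B" in m.group


class TestTopKFilter:
    def test_fifteen_predictions_cut_to_top_ten(self):
        p = preds(*[(f"c{i}", 0.01 * (i + 1)) for i in range(15)])
        out = filter_topk_confidence(p)
        assert len(out) == 10
        assert out["confidence"].is_monotonic_decreasing
        assert out["confidence"].min() == pytest.approx(0.06)

    def test_confidence_below_floor_dropped(self):
        out = filter_topk_confidence(preds(("a", 5e-5), ("b", 2e-4)))
        assert out["class_name"].tolist() == ["b"]

    def test_floor_is_inclusive(self):
        out = filter_topk_confidence(preds(("a", 1e-4)))
        assert len(out) == 1

    def test_empty_input_empty_output(self):
        assert filter_topk_confidence(preds()).empty if len(preds()) else True
        empty = pd.DataFrame(columns=["segment_id", "class_name", "confidence"])
        assert filter_topk_confidence(empty).empty


class TestCryBabblePruning:
    CRY, BABBLE = classmap.CRY_CLASS, classmap.BABBLE_CLASS

    def test_loud_segment_keeps_cry_drops_babble(self, gmap):
        p = preds((self.CRY, 0.6), (self.BABBLE, 0.5), ("Speech", 0.2))
        rmse = FrameSeries("rmse", np.full(431, 0.04).clip(None).copy())
        rmse.values[10] = 4 * STATS.mean_rmse  # > 3x participant mean
        out = prune_cry_babble(p, rmse, STATS, gmap)
        assert self.BABBLE not in set(out["class_name"])
        assert self.CRY in set(out["class_name"])

    def test_quiet_segment_keeps_babble_drops_cry(self, gmap):
        p = preds((self.CRY, 0.6), (self.BABBLE, 0.5))
        rmse = FrameSeries("rmse", np.full(431, 2 * STATS.mean_rmse))
        out = prune_cry_babble(p, rmse, STATS, gmap)
        assert self.CRY not in set(out["class_name"])
        assert self.BABBLE in set(out["class_name"])

    def test_cry_alone_unchanged(self, gmap):
        p = preds((self.CRY, 0.6), ("Speech", 0.2))
        rmse = FrameSeries("rmse", np.full(431, 0.01))
        out = prune_cry_babble(p, rmse, STATS, gmap)
        assert set(out["class_name"]) == {self.CRY, "Speech"}

    def test_missing_stats_rejected(self, gmap):
        p = preds((self.CRY, 0.6), (self.BABBLE, 0.5))
        with pytest.raises(ValueError):
            prune_cry_babble(p, np.full(431, 0.1), None, gmap)

    def test_threshold_is_strictly_greater_than_three_times(self, gmap):
        p = preds((self.CRY, 0.6), (self.BABBLE, 0.5))
        rmse = FrameSeries("rmse", np.full(431, 3.0 * STATS.mean_rmse))
        out = prune_cry_babble(p, rmse, STATS, gmap)  # exactly 3x is not loud
        assert self.CRY not in set(out["class_name"])


class TestWhiteNoiseVehiclePruning:
    def test_vehicle_on_white_noise_segment_removed(self, gmap, rng):
        seg = make_segment(rng.normal(0, 0.2, SR * 5).clip(-1, 1))
        from chaosaudio.features import spectral_flatness_series, zero_crossings

        flat = spectral_flatness_series(seg)
        assert np.all(flat.values > 1e-4)  # the white-noise signature
        p = preds(("Vehicle", 0.7), ("Speech", 0.3))
        out = prune_whitenoise_vehicle(p, flat, zero_crossings(seg), gmap)
        assert "Vehicle" not in set(out["class_name"])
        assert "Speech" in set(out["class_name"])

    def test_vehicle_on_pure_tone_kept(self, gmap):
        t = np.arange(SR * 5) / SR
        seg = make_segment(0.4 * np.sin(2 * np.pi * 5000.0 * t))
        from chaosaudio.features import spectral_flatness_series, zero_crossings

        flat = spectral_flatness_series(seg)
        zc = zero_crossings(seg)  # ~50,000 — far outside [1000, 4000]
        assert not (1000 <= zc <= 4000)
        p = preds(("Vehicle", 0.7))
        out = prune_whitenoise_vehicle(p, flat, zc, gmap)
        assert "Vehicle" in set(out["class_name"])

    def test_zero_crossing_band_alone_triggers_drop(self, gmap):
        # a 300 Hz tone has ~3000 crossings in 5 s: inside [1000, 4000]
        t = np.arange(SR * 5) / SR
        seg = make_segment(0.4 * np.sin(2 * np.pi * 300.0 * t))
        from chaosaudio.features import spectral_flatness_series, zero_crossings

        zc = zero_crossings(seg)
        assert 1000 <= zc <= 4000
        out = prune_whitenoise_vehicle(
            preds(("Car", 0.6)), spectral_flatness_series(seg), zc, gmap
        )
        assert out.empty

    def test_non_vehicle_predictions_untouched_on_noise(self, gmap):
        flat = FrameSeries("spectral_flatness", np.full(431, 0.5))
        out = prune_whitenoise_vehicle(preds(("Speech", 0.5)), flat, 2000, gmap)
        assert set(out["class_name"]) == {"Speech"}

    def test_drop_segment_reading_empties_predictions(self, gmap):
        flat = FrameSeries("spectral_flatness", np.full(431, 0.5))
        p = preds(("Vehicle", 0.7), ("Speech", 0.3))
        out = prune_whitenoise_vehicle(p, flat, 2000, gmap, drop_segment=True)
        assert out.empty


class TestCandidateSelection:
    def test_screaming_triggers_high_group(self, gmap):
        res = detect_high_chaos(preds(("Screaming", 0.8)), None, None, gmap)
        assert res.is_candidate and res.trigger == "high_group_class"

    def test_loudness_override_without_high_predictions(self, gmap):
        rmse = FrameSeries("rmse", np.full(431, 0.01))
        rmse.values[100] = 8 * STATS.mean_rmse
        res = detect_high_chaos(preds(("Speech", 0.9)), rmse, STATS, gmap)
        assert res.is_candidate and res.trigger == "loudness_override"

    def test_quiet_white_noise_not_a_candidate(self, gmap):
        rmse = FrameSeries("rmse", np.full(431, 0.01))
        res = detect_high_chaos(preds(("White noise", 0.9)), rmse, STATS, gmap)
        assert not res.is_candidate and res.trigger == "none"

    def test_override_applies_to_empty_prediction_set(self, gmap):
        empty = pd.DataFrame(columns=["segment_id", "class_name", "confidence"])
        rmse = FrameSeries("rmse", np.full(431, 8 * STATS.mean_rmse))
        res = detect_high_chaos(empty, rmse, STATS, gmap)
        assert res.is_candidate and res.trigger == "loudness_override"

    def test_exactly_seven_times_mean_is_not_loud_enough(self, gmap):
        rmse = FrameSeries("rmse", np.full(431, 7.0 * STATS.mean_rmse))
        res = detect_high_chaos(preds(("Speech", 0.5)), rmse, STATS, gmap)
        assert not res.is_candidate

    def test_adding_high_group_prediction_never_unflags(self, gmap, rng):
        """Monotonicity: a high-group prediction can only add candidacy."""
        names = list(gmap.group)
        for _ in range(25):
            k = int(rng.integers(0, 6))
            chosen = rng.choice(names, size=k, replace=False) if k else []
            base = preds(*[(c, float(rng.uniform(0.01, 0.9))) for c in chosen])
            before = detect_high_chaos(base, None, None, gmap).is_candidate
            augmented = pd.concat(
                [base, preds(("Screaming", 0.5))], ignore_index=True
            )
            after = detect_high_chaos(augmented, None, None, gmap).is_candidate
            assert after >= before
            assert after  # the added high-group class always flags

    def test_pruning_never_increases_prediction_count(self, gmap, rng):
        seg = make_segment(rng.normal(0, 0.2, SR * 5).clip(-1, 1))
        rmse = frame_rmse(seg)
        from chaosaudio.features import spectral_flatness_series, zero_crossings

        flat, zc = spectral_flatness_series(seg), zero_crossings(seg)
        p = preds(
            ("Vehicle", 0.7), (classmap.CRY_CLASS, 0.6), (classmap.BABBLE_CLASS, 0.5),
            ("Speech", 0.4), *[(f"x{i}", 0.001 * (i + 1)) for i in range(12)],
        )
        f1 = filter_topk_confidence(p)
        assert len(f1) <= 10 <= len(p)
        f2 = prune_cry_babble(f1, rmse, STATS, gmap)
        assert len(f2) <= len(f1)
        f3 = prune_whitenoise_vehicle(f2, flat, zc, gmap)
        assert len(f3) <= len(f2)


class TestEfficiencyEvaluation:
    @staticmethod
    def _results(ids, flagged):
        return pd.DataFrame(
            {"segment_id": ids, "is_candidate": flagged, "trigger": "high_group_class"}
        )

    def test_printed_enrichment_example(self):
        """Candidate high rate 16.8% vs random 2.02% -> enrichment 8.32."""
        n = 10_000
        ids = [f"s{i}" for i in range(n)]
        truth = {s: 0 for s in ids}
        cand = ids[:1000]
        for s in cand[:168]:
            truth[s] = 3  # 16.8% of candidates truly high
        rand = ids[1000:1990]
        for s in rand[:20]:
            truth[s] = 3  # 20/990 = 2.02%
        flagged = [s in set(cand) for s in ids]
        rep = evaluate_detector(self._results(ids, flagged), truth, rand)
        assert rep.candidate_high_rate == pytest.approx(0.168)
        assert rep.random_high_rate == pytest.approx(0.0202, abs=1e-4)
        assert rep.enrichment == pytest.approx(8.32, abs=0.01)

    def test_candidate_set_equal_to_random_set_enrichment_one(self):
        ids = [f"s{i}" for i in range(100)]
        truth = {s: (3 if i < 10 else 1) for i, s in enumerate(ids)}
        rep = evaluate_detector(
            self._results(ids, [i < 50 for i in range(100)]), truth, ids[:50]
        )
        assert rep.enrichment == pytest.approx(1.0)

    def test_empty_candidate_set_flagged(self):
        ids = ["a", "b"]
        rep = evaluate_detector(
            self._results(ids, [False, False]), {"a": 3, "b": 0}, ["a"]
        )
        assert np.isnan(rep.precision)
        assert "empty_candidate_set" in rep.flags

    def test_recall_precision_on_known_split(self):
        ids = [f"s{i}" for i in range(10)]
        truth = dict(zip(ids, [3, 3, 3, 3, 0, 0, 0, 0, 0, 0]))
        flagged = [True, True, False, False, True, False, False, False, False, False]
        rep = evaluate_detector(self._results(ids, flagged), truth)
        assert rep.recall == pytest.approx(0.5)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.candidate_fraction == pytest.approx(0.3)


class TestBayesConsistency:
    def test_recall_and_precision_follow_error_model(self):
        """Prediction-only detection: recall = 1-m; precision Bayes-consistent."""
        from chaosaudio.synthetic import PredictionNoiseSpec, generate_prediction_table, generate_recording

        m, f, p = 0.2, 0.05, 0.1
        gmap = build_group_map(classmap.default_class_table())
        recs, precs = [], []
        for seed in range(5):
            rec = generate_recording("P1", 2.0, (0.3, 0.3, 0.3, p), 100 + seed)
            noise = PredictionNoiseSpec(m, f, 0.0, 0.0, seed=seed)
            table = generate_prediction_table(rec, noise)
            res = run_detector(table, gmap, segment_ids=rec.segment_ids)
            truth = dict(zip(rec.segment_ids, map(int, rec.labels)))
            rep = evaluate_detector(res, truth)
            recs.append(rep.recall)
            precs.append(rep.precision)
        expected_precision = p * (1 - m) / (p * (1 - m) + (1 - p) * f)
        assert np.mean(recs) == pytest.approx(1 - m, abs=0.05)
        assert np.mean(precs) == pytest.approx(expected_precision, abs=0.05)
        for r, q in zip(recs, precs):
            assert r == pytest.approx(1 - m, abs=0.12)
            assert q == pytest.approx(expected_precision, abs=0.12)
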