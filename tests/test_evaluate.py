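"""Metric formulas against brute-force oracles, LOSO fold properties,
and end-to-end orchestration (leakage, determinism, report structure)."""

import json
import math

import numpy as np
import pytest

from nfspeech.corpus_io import Dataset, MedState, Transcript, write_report
from nfspeech.evaluate import (
    ApproachConfig,
    calibration_metrics,
    classification_metrics,
    make_loso_folds,
    regression_metrics,
    run_approach,
)


from oracles import brute_auc, brute_confusion_metrics, brute_percentile, brute_spearman

# --- fold plan -----------------------------------------------------------

class TestLosoFolds:
    def test_paired_cohort_fold_shape(self, cohort):
        plan = make_loso_folds(cohort)
        assert len(plan.folds) == 33
        for fold in plan.folds:
            assert len(fold.test_recording_ids) == 2
            assert len(fold.train_recording_ids) == 64

    def test_folds_partition_all_recordings(self, cohort):
        plan = make_loso_folds(cohort)
        seen = [rid for f in plan.folds for rid in f.test_recording_ids]
        assert sorted(seen) == sorted(t.recording_id for t in cohort)
        for fold in plan.folds:
            assert not set(fold.test_recording_ids) & set(fold.train_recording_ids)

    def test_single_patient_fold_is_degenerate(self):
        ds = Dataset([Transcript("p1", "r1", MedState.ON, "hello there")])
        plan = make_loso_folds(ds)
        assert len(plan.folds) == 1
        assert plan.folds[0].degenerate


# --- classification metrics ----------------------------------------------

class TestClassificationMetrics:
    def test_perfect_predictions(self):
        rep = classification_metrics(["ON", "OFF"] * 5, ["ON", "OFF"] * 5)
        assert rep.accuracy == 1.0
        assert rep.f1_macro == 1.0

    def test_separated_confidences_auc_one(self):
        truth = ["ON"] * 5 + ["OFF"] * 5
        conf = [0.9] * 5 + [0.1] * 5
        rep = classification_metrics(truth, truth, confidence_on=conf)
        assert rep.auc == pytest.approx(1.0)

    def test_constant_confidence_auc_half(self):
        truth = ["ON"] * 5 + ["OFF"] * 5
        rep = classification_metrics(truth, truth, confidence_on=[0.5] * 10)
        assert rep.auc == pytest.approx(0.5)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            truth = ["ON" if rng.random() < 0.5 else "OFF" for _ in range(n)]
            if len(set(truth)) < 2:
                truth[0] = "ON" if truth[0] == "OFF" else "OFF"
            pred = ["ON" if rng.random() < 0.5 else "OFF" for _ in range(n)]
            conf = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n).tolist()
            rep = classification_metrics(truth, pred, confidence_on=conf)
            acc, prec, rec, f1 = brute_confusion_metrics(truth, pred)
            assert rep.accuracy == pytest.approx(acc, abs=1e-9)
            assert rep.precision_macro == pytest.approx(prec, abs=1e-9)
            assert rep.recall_macro == pytest.approx(rec, abs=1e-9)
            assert rep.f1_macro == pytest.approx(f1, abs=1e-9)
            assert rep.auc == pytest.approx(brute_auc(truth, conf), abs=1e-9)

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(32)
        truth = ["ON" if rng.random() < 0.5 else "OFF" for _ in range(40)]
        truth[0], truth[1] = "ON", "OFF"
        conf = rng.random(40).tolist()
        rep = classification_metrics(truth, truth, confidence_on=conf)
        fprs = [p[0] for p in rep.roc_points]
        tprs = [p[1] for p in rep.roc_points]
        assert fprs == sorted(fprs)
        assert tprs == sorted(tprs)


# --- regression metrics ---------------------------------------------------

class TestRegressionMetrics:
    def test_identity_prediction(self):
        y = [10.0, 20.0, 30.0, 40.0]
        rep = regression_metrics(y, y)
        assert rep.rmse == 0.0
        assert rep.mae == 0.0
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.r2 == pytest.approx(1.0)

    def test_anticorrelated_extremes(self):
        rep = regression_metrics([0.0, 60.0], [60.0, 0.0])
        assert rep.mae == pytest.approx(60.0)
        assert rep.spearman_rho == pytest.approx(-1.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(33)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            y = rng.uniform(0, 60, n)
            p = rng.uniform(0, 60, n)
            states = ["ON" if rng.random() < 0.5 else "OFF" for _ in range(n)]
            rep = regression_metrics(y, p, states=states)
            err = np.abs(y - p)
            assert rep.rmse == pytest.approx(math.sqrt(np.mean((y - p) ** 2)), abs=1e-9)
            assert rep.mae == pytest.approx(err.mean(), abs=1e-9)
            assert rep.mae_std == pytest.approx(float(np.std(err, ddof=1)), abs=1e-9)
            assert rep.median_ae == pytest.approx(brute_percentile(err, 0.5), abs=1e-9)
            assert rep.q1_ae == pytest.approx(brute_percentile(err, 0.25), abs=1e-9)
            assert rep.q3_ae == pytest.approx(brute_percentile(err, 0.75), abs=1e-9)
            assert rep.spearman_rho == pytest.approx(brute_spearman(y, p), abs=1e-9)
            assert rep.r2 == pytest.approx(
                1 - np.sum((y - p) ** 2) / np.sum((y - y.mean()) ** 2), abs=1e-9
            )
            for state in ("ON", "OFF"):
                mask = np.array([s == state for s in states])
                if mask.any():
                    assert rep.per_state_mae[state] == pytest.approx(err[mask].mean(), abs=1e-9)
            assert rep.rmse >= rep.mae - 1e-12
            assert rep.q1_ae <= rep.median_ae <= rep.q3_ae

    def test_constant_truth_flags_degenerate(self):
        rep = regression_metrics([30.0, 30.0, 30.0], [10.0, 30.0, 50.0])
        assert rep.degenerate
        assert rep.r2 is None
        assert rep.mae == pytest.approx(40.0 / 3)


# --- calibration ----------------------------------------------------------

class TestCalibrationMetrics:
    def test_perfectly_confident_and_correct(self):
        rep = calibration_metrics([1.0] * 8, ["ON"] * 8)
        assert (rep.brier, rep.ece, rep.mce) == (0.0, 0.0, 0.0)

    def test_perfectly_confident_and_wrong(self):
        rep = calibration_metrics([1.0] * 8, ["OFF"] * 8)
        assert (rep.brier, rep.ece, rep.mce) == (1.0, 1.0, 1.0)

    def test_constructed_two_bin_example(self):
        conf = [0.9] * 10 + [0.1] * 10
        truth = ["ON"] * 5 + ["OFF"] * 5 + ["OFF"] * 10
        rep = calibration_metrics(conf, truth, n_bins=10)
        assert rep.ece == pytest.approx(0.25)
        assert rep.mce == pytest.approx(0.4)

    def test_ece_never_exceeds_mce(self):
        rng = np.random.default_rng(34)
        for _ in range(50):
            n = int(rng.integers(3, 60))
            conf = rng.random(n)
            truth = ["ON" if rng.random() < 0.5 else "OFF" for _ in range(n)]
            rep = calibration_metrics(conf, truth)
            assert rep.ece <= rep.mce + 1e-12
            assert sum(c for _, _, c in rep.bins) == n

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibration_metrics([], [])


# --- orchestration --------------------------------------------------------

class TestRunApproach:
    def test_semsearch_report_structure(self, small_cohort):
        preds, rep = run_approach("semsearch", small_cohort, ApproachConfig())
        assert rep.classification is not None
        assert rep.regression is not None
        assert rep.calibration is not None
        assert rep.item_frequency is not None
        assert not rep.failed_folds
        assert rep.n_predictions == len(small_cohort)

    def test_item_profile_poles_align_with_states(self, cohort):
        # ON-pole items dominate voters of ON recordings and vice versa
        _, rep = run_approach("semsearch", cohort, ApproachConfig())
        profile = rep.item_frequency
        on_mass = sum(v for iid, v in profile["ON"].items() if iid <= 10)
        off_mass = sum(v for iid, v in profile["OFF"].items() if iid > 10)
        assert on_mass > 0.5
        assert off_mass > 0.5

    def test_no_patient_leakage_in_retrieval(self, small_cohort):
        for approach in ("semsearch", "llm"):
            preds, _ = run_approach(approach, small_cohort, ApproachConfig())
            rec_to_patient = {t.recording_id: t.patient_id for t in small_cohort}
            for p in preds:
                for key in ("neighbour_ids", "example_ids", "regress_example_ids"):
                    for rid in p.detail.get(key, []):
                        assert rec_to_patient[rid] != p.patient_id

    def test_predicted_scores_within_scale(self, small_cohort):
        for approach in ("semsearch", "llm"):
            preds, _ = run_approach(approach, small_cohort, ApproachConfig())
            for p in preds:
                assert p.pred_score is None or 0.0 <= p.pred_score <= 60.0

    def test_repeated_run_reports_identical_bytes(self, small_cohort, tmp_path):
        blobs = []
        for i in range(2):
            _, rep = run_approach("llm", small_cohort, ApproachConfig())
            path = tmp_path / f"r{i}.json"
            write_report(rep, path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]

    def test_unknown_approach_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown approach"):
            run_approach("deep", small_cohort, ApproachConfig())

    def test_ml_approach_runs_and_reports(self, small_cohort):
        config = ApproachConfig(classify_family="gaussian_nb", regress_family="ridge")
        preds, rep = run_approach("ml", small_cohort, config)
        assert rep.classification is not None
        assert rep.regression is not None
        for p in preds:
            assert 0.0 <= p.p_on <= 1.0
            assert 0.0 <= p.pred_score <= 60.0
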