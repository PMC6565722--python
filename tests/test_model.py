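"""Perturbed targets, bagged-tree training, LOSO and personal calibration."""
import numpy as np
import pandas as pd
import pytest

from ppgbp import model as mdl
from ppgbp import pipeline as pl
from ppgbp.config import PipelineConfig
from ppgbp.exceptions import CalibrationError, PredictionError


class TestPerturbTargets:
    def test_all_draws_inside_band(self):
        y = mdl.perturb_targets(130.0, 30, rng=1)
        assert y.shape == (30,)
        assert np.all((y >= 129.5) & (y <= 130.5))

    def test_deterministic_given_seed(self):
        assert mdl.perturb_targets(120.0, 1, rng=42)[0] == mdl.perturb_targets(120.0, 1, rng=42)[0]

    def test_mean_matches_uniform_moments(self):
        n = 100_000
        y = mdl.perturb_targets(130.0, n, rng=3)
        se = (1.0 / np.sqrt(12)) / np.sqrt(n)  # sd of U(-0.5, 0.5) over sqrt(n)
        assert abs(y.mean() - 130.0) < 3 * se

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            mdl.perturb_targets(130.0, 0)


@pytest.fixture(scope="module")
def processed(small_cohort, cfg):
    acc, _ = pl.process_dataset(
        small_cohort.records, small_cohort.biometrics(), small_cohort.references(), cfg
    )
    assert len(acc) >= 12
    return acc


@pytest.fixture(scope="module")
def loso_result(processed, cfg):
    return mdl.loso_validate(processed, cfg)


class TestTraining:
    def test_constant_targets_give_constant_model(self, processed, cfg):
        ppg_b, sd_b = mdl.fit_fold_bases(processed, cfg)
        ts = mdl.build_training_set(processed, ppg_b, sd_b, cfg)
        ts = mdl.TrainingSet(
            ts.X, np.full_like(ts.y_sbp, 120.0), np.full_like(ts.y_dbp, 80.0),
            ts.measurement_ids, ts.subject_ids, ts.beat_ordinals,
        )
        with pytest.warns(UserWarning, match="degenerate"):
            est = mdl.train(ts, ppg_b, sd_b, cfg)
        p = mdl.predict(est, processed[0], cfg)
        assert p.test_sbp == pytest.approx(120.0)
        assert p.test_dbp == pytest.approx(80.0)

    def test_row_order_insensitive(self, processed, cfg):
        ppg_b, sd_b = mdl.fit_fold_bases(processed, cfg)
        ts = mdl.build_training_set(processed, ppg_b, sd_b, cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ts.X.shape[0])
        ts_perm = mdl.TrainingSet(
            ts.X[perm], ts.y_sbp[perm], ts.y_dbp[perm],
            ts.measurement_ids[perm], ts.subject_ids[perm], ts.beat_ordinals[perm],
        )
        e1 = mdl.train(ts, ppg_b, sd_b, cfg)
        e2 = mdl.train(ts_perm, ppg_b, sd_b, cfg)
        p1 = mdl.predict(e1, processed[0], cfg)
        p2 = mdl.predict(e2, processed[0], cfg)
        assert p1.test_sbp == p2.test_sbp and p1.test_dbp == p2.test_dbp

    def test_perturbed_targets_within_half_mmhg(self, processed, cfg):
        ppg_b, sd_b = mdl.fit_fold_bases(processed, cfg)
        ts = mdl.build_training_set(processed, ppg_b, sd_b, cfg)
        refs = {m.measurement_id: (m.ref_sbp, m.ref_dbp) for m in processed}
        for mid in np.unique(ts.measurement_ids):
            sel = ts.measurement_ids == mid
            assert sel.sum() == cfg.beats_selected
            assert np.all(np.abs(ts.y_sbp[sel] - refs[mid][0]) <= 0.5)
            assert np.all(np.abs(ts.y_dbp[sel] - refs[mid][1]) <= 0.5)

    def test_save_load_roundtrip(self, processed, cfg, tmp_path):
        ppg_b, sd_b = mdl.fit_fold_bases(processed, cfg)
        ts = mdl.build_training_set(processed, ppg_b, sd_b, cfg)
        est = mdl.train(ts, ppg_b, sd_b, cfg)
        est.save(tmp_path / "bundle")
        loaded = mdl.TrainedEstimator.load(tmp_path / "bundle")
        p0 = mdl.predict(est, processed[0], cfg)
        p1 = mdl.predict(loaded, processed[0], cfg)
        assert p0.test_sbp == p1.test_sbp


class TestPredict:
    def test_beat_order_invariance(self, processed, cfg):
        ppg_b, sd_b = mdl.fit_fold_bases(processed, cfg)
        ts = mdl.build_training_set(processed, ppg_b, sd_b, cfg)
        est = mdl.train(ts, ppg_b, sd_b, cfg)
        m = processed[0]
        perm = np.random.default_rng(1).permutation(m.n_beats)
        m_perm = pl.ProcessedMeasurement(
            measurement_id=m.measurement_id, subject_id=m.subject_id,
            ppg_shapes=m.ppg_shapes[perm], sdptg_shapes=m.sdptg_shapes[perm],
            scalars=m.scalars[perm], beat_indices=m.beat_indices[perm],
            bmi=m.bmi, age=m.age, height_cm=m.height_cm,
            ref_sbp=m.ref_sbp, ref_dbp=m.ref_dbp, mean_pi=m.mean_pi,
        )
        assert mdl.predict(est, m, cfg).test_sbp == mdl.predict(est, m_perm, cfg).test_sbp

    def test_wrong_beat_count_errors_with_count(self, processed, cfg):
        ppg_b, sd_b = mdl.fit_fold_bases(processed, cfg)
        ts = mdl.build_training_set(processed, ppg_b, sd_b, cfg)
        est = mdl.train(ts, ppg_b, sd_b, cfg)
        m = processed[0]
        short = pl.ProcessedMeasurement(
            measurement_id=m.measurement_id, subject_id=m.subject_id,
            ppg_shapes=m.ppg_shapes[:10], sdptg_shapes=m.sdptg_shapes[:10],
            scalars=m.scalars[:10], beat_indices=m.beat_indices[:10],
            bmi=m.bmi, age=m.age, height_cm=m.height_cm,
            ref_sbp=m.ref_sbp, ref_dbp=m.ref_dbp, mean_pi=m.mean_pi,
        )
        with pytest.raises(PredictionError, match="10"):
            mdl.predict(est, short, cfg)

    def test_aggregate_robust_to_single_wild_beat(self):
        # one wild per-beat prediction among 30 must not move the aggregate
        per_beat = np.array([118.0] * 29 + [200.0])
        assert mdl._aggregate(per_beat, trim=0.2) == 118.0
        assert mdl._aggregate(per_beat, trim=0.5) == 118.0  # median limit

    def test_aggregate_of_identical_predictions_is_that_value(self):
        assert mdl._aggregate(np.full(30, 121.5), trim=0.2) == 121.5


class TestLOSO:
    def test_one_fold_per_subject(self, processed, loso_result):
        n_subjects = len({m.subject_id for m in processed})
        assert loso_result["fold"].nunique() == n_subjects
        assert len(loso_result) == len(processed)

    def test_holdout_subject_never_in_training(self, loso_result):
        membership = loso_result.attrs["fold_membership"]
        assert membership
        for fold, info in membership.items():
            assert info["holdout"] not in info["train_subjects"]
            assert info["holdout"] not in info["basis_subjects"]

    def test_single_subject_dataset_rejected(self, processed, cfg):
        one = [m for m in processed if m.subject_id == processed[0].subject_id]
        with pytest.raises(ValueError):
            mdl.loso_validate(one, cfg)


class TestCalibration:
    def test_median_of_prior_errors(self):
        f = mdl.calibration_factor("S1", [5.0, 3.0, 7.0], [1.0, 2.0, 3.0])
        assert f.sbp_factor == 5.0 and f.dbp_factor == 2.0 and f.n_prior == 3

    def test_single_and_even_counts(self):
        assert mdl.calibration_factor("S1", [4.0], [4.0]).sbp_factor == 4.0
        assert mdl.calibration_factor("S1", [-2.0, 2.0], [0.0, 0.0]).sbp_factor == 0.0

    def test_empty_priors_rejected(self):
        with pytest.raises(CalibrationError, match="no prior"):
            mdl.calibration_factor("S1", [], [])

    def test_subtraction_and_identity(self):
        p = mdl.Prediction("M1", "S1", 130.0, 85.0, np.full(30, 130.0), np.full(30, 85.0))
        f = mdl.CalibrationFactor("S1", 5.0, 0.0, 2)
        out = mdl.apply_calibration(p, f)
        assert out.test_sbp == 125.0 and out.test_dbp == 85.0

    def test_subject_mismatch_rejected(self):
        p = mdl.Prediction("M1", "S1", 130.0, 85.0, np.zeros(30), np.zeros(30))
        with pytest.raises(CalibrationError):
            mdl.apply_calibration(p, mdl.CalibrationFactor("S2", 5.0, 0.0, 1))

    def test_median_self_centering_is_exact(self):
        rng = np.random.default_rng(4)
        errors = rng.normal(3.0, 5.0, 11)
        factor = float(np.median(errors))
        assert np.median(errors - factor) == 0.0

    def test_calibrate_loso_errors_layout(self, loso_result):
        calib = mdl.calibrate_loso_errors(loso_result, n_prior=1)
        assert not calib.empty
        # held-out rows only: one per subject with 2 measurements
        assert calib["n_prior"].eq(1).all()
        assert set(calib.columns) >= {"err_sbp_free", "err_sbp_cal", "err_dbp_free", "err_dbp_cal"}
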