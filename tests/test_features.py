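"""Feature assembly and the two-stage SVM grading cascade."""

import numpy as np
import pytest

from curvegrade.exudates import ExudateResult
from curvegrade.faz import FazResult
from curvegrade.features import (
    DegenerateTrainingSetError,
    FeatureVector,
    evaluate,
    extract_features,
    predict_grade,
    predict_grades,
    repeated_split_protocol,
    train_cascade,
)
from curvegrade.microaneurysms import MaResult
from curvegrade.phantom import COHORT_FEATURE_MEANS, sample_feature_cohort


def _stage_results(shape=(64, 64), ex_area=0, ma_total=0, ma_in_faz=0,
                   vessel_px=0, faz_area=0, dvar=0.0):
    ex_mask = np.zeros(shape, dtype=bool)
    ex_mask.flat[:ex_area] = True
    vm = np.zeros(shape, dtype=bool)
    vm.flat[:vessel_px] = True
    faz_mask = np.zeros(shape, dtype=bool)
    faz_mask.flat[:faz_area] = True
    ex = ExudateResult(mask=ex_mask, total_area=ex_area, n_regions=int(ex_area > 0),
                       od_removed=True)
    ma = MaResult(centers=np.zeros((ma_total, 2)), total_count=ma_total,
                  count_in_faz=ma_in_faz, mask=np.zeros(shape, dtype=bool))
    faz = FazResult(mask=faz_mask, area=faz_area, centroid=(0.0, 0.0),
                    boundary_points=np.zeros((0, 2)), distance_variance=dvar)
    return ex, ma, vm, faz


class TestExtractFeatures:
    def test_all_empty_gives_zero_vector(self):
        fv = extract_features(*_stage_results())
        assert fv.as_array().tolist() == [0, 0, 0, 0, 0, 0]

    def test_maps_stage_results_onto_features(self):
        fv = extract_features(*_stage_results(
            ex_area=300, ma_total=10, ma_in_faz=4, vessel_px=500, faz_area=120, dvar=7.5
        ))
        assert fv.area_exudates == 300
        assert fv.mas_in_faz == 4
        assert fv.total_mas == 10
        assert fv.area_vessels == 500
        assert fv.area_faz == 120
        assert fv.faz_distance_variance == 7.5

    def test_recomputation_is_bit_identical(self):
        args = _stage_results(ex_area=42, ma_total=3, vessel_px=100, faz_area=20)
        a = extract_features(*args).as_array()
        b = extract_features(*args).as_array()
        assert np.array_equal(a, b)

    def test_shape_mismatch_raises(self):
        ex, ma, vm, faz = _stage_results()
        with pytest.raises(ValueError):
            extract_features(ex, ma, np.zeros((32, 32), dtype=bool), faz)

    def test_negative_feature_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(-1, 0, 0, 0, 0, 0)


@pytest.fixture(scope="module")
def cohort():
    return sample_feature_cohort((30, 25, 15), cv=0.10, seed=42)


@pytest.fixture(scope="module")
def model(cohort):
    X, y = cohort
    return train_cascade(X, y, seed=0)


class TestCascade:
    def test_training_accuracy_is_perfect(self, cohort, model):
        X, y = cohort
        assert (predict_grades(model, X) == y).all()

    def test_single_grade_training_raises(self, cohort):
        X, y = cohort
        with pytest.raises(DegenerateTrainingSetError):
            train_cascade(X[y == 1], y[y == 1])

    def test_class_mean_vectors_get_their_grade(self, model):
        assert predict_grade(model, COHORT_FEATURE_MEANS[1]) == 1
        assert predict_grade(model, COHORT_FEATURE_MEANS[2]) == 2
        assert predict_grade(model, COHORT_FEATURE_MEANS[3]) == 3

    def test_duplicated_training_set_gives_identical_predictions(self, cohort, model):
        X, y = cohort
        doubled = train_cascade(np.vstack([X, X]), np.concatenate([y, y]), seed=0)
        assert (predict_grades(doubled, X) == predict_grades(model, X)).all()

    def test_cascade_consistency(self, cohort, model):
        """A sample stage 1 accepts as grade 1 is never labeled 2 or 3."""
        X, _ = cohort
        Z = model.scaler.transform(X)
        stage1_says_one = model.stage1.predict(Z).astype(bool)
        pred = predict_grades(model, X)
        assert (pred[stage1_says_one] == 1).all()

    def test_affine_feature_rescaling_is_absorbed_by_standardization(self, cohort):
        X, y = cohort
        scale = np.array([2.0, 10.0, 0.5, 3.0, 0.1, 7.0])
        shift = np.array([5.0, 1.0, 0.0, 100.0, 2.0, 0.3])
        m1 = train_cascade(X, y, seed=0)
        m2 = train_cascade(X * scale + shift, y, seed=0)
        assert (predict_grades(m1, X) == predict_grades(m2, X * scale + shift)).all()


class TestEvaluate:
    def test_perfect_predictions_give_unit_metrics(self, cohort, model):
        X, y = cohort
        rep = evaluate(model, X, y)
        assert rep["macro_sensitivity"] == 1.0
        assert rep["macro_specificity"] == 1.0

    def test_degenerate_predictor_metrics(self):
        """All-grade-1 predictions on a balanced set: grade-1 specificity 0,
        grades 2/3 sensitivity 0."""
        X = np.tile(np.asarray(COHORT_FEATURE_MEANS[1]), (30, 1))
        y = np.repeat([1, 2, 3], 10)
        fit_y = np.repeat([1, 2, 3], 10)
        fit_X = np.vstack([np.tile(COHORT_FEATURE_MEANS[g], (10, 1)) for g in (1, 2, 3)])
        m = train_cascade(fit_X, fit_y, seed=0)
        rep = evaluate(m, X, y)  # identical inputs -> constant prediction
        assert rep["per_grade"][1]["specificity"] == 0.0
        assert rep["per_grade"][2]["sensitivity"] == 0.0
        assert rep["per_grade"][3]["sensitivity"] == 0.0

    def test_empty_evaluation_raises(self, model):
        with pytest.raises(ValueError):
            evaluate(model, np.zeros((0, 6)), [])


class TestProtocol:
    def test_repeated_split_reaches_unit_metrics(self, cohort):
        X, y = cohort
        rep = repeated_split_protocol(X, y, train_frac=0.3, n_repeats=10, seed=0)
        assert rep["mean_sensitivity"] == 1.0
        assert rep["mean_specificity"] == 1.0

    def test_accuracy_degrades_as_class_gaps_shrink(self):
        """Shrinking the between-class mean separation lowers accuracy."""
        rng_seed = 7
        grand = np.mean([np.asarray(COHORT_FEATURE_MEANS[g]) for g in (1, 2, 3)], axis=0)
        accs = []
        for gap in (1.0, 0.5, 0.2, 0.05, 0.01):
            import curvegrade.phantom as ph

            means = {
                g: tuple(grand + gap * (np.asarray(COHORT_FEATURE_MEANS[g]) - grand))
                for g in (1, 2, 3)
            }
            rng = np.random.default_rng(rng_seed)
            X, y = [], []
            for g in (1, 2, 3):
                mu = np.asarray(means[g])
                sigma2 = np.log1p(0.1**2)
                for _ in range(20):
                    draw = np.where(
                        mu > 0,
                        np.exp(rng.normal(np.log(np.where(mu > 0, mu, 1.0)) - sigma2 / 2,
                                          np.sqrt(sigma2))),
                        0.0,
                    )
                    X.append(draw)
                    y.append(g)
            rep = repeated_split_protocol(np.asarray(X), np.asarray(y), 0.3, 5, seed=0)
            accs.append(rep["mean_accuracy"])
        # monotone trend with a small slack for split noise
        assert accs[0] >= accs[2] - 0.05 >= accs[4] - 0.10
        assert accs[0] > accs[4]
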