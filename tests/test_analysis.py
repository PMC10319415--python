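import numpy as np
import pytest

from vityield.analysis import (
    CounterfactualResult, aver_seed_baseline, average_all_baseline,
    counterfactual_seed_analysis, describe_yield, iqr_coverage,
    low_yield_sign_test, lr_reference_model, reference_features,
)
from vityield.errors import ConfigurationError, InvalidArgumentError
from vityield.records import PlotRecord
from vityield.synthetic_data import (
    SceneParams, YieldModelParams, generate_dataset,
)
from vityield.train_eval import r_squared, rmse, split_dataset
from vityield.yield_models import forward_proposed


def _records_with_yields(yields, combos=None):
    img = np.zeros((4, 4, 3))
    return [PlotRecord(i, [img], int(c) if combos is not None else 0, float(y))
            for i, (y, c) in enumerate(
                zip(yields, combos if combos is not None else [0] * len(yields)))]


class TestAverageBaselines:
    def test_average_all_constant_train(self):
        recs = _records_with_yields([5.0] * 4)
        pred = average_all_baseline([7.0, 7.0, 7.0], recs)
        np.testing.assert_array_equal(pred, 7.0)

    def test_average_all_r2_zero_when_means_coincide(self):
        y = np.array([3000.0, 4000.0, 5000.0, 4500.0])
        recs = _records_with_yields(y)
        pred = average_all_baseline(y, recs)
        assert r_squared(y, pred) == pytest.approx(0.0)

    def test_average_all_rmse_geq_test_mean_oracle(self, rng):
        y_train = rng.normal(4000, 400, size=100)
        y_test = rng.normal(4200, 400, size=50)
        recs = _records_with_yields(y_test)
        pred = average_all_baseline(y_train, recs)
        oracle = np.full_like(y_test, y_test.mean())
        assert rmse(y_test, pred) >= rmse(y_test, oracle)

    def test_empty_train_raises(self):
        with pytest.raises(InvalidArgumentError):
            average_all_baseline([], _records_with_yields([1.0]))

    def test_aver_seed_single_combo_reduces_to_average_all(self):
        train = _records_with_yields([1.0, 2.0, 3.0])
        test = _records_with_yields([2.0, 2.0])
        np.testing.assert_array_equal(
            aver_seed_baseline(train, test),
            average_all_baseline([1.0, 2.0, 3.0], test))

    def test_aver_seed_uses_group_means(self):
        train = _records_with_yields([10.0, 20.0, 100.0], combos=[0, 0, 1])
        test = _records_with_yields([0.0, 0.0], combos=[1, 0])
        np.testing.assert_array_equal(aver_seed_baseline(train, test),
                                      [100.0, 15.0])

    def test_aver_seed_unseen_combo_falls_back_to_global_mean(self):
        train = _records_with_yields([10.0, 20.0], combos=[0, 0])
        test = _records_with_yields([0.0], combos=[9])
        np.testing.assert_array_equal(aver_seed_baseline(train, test), [15.0])

    def test_aver_seed_beats_average_all_on_seed_driven_data(self):
        """Strong seed effects, no image signal: group means win."""
        scene = SceneParams(image_size=(16, 16), row_spacing=4)
        effects = {i: (-800.0 if i % 5 == 0 else 100.0) for i in range(51)}
        params = YieldModelParams(beta_coverage=0.0, beta_greenness=0.0,
                                  seed_effects=effects, noise_sd=40.0)
        ds = generate_dataset(200, scene, params, 3, write_images=False)
        tr, va, te = split_dataset(200, (150, 10, 40), 0,
                                   [p.combo_index for p in ds.plots])
        train = [ds.plots[i] for i in np.concatenate([tr, va])]
        test = [ds.plots[i] for i in te]
        y_test = np.array([r.yield_kg_ha for r in test])
        rmse_seed = rmse(y_test, aver_seed_baseline(train, test))
        rmse_all = rmse(y_test, average_all_baseline(
            [r.yield_kg_ha for r in train], test))
        assert rmse_seed < rmse_all


class TestLrReferenceModels:
    def test_variant1_pure_noise_r2_near_zero(self):
        """20 simulations of seed-only features on noise yields."""
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            recs = _records_with_yields(rng.normal(4000, 300, size=80),
                                        combos=rng.integers(0, 51, size=80))
            tr = np.arange(60)
            te = np.arange(60, 80)
            report, _ = lr_reference_model(recs, tr, te, variant=1)
            r2s.append(report.r_squared)
        assert np.mean(r2s) < 0.05

    def test_feature_width_progression(self, small_dataset):
        rec = small_dataset.plots[0]
        w1 = len(reference_features(rec, 1, downsample=2))
        w2 = len(reference_features(rec, 2, downsample=2))
        w3 = len(reference_features(rec, 3, downsample=2))
        t = rec.n_timestamps
        image_width = w2 - w1
        assert w3 == w2 + (t - 1) * image_width
        assert w1 == 51

    def test_variant2_beats_variant1_on_image_driven_data(self):
        scene = SceneParams(image_size=(32, 32), row_spacing=8)
        params = YieldModelParams(beta_coverage=1500.0, beta_greenness=800.0,
                                  noise_sd=30.0)
        ds = generate_dataset(120, scene, params, 5, write_images=False)
        tr, va, te = split_dataset(120, (90, 10, 20), 1,
                                   [p.combo_index for p in ds.plots])
        tr = np.concatenate([tr, va])
        r1, _ = lr_reference_model(ds.plots, tr, te, variant=1, downsample=2)
        r2, _ = lr_reference_model(ds.plots, tr, te, variant=2, downsample=2)
        assert r2.rmse < r1.rmse

    def test_unknown_variant_raises(self, small_dataset):
        with pytest.raises(ConfigurationError):
            lr_reference_model(small_dataset.plots, np.arange(10),
                               np.arange(10, 20), variant=4)


class TestCounterfactual:
    def test_status_rules_on_hand_built_fixture(self):
        preds = np.array([10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0, 17.0])
        r = CounterfactualResult.from_predictions(0, preds, 0)
        q1, med, q3 = np.percentile(preds, [25, 50, 75])
        assert (r.q1, r.median, r.q3) == (q1, med, q3)
        assert r.iqr == q3 - q1

        # enumeration oracle over every candidate true index
        for idx in range(len(preds)):
            res = CounterfactualResult.from_predictions(0, preds, idx)
            tp = preds[idx]
            if tp < q1 - 1.5 * (q3 - q1):
                expected = "low_outlier"
            elif q1 <= tp <= q3:
                expected = "inside_iqr"
            else:
                expected = "outside_iqr"
            assert res.status == expected

    def test_low_outlier_detection(self):
        preds = np.concatenate([[0.0], np.linspace(100, 110, 50)])
        r = CounterfactualResult.from_predictions(3, preds, 0)
        assert r.status == "low_outlier"

    def test_zero_seed_branch_gives_degenerate_box(self, small_dataset):
        from test_yield_models import tiny_model
        model = tiny_model()
        model.is_trained = True  # bypass the trained-model precondition
        for _, p in model.seed_encoder.named_parameters():
            p.data[:] = 0.0
        results = counterfactual_seed_analysis(model, small_dataset.plots[:3])
        for r in results:
            assert r.iqr == 0.0
            assert np.ptp(r.predictions) == 0.0
            assert r.status == "inside_iqr"
        inside, outside, n_low = iqr_coverage(results)
        assert (inside, outside, n_low) == (1.0, 0.0, 0)

    def test_true_combo_matches_forward_pass_bit_exactly(self, small_dataset):
        from test_yield_models import tiny_model
        model = tiny_model(seed=4)
        model.is_trained = True  # bypass the trained-model precondition
        records = small_dataset.plots[:4]
        results = counterfactual_seed_analysis(model, records)
        for rec, res in zip(records, results):
            assert res.predictions[rec.combo_index] == \
                forward_proposed(rec, model)

    def test_iqr_coverage_47_of_68(self):
        """47 inside of 68 -> 69.1% to one decimal place."""
        results = []
        inside_preds = np.linspace(0, 1, 51)
        for i in range(68):
            true_idx = 25 if i < 47 else 0  # median vs extreme low
            results.append(CounterfactualResult.from_predictions(
                i, inside_preds, true_idx))
        inside, outside, _ = iqr_coverage(results)
        assert round(100 * inside, 1) == 69.1
        assert inside + outside == pytest.approx(1.0)

    def test_iqr_coverage_empty_raises(self):
        with pytest.raises(InvalidArgumentError):
            iqr_coverage([])

    def test_sign_test_counts(self):
        preds = np.linspace(0, 100, 51)
        results = [CounterfactualResult.from_predictions(i, preds, 0)
                   for i in range(10)]  # true pred 0 < median for all
        below, total, p = low_yield_sign_test(results, [0])
        assert (below, total) == (10, 10)
        assert p < 0.01


class TestDescribeYield:
    def test_symmetric_two_point_sample(self):
        skew, _ = describe_yield([-1.0, 1.0, -1.0, 1.0])
        assert skew == pytest.approx(0.0)

    def test_normal_sample_kurtosis_three(self):
        y = np.random.default_rng(0).standard_normal(100_000)
        _, kurt = describe_yield(y)
        assert kurt == pytest.approx(3.0, abs=0.1)

    def test_left_skewed_generator_output(self, small_dataset):
        # larger sample via the yield model marginals
        from vityield.synthetic_data import (
            REFERENCE_TREATMENT_COUNTS, default_seed_effects, enumerate_seed_combos,
            sample_yield,
        )
        params = YieldModelParams(seed_effects=default_seed_effects(51))
        combos = enumerate_seed_combos(REFERENCE_TREATMENT_COUNTS)
        rng = np.random.default_rng(8)
        ys = [sample_yield(rng.uniform(0.55, 1), rng.uniform(0.3, 0.9),
                           combos[i % 51], params, i) for i in range(3000)]
        skew, _ = describe_yield(ys)
        assert skew < 0

    def test_too_few_samples_raises(self):
        with pytest.raises(InvalidArgumentError):
            describe_yield([1.0, 2.0])

    def test_zero_variance_raises(self):
        with pytest.raises(InvalidArgumentError):
            describe_yield([3.0] * 10)


def test_counterfactual_untrained_model_rejected(small_dataset):
    from test_yield_models import tiny_model
    with pytest.raises(InvalidArgumentError):
        counterfactual_seed_analysis(tiny_model(), small_dataset.plots[:1])
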