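"""Fold construction, metrics, curves, attribution and leakage guards."""

import numpy as np
import pandas as pd
import pytest

from latentrad.features import FeatureBlock
from latentrad.modeling import (CLASSIFIER_NAMES, ClassifierSpec, LeakageError,
                                ResultGrid, binary_metrics, calibration_curve,
                                decision_curve, default_classifier_specs,
                                group_attribution, guard_disjoint, roc_auc,
                                run_grid, stratified_kfold)


class TestStratifiedKFold:
    def test_exact_positive_balance(self):
        y = np.array([1] * 20 + [0] * 80)
        folds = stratified_kfold(y, k=5, seed=0)
        for _, va in folds:
            assert y[va].sum() == 4

    def test_partition(self):
        y = np.array([0, 1] * 25)
        folds = stratified_kfold(y, k=5, seed=1)
        all_idx = np.sort(np.concatenate([va for _, va in folds]))
        np.testing.assert_array_equal(all_idx, np.arange(50))
        for tr, va in folds:
            assert not set(tr) & set(va)

    def test_seed_reproducibility(self):
        y = np.array([0, 1] * 20)
        a = stratified_kfold(y, k=5, seed=7)
        b = stratified_kfold(y, k=5, seed=7)
        for (_, va1), (_, va2) in zip(a, b):
            np.testing.assert_array_equal(va1, va2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            stratified_kfold(np.zeros(10), k=5)


class TestBinaryMetrics:
    def test_perfect_separation(self):
        m = binary_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m["auc"] == 1.0
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_reversed_scores_complement_auc(self, rng):
        y = rng.integers(0, 2, 40)
        y[:3] = 1
        y[-3:] = 0
        s = rng.random(40)
        assert roc_auc(-s, y) == pytest.approx(1.0 - roc_auc(s, y))

    def test_hand_enumerated_auc(self):
        # pairs: (0.9,0.8) conc, (0.9,0.6) conc, (0.7,0.8) disc, (0.7,0.6) conc
        m = binary_metrics([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert m["auc"] == pytest.approx(0.75)

    def test_tied_scores_half_credit(self):
        assert roc_auc([0.5, 0.5], [1, 0]) == pytest.approx(0.5)

    def test_undefined_ppv_reported_missing(self):
        m = binary_metrics([0.1, 0.2, 0.3], [0, 0, 1], threshold=0.5)
        assert np.isnan(m["ppv"])  # no positive predictions

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics([0.1, 0.9], [1, 1])

    def test_metric_identities_on_random_tables(self, rng):
        for _ in range(30):
            y = rng.integers(0, 2, 50)
            s = rng.random(50)
            if len(np.unique(y)) < 2:
                continue
            m = binary_metrics(s, y, threshold=0.5)
            pred = (s >= 0.5).astype(int)
            tp = int(((pred == 1) & (y == 1)).sum())
            fn = int(((pred == 0) & (y == 1)).sum())
            tn = int(((pred == 0) & (y == 0)).sum())
            fp = int(((pred == 1) & (y == 0)).sum())
            if tp + fn:
                assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m["specificity"] == pytest.approx(tn / (tn + fp))
            if not np.isnan(m["f1"]) and m["f1"] > 0:
                assert m["f1"] == pytest.approx(
                    2 * m["ppv"] * m["sensitivity"] / (m["ppv"] + m["sensitivity"]))


class TestCalibration:
    def test_well_calibrated_scores(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.95, 4000)
        y = (rng.random(4000) < p).astype(int)
        curve, brier = calibration_curve(p, y, bins=10)
        assert np.max(np.abs(curve["mean_predicted"] - curve["observed_rate"])) < 0.05

    def test_constant_scores_single_bin(self):
        y = np.array([0, 1] * 10)
        curve, _ = calibration_curve(np.full(20, 0.5), y, bins=5)
        assert len(curve) == 1
        assert curve["observed_rate"].iloc[0] == pytest.approx(0.5)

    def test_perfect_predictions_zero_brier(self):
        y = np.array([0, 1, 1, 0] * 5)
        _, brier = calibration_curve(y.astype(float), y, bins=2)
        assert brier == 0.0


class TestDecisionCurve:
    def test_treat_none_zero_everywhere(self, rng):
        y = rng.integers(0, 2, 30)
        table = decision_curve(rng.random(30), y)
        assert np.all(table["treat_none"] == 0.0)

    def test_treat_all_approaches_prevalence(self):
        y = np.array([1, 1, 0, 0, 0])
        table = decision_curve(np.linspace(0, 1, 5), y, thresholds=[0.001])
        assert table["treat_all"].iloc[0] == pytest.approx(0.4, abs=0.01)

    def test_hand_computed_net_benefit(self):
        # n=10, 4 positives; classifier flags 5 (3 TP, 2 FP), pt=0.2:
        # NB = 3/10 - (2/10) * 0.25 = 0.25
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.1, 0.6, 0.5, 0.1, 0.1, 0.1, 0.1])
        table = decision_curve(s, y, thresholds=[0.2])
        assert table["net_benefit"].iloc[0] == pytest.approx(0.25)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=[1.5])


@pytest.fixture(scope="module")
def signal_and_noise_model():
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(3)
    n = 1000
    X = rng.normal(size=(n, 6))
    logit = 2.0 * X[:, 0] + 1.5 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    model = LogisticRegression().fit(X, y)
    return model, X, y


class TestGroupAttribution:
    def test_noise_group_near_zero(self, signal_and_noise_model):
        model, X, y = signal_and_noise_model
        groups = {"signal": [0, 1], "noise": [2, 3, 4, 5]}
        imp = group_attribution(model, X, y, groups, seed=0, n_repeats=20)
        noise_imp = imp.set_index("group").loc["noise", "importance"]
        assert noise_imp < 0.02

    def test_signal_group_ranks_first(self, signal_and_noise_model):
        model, X, y = signal_and_noise_model
        groups = {"signal": [0, 1], "noise": [2, 3, 4, 5]}
        imp = group_attribution(model, X, y, groups, seed=0, n_repeats=10)
        assert imp.iloc[0]["group"] == "signal"
        assert imp.iloc[0]["importance"] > imp.iloc[1]["importance"]

    def test_permuting_everything_destroys_auc(self, signal_and_noise_model):
        model, X, y = signal_and_noise_model
        base = roc_auc(model.predict_proba(X)[:, 1], y)
        imp = group_attribution(model, X, y, {"all": list(range(6))},
                                seed=0, n_repeats=20)
        drop = imp.set_index("group").loc["all", "raw_mean_drop"]
        assert drop == pytest.approx(base - 0.5, abs=0.05)

    def test_non_partition_rejected(self, signal_and_noise_model):
        model, X, y = signal_and_noise_model
        with pytest.raises(ValueError, match="partition"):
            group_attribution(model, X, y, {"a": [0, 1]}, seed=0)


class TestClassifierSpecs:
    def test_exactly_six_specs(self):
        specs = default_classifier_specs(seed=1)
        assert [s.name for s in specs] == list(CLASSIFIER_NAMES)

    def test_all_build_and_fit(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        for spec in default_classifier_specs(seed=0, n_estimators=10):
            est = spec.build()
            est.fit(X, y)
            p = est.predict_proba(X)[:, 1]
            assert p.shape == (40,)
            assert np.all((p >= 0) & (p <= 1))

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("MLP")


def _toy_raw_blocks(n=36, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"train_{i}" for i in range(n)] + [f"test_{i}" for i in range(n // 3)]
    total = len(ids)

    def blk(width, prefix, family="latent"):
        return FeatureBlock(names=[f"{prefix}_{j}" for j in range(width)],
                            matrix=rng.uniform(0, 1, (total, width)),
                            family=family, case_ids=list(ids))

    blocks = dict(radiomics=blk(20, "radiomics", "radiomics"),
                  shape=blk(14, "shape", "shape"),
                  seg_full=blk(16, "seg_full"), seg_half=blk(8, "seg_half"),
                  vaegan=blk(16, "vaegan"))
    signal = blocks["radiomics"].matrix[:, 0]
    labels = pd.DataFrame(index=ids)
    for outcome in ("poor_outcome", "exp3", "exp6", "exp9"):
        y = (signal + 0.3 * rng.normal(size=total) > 0.5).astype(int)
        y[:2] = [0, 1]
        labels[outcome] = y
    train_ids = ids[:n]
    test_ids = ids[n:]
    return blocks, labels, train_ids, test_ids


@pytest.fixture(scope="module")
def toy_grid():
    blocks, labels, train_ids, test_ids = _toy_raw_blocks()
    specs = default_classifier_specs(seed=0, n_estimators=10)
    return run_grid(blocks, labels, train_ids, test_ids, specs=specs,
                    k=4, n_folds=3, nmf_iters=30, seed=0)


class TestRunGrid:
    def test_full_grid_completeness(self, toy_grid):
        # 7 configurations x 6 classifiers x 4 outcomes on the test split
        toy_grid.check_complete()
        df = toy_grid.to_frame()
        assert len(df[df.split == "test"]) == 7 * 6 * 4

    def test_cv_has_fold_vectors(self, toy_grid):
        aucs = toy_grid.cv_fold_aucs("radiomics_all", "RF", "poor_outcome")
        assert len(aucs) == 3
        assert np.all((aucs >= 0) & (aucs <= 1))

    def test_overlapping_train_test_rejected(self):
        blocks, labels, train_ids, test_ids = _toy_raw_blocks()
        with pytest.raises(LeakageError):
            run_grid(blocks, labels, train_ids, train_ids[:5],
                     specs=default_classifier_specs(0, 5), k=2, n_folds=2)

    def test_guard_disjoint_negative(self):
        with pytest.raises(LeakageError, match="leakage"):
            guard_disjoint(["a", "b"], ["b", "c"], "unit")


class TestPlots:
    def test_calibration_and_decision_svg_written(self, tmp_path, rng):
        from latentrad.modeling import plot_calibration, plot_decision_curve

        y = rng.integers(0, 2, 50)
        s = rng.random(50)
        curve, brier = calibration_curve(s, y, bins=5)
        plot_calibration(curve, brier, tmp_path / "cal.svg")
        table = decision_curve(s, y)
        plot_decision_curve(table, tmp_path / "dc.svg")
        assert (tmp_path / "cal.svg").read_text().startswith("<?xml")
        assert (tmp_path / "dc.svg").exists()


class TestResultGrid:
    def test_incomplete_grid_detected(self):
        grid = ResultGrid()
        grid.add("radiomics_all", "RF", "poor_outcome", "test", dict(auc=0.5))
        with pytest.raises(ValueError, match="incomplete"):
            grid.check_complete()

    def test_tidy_csv_roundtrip(self, tmp_path):
        grid = ResultGrid()
        grid.add("radiomics_all", "RF", "poor_outcome", "test", dict(auc=0.7, f1=0.5))
        path = tmp_path / "grid.csv"
        grid.to_csv(path)
        back = pd.read_csv(path)
        assert back.loc[0, "auc"] == 0.7
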