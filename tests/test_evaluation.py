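import numpy as np
import pandas as pd
import pytest

from glysense.evaluation import (CVConfig, compute_metrics, months_to_objects,
                                 oversample_nontarget, run_cv, timing_profile)
from glysense.features import NONTARGET, TARGET, FeatureSeries, LabeledDataset


def _dataset(Xt, Xn):
    X = np.vstack([Xt, Xn])
    index = pd.date_range("2021-01-01", periods=len(X), freq="D")
    series = FeatureSeries(
        pd.DataFrame({"x1": X[:, 0], "x2": X[:, 1]}, index=index), "daily"
    )
    labels = np.r_[np.full(len(Xt), TARGET), np.full(len(Xn), NONTARGET)]
    return LabeledDataset(series, labels)


@pytest.fixture(scope="module")
def separable_dataset():
    rng = np.random.default_rng(0)
    Xt = rng.normal(size=(120, 2)) * 0.02 + [0.1, 120.0 / 400]
    Xn = rng.normal(size=(8, 2)) * 0.02 + [0.9, 350.0 / 400]
    return _dataset(Xt, Xn)


class TestMetrics:
    def test_perfect_ranking_gives_auc_100(self):
        m = compute_metrics(np.array([0.1, 0.2, 0.8, 0.9]),
                            np.array([TARGET, TARGET, NONTARGET, NONTARGET]),
                            threshold=0.5)
        assert m["auc"] == pytest.approx(100.0)

    def test_specificity_counts_flagged_nontarget(self):
        scores = np.array([0.0] * 3 + [1.0, 1.0, 1.0, 1.0, 0.0, 0.0])
        labels = np.array([TARGET] * 3 + [NONTARGET] * 6)
        m = compute_metrics(scores, labels, threshold=0.5)
        assert m["specificity"] == pytest.approx(100 * 4 / 6)

    def test_f1_is_harmonic_mean_of_precision_recall(self):
        # build counts with precision 0.8 (TP=8, FP=2), recall 0.5 (FN=8)
        scores = np.r_[np.zeros(8), np.ones(8), np.zeros(2), np.ones(5)]
        labels = np.r_[np.full(16, TARGET), np.full(7, NONTARGET)]
        m = compute_metrics(scores, labels, threshold=0.5)
        assert m["f1"] == pytest.approx(100 * 2 * 0.8 * 0.5 / 1.3, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.arange(3.0), np.zeros(3, int), 0.5)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        a = compute_metrics(scores, labels, 0.0)["auc"]
        b = compute_metrics(np.exp(scores), labels, 1.0)["auc"]
        assert a == pytest.approx(b)


class TestOversampling:
    def test_all_originals_present_when_upsampling(self):
        Xn = np.arange(7.0)[:, None]
        out = oversample_nontarget(Xn, 72, seed_or_rng=0)
        assert len(out) == 72
        assert set(out.ravel()) == set(Xn.ravel())

    def test_equal_count_keeps_every_object(self):
        Xn = np.arange(5.0)[:, None]
        out = oversample_nontarget(Xn, 5, seed_or_rng=1)
        assert sorted(out.ravel()) == sorted(Xn.ravel())

    def test_seeded_reproducibility(self):
        Xn = np.arange(6.0)[:, None]
        a = oversample_nontarget(Xn, 20, seed_or_rng=3)
        b = oversample_nontarget(Xn, 20, seed_or_rng=3)
        np.testing.assert_array_equal(a, b)

    def test_empty_nontarget_rejected(self):
        with pytest.raises(ValueError):
            oversample_nontarget(np.empty((0, 2)), 5)


class TestRunCV:
    def test_perfectly_separable_gives_auc_100_sd_0(self, separable_dataset):
        rep = run_cv(separable_dataset, "gaussian",
                     CVConfig(repetitions=2, seed=0))
        assert rep.mean["auc"] == pytest.approx(100.0)
        assert rep.sd["auc"] == pytest.approx(0.0)

    def test_same_seed_reproduces_report(self, separable_dataset):
        a = run_cv(separable_dataset, "knn", CVConfig(repetitions=2, seed=5),
                   model_params={"k": 3})
        b = run_cv(separable_dataset, "knn", CVConfig(repetitions=2, seed=5),
                   model_params={"k": 3})
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_shuffled_labels_give_null_auc(self, rng):
        """With labels carrying no signal the AUC, averaged over several
        random label shuffles, sits near 50% (a single shuffle of only 15
        nontarget objects carries ~8% sampling noise)."""
        aucs = []
        for shuffle in range(5):
            X = rng.normal(size=(200, 2))
            perm = rng.permutation(200)
            ds = _dataset(X[perm[15:]], X[perm[:15]])
            rep = run_cv(ds, "gaussian", CVConfig(repetitions=2, seed=shuffle))
            aucs.append(rep.mean["auc"])
        assert np.mean(aucs) == pytest.approx(50.0, abs=10.0)

    def test_sample_size_subsampling(self, separable_dataset):
        rep = run_cv(separable_dataset, "gaussian",
                     CVConfig(repetitions=1, seed=0,
                              sample_size=months_to_objects(1)))
        assert rep.mean["auc"] == pytest.approx(100.0)

    def test_no_nontarget_rejected(self, rng):
        ds = _dataset(rng.normal(size=(50, 2)), np.empty((0, 2)))
        with pytest.raises(ValueError, match="nothing to detect"):
            run_cv(ds, "gaussian", CVConfig(repetitions=1))

    def test_stratification_fold_sizes_differ_by_at_most_one(self):
        from sklearn.model_selection import KFold

        sizes = [len(te) for _, te in
                 KFold(5, shuffle=True, random_state=0).split(np.arange(123))]
        assert max(sizes) - min(sizes) <= 1


class TestTiming:
    def test_profile_shape_and_serialization(self, tmp_path):
        table = timing_profile("knn", sizes=(240, 480), runs=1,
                               model_params={"k": 5})
        assert list(table["size"]) == [240, 480]
        assert (table[["train_seconds", "test_seconds"]] >= 0).all().all()
        out = tmp_path / "timing.csv"
        table.to_csv(out, index=False)
        assert out.read_text().startswith("size,")
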