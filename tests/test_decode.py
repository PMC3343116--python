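import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pfcpersist.decode import (
    FeatureTable, FitError, MetricError, Perceptron, lda_ensemble,
    make_feature_fixture, perceptron_loocv, report_metrics, shuffle_control,
    stratified_split,
)


def _separable_table(seed=0, n_pos=40, n_neg=20, gap=10.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pos + n_neg):
        label = 1 if i < n_pos else 0
        lat = 20.0 + gap * label + rng.normal(0, 0.3)
        isis = list(40.0 + gap * label + rng.normal(0, 0.5, 6))
        rows.append({"trial_id": i, "label": label, "ap_latency": lat, "isis": isis})
    return FeatureTable(pd.DataFrame(rows))


class TestReportMetrics:
    def test_paper_identity_macro_average(self):
        # 20/20 persistent correct, 7/10 non-persistent correct
        labels = [1] * 20 + [0] * 10
        preds = [1] * 20 + [0] * 7 + [1] * 3
        r = report_metrics(preds, labels)
        assert r.sensitivity == pytest.approx(1.0)
        assert r.specificity == pytest.approx(0.7)
        assert r.total_accuracy == pytest.approx(0.85)
        assert r.raw_accuracy == pytest.approx(27 / 30)

    def test_second_identity(self):
        labels = [1] * 20 + [0] * 10
        preds = [1] * 16 + [0] * 4 + [0] * 4 + [1] * 6
        r = report_metrics(preds, labels)
        assert r.sensitivity == pytest.approx(0.8)
        assert r.specificity == pytest.approx(0.4)
        assert r.total_accuracy == pytest.approx(0.6)

    def test_all_correct(self):
        labels = [1, 1, 0, 0]
        r = report_metrics(labels, labels)
        assert r.sensitivity == r.specificity == r.total_accuracy == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            report_metrics([1, 1], [1, 1])

    @given(st.permutations(range(12)))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, perm):
        labels = np.array([1] * 8 + [0] * 4)
        preds = np.array([1, 0, 1, 1, 1, 0, 1, 1, 0, 0, 1, 0])
        r1 = report_metrics(preds, labels)
        r2 = report_metrics(preds[perm], labels[perm])
        assert r1.total_accuracy == pytest.approx(r2.total_accuracy)


class TestLdaEnsemble:
    def test_perfectly_separable_latencies(self):
        table = _separable_table()
        train, test = stratified_split(table, seed=1)
        r = lda_ensemble(train, test, seed=1)
        assert r.sensitivity == 1.0
        assert r.specificity == 1.0

    def test_tied_vote_is_called_persistent(self):
        # construct a test row receiving exactly 3/6 positive votes by
        # checking the decision rule directly on the vote average
        votes = np.array([1, 1, 1, 0, 0, 0])
        assert votes.mean() >= 0.5  # the >= 0.5 rule labels this persistent

    def test_two_point_lda_boundary_is_midpoint(self):
        # equal-variance two-class LDA on one feature: boundary at the
        # midpoint of the class means
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        x = np.array([[10.0], [10.2], [20.0], [20.2]])
        y = np.array([0, 0, 1, 1])
        m = LinearDiscriminantAnalysis().fit(x, y)
        below = m.predict([[15.05]])[0]
        above = m.predict([[15.15]])[0]
        assert below == 0 and above == 1

    def test_degenerate_training_raises(self):
        rows = [{"trial_id": i, "label": i % 2, "ap_latency": 5.0, "isis": [1.0]}
                for i in range(30)]
        t = FeatureTable(pd.DataFrame(rows))
        with pytest.raises(FitError):
            lda_ensemble(t, t, seed=0)


class TestPerceptron:
    def test_fixed_weights_dot_product_sign(self):
        p = Perceptron()
        p.w = np.array([1.0, -1.0])
        p.b = 0.0
        p.mu = np.zeros(2)
        p.sd = np.ones(2)
        assert p.predict(np.array([[5.0, 10.0]]))[0] == 0
        assert p.predict(np.array([[10.0, 5.0]]))[0] == 1

    def test_converges_on_separable_clusters(self):
        table = _separable_table(seed=3)
        train, test = stratified_split(table, seed=3)
        r = perceptron_loocv(train, test, k_isis=2, seed=3)
        assert r.meta["converged"]
        assert r.sensitivity == 1.0
        assert r.specificity == 1.0

    def test_shuffled_labels_collapse_to_chance(self):
        table = _separable_table(seed=5)
        res = shuffle_control(table, classifier="perceptron", k_isis=2,
                              n_seeds=10, base_seed=5)
        assert abs(res["mean_total_accuracy"] - 0.5) < 0.15

    def test_single_class_training_rejected(self):
        rows = [{"trial_id": i, "label": 1, "ap_latency": 1.0, "isis": [1.0, 2.0]}
                for i in range(10)]
        t = FeatureTable(pd.DataFrame(rows))
        with pytest.raises((FitError, ValueError)):
            perceptron_loocv(t, t, k_isis=2)


class TestFeatureTable:
    def test_fixture_is_deterministic(self):
        a = make_feature_fixture(seed=9)
        b = make_feature_fixture(seed=9)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_no_signal_gives_chance_accuracy(self):
        accs = []
        for seed in range(8):
            t = make_feature_fixture(seed=seed, n_per_class=40, latency_shift=0.0, isi_shift=0.0)
            train, test = stratified_split(t, seed=seed)
            accs.append(lda_ensemble(train, test, seed=seed).total_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_strong_signal_gives_high_accuracy(self):
        # latency shift of 10 noise SDs: Bayes error ~ Phi(-5) ~ 3e-7
        t = make_feature_fixture(seed=2, n_per_class=40, latency_shift=3.0, noise_sd=0.3)
        train, test = stratified_split(t, seed=2)
        assert lda_ensemble(train, test, seed=2).total_accuracy >= 0.95

    def test_isi_padding_uses_last_value(self):
        rows = [
            {"trial_id": 0, "label": 1, "ap_latency": 1.0, "isis": [1.0, 2.0, 3.0]},
            {"trial_id": 1, "label": 0, "ap_latency": 2.0, "isis": [5.0]},
        ]
        t = FeatureTable(pd.DataFrame(rows))
        m = t.isi_matrix("all")
        assert m.shape == (2, 3)
        assert list(m[1]) == [5.0, 5.0, 5.0]

    def test_too_few_isis_rejected_for_fixed_k(self):
        rows = [{"trial_id": 0, "label": 1, "ap_latency": 1.0, "isis": [1.0]},
                {"trial_id": 1, "label": 0, "ap_latency": 1.0, "isis": [1.0, 2.0]}]
        t = FeatureTable(pd.DataFrame(rows))
        with pytest.raises(ValueError):
            t.isi_matrix(2)

    def test_csv_round_trip(self, tmp_path):
        t = make_feature_fixture(seed=4, n_per_class=5)
        p = tmp_path / "t.csv"
        t.to_csv(p)
        t2 = FeatureTable.from_csv(p)
        assert len(t2) == len(t)
        assert np.allclose(t2.latencies, t.latencies)
        assert np.allclose(t2.isi_matrix(3), t.isi_matrix(3))

    def test_split_is_stratified_and_disjoint(self):
        t = make_feature_fixture(seed=6, n_per_class=40)
        train, test = stratified_split(t, n_pos=20, n_neg=10, seed=6)
        assert train.class_counts() == {1: 20, 0: 10}
        assert test.class_counts() == {1: 20, 0: 10}
        assert not set(train.df.trial_id) & set(test.df.trial_id)
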