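"""Cohort simulation, zero-redistribution renormalization, the BiRNN
classifier and the ranking metrics."""

import numpy as np
import pytest

from phylodiff.downstream import (
    BiRNNHyper,
    pr_auc,
    renormalize_with_redistribution,
    roc_auc,
    simulate_cohort,
    train_birnn,
)


class TestRenormalize:
    def test_worked_example(self):
        out = renormalize_with_redistribution(np.array([0.6, 0.4, 0.00005]))
        np.testing.assert_allclose(out, [0.600025, 0.400025, 0.0], atol=1e-12)

    def test_identity_when_all_above_threshold(self):
        p = np.array([0.6, 0.4])
        np.testing.assert_allclose(renormalize_with_redistribution(p), p)

    def test_unit_sum_and_exact_zeros(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.full(30, 0.2))
            out = renormalize_with_redistribution(p)
            assert out.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(out[p < 1e-4] == 0.0)

    def test_all_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            renormalize_with_redistribution(np.full(5, 1e-6))


class TestSimulateCohort:
    def test_sample_counts_and_unit_sums(self, golden):
        profile, _, labels = golden
        cohort = simulate_cohort(profile, labels, seed=0)
        assert cohort.samples.shape[0] == 300
        assert cohort.is_train.sum() == 210
        assert (~cohort.is_train).sum() == 90
        sums = cohort.samples.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_train_test_subject_pools_disjoint(self, golden):
        profile, _, labels = golden
        cohort = simulate_cohort(profile, labels, seed=1)
        train_src = set(cohort.provenance[cohort.is_train])
        test_src = set(cohort.provenance[~cohort.is_train])
        assert train_src.isdisjoint(test_src)

    def test_labels_copied_from_source_subjects(self, golden):
        profile, _, labels = golden
        cohort = simulate_cohort(profile, labels, seed=2)
        np.testing.assert_array_equal(cohort.labels,
                                      labels[cohort.provenance])

    def test_zero_noise_reproduces_source_exactly(self, golden):
        profile, _, labels = golden
        cohort = simulate_cohort(profile, labels, seed=3,
                                 noise_mean_range=(0.0, 0.0), noise_sd=0.0)
        for i in range(0, 300, 50):
            np.testing.assert_allclose(
                cohort.samples[i], profile.values[cohort.provenance[i]],
                atol=1e-12)


class TestMetrics:
    def brute_force_roc(self, scores, labels):
        """Exhaustive pairwise concordance with half credit for ties."""
        pos = [s for s, y in zip(scores, labels) if y == 1]
        neg = [s for s, y in zip(scores, labels) if y == 0]
        total = 0.0
        for p in pos:
            for n in neg:
                total += 1.0 if p > n else (0.5 if p == n else 0.0)
        return total / (len(pos) * len(neg))

    def test_worked_example(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3])
        labels = np.array([1, 0, 1, 0])
        assert roc_auc(scores, labels) == pytest.approx(0.75)

    def test_perfect_and_tied_rankings(self):
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), labels) == 1.0
        assert roc_auc(np.full(4, 0.5), labels) == pytest.approx(0.5)

    def test_matches_concordance_oracle_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = rng.integers(10, 50)
            scores = rng.choice(np.linspace(0, 1, 11), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels) == pytest.approx(
                self.brute_force_roc(scores, labels), abs=1e-9)

    def test_pr_auc_bounds_and_perfect_case(self):
        labels = np.array([1, 1, 0, 0])
        perfect = pr_auc(np.array([0.9, 0.8, 0.2, 0.1]), labels)
        assert perfect == pytest.approx(1.0, abs=1e-9)
        random_like = pr_auc(np.array([0.5, 0.1, 0.9, 0.4]), labels)
        assert 0.0 <= random_like <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))
        with pytest.raises(ValueError):
            pr_auc(np.array([0.1, 0.2]), np.array([0, 0]))


class TestBiRNN:
    def separable_data(self, n=60, L=4, K=10, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < 0.5).astype(np.int8)
        x = rng.normal(size=(n, L, K))
        x[y == 1, :, :3] += 2.0   # one block of features shifts with the label
        return x, y

    def test_predictions_in_unit_interval(self):
        x, y = self.separable_data()
        model = train_birnn(x, y, BiRNNHyper(hidden=8, epochs=5, seed=0))
        p = model.predict_proba(x)
        assert np.all((p >= 0) & (p <= 1))

    def test_same_seed_same_predictions(self):
        x, y = self.separable_data()
        p = [train_birnn(x, y, BiRNNHyper(hidden=8, epochs=5, seed=3)
                         ).predict_proba(x) for _ in range(2)]
        np.testing.assert_allclose(p[0], p[1], rtol=1e-6)

    def test_single_class_rejected(self):
        x, _ = self.separable_data()
        with pytest.raises(ValueError):
            train_birnn(x, np.ones(len(x)), BiRNNHyper(epochs=1))

    def test_learns_separable_fixture(self):
        x, y = self.separable_data(n=80, seed=1)
        model = train_birnn(x[:60], y[:60],
                            BiRNNHyper(hidden=16, epochs=40, seed=1))
        scores = model.predict_proba(x[60:])
        assert roc_auc(scores, y[60:]) > 0.9
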