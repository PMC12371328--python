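"""Preprocessing: taxonomy parsing, filtering, clr transform, feature
ordering and per-sample ecological summaries."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from phylodiff.preprocess import (
    TaxonomyError,
    clr_transform,
    compute_pseudo_count,
    filter_low_abundance,
    inverse_clr,
    order_features,
    parse_taxonomy,
    shannon_index,
    zero_proportion,
)
from phylodiff.profiles import TaxonProfile


def make_profile(values, observed=None):
    values = np.asarray(values, dtype=float)
    S, L, K = values.shape
    if observed is None:
        observed = np.ones((S, L), dtype=np.int8)
    labels = [f"k__Bacteria|p__P{k % 2}|s__sp_{k}" for k in range(K)]
    return TaxonProfile(values, [f"s{i}" for i in range(S)],
                        list(range(L)), labels, observed)


class TestParseTaxonomy:
    @pytest.mark.parametrize("label,expected", [
        ("k__Bacteria|p__Firmicutes|c__Clostridia|s__Blautia_producta",
         ("Firmicutes", "Blautia_producta")),
        ("k__Bacteria|p__Bacteroidetes|o__Bacteroidales|g__Bacteroides",
         ("Bacteroidetes", "unclassified")),
        ("k__Bacteria|p__Firmicutes|s__unclassified",
         ("Firmicutes", "unclassified")),
    ])
    def test_token_extraction(self, label, expected):
        assert parse_taxonomy(label) == expected

    def test_missing_phylum_raises(self):
        with pytest.raises(TaxonomyError, match="unassignable phylum"):
            parse_taxonomy("no_rank_prefixes_here")


class TestFilter:
    def test_strictly_below_threshold_zeroed(self):
        row = [5e-5, 1e-4, 0.9, 0.0]
        profile = make_profile([[row, row]])
        out = filter_low_abundance(profile, threshold=1e-4)
        assert out.values[0, 0, 0] == 0.0          # below: zeroed
        assert out.values[0, 0, 1] == 1e-4         # boundary: kept (strict <)
        assert out.values[0, 0, 2] == 0.9
        assert out.values[0, 0, 3] == 0.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        vals = rng.dirichlet(np.full(6, 0.3), size=(3, 4))[None].reshape(3, 4, 6)[:2]
        profile = make_profile(vals)
        once = filter_low_abundance(profile)
        twice = filter_low_abundance(once)
        np.testing.assert_array_equal(once.values, twice.values)


class TestClr:
    def test_equal_parts_map_to_zero(self):
        profile = make_profile([[[1 / 3, 1 / 3, 1 / 3]] * 2])
        clr = clr_transform(profile)
        # equal entries give zero clr regardless of the pseudo-count
        np.testing.assert_allclose(clr.values, 0.0, atol=1e-12)

    def test_known_row_against_direct_formula(self):
        # one-row fitting set: min positive 0.4 -> delta = 0.2
        profile = make_profile([[[0.6, 0.4, 0.0], [0.6, 0.4, 0.0]]])
        clr = clr_transform(profile)
        assert clr.pseudo_count == pytest.approx(0.2)
        x = np.array([0.6, 0.4, 0.0]) + 0.2
        expected = np.log(x) - np.log(x).mean()
        np.testing.assert_allclose(clr.values[0, 0], expected, rtol=1e-12)
        np.testing.assert_allclose(clr.values[0, 0],
                                   [0.558, 0.270, -0.828], atol=5e-4)

    def test_rows_sum_to_zero_on_random_fixture(self, small_profile):
        clr = clr_transform(small_profile)
        obs = small_profile.observed.astype(bool)
        sums = clr.values[obs].sum(axis=-1)
        np.testing.assert_allclose(sums, 0.0, atol=1e-6)

    def test_unobserved_rows_left_zero(self):
        observed = np.array([[1, 0, 1]], dtype=np.int8)
        profile = make_profile([[[0.5, 0.5, 0.0]] * 3], observed)
        clr = clr_transform(profile)
        np.testing.assert_array_equal(clr.values[0, 1], 0.0)

    def test_all_zero_profile_raises(self):
        vals = np.full((1, 2, 3), 0.2)
        profile = make_profile(vals)
        profile.values[:] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            compute_pseudo_count(profile)


class TestInverseClr:
    def test_uniform(self):
        np.testing.assert_allclose(inverse_clr(np.zeros(3)), 1 / 3)

    def test_round_trip_strictly_positive(self):
        rng = np.random.default_rng(1)
        x = rng.dirichlet(np.ones(5) * 5, size=(1, 2))
        profile = make_profile(x.reshape(1, 2, 5))
        clr = clr_transform(profile)
        recovered = inverse_clr(clr.values[0, 0])
        shifted = (x.reshape(1, 2, 5)[0, 0] + clr.pseudo_count)
        np.testing.assert_allclose(recovered, shifted / shifted.sum(), rtol=1e-9)

    def test_shift_invariance_and_unit_sum(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(4, 7))
        np.testing.assert_allclose(inverse_clr(z), inverse_clr(z + 3.7), rtol=1e-12)
        np.testing.assert_allclose(inverse_clr(z).sum(axis=-1), 1.0, atol=1e-9)


class TestOrderFeatures:
    def brute_force(self, rows):
        """Independent O(K^2) oracle: full Spearman matrix + explicit
        geometric means excluding the self term."""
        m = rows.shape[1]
        scores = []
        for j in range(m):
            prod = 1.0
            for p in range(m):
                if p == j:
                    continue
                r = spearmanr(rows[:, j], rows[:, p]).statistic
                prod *= abs(0.0 if np.isnan(r) else r)
            scores.append(prod ** (1.0 / (m - 1)))
        return np.array(scores)

    def test_worked_example(self):
        rows = np.array([
            [1, 2, 5, 1], [2, 4, 4, 3], [3, 6, 3, 2], [4, 8, 2, 5], [5, 10, 1, 4],
        ], dtype=float)
        ordering = order_features(rows, ["P"] * 4)
        expected = self.brute_force(rows)
        np.testing.assert_allclose(ordering.scores, expected, atol=1e-9)
        np.testing.assert_allclose(
            ordering.scores, [0.928, 0.928, 0.928, 0.800], atol=1e-3)
        # A,B,C tie at 0.928 and keep input order; D sorts last
        np.testing.assert_array_equal(ordering.permutation, [0, 1, 2, 3])

    def test_matches_oracle_on_random_blocks(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            rows = rng.normal(size=(12, 8))
            ordering = order_features(rows, ["X"] * 8)
            np.testing.assert_allclose(ordering.scores,
                                       self.brute_force(rows), atol=1e-9)

    def test_perfect_correlation_keeps_input_order(self):
        base = np.arange(6, dtype=float)
        rows = np.stack([base, 2 * base, -base], axis=1)
        ordering = order_features(rows, ["X"] * 3)
        np.testing.assert_allclose(ordering.scores, 1.0, atol=1e-12)
        np.testing.assert_array_equal(ordering.permutation, [0, 1, 2])

    def test_constant_feature_sorts_last(self):
        rng = np.random.default_rng(6)
        rows = rng.normal(size=(10, 3))
        rows[:, 1] = 4.2
        ordering = order_features(rows, ["X"] * 3)
        assert ordering.scores[1] == 0.0
        assert ordering.permutation[-1] == 1

    def test_permutation_round_trip(self, small_profile):
        clr = clr_transform(small_profile)
        phyla = [parse_taxonomy(l)[0] for l in small_profile.feature_labels]
        obs = small_profile.observed.astype(bool)
        ordering = order_features(clr.values[obs], phyla)
        x = ordering.apply(clr.values)
        np.testing.assert_array_equal(ordering.invert(x), clr.values)

    def test_blocks_partition_and_scores_non_increasing(self, small_profile):
        clr = clr_transform(small_profile)
        phyla = [parse_taxonomy(l)[0] for l in small_profile.feature_labels]
        obs = small_profile.observed.astype(bool)
        ordering = order_features(clr.values[obs], phyla)
        permuted_scores = ordering.scores[ordering.permutation]
        for _, a, b in ordering.blocks:
            block = permuted_scores[a:b]
            assert np.all(np.diff(block) <= 1e-12)


class TestSummaries:
    def test_shannon_analytic_values(self):
        assert shannon_index(np.full(4, 0.25)) == pytest.approx(np.log(4))
        assert shannon_index(np.array([0, 0, 1.0])) == pytest.approx(0.0)
        assert shannon_index(np.array([0.5, 0.5, 0.0])) == pytest.approx(np.log(2))

    def test_shannon_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            shannon_index(np.zeros(3))

    def test_zero_proportion(self):
        assert zero_proportion(np.array([0, 0, 1.0])) == pytest.approx(2 / 3)
        assert zero_proportion(np.ones(5)) == 0.0
        assert zero_proportion(np.zeros(4)) == 1.0
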