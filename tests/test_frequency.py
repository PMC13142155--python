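"""Count-rank frequency tables, value merging and matrix diagnostics."""

import numpy as np
import pytest
import scipy.sparse as sp

from denorm import (
    DeltaParams,
    FrequencyTable,
    GeneExpressionMatrix,
    count_rank_consistency,
    delta_normalize,
    detect_log_transform,
    merge_near_duplicates,
    rank_frequencies,
    simulate_counts,
)
from denorm.frequency import IndeterminateMatrixError, overdispersion_fraction


class TestRankFrequencies:
    def test_direct_tally(self):
        v, f = rank_frequencies(np.array([1, 1, 1, 2, 2, 5]))
        assert list(v) == [1, 2, 5]
        assert list(f) == [3, 2, 1]

    def test_tie_broken_toward_smaller_value(self):
        v, f = rank_frequencies(np.array([3, 3, 7, 7]))
        assert list(v) == [3, 7]
        assert list(f) == [2, 2]

    def test_zeros_excluded_and_empty_rejected(self):
        v, f = rank_frequencies(np.array([0, 0, 4]))
        assert list(v) == [4]
        with pytest.raises(ValueError):
            rank_frequencies(np.array([0.0, 0.0]))

    def test_simulated_cells_rank_one_is_count_one(self):
        # droplet-like cells: rank-1 value 1 and rank-2 value 2 in the vast majority
        m = simulate_counts(1000, 2000, seed=0)
        table = FrequencyTable.from_matrix(m)
        top_ok = sum(
            v.size >= 2 and v[0] == 1 and v[1] == 2 for v in table.values
        )
        assert top_ok / table.n_cells > 0.95


class TestMergeNearDuplicates:
    def _table(self, values, freqs):
        return FrequencyTable([np.asarray(values, float)], [np.asarray(freqs, float)])

    def test_obvious_duplicate_pooled(self):
        t = self._table([0.9999999, 1.0000001], [300, 200])
        out = merge_near_duplicates(t)
        assert out.values[0].size == 1
        assert out.values[0][0] == pytest.approx(1.0, abs=1e-6)
        assert out.freqs[0][0] == 500

    def test_distinct_values_unchanged(self):
        t = self._table([1.0, 2.0], [300, 200])
        out = merge_near_duplicates(t)
        assert list(out.values[0]) == [1.0, 2.0]
        assert list(out.freqs[0]) == [300, 200]

    def test_representative_is_frequency_weighted_mean(self):
        t = self._table([1.00, 1.0002], [300, 100])
        out = merge_near_duplicates(t, start_decimals=3, min_decimals=3)
        assert out.values[0][0] == pytest.approx((300 * 1.0 + 100 * 1.0002) / 400)

    def test_split_ladder_restored_by_merging(self):
        # storage noise splits the image of count 1 into near-duplicates,
        # demoting it below count 2; merging restores the (1, 2) ladder
        rng = np.random.default_rng(1)
        base = np.concatenate([np.full(200, 1.609438), np.full(120, 2.197225)])
        noisy = base + rng.choice([-2e-6, -1e-6, 0, 1e-6, 2e-6], size=base.size)
        m = GeneExpressionMatrix(sp.csr_matrix(noisy[None, :]), stage="normalized")
        raw = FrequencyTable.from_matrix(m)
        assert raw.values[0].size > 2  # ladder broken: splits outrank count 2
        assert abs(raw.values[0][1] - raw.values[0][0]) < 1e-4
        merged = merge_near_duplicates(raw)
        assert merged.values[0][0] == pytest.approx(1.609438, abs=1e-5)
        assert merged.values[0][1] == pytest.approx(2.197225, abs=1e-3)
        assert merged.freqs[0][0] == 200


class TestDetectLogTransform:
    def test_counts_are_untransformed(self):
        m = simulate_counts(500, 1000, dispersion=0.5, seed=1)
        assert detect_log_transform(m) == "untransformed"
        assert overdispersion_fraction(m) > 0.9

    def test_delta_normalized_is_transformed(self):
        m = simulate_counts(500, 1000, dispersion=0.5, seed=1)
        n = delta_normalize(m, DeltaParams())
        assert detect_log_transform(n) == "transformed"

    def test_verdicts_stable_across_seeds(self):
        for seed in range(10):
            m = simulate_counts(300, 1000, dispersion=0.3, seed=seed)
            n = delta_normalize(m, DeltaParams())
            assert detect_log_transform(m) == "untransformed"
            assert detect_log_transform(n) == "transformed"

    def test_negative_values_short_circuit_to_transformed(self):
        X = sp.csr_matrix(np.array([[1.0, -0.5], [0.3, 0.2]]))
        m = GeneExpressionMatrix(X, stage="normalized")
        assert detect_log_transform(m) == "transformed"

    def test_degenerate_matrix_is_indeterminate(self):
        one_cell = GeneExpressionMatrix(sp.csr_matrix(np.ones((1, 50))), stage="counts")
        with pytest.raises(IndeterminateMatrixError):
            detect_log_transform(one_cell)
        constant = GeneExpressionMatrix(sp.csr_matrix(np.ones((30, 50))), stage="counts")
        with pytest.raises(IndeterminateMatrixError):
            detect_log_transform(constant)


class TestCountRankConsistency:
    def _matrix(self, tallies):
        data = np.concatenate([[v] * int(f) for v, f in tallies]).astype(float)
        return GeneExpressionMatrix(sp.csr_matrix(data[None, :]), stage="counts")

    def test_consistent_ladder_through_k3(self):
        m = self._matrix([(1, 500), (2, 200), (3, 80)])
        assert list(count_rank_consistency(m, 3)) == [100.0, 100.0, 100.0]

    def test_gap_fails_at_k2(self):
        m = self._matrix([(1, 500), (3, 200)])
        out = count_rank_consistency(m, 3)
        assert list(out) == [100.0, 0.0, 0.0]

    def test_cumulative_is_monotone_non_increasing(self, counts_300):
        out = count_rank_consistency(counts_300, 8)
        assert np.all(np.diff(out) <= 0)

    def test_per_rank_form_exposed(self):
        # value 3 sits at rank 3 even though rank 2 is wrong
        m = self._matrix([(1, 500), (5, 200), (3, 80)])
        per_rank = count_rank_consistency(m, 3, cumulative=False)
        assert list(per_rank) == [100.0, 0.0, 100.0]

    def test_simulated_consistency_decreases_with_k(self):
        m = simulate_counts(500, 2000, seed=0)
        out = count_rank_consistency(m, 5)
        assert out[2] >= out[4]
        assert out[0] > 99.0
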