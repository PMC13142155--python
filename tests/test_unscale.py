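"""Per-cell scale-factor estimation and the unscale step."""

import numpy as np
import pytest
import scipy.sparse as sp

from denorm import DeltaParams, GeneExpressionMatrix, delta_normalize, simulate_counts
from denorm.matrix import NO_LOG
from denorm.unscale import (
    UnsolvableCellError,
    estimate_scales,
    scale_closed_form,
    scale_regression,
    unscale_matrix,
)


def _scaled_from_counts(counts):
    scaled = delta_normalize(counts, DeltaParams(base=NO_LOG, pseudo_count=0))
    return GeneExpressionMatrix(scaled.X, counts.cell_ids, counts.gene_ids, "scaled")


class TestClosedForm:
    def test_unit_difference(self):
        assert scale_closed_form(0.001, 0.002) == pytest.approx(1000.0)

    def test_cell_scaled_up(self):
        assert scale_closed_form(4.0, 8.0) == pytest.approx(0.25)

    def test_forward_simulated_cell_gives_t_over_l(self):
        # counts 1 and 2 scaled by L/T with T=2500, L=1e4: s = T/L = 0.25
        x1, x2 = 1 * 1e4 / 2500, 2 * 1e4 / 2500
        assert scale_closed_form(x1, x2) == pytest.approx(0.25, abs=1e-15)

    def test_equal_values_unsolvable(self):
        with pytest.raises(UnsolvableCellError):
            scale_closed_form(3.0, 3.0)


class TestRegression:
    def test_noiseless_ladder_exact(self):
        c = np.arange(1, 6, dtype=float)
        x = c / 250.0
        s, resid = scale_regression(c, x)
        assert s == pytest.approx(250.0, rel=1e-6)
        assert resid < 1e-20

    def test_pseudo_count_convention(self):
        # with p retained in the model, x_i = c_i/s + p
        c = np.arange(1, 6, dtype=float)
        x = c / 250.0 + 1.0
        s, _ = scale_regression(c, x, pseudo_count=1.0)
        assert s == pytest.approx(250.0, rel=1e-6)

    def test_noisy_ladder_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(7)
        c = np.arange(1, 6, dtype=float)
        x = c / 250.0 + rng.normal(0, 1e-4, 5)
        s, _ = scale_regression(c, x)
        grid = np.linspace(100, 500, 2_000_001)
        obj = ((c[None, :] / grid[:, None] - x[None, :]) ** 2).sum(axis=1)
        s_oracle = grid[np.argmin(obj)]
        assert s == pytest.approx(s_oracle, rel=1e-3)
        # sigma=1e-4 noise on x1 ~ 0.004 is 2.5% relative: the estimate is
        # only expected back within ~1% of the truth
        assert s == pytest.approx(250.0, rel=1e-2)

    def test_agrees_with_closed_form_on_noiseless_pairs(self):
        c = np.arange(1, 6, dtype=float)
        x = c / 3.7
        s_reg, _ = scale_regression(c, x)
        s_cf = scale_closed_form(x[0], x[1])
        assert s_reg == pytest.approx(s_cf, rel=1e-6)

    def test_regression_residual_never_worse_than_closed_form(self):
        # both minimize the same objective; regression is the optimizer
        rng = np.random.default_rng(12)
        for _ in range(50):
            c = np.arange(1, 6, dtype=float)
            x = c / rng.uniform(0.1, 10) + rng.normal(0, 1e-3, 5)
            if x[1] <= x[0]:
                continue
            s_reg, resid_reg = scale_regression(c, x)
            s_cf = scale_closed_form(x[0], x[1])
            resid_cf = float(np.sum((c / s_cf - x) ** 2))
            assert resid_reg <= resid_cf + 1e-15

    def test_degenerate_pairs_flagged(self):
        with pytest.raises(UnsolvableCellError):
            scale_regression(np.array([1.0, 2.0]), np.array([5.0, 5.0]))
        with pytest.raises(UnsolvableCellError):
            scale_regression(np.array([1.0, 2.0]), np.array([3.0, -9.0]))


class TestEstimateScales:
    def test_closed_form_recovers_t_over_l_exactly(self):
        counts = simulate_counts(500, 1500, seed=6)
        scaled = _scaled_from_counts(counts)
        scales = estimate_scales(scaled, method="closed-form")
        truth = counts.row_sums() / 1e4
        ok = scales.solvable
        assert ok.all()
        assert np.allclose(scales.scales[ok], truth[ok], rtol=1e-9)

    def test_regression_method_also_exact_on_clean_ladders(self):
        counts = simulate_counts(200, 1500, seed=8)
        scaled = _scaled_from_counts(counts)
        scales = estimate_scales(scaled, method="regression")
        truth = counts.row_sums() / 1e4
        # regression uses ranks 1..5 positionally; cells whose ladder is clean
        # through rank 5 recover exactly, and the vast majority are clean
        rel = np.abs(scales.scales[scales.solvable] / truth[scales.solvable] - 1)
        assert np.median(rel) < 1e-9
        assert np.mean(rel < 1e-6) > 0.8

    def test_single_value_cell_flagged_not_dropped(self):
        X = sp.csr_matrix(np.array([[2.0, 2.0, 0.0], [1.0, 2.0, 3.0]]))
        m = GeneExpressionMatrix(X, stage="scaled")
        scales = estimate_scales(m)
        assert not scales.solvable[0] and scales.solvable[1]
        assert scales.n_cells == 2  # stays in Ntotal

    def test_unknown_method_rejected(self, counts_300):
        with pytest.raises(ValueError):
            estimate_scales(_scaled_from_counts(counts_300), method="magic")


class TestUnscaleMatrix:
    def _one_cell(self, values):
        return GeneExpressionMatrix(sp.csr_matrix(np.asarray([values])), stage="scaled")

    def _unit_scales(self, n=1):
        from denorm.unscale import CellScaleSet

        return CellScaleSet(
            scales=np.ones(n), solvable=np.ones(n, dtype=bool), method="closed-form"
        )

    def test_near_integer_cell_succeeds(self):
        m = self._one_cell([1.0004, 2.0001, 0.9998])
        out, scales = unscale_matrix(m, self._unit_scales(), refine=False)
        assert scales.mae[0] == pytest.approx((0.0004 + 0.0001 + 0.0002) / 3)
        assert scales.success[0]

    def test_half_integer_cell_fails(self):
        m = self._one_cell([0.5, 1.5])
        out, scales = unscale_matrix(m, self._unit_scales(), refine=False)
        assert scales.mae[0] == pytest.approx(0.5)
        assert not scales.success[0]

    def test_full_round_trip_recovers_counts_exactly(self):
        from denorm import round_to_counts

        counts = simulate_counts(300, 1500, seed=10)
        scaled = _scaled_from_counts(counts)
        scales = estimate_scales(scaled)
        denorm, scales = unscale_matrix(scaled, scales)
        assert scales.success.all()
        assert scales.matrix_mae < 1e-9
        assert (round_to_counts(denorm).X != counts.X).nnz == 0

    def test_collapsing_scale_does_not_fake_success(self):
        # a tiny factor pushes everything below 0.5: near-zero MAE but nothing
        # is recovered, so the cell must not count as a success
        from denorm.unscale import CellScaleSet

        m = self._one_cell([100.0, 200.0, 300.0])
        scales = CellScaleSet(
            scales=np.array([1e-5]), solvable=np.array([True]), method="closed-form"
        )
        out, scales = unscale_matrix(m, scales)
        assert scales.mae[0] < 0.05
        assert not scales.success[0]

    def test_mae_degrades_monotonically_with_storage_precision(self):
        from denorm import degrade_precision, denormalize

        counts = simulate_counts(150, 1200, seed=3)
        normalized = delta_normalize(counts, DeltaParams())
        medians = []
        for d in (8, 6, 4, 3, 2):
            out, rep = denormalize(degrade_precision(normalized, "decimals", decimals=d))
            medians.append(float(np.nanmedian(rep.scales_.mae)))
        assert all(b >= a - 1e-12 for a, b in zip(medians, medians[1:]))

    def test_refinement_is_fixed_point_on_exact_data(self):
        counts = simulate_counts(100, 1000, seed=21)
        scaled = _scaled_from_counts(counts)
        raw = estimate_scales(scaled)
        before = raw.scales.copy()
        _, refined = unscale_matrix(scaled, raw, refine=True)
        assert np.allclose(refined.scales, before, rtol=1e-12)

    def test_refinement_tightens_degraded_precision_recovery(self):
        from denorm import degrade_precision, denormalize

        counts = simulate_counts(150, 1200, seed=13)
        normalized = delta_normalize(counts, DeltaParams())
        stored = degrade_precision(normalized, "decimals", decimals=5)
        _, rep_ref = denormalize(stored, refine_scales=True)
        _, rep_raw = denormalize(stored, refine_scales=False)
        err_ref = np.abs(rep_ref.denormalized_.X.data - counts.X.data).max()
        err_raw = np.abs(rep_raw.denormalized_.X.data - counts.X.data).max()
        assert err_ref <= err_raw
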