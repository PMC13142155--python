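"""Log-base / pseudo-count inference and the inverse log transform."""

import math

import numpy as np
import pytest

from denorm import DeltaParams, GeneExpressionMatrix, delta_normalize, simulate_counts
from denorm.detransform import (
    TransformFit,
    apply_detransform,
    empirical_search,
    equation_objective,
    fit_base_pseudocount,
    validate_scaled,
)
from denorm.frequency import FrequencyTable, merge_near_duplicates
from denorm.matrix import NO_LOG

import scipy.sparse as sp


def _normalized(params, n_cells=150, n_genes=1200, seed=11):
    counts = simulate_counts(n_cells, n_genes, seed=seed)
    return counts, delta_normalize(counts, params)


def _pairs_for(s, base, pseudo):
    n1 = np.log(1.0 / s + pseudo) / math.log(base)
    n2 = np.log(2.0 / s + pseudo) / math.log(base)
    return n1, n2


class TestEquationIdentity:
    def test_single_cell_closed_identity(self):
        # s=100, b=2, p=1: N1=log2(1.01), N2=log2(1.02); 2*1.01 - 1.02 = 1
        n1, n2 = math.log2(1.01), math.log2(1.02)
        assert equation_objective(2.0, 1.0, np.array([n1]), np.array([n2])) < 1e-24

    def test_identity_over_random_parameter_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = rng.uniform(0.01, 100)
            b = rng.uniform(1.1, 50)
            p = rng.uniform(0, 5)
            n1, n2 = _pairs_for(np.array([s]), b, p)
            solved = 2 * b ** n1[0] - b ** n2[0]
            assert solved == pytest.approx(p, abs=1e-9 * max(1, p))


class TestEmpiricalSearch:
    def test_recovers_base10_pseudo_01(self):
        counts, n = _normalized(DeltaParams(base=10.0, pseudo_count=0.1))
        table = merge_near_duplicates(FrequencyTable.from_matrix(n))
        fit = empirical_search(n, table)
        assert fit is not None
        assert fit.base == 10.0 and fit.pseudo_count == 0.1
        assert fit.method == "empirical"
        assert fit.objective < 1e-10

    def test_base_outside_candidate_set_returns_none(self):
        counts, n = _normalized(DeltaParams(base=5.0))
        table = merge_near_duplicates(FrequencyTable.from_matrix(n))
        assert empirical_search(n, table) is None

    def test_scaled_untransformed_data_fails_all_log_candidates(self):
        counts, _ = _normalized(DeltaParams())
        scaled = delta_normalize(counts, DeltaParams(base=NO_LOG, pseudo_count=0))
        scaled = GeneExpressionMatrix(scaled.X, stage="normalized")
        table = merge_near_duplicates(FrequencyTable.from_matrix(scaled))
        assert empirical_search(scaled, table) is None


class TestFitBasePseudocount:
    def test_recovers_natural_log_with_unit_pseudo_count(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0.05, 0.5, 100)
        n1, n2 = _pairs_for(s, math.e, 1.0)
        fit = fit_base_pseudocount(n1, n2)
        assert fit.status == "accepted"
        assert fit.base == pytest.approx(math.e, abs=1e-3)
        assert fit.pseudo_count == pytest.approx(1.0, abs=1e-3)

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0.05, 0.5, 100)
        n1, n2 = _pairs_for(s, math.e, 1.0)
        bs = np.linspace(1.5, 12, 400)
        ps = np.linspace(0, 2, 200)
        obj = np.array([[equation_objective(b, p, n1, n2) for p in ps] for b in bs])
        ib, ip = np.unravel_index(np.argmin(obj), obj.shape)
        fit = fit_base_pseudocount(n1, n2)
        # the objective valley is diagonal in (b, p): allow a couple of
        # oracle grid steps of slack on each coordinate
        assert fit.base == pytest.approx(bs[ib], abs=2 * (bs[1] - bs[0]) + 1e-3)
        assert fit.pseudo_count == pytest.approx(ps[ip], abs=2 * (ps[1] - ps[0]) + 1e-3)
        assert fit.objective <= obj[ib, ip] + 1e-12

    def test_agrees_with_empirical_search_when_truth_in_candidates(self):
        counts, n = _normalized(DeltaParams(base=2.0, pseudo_count=1.0))
        table = merge_near_duplicates(FrequencyTable.from_matrix(n))
        emp = empirical_search(n, table)
        n1, n2, mask = table.top_pairs()
        opt = fit_base_pseudocount(n1[mask], n2[mask])
        assert abs(opt.base - emp.base) < 1e-3
        assert abs(opt.pseudo_count - emp.pseudo_count) < 1e-3

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError, match="unsolvable"):
            fit_base_pseudocount(np.ones(20), np.ones(20))
        with pytest.raises(ValueError, match=">= 10"):
            fit_base_pseudocount(np.arange(5.0), np.arange(5.0) + 1)

    def test_validation_callback_steers_selection(self):
        # with a validator that rejects everything the fit must come back rejected
        rng = np.random.default_rng(3)
        s = rng.uniform(0.05, 0.5, 50)
        n1, n2 = _pairs_for(s, math.e, 1.0)
        fit = fit_base_pseudocount(n1, n2, validate=lambda b, p: False)
        assert fit.status == "rejected"


class TestApplyDetransform:
    def test_exponential_minus_pseudo_count(self):
        m = GeneExpressionMatrix(
            sp.csr_matrix(np.array([[math.log(5.0), math.log(2.0)]])), stage="normalized"
        )
        fit = TransformFit(base=math.e, pseudo_count=1.0, method="empirical")
        out = apply_detransform(m, fit)
        assert out.X[0, 0] == pytest.approx(4.0, abs=1e-12)
        assert out.X[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert out.stage == "scaled"

    def test_no_log_is_identity(self):
        m = GeneExpressionMatrix(sp.csr_matrix(np.array([[1.5, 2.5]])), stage="normalized")
        fit = TransformFit(base=NO_LOG, pseudo_count=0.0, method="no-log")
        out = apply_detransform(m, fit)
        assert np.array_equal(out.X.data, m.X.data)

    def test_exact_inverse_of_log_step(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.001, 5000, 500)
        for b, p in ((2.0, 1.0), (math.e, 0.1), (10.0, 0.01)):
            n = np.log(v + p) / math.log(b)
            back = b**n - p
            assert np.allclose(back, v, rtol=1e-12, atol=1e-12)

    def test_sign_violations_recorded(self):
        m = GeneExpressionMatrix(sp.csr_matrix(np.array([[-2.0, 1.0]])), stage="normalized")
        fit = TransformFit(base=math.e, pseudo_count=1.0, method="empirical")
        out = apply_detransform(m, fit)
        assert 0 in out.meta["sign_violations"]

    def test_rejected_fit_refused(self):
        m = GeneExpressionMatrix(sp.csr_matrix(np.array([[1.0]])), stage="normalized")
        fit = TransformFit(base=2.0, pseudo_count=1.0, method="optimized", status="rejected")
        with pytest.raises(ValueError, match="rejected"):
            apply_detransform(m, fit)


class TestValidateScaled:
    def _scaled(self, rows):
        return GeneExpressionMatrix(sp.csr_matrix(np.asarray(rows, float)), stage="scaled")

    def test_sum_check_passes_on_near_equal_sums(self):
        m = self._scaled([[9999.7, 0.0], [10000.1, 0.0], [0.0, 10000.2]])
        res = validate_scaled(m, sum_tol=0.5)
        assert res.passed and res.path == "sum-check"

    def test_gene_filtered_sums_fail_but_probe_path_passes(self):
        # scaled counts with columns dropped: sums differ, values still exact
        counts = simulate_counts(60, 800, seed=4)
        scaled = delta_normalize(counts, DeltaParams(base=NO_LOG, pseudo_count=0))
        keep = np.arange(0, 800, 2)
        sub = scaled.subset_genes(keep)
        sub = GeneExpressionMatrix(sub.X, sub.cell_ids, sub.gene_ids, "scaled")
        res = validate_scaled(sub, sum_tol=0.5)
        assert res.passed and res.path == "probe-mse"
        assert res.detail["fraction_within_sum_tol"] < 0.9

    def test_non_ladder_data_fails_both_paths(self):
        rng = np.random.default_rng(0)
        m = self._scaled(rng.uniform(0.3, 50, size=(30, 40)))
        res = validate_scaled(m)
        assert not res.passed and res.path == "failed"
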