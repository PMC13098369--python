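"""Pearson gate and first-order partial correlation against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcgrn.correlation import (ConstantVectorError, CorrelationTriple,
                               DegenerateConditioningError, coexpressed_pairs,
                               partial_correlation, pcc_for_pair, pearson)
from pcgrn.synthetic import ExpressionMatrix, SampleInfo


def _matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [SampleInfo(f"WT_control_{j + 1}", "WT", "control", j + 1)
               for j in range(values.shape[1])]
    return ExpressionMatrix(values=values, genes=genes, samples=samples)


class TestPearson:
    @pytest.mark.parametrize("x, y, r_exp, p_exp", [
        ([1, 2, 3], [2, 4, 6], 1.0, 0.0),
        ([1, 2, 3], [3, 2, 1], -1.0, 0.0),
    ])
    def test_perfect_collinearity(self, x, y, r_exp, p_exp):
        res = pearson(x, y)
        assert res.r == pytest.approx(r_exp)
        assert res.p_value == p_exp

    def test_constant_vector_raises(self):
        with pytest.raises(ConstantVectorError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_p_value_matches_permutation_oracle(self, rng):
        """t-based two-sided p agrees with a 20000-resample permutation p."""
        n = 50
        x = rng.normal(size=n)
        y = 0.35 * x + rng.normal(size=n)
        res = pearson(x, y)
        n_perm = 20_000
        perms = np.array([np.corrcoef(x, rng.permutation(y))[0, 1]
                          for _ in range(n_perm)])
        p_perm = (1 + np.sum(np.abs(perms) >= abs(res.r))) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p_value - p_perm) < 3 * se + 1e-4


class TestCoexpressedPairs:
    def test_proportional_genes_detected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        expr = _matrix(np.vstack([x, 2 * x + 1]))
        pairs = coexpressed_pairs(expr, ["g0", "g1"])
        assert len(pairs) == 1 and pairs[0].genes == {"g0", "g1"}

    def test_orthogonal_residuals_yield_nothing(self):
        # rows constructed mutually orthogonal after centering -> r = 0
        rows = np.array([[1, -1, 1, -1, 0.0],
                         [1, 1, -1, -1, 0.0],
                         [1, -1, -1, 1, 0.0]])
        pairs = coexpressed_pairs(_matrix(rows), ["g0", "g1", "g2"])
        assert pairs == []

    def test_planted_block_matches_bruteforce(self, rng):
        """Correlated 5-gene block among independent genes: the pipeline
        output equals an all-pairs brute-force scan, and equals the 10
        within-block pairs."""
        n = 30
        driver = rng.normal(size=n)
        block = np.vstack([driver + rng.normal(scale=0.05, size=n)
                           for _ in range(5)])
        noise = rng.normal(size=(20, n))
        expr = _matrix(np.vstack([block, noise]))
        pairs = coexpressed_pairs(expr, expr.genes)
        got = {(p.gene_x, p.gene_y) for p in pairs}
        brute = set()
        for i in range(25):
            for j in range(i + 1, 25):
                res = pearson(expr.values[i], expr.values[j])
                if abs(res.r) >= 0.8 and res.p_value < 0.001:
                    brute.add(tuple(sorted((f"g{i}", f"g{j}"))))
        assert got == brute
        assert got == {(f"g{i}", f"g{j}") for i in range(5)
                       for j in range(i + 1, 5)}

    def test_threshold_monotonicity(self, benchmark_expr):
        loose = coexpressed_pairs(benchmark_expr, benchmark_expr.genes,
                                  cc_min=0.8)
        tight = coexpressed_pairs(benchmark_expr, benchmark_expr.genes,
                                  cc_min=0.9)
        assert {p.genes for p in tight} <= {p.genes for p in loose}


class TestPartialCorrelation:
    def test_conditioning_on_independent_variable_is_noop(self):
        t = CorrelationTriple(r_xy=0.9, r_xz=0.0, r_yz=0.0)
        assert partial_correlation(t) == pytest.approx(0.9)

    def test_full_mediation_vanishes_exactly(self):
        t = CorrelationTriple(r_xy=0.81, r_xz=0.9, r_yz=0.9)
        assert partial_correlation(t) == 0.0

    def test_degenerate_conditioning_rejected(self):
        with pytest.raises(DegenerateConditioningError):
            partial_correlation(CorrelationTriple(0.5, 1.0, 0.5))

    def test_printed_variant_differs_and_is_asymmetric(self):
        t = CorrelationTriple(r_xy=0.81, r_xz=0.9, r_yz=0.7)
        std = partial_correlation(t, formula="standard")
        lit = partial_correlation(t, formula="printed")
        assert std != pytest.approx(lit)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetry_in_x_and_y(self, seed):
        rng = np.random.default_rng(seed)
        # sample a valid correlation matrix to get a PSD triple
        a = rng.normal(size=(3, 6))
        r = np.corrcoef(a)
        t = CorrelationTriple(r_xy=r[0, 1], r_xz=r[0, 2], r_yz=r[1, 2])
        swapped = CorrelationTriple(r_xy=r[0, 1], r_xz=r[1, 2], r_yz=r[0, 2])
        assert partial_correlation(t) == pytest.approx(
            partial_correlation(swapped), abs=1e-12)

    def test_matches_regression_residual_oracle(self, rng):
        """Formula PCC equals the correlation of OLS residuals of x|z and
        y|z to 1e-10, over many random trivariate draws."""
        worst = 0.0
        for _ in range(1000):
            n = 200
            z = rng.normal(size=n)
            x = z + rng.normal(size=n)
            y = 0.8 * z + rng.normal(size=n)
            t = CorrelationTriple(r_xy=np.corrcoef(x, y)[0, 1],
                                  r_xz=np.corrcoef(x, z)[0, 1],
                                  r_yz=np.corrcoef(y, z)[0, 1])
            formula = partial_correlation(t)
            zc = np.column_stack([np.ones(n), z])
            rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
            ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
            oracle = np.corrcoef(rx, ry)[0, 1]
            worst = max(worst, abs(formula - oracle))
        assert worst < 1e-10


class TestPccForPair:
    def test_tf_in_pair_rejected(self, benchmark_expr):
        pairs = coexpressed_pairs(benchmark_expr, ["TF002", "TF003"])
        if pairs:
            with pytest.raises(ValueError):
                pcc_for_pair(benchmark_expr, pairs[0], "TF002")

    def test_true_mediator_collapses_pair(self, benchmark_net, benchmark_expr):
        """Siblings driven by their shared parent: conditioning on the
        parent leaves only independent noise."""
        kids = sorted(t for r, t in benchmark_net.edges
                      if r == benchmark_net.root_tf)
        pairs = coexpressed_pairs(benchmark_expr, kids)
        assert pairs, "some root children should be coexpressed"
        for pair in pairs:
            pcc = pcc_for_pair(benchmark_expr, pair, benchmark_net.root_tf)
            assert abs(pcc) < 0.3

    def test_independent_tf_preserves_pair_correlation(self, rng):
        n = 80
        driver = rng.normal(size=n)
        x = driver + rng.normal(scale=0.2, size=n)
        y = driver + rng.normal(scale=0.2, size=n)
        z = rng.normal(size=n)  # unrelated TF
        expr = _matrix(np.vstack([x, y, z]), genes=["gx", "gy", "tf"])
        pairs = coexpressed_pairs(expr, ["gx", "gy"])
        pcc = pcc_for_pair(expr, pairs[0], "tf")
        assert pcc == pytest.approx(pairs[0].result.r, abs=0.1)
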