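import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connectogene import (
    AssociationMatrix,
    TimeSeriesMatrix,
    association_matrix,
    correlation_matrix,
    fdr_threshold,
    fisher_z,
    minmax_normalize,
    remove_negatives,
)
from _oracles import bh_survivors, pearson_loop


class TestCorrelationMatrix:
    def test_identical_and_opposed_series(self, rng):
        x = rng.standard_normal(30)
        ts = np.column_stack([x, x, -x])
        a = correlation_matrix(ts)
        assert a.r[0, 1] == pytest.approx(1.0)
        assert a.r[0, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(a.r) == 0)

    def test_matches_textbook_pearson(self, rng):
        ts = rng.standard_normal((10, 5))
        a = correlation_matrix(ts)
        for i in range(5):
            for j in range(i + 1, 5):
                assert a.r[i, j] == pytest.approx(pearson_loop(ts[:, i], ts[:, j]), abs=1e-12)
                assert a.r[i, j] == a.r[j, i]

    def test_zero_variance_node_named(self):
        ts = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match="n1"):
            correlation_matrix(TimeSeriesMatrix(ts))

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match="timepoints"):
            correlation_matrix(np.ones((2, 4)))


class TestFisherZ:
    def test_values_and_odd_symmetry(self, rng):
        r = rng.uniform(-0.9, 0.9, size=(6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        a = AssociationMatrix(r)
        z = fisher_z(a)
        assert np.allclose(z.r, np.arctanh(r))
        zneg = fisher_z(AssociationMatrix(-r))
        assert np.allclose(zneg.r, -z.r)
        # r = 0.5 -> atanh evaluated by series: sum r^(2k+1)/(2k+1)
        series = sum(0.5 ** (2 * k + 1) / (2 * k + 1) for k in range(60))
        assert fisher_z(AssociationMatrix(np.array([[0, 0.5], [0.5, 0]]))).r[0, 1] == pytest.approx(series, abs=1e-12)

    def test_perfect_correlation_clipped_finite(self):
        a = AssociationMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.isfinite(fisher_z(a).r).all()


class TestRemoveNegatives:
    def test_mixed_matrix_zero_count(self, rng):
        r = rng.uniform(-1, 1, size=(8, 8))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        n_neg = int((r < 0).sum())
        out = remove_negatives(AssociationMatrix(r)).r
        assert int((out == 0).sum()) == n_neg + 8
        assert np.all(out[r >= 0] == r[r >= 0])


class TestFdrThreshold:
    def test_hand_run_bh(self):
        # craft correlations whose p-values are far apart; q = 0.005 keeps only the strongest
        n_tp = 50
        r = np.zeros((3, 3))
        r[0, 1] = r[1, 0] = 0.9   # p ~ 1e-18
        r[0, 2] = r[2, 0] = 0.15  # p ~ 0.3
        r[1, 2] = r[2, 1] = 0.02  # p ~ 0.9
        out = fdr_threshold(AssociationMatrix(r), n_timepoints=n_tp, q=0.005).r
        assert out[0, 1] == 0.9 and out[0, 2] == 0 and out[1, 2] == 0

    def test_survivors_match_bh_oracle(self, rng):
        n = 21  # 210 edges
        r = rng.uniform(-0.6, 0.6, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        n_tp = 30
        out = fdr_threshold(AssociationMatrix(r), n_timepoints=n_tp, q=0.2).r
        iu = np.triu_indices(n, 1)
        from scipy import stats
        t = r[iu] * np.sqrt((n_tp - 2) / (1 - r[iu] ** 2))
        p = 2 * stats.t.sf(np.abs(t), n_tp - 2)
        expected = bh_survivors(list(p), 0.2)
        got = {k for k in range(len(p)) if out[iu][k] != 0}
        assert got == expected

    def test_sparsity_monotone_in_q(self, rng):
        n = 15
        r = rng.uniform(-0.8, 0.8, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        a = AssociationMatrix(r)
        kept = [np.count_nonzero(fdr_threshold(a, 40, q).r) for q in (0.001, 0.01, 0.1, 0.5)]
        assert kept == sorted(kept)

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError):
            fdr_threshold(AssociationMatrix(np.zeros((3, 3))), n_timepoints=3)


class TestMinmaxNormalize:
    def test_affine_map_forced_by_definition(self):
        m = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0.0]])
        out = minmax_normalize(m)
        assert out[0, 1] == 0 and out[0, 2] == 0.5 and out[1, 2] == 1

    def test_idempotent(self, rng):
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        once = minmax_normalize(m)
        assert np.allclose(minmax_normalize(once), once)

    def test_constant_offdiag_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            minmax_normalize(np.ones((4, 4)))


class TestFullChain:
    def test_output_contract(self, rng):
        ts = rng.standard_normal((80, 25)) @ rng.standard_normal((25, 25))
        a = association_matrix(ts, q=0.05)
        off = a.r[~np.eye(a.n, dtype=bool)]
        assert np.allclose(a.r, a.r.T)
        assert off.min() == 0 and off.max() == 1
        assert np.all(np.diag(a.r) == 0)

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_chain_matches_naive_loop(self, seed):
        """Entrywise equivalence of the vectorized chain with per-pair loops."""
        rng = np.random.default_rng(seed)
        latent = rng.standard_normal(30)
        ts = 0.8 * latent[:, None] + rng.standard_normal((30, 12))
        a = association_matrix(ts, q=0.2)
        # naive: loop Pearson -> atanh -> clamp -> BH by hand -> minmax
        n = 12
        z = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    r = pearson_loop(ts[:, i], ts[:, j])
                    r = min(max(r, -(1 - 1e-7)), 1 - 1e-7)
                    z[i, j] = max(np.arctanh(r), 0.0)
        from scipy import stats
        iu = np.triu_indices(n, 1)
        rr = np.tanh(z[iu])
        p = 2 * stats.t.sf(np.abs(rr * np.sqrt(28 / (1 - rr**2))), 28)
        keep = bh_survivors(list(p), 0.2)
        zz = np.zeros_like(z)
        vals = [z[iu][k] if k in keep else 0.0 for k in range(len(p))]
        zz[iu] = vals
        zz = zz + zz.T
        lo, hi = zz[iu].min(), zz[iu].max()
        expected = (zz - lo) / (hi - lo)
        np.fill_diagonal(expected, 0)
        assert np.abs(a.r - expected).max() < 1e-10
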