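"""Sparse CCA: inner steps against independent oracles, fit invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neurocca as nc
from neurocca.errors import ValidationError
from neurocca.scca import l1_constrained_unit_vector, soft_threshold

from conftest import assert_scca_feasible


def classical_cca_first_correlation(x, z):
    """Generalized-eigenproblem oracle for the first canonical correlation."""
    x = x - x.mean(axis=0)
    z = z - z.mean(axis=0)
    n = x.shape[0]
    sxx, szz, sxz = x.T @ x / (n - 1), z.T @ z / (n - 1), x.T @ z / (n - 1)

    def isqrt(s):
        vals, vecs = np.linalg.eigh(s)
        return vecs @ np.diag(vals ** -0.5) @ vecs.T

    return np.linalg.svd(isqrt(sxx) @ sxz @ isqrt(szz), compute_uv=False)[0]


class TestSoftThreshold:
    @pytest.mark.parametrize("v,delta,nonneg,expected", [
        (3.0, 1.0, False, 2.0),
        (-3.0, 1.0, True, 0.0),
        (0.5, 1.0, False, 0.0),
        (-3.0, 1.0, False, -2.0),
    ])
    def test_definition(self, v, delta, nonneg, expected):
        assert soft_threshold([v], delta, nonneg)[0] == expected

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=20),
           st.floats(0, 5))
    def test_shrinks_magnitude_and_preserves_sign(self, v, delta):
        out = soft_threshold(v, delta)
        assert (np.abs(out) <= np.abs(v)).all()
        assert (out * np.asarray(v) >= 0).all()


class TestL1UnitVector:
    def test_inactive_budget_returns_plain_unit_vector(self):
        np.testing.assert_allclose(
            l1_constrained_unit_vector([3, 4], 1.414), [0.6, 0.8])

    def test_budget_one_selects_single_largest_coordinate(self):
        np.testing.assert_allclose(
            l1_constrained_unit_vector([3, 4], 1.0), [0, 1], atol=1e-9)

    def test_matches_dense_grid_search_oracle(self):
        a = np.array([1.0, 2.0, 3.0])
        u = l1_constrained_unit_vector(a, 1.5)
        # oracle: smallest delta on a dense grid whose normalized
        # soft-threshold meets the budget
        grid = np.linspace(0, 3, 3_000_001)
        for d in grid:
            s = soft_threshold(a, d)
            nrm = np.linalg.norm(s)
            if nrm and np.abs(s / nrm).sum() <= 1.5:
                oracle = s / nrm
                break
        np.testing.assert_allclose(u, oracle, atol=1e-6)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000), st.booleans())
    def test_feasibility_on_random_instances(self, seed, nonneg):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 40))
        a = rng.standard_normal(p) * rng.uniform(0.01, 100)
        if nonneg and (a <= 0).all():
            a[0] = abs(a[0]) + 0.1
        c = float(rng.uniform(1, np.sqrt(p)))
        u = l1_constrained_unit_vector(a, c, nonneg=nonneg)
        assert np.linalg.norm(u) <= 1 + 1e-9
        assert np.abs(u).sum() <= c + 1e-6
        if nonneg:
            assert (u >= 0).all()

    def test_rejects_infeasible_budget_and_zero_vector(self):
        with pytest.raises(ValidationError):
            l1_constrained_unit_vector([1, 2], 0.5)
        with pytest.raises(ValidationError):
            l1_constrained_unit_vector([0.0, 0.0], 1.2)

    def test_tied_maxima_pick_lowest_index(self):
        u = l1_constrained_unit_vector([2.0, 2.0, 1.0], 1.0)
        np.testing.assert_allclose(u, [1, 0, 0])


class TestFitScca:
    def test_identical_single_columns_give_correlation_one(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal((20, 1))
        r = nc.fit_scca(col, col)
        assert r.canonical_correlation == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(r.weight_x), [1.0])
        np.testing.assert_allclose(np.abs(r.weight_z), [1.0])

    def test_unconstrained_whitened_fit_equals_classical_cca(self):
        rng = np.random.default_rng(1)
        n, p, q = 50, 2, 2
        shared = rng.standard_normal((n, 2))
        x = shared @ rng.standard_normal((2, p)) + rng.standard_normal((n, p))
        z = shared @ rng.standard_normal((2, q)) + rng.standard_normal((n, q))
        params = nc.SccaParams(l1_fraction_x=1, l1_fraction_z=1,
                               nonneg_x=False, nonneg_z=False,
                               scale="whiten", tol=1e-12, max_iter=5000)
        r = nc.fit_scca(x, z, params)
        assert r.canonical_correlation == pytest.approx(
            classical_cca_first_correlation(x, z), abs=1e-6)

    def test_planted_supports_recovered(self, coupled_cohort):
        from conftest import wscore_views
        cohort, gm, wm = coupled_cohort
        wg, ww = wscore_views(cohort, gm, wm)
        params = nc.SccaParams()
        r = nc.fit_scca(wg, ww, params)
        assert_scca_feasible(r, params, 60, 80)
        top_x = set(np.argsort(-r.weight_x)[:10])
        top_z = set(np.argsort(-r.weight_z)[:10])
        assert len(top_x & set(range(10))) >= 8
        assert len(top_z & set(range(10))) >= 8

    def test_feasibility_and_monotone_ascent_across_configs(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            n = int(rng.integers(10, 40))
            p, q = int(rng.integers(3, 25)), int(rng.integers(3, 25))
            x = rng.standard_normal((n, p))
            z = rng.standard_normal((n, q))
            params = nc.SccaParams(
                l1_fraction_x=float(rng.uniform(0.2, 1.0)),
                l1_fraction_z=float(rng.uniform(0.2, 1.0)),
                nonneg_x=bool(rng.integers(2)),
                nonneg_z=bool(rng.integers(2)))
            r = nc.fit_scca(x, z, params)
            assert_scca_feasible(r, params, p, q)

    def test_column_scale_invariance_under_standardize(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((30, 8))
        z = rng.standard_normal((30, 6))
        params = nc.SccaParams(scale="standardize")
        r1 = nc.fit_scca(x, z, params)
        x2 = x.copy()
        x2[:, 3] *= 50.0
        r2 = nc.fit_scca(x2, z, params)
        np.testing.assert_allclose(r1.weight_x, r2.weight_x, atol=1e-8)
        assert r1.canonical_correlation == pytest.approx(
            r2.canonical_correlation, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValidationError):
            nc.fit_scca(rng.standard_normal((10, 3)),
                        rng.standard_normal((9, 3)))
        with pytest.raises(ValidationError):
            nc.fit_scca(np.ones((10, 3)), rng.standard_normal((10, 3)))
        with pytest.raises(ValidationError):
            nc.fit_scca(rng.standard_normal((2, 3)),
                        rng.standard_normal((2, 3)))
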