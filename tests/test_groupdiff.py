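"""GLM t maps, TFCE enhancement, and permutation FWE correction."""

import numpy as np
import pandas as pd
import pytest

import neurocca as nc
from neurocca.errors import ValidationError
from neurocca.groupdiff import GlmDesign, TfceParams, glm_tstat, tfce


def two_group_design(n0, n1):
    x = np.column_stack([np.ones(n0 + n1), np.r_[np.zeros(n0), np.ones(n1)]])
    return GlmDesign(x, np.array([0.0, 1.0]), ("intercept", "group"))


class TestGlmTstat:
    def test_identical_groups_give_zero_t(self):
        y = np.tile(np.r_[1.0, 2.0, 3.0, 1.0, 2.0, 3.0][:, None], (1, 4))
        t = glm_tstat(y, two_group_design(3, 3))
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_closed_form_two_sample_t(self):
        # groups {1,2,3} vs {4,5,6}: means 2 vs 5, pooled SD 1,
        # t = 3 / (1 * sqrt(1/3 + 1/3)) = 3.674...
        y = np.array([1.0, 2, 3, 4, 5, 6])[:, None]
        t = glm_tstat(y, two_group_design(3, 3))
        assert t[0] == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-10)

    def test_orthogonal_covariate_leaves_t_unchanged(self):
        rng = np.random.default_rng(0)
        n = 40
        group = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        y = rng.standard_normal((n, 6))
        base = GlmDesign(np.column_stack([np.ones(n), group]),
                         np.array([0.0, 1.0]), ("i", "g"))
        t0 = glm_tstat(y, base)
        cov = rng.standard_normal(n)
        # orthogonalize against the base design and the outcomes
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), group, y]))
        cov = cov - q @ (q.T @ cov)
        aug = GlmDesign(np.column_stack([np.ones(n), group, cov]),
                        np.array([0.0, 1.0, 0.0]), ("i", "g", "c"))
        t1 = glm_tstat(y, aug)
        # identical contrast estimate and residuals; only dof changes se
        np.testing.assert_allclose(t1 / t0,
                                   np.sqrt((n - 2) / (n - 3)) ** -1, atol=1e-10)

    def test_rank_deficient_design_rejected(self):
        x = np.column_stack([np.ones(6), np.ones(6)])
        d = GlmDesign(x, np.array([0.0, 1.0]), ("a", "b"))
        with pytest.raises(ValidationError):
            glm_tstat(np.zeros((6, 1)), d)


class TestTfce:
    def test_zero_map_enhances_to_zero(self, grid5):
        assert np.abs(tfce(np.zeros(25), grid5)).max() == 0.0

    def test_isolated_peak_matches_closed_form_integral(self, grid5):
        # single feature of height h: enhanced -> integral_0^h x^H dx
        # = h^(H+1)/(H+1) as dh -> 0; within 5% already at dh = 0.1 h
        s = np.zeros(25)
        s[7] = 2.0
        e = tfce(s, grid5, TfceParams(E=1.0, H=2.0, dh=0.2))
        assert e[7] == pytest.approx(2.0 ** 3 / 3.0, rel=0.05)
        fine = tfce(s, grid5, TfceParams(E=1.0, H=2.0, dh=0.002))
        assert fine[7] == pytest.approx(2.0 ** 3 / 3.0, rel=1e-3)

    def test_scaling_identity_k_to_the_h_plus_one(self, grid5):
        rng = np.random.default_rng(1)
        params = TfceParams(E=1.0, H=2.0)  # relative dh scales with the map
        for _ in range(10):
            m = rng.standard_normal(25)
            k = float(rng.uniform(0.5, 5.0))
            e1 = tfce(m, grid5, params)
            e2 = tfce(k * m, grid5, params)
            np.testing.assert_allclose(e2, k ** 3 * e1, atol=1e-6 * k ** 3)

    def test_monotone_in_the_statistic(self, grid5):
        rng = np.random.default_rng(2)
        m = np.abs(rng.standard_normal(25))
        base = tfce(m, grid5)
        for i in (0, 12, 24):
            raised = m.copy()
            raised[i] += 0.7
            assert (tfce(raised, grid5) >= base - 1e-12).all()

    def test_isolated_features_reduce_to_height_integral(self):
        # no adjacency and E = 0: the enhanced value is the Riemann sum of
        # h^H dh up to each height -> h^(H+1)/(H+1)
        g = nc.FeatureGeometry(kind="skeleton", n_features=4,
                               grid_shape=(1, 4))
        import scipy.sparse as sp
        g._adjacency = sp.csr_matrix((4, 4), dtype=np.int8)
        heights = np.array([0.5, 1.0, 2.0, 3.0])
        e = tfce(heights, g, TfceParams(E=0.0, H=2.0, dh=0.001))
        np.testing.assert_allclose(e, heights ** 3 / 3.0, rtol=0.01)

    def test_negative_values_enhanced_symmetrically(self, grid5):
        rng = np.random.default_rng(3)
        m = rng.standard_normal(25)
        np.testing.assert_allclose(tfce(-m, grid5), -tfce(m, grid5),
                                   atol=1e-12)


@pytest.fixture(scope="module")
def null_data():
    cfg = nc.GeneratorConfig(
        n_per_group={"NC": 16, "pureADD": 16}, groups=("NC", "pureADD"),
        p_thickness=36, p_dti=4, latent_strength=0.0,
        group_effect_gm=0.0, group_effect_wm=0.0, seed=21)
    return nc.generate_cohort(cfg)


class TestPermutationFwe:
    def test_same_seed_reproduces_corrected_p(self, null_data):
        cohort, gm, _ = null_data
        design = nc.design_from_cohort(cohort, "pureADD")
        kw = dict(n_permutations=100, seed=5)
        s1 = nc.permutation_fwe(gm, design, gm.geometry, **kw)
        s2 = nc.permutation_fwe(gm, design, gm.geometry, **kw)
        np.testing.assert_array_equal(s1.p_fwe, s2.p_fwe)
        assert (s1.p_fwe >= 1 / 101).all()
        assert (s1.p_fwe <= 1.0).all()

    def test_corrected_p_monotone_in_enhanced_statistic(self, null_data):
        cohort, gm, _ = null_data
        design = nc.design_from_cohort(cohort, "pureADD")
        sm = nc.permutation_fwe(gm, design, gm.geometry,
                                n_permutations=200, seed=6)
        pos = sm.enhanced > 0
        if pos.sum() > 1:
            order = np.argsort(sm.enhanced[pos])
            assert (np.diff(sm.p_fwe[pos][order]) <= 1e-12).all()

    def test_planted_cluster_detected_and_background_clean(self):
        cfg = nc.GeneratorConfig(
            n_per_group={"NC": 25, "pureSVaD": 25}, groups=("NC", "pureSVaD"),
            p_thickness=64, p_dti=4, latent_strength=0.0,
            group_effect_gm=-1.0, noise_sd_gm=0.25,
            affected_gm=list(range(8)), seed=22)
        cohort, gm, _ = nc.generate_cohort(cfg)
        design = nc.design_from_cohort(cohort, "pureSVaD")
        sm = nc.permutation_fwe(gm, design, gm.geometry,
                                n_permutations=300, seed=7)
        sig = sm.significant_mask()
        assert sig[:8].all()          # the affected block reaches FWE < .05
        assert sig[8:].sum() <= 2     # background essentially clean
        assert (sm.raw_stat[:8] < 0).all()  # thinning: patients lower
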