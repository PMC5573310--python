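import numpy as np
import pytest

import neurocca as nc


@pytest.fixture(scope="session")
def small_cohort():
    """Controls-only cohort with two small feature views, no coupling."""
    cfg = nc.GeneratorConfig(
        n_per_group={"NC": 40}, groups=("NC",),
        p_thickness=30, p_dti=36, latent_strength=0.0, seed=11)
    return nc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def coupled_cohort():
    """Controls-only cohort with a strong planted rank-1 GM-WM coupling."""
    cfg = nc.GeneratorConfig(
        n_per_group={"NC": 40}, groups=("NC",),
        p_thickness=60, p_dti=80,
        latent_strength=0.6, noise_sd_gm=0.25, noise_sd_wm=0.25,
        latent_support_gm=list(range(10)), latent_support_wm=list(range(10)),
        seed=12)
    return nc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def grid5():
    return nc.make_geometry("skeleton", (5, 5))


def wscore_views(cohort, gm, wm):
    """Fit normative models on the (all-control) cohort and W-score it."""
    mg = nc.fit_normative_model(gm, cohort)
    mw = nc.fit_normative_model(wm, cohort)
    return (nc.compute_wscores(mg, gm, cohort),
            nc.compute_wscores(mw, wm, cohort))


def assert_scca_feasible(result, params, p, q):
    """Check every constraint the returned weight vectors must satisfy."""
    for w, frac, nonneg, dim in [
            (result.weight_x, params.l1_fraction_x, params.nonneg_x, p),
            (result.weight_z, params.l1_fraction_z, params.nonneg_z, q)]:
        budget = max(1.0, frac * np.sqrt(dim))
        assert np.linalg.norm(w) <= 1 + 1e-8
        assert np.abs(w).sum() <= budget + 1e-6
        if nonneg:
            assert (w >= 0).all()
    trace = np.asarray(result.objective_trace)
    if trace.size > 1:
        assert (np.diff(trace) >= -1e-8 * (1 + np.abs(trace[:-1]))).all(), \
            "objective must ascend monotonically"
    assert -1 - 1e-12 <= result.canonical_correlation <= 1 + 1e-12
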