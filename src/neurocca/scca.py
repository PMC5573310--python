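"""Sparse canonical correlation analysis by penalized matrix decomposition.

Given two centered views ``X`` (n x p) and ``Z`` (n x q) over the same
subjects, find weight vectors ``u`` and ``v`` maximizing the coupling
objective

    u' X' Z v      subject to   ||u||_2 <= 1, ||u||_1 <= c_x, (u >= 0)
                                ||v||_2 <= 1, ||v||_1 <= c_z, (v >= 0)

by alternating exact maximization over one weight vector with the other
held fixed.  Each half step is a soft-thresholded, L2-normalized copy of
the cross-product image (``X'Zv`` or ``Z'Xu``), with the threshold found by
binary search so the L1 budget is met; the objective is therefore
nondecreasing across iterations.  The L1 budget on a unit vector can range
only in ``[1, sqrt(p)]``, so budgets are parameterized as a fraction of
``sqrt(p)``; the default fraction 0.5 keeps roughly half of the features
active, and the optional non-negativity ("positivity") constraint — on by
default for both views — restricts weights to coherent, same-signed
patterns.

When both budgets are inactive (fraction 1) and positivity is off, the
iteration converges to the leading singular pair of ``X'Z``, i.e. the
maximal-covariance directions; that equals classical CCA exactly when each
view is whitened, which ``scale="whiten"`` provides.  The default
``scale="center"`` only removes column means, because the intended inputs
are W-score matrices whose columns already have SD ~ 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import as_matrix, FeatureMatrix
from .errors import ValidationError
from .wscore import WScoreMatrix

_ASCENT_SLACK = 1e-9


@dataclass
class SccaParams:
    """Tuning parameters of the sparse CCA fit.

    l1_fraction_x, l1_fraction_z : float in (0, 1]
        L1 budget per view as a fraction of sqrt(p); 1 disables sparsity.
    nonneg_x, nonneg_z : bool
        Positivity constraint per view (default on).
    scale : {"center", "standardize", "whiten"}
        Column handling before the fit.
    init : {"first_svd", "random"}
        Start ``v`` from the leading right singular vector of X'Z, or from
        a seeded random direction (for degenerate cross-products).
    """

    l1_fraction_x: float = 0.5
    l1_fraction_z: float = 0.5
    nonneg_x: bool = True
    nonneg_z: bool = True
    max_iter: int = 200
    tol: float = 1e-8
    init: str = "first_svd"
    seed: int | None = None
    scale: str = "center"

    def validate(self) -> None:
        for f in (self.l1_fraction_x, self.l1_fraction_z):
            if not 0 < f <= 1:
                raise ValidationError("l1 fractions must lie in (0, 1]")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.init not in ("first_svd", "random"):
            raise ValidationError(f"unknown init {self.init!r}")
        if self.scale not in ("center", "standardize", "whiten"):
            raise ValidationError(f"unknown scale {self.scale!r}")


@dataclass
class SccaResult:
    """First canonical pair: weights, correlation, convergence trace."""

    weight_x: np.ndarray
    weight_z: np.ndarray
    canonical_correlation: float
    iterations: int
    converged: bool
    objective_trace: list = field(default_factory=list)
    feature_ids_x: pd.Index | None = None
    feature_ids_z: pd.Index | None = None

    def weights_frame(self, view: str) -> pd.DataFrame:
        w = self.weight_x if view == "x" else self.weight_z
        ids = self.feature_ids_x if view == "x" else self.feature_ids_z
        if ids is None:
            ids = pd.RangeIndex(len(w))
        return pd.DataFrame({"feature": ids, "weight": w})


def soft_threshold(v, delta: float, nonneg: bool = False) -> np.ndarray:
    """Elementwise ``sign(v) * max(|v| - delta, 0)``.

    With ``nonneg`` set, negative inputs are clamped to zero before the
    shrinkage (positivity constraint).
    """
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    v = np.asarray(v, dtype=float)
    if nonneg:
        v = np.maximum(v, 0.0)
    return np.sign(v) * np.maximum(np.abs(v) - delta, 0.0)


def l1_constrained_unit_vector(
        a, c: float, nonneg: bool = False,
        tol: float = 1e-12, max_bisect: int = 100) -> np.ndarray:
    """Maximize ``u'a`` over unit vectors with an L1 budget.

    Returns ``u = S(a, delta) / ||S(a, delta)||_2`` with ``delta`` the
    smallest soft threshold at which ``||u||_1 <= c`` (binary search);
    ``delta = 0`` when the plain unit vector is already feasible.  The
    budget must satisfy ``c >= 1`` (smaller budgets are infeasible under a
    unit L2 norm).  If ties at the maximum entry prevent the budget from
    being reached, the tied entry with the lowest index wins.
    """
    a = np.asarray(a, dtype=float)
    if c < 1:
        raise ValidationError("L1 budget must be >= 1 for a unit vector")
    work = np.maximum(a, 0.0) if nonneg else a
    amax = np.max(np.abs(work)) if work.size else 0.0
    if amax == 0.0:
        if np.any(np.asarray(a) != 0):
            # positivity clamped everything away: the constrained optimum
            # is the zero vector
            return np.zeros_like(a)
        raise ValidationError("cannot normalize an all-zero vector")

    def unit(delta):
        s = soft_threshold(work, delta)
        nrm = np.linalg.norm(s)
        return s / nrm if nrm > 0 else s

    u = unit(0.0)
    if np.abs(u).sum() <= c + tol:
        return u
    delta = _exact_delta(np.abs(work), c)
    if delta is not None:
        u = unit(delta)
        if np.abs(u).sum() <= c + 1e-9:
            return u
    # fallback: binary search on the (decreasing) normalized L1 norm
    lo, hi = 0.0, amax * (1.0 - 1e-12)
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        if np.abs(unit(mid)).sum() > c:
            lo = mid
        else:
            hi = mid
    u = unit(hi)
    if np.abs(u).sum() > c + 1e-6:
        # tied maxima make the budget unreachable by thresholding alone:
        # fall back to the single tied coordinate with the lowest index
        i = int(np.argmax(np.abs(work)))
        e = np.zeros_like(work)
        e[i] = np.sign(work[i]) if work[i] != 0 else 1.0
        return e
    return u


def _exact_delta(b: np.ndarray, c: float) -> float | None:
    """Smallest delta with ||S(b, delta)||_1 / ||S(b, delta)||_2 = c.

    On the interval where the top-m magnitudes stay active the constraint
    is a quadratic in delta; scanning all m with cumulative sums gives the
    root in closed form.  Returns None when no clean root exists (e.g. tied
    maxima), in which case the caller bisects.
    """
    bs = np.sort(b)[::-1]
    p = bs.size
    m = np.arange(1, p + 1, dtype=float)
    s1 = np.cumsum(bs)
    s2 = np.cumsum(bs ** 2)
    aa = m * (m - c ** 2)
    bb = 2.0 * s1 * (c ** 2 - m)
    cc = s1 ** 2 - c ** 2 * s2
    lo = np.append(bs[1:], 0.0)          # interval [lo_m, hi_m) per m
    hi = bs
    best = None
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = bb ** 2 - 4.0 * aa * cc
        sq = np.sqrt(np.maximum(disc, 0.0))
        roots = np.stack([(-bb + sq) / (2.0 * aa), (-bb - sq) / (2.0 * aa),
                          np.where(bb != 0, -cc / bb, np.nan)])
    quad = np.abs(aa) > 1e-12 * np.maximum(m ** 2, 1.0)
    roots[0:2, ~quad] = np.nan           # linear case: only the third row
    roots[2, quad] = np.nan
    eps = 1e-12 * (1.0 + bs[0])
    valid = np.isfinite(roots) & (roots >= lo - eps) & (roots < hi) \
        & (roots >= 0)
    if valid.any():
        best = float(np.min(roots[valid]))
    return best


def _prepare(x: np.ndarray, scale: str, label: str) -> np.ndarray:
    x = x - x.mean(axis=0)
    if scale == "standardize":
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    elif scale == "whiten":
        n, p = x.shape
        if n <= p:
            raise ValidationError(
                f"whitening view {label} needs n > p (got n={n}, p={p})")
        cov = x.T @ x / (n - 1)
        vals, vecs = np.linalg.eigh(cov)
        if vals.min() <= 1e-12 * vals.max():
            raise ValidationError(f"view {label} is rank deficient; "
                                  "cannot whiten")
        x = x @ (vecs / np.sqrt(vals)) @ vecs.T
    if not np.any(x):
        raise ValidationError(f"view {label} is constant (all zero after "
                              "centering)")
    return x


def _init_v(c: np.ndarray, params: SccaParams) -> np.ndarray:
    q = c.shape[1]
    if params.init == "random":
        rng = np.random.default_rng(params.seed)
        v = rng.standard_normal(q)
    elif min(c.shape) <= 5:
        v = np.linalg.svd(c, full_matrices=False)[2][0]
    else:
        from scipy.sparse.linalg import svds
        try:
            v = svds(c, k=1)[2][0]
        except Exception:
            v = np.linalg.svd(c, full_matrices=False)[2][0]
    if v.sum() < 0:  # deterministic sign
        v = -v
    return v / np.linalg.norm(v)


def fit_scca(x, z, params: SccaParams | None = None) -> SccaResult:
    """Fit the first sparse canonical pair of two views.

    Views may be :class:`~neurocca.wscore.WScoreMatrix`,
    :class:`~neurocca.containers.FeatureMatrix`, DataFrame or ndarray; rows
    must be the same subjects in the same order (checked when both sides
    carry subject indices).  Returns the weight vectors, the Pearson
    correlation of the final projections, and the per-iteration objective
    trace (guaranteed nondecreasing).
    """
    params = params or SccaParams()
    params.validate()
    ids_x = ids_z = None
    feats_x = feats_z = None
    for side, view in (("x", x), ("z", z)):
        if isinstance(view, (FeatureMatrix, WScoreMatrix)):
            if side == "x":
                ids_x, feats_x = view.values.index, view.values.columns
            else:
                ids_z, feats_z = view.values.index, view.values.columns
    if ids_x is not None and ids_z is not None and not ids_x.equals(ids_z):
        raise ValidationError("the two views have mismatched subject sets")
    xm, zm = as_matrix(x), as_matrix(z)
    if xm.shape[0] != zm.shape[0]:
        raise ValidationError("views have different numbers of subjects")
    n = xm.shape[0]
    if n < 3:
        raise ValidationError("sparse CCA needs at least 3 subjects")
    if np.isnan(xm).any() or np.isnan(zm).any():
        raise ValidationError("views contain NaN; drop degenerate features "
                              "before fitting")
    xm = _prepare(xm, params.scale, "x")
    zm = _prepare(zm, params.scale, "z")
    p, q = xm.shape[1], zm.shape[1]
    c_x = max(1.0, params.l1_fraction_x * np.sqrt(p))
    c_z = max(1.0, params.l1_fraction_z * np.sqrt(q))

    cross = xm.T @ zm
    v = _init_v(cross, params)
    u = np.zeros(p)
    obj_prev = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        u = l1_constrained_unit_vector(cross @ v, c_x, params.nonneg_x)
        if not np.any(u):
            break
        v = l1_constrained_unit_vector(cross.T @ u, c_z, params.nonneg_z)
        if not np.any(v):
            break
        obj = float(u @ cross @ v)
        trace.append(obj)
        if obj < obj_prev - _ASCENT_SLACK * (1.0 + abs(obj_prev)):
            raise RuntimeError(
                "sparse CCA objective decreased; this indicates a bug in "
                "the alternating update")
        if np.isfinite(obj_prev) and abs(obj - obj_prev) <= \
                params.tol * (1.0 + abs(obj)):
            converged = True
            break
        obj_prev = obj

    px, pz = xm @ u, zm @ v
    if px.std() == 0 or pz.std() == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(px, pz)[0, 1])
    return SccaResult(
        weight_x=u, weight_z=v, canonical_correlation=corr,
        iterations=it, converged=converged, objective_trace=trace,
        feature_ids_x=feats_x, feature_ids_z=feats_z)
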