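"""Pair-permutation significance test for sparse CCA.

The null hypothesis is that the two modality views carry no subject-level
coupling: any observed canonical correlation would then be an artifact of
the fitting procedure.  The test reshuffles which white-matter image is
paired with which gray-matter image — by default through *derangements*
(permutations without fixed points), so that no subject ever keeps its own
pair — refits the sparse CCA with identical parameters on every reshuffled
pairing, and reports the exceedance ratio

    p = #{ null correlation > observed correlation } / n_permutations

with a strict inequality and no add-one smoothing (``add_one=True`` gives
the guaranteed-positive (1 + count)/(1 + B) variant).  The default number
of permutations is 2,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import as_matrix
from .errors import ValidationError
from .scca import SccaParams, fit_scca


@dataclass
class PermutationScheme:
    n_subjects: int
    n_permutations: int = 2000
    forbid_fixed_points: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        if self.forbid_fixed_points and self.n_subjects < 2:
            raise ValidationError(
                "no derangement exists for fewer than 2 subjects")
        if self.n_subjects < 2:
            raise ValidationError("need at least 2 subjects")


@dataclass
class PermutationVerdict:
    observed_correlation: float
    null_correlations: np.ndarray
    p_value: float
    scheme: PermutationScheme
    n_failed: int = 0
    add_one: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def permute_pairs(scheme: PermutationScheme, iteration: int) -> np.ndarray:
    """Draw the ``iteration``-th reshuffling of subject pairings.

    Uniform over all permutations of ``n_subjects`` indices, or over all
    derangements when fixed points are forbidden (rejection sampling, ~e
    rejections expected per draw).  Fully determined by
    ``(scheme.seed, iteration)``.
    """
    scheme.validate()
    if iteration < 0:
        raise ValidationError("iteration must be >= 0")
    rng = np.random.default_rng([scheme.seed, iteration])
    n = scheme.n_subjects
    while True:
        perm = rng.permutation(n)
        if not scheme.forbid_fixed_points or not np.any(perm == np.arange(n)):
            return perm


def scca_permutation_test(
        x, z,
        params: SccaParams | None = None,
        scheme: PermutationScheme | None = None,
        add_one: bool = False,
) -> PermutationVerdict:
    """Observed sparse-CCA correlation against its pair-reshuffled null.

    Sparseness and positivity parameters are held fixed across
    permutations (the model is tuned once, then tested).  Individual
    permutation fits that fail are counted; more than 5% failures aborts.
    """
    params = params or SccaParams()
    xm, zm = as_matrix(x), as_matrix(z)
    if xm.shape[0] != zm.shape[0]:
        raise ValidationError("views have different numbers of subjects")
    scheme = scheme or PermutationScheme(n_subjects=xm.shape[0])
    if scheme.n_subjects != xm.shape[0]:
        raise ValidationError("scheme.n_subjects does not match the data")
    scheme.validate()

    observed = fit_scca(xm, zm, params).canonical_correlation
    nulls = np.full(scheme.n_permutations, np.nan)
    n_failed = 0
    max_failed = 0.05 * scheme.n_permutations
    for b in range(scheme.n_permutations):
        perm = permute_pairs(scheme, b)
        try:
            nulls[b] = fit_scca(xm, zm[perm], params).canonical_correlation
        except (ValidationError, RuntimeError, np.linalg.LinAlgError):
            n_failed += 1
            if n_failed > max_failed:
                raise RuntimeError(
                    f"more than 5% of permutation fits failed "
                    f"({n_failed}/{b + 1})")
    ok = nulls[~np.isnan(nulls)]
    count = int(np.sum(ok > observed))
    if add_one:
        p = (1 + count) / (1 + ok.size)
    else:
        p = count / ok.size
    return PermutationVerdict(
        observed_correlation=observed, null_correlations=nulls,
        p_value=float(p), scheme=scheme, n_failed=n_failed, add_one=add_one)
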