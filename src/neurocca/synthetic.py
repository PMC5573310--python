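"""Synthetic multimodal cohort generator.

Emulates the data structure that the downstream analysis assumes, at desk
scale: a four-group dementia cohort (normal controls, pure Alzheimer's
dementia, pure subcortical vascular dementia, and mixed dementia) with

* per-group covariate distributions (age, sex, education) patterned on the
  demographics of a typical memory-clinic sample of this design,
* linear age/sex/education effects on every feature,
* a group-specific mean shift in a designated set of "affected" features
  (negative for cortical thickness and FA, positive for radial/axial
  diffusivity, matching the directionality of degeneration),
* a rank-1 latent factor that couples a sparse subset of gray-matter
  features with a sparse subset of white-matter features across subjects —
  exactly the structure sparse CCA is designed to recover, and
* i.i.d. Gaussian measurement noise.

Features are exchangeable within supports: no spatial autocorrelation is
simulated beyond the adjacency used later by TFCE.  Both views are laid out
on a 2D toy lattice so that cluster-based statistics have an adjacency to
work with.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import GROUPS, FeatureMatrix, validate_cohort
from .errors import ValidationError
from .geometry import make_geometry

#: Per-group covariate profiles: age mean/SD (years), fraction female,
#: education mean/SD (years).  Ages are drawn uniformly within mean +/- SD.
COVARIATE_PROFILES: dict[str, dict[str, float]] = {
    "NC":       {"age_mean": 62.5, "age_sd": 7.5, "female": 0.714,
                 "edu_mean": 12.5, "edu_sd": 5.0},
    "pureADD":  {"age_mean": 67.0, "age_sd": 9.1, "female": 0.650,
                 "edu_mean": 10.4, "edu_sd": 5.3},
    "pureSVaD": {"age_mean": 71.3, "age_sd": 7.3, "female": 0.469,
                 "edu_mean": 8.6, "edu_sd": 4.6},
    "mixed":    {"age_mean": 78.1, "age_sd": 4.7, "female": 0.739,
                 "edu_mean": 9.1, "edu_sd": 5.5},
}

#: Default cohort sizes, matching the study design this generator emulates.
DEFAULT_N_PER_GROUP: dict[str, int] = {
    "NC": 56, "pureADD": 40, "pureSVaD": 32, "mixed": 23}

#: Control-group baselines per white-matter metric.  DR and DA are in units
#: of 1e-4 mm^2/s (the scale on which such values are conventionally
#: reported); FA is dimensionless.
WM_BASELINES = {"FA": 0.475, "DR": 5.670, "DA": 12.334}
WM_NOISE_SD = {"FA": 0.04, "DR": 0.35, "DA": 0.35}
#: Degeneration direction: thickness and FA decrease, DR/DA increase.
WM_GROUP_EFFECT = {"FA": -0.05, "DR": +1.0, "DA": +0.5}
WM_COVARIATE_EFFECTS = {
    "FA": {"age": -0.0010, "sex": 0.0, "education": 0.0003},
    "DR": {"age": +0.0100, "sex": 0.0, "education": -0.0020},
    "DA": {"age": +0.0060, "sex": 0.0, "education": -0.0010},
}

_GM_COVARIATE_EFFECTS = {"age": -0.008, "sex": 0.05, "education": 0.002}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``n_per_group`` may be a single count applied to every generated group
    or a mapping from group name to count.  ``affected_*`` designate the
    features carrying the group mean shift (default: the first 20% of each
    view); ``latent_support_*`` designate the features loaded by the shared
    rank-1 factor (default: the first 10 of each view).  ``latent_groups``
    restricts the factor to certain groups (``None`` = every subject).
    """

    n_per_group: int | Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    groups: Sequence[str] = GROUPS
    p_thickness: int = 500
    p_dti: int = 800
    dti_metric: str = "FA"
    baseline_gm: float = 2.5
    baseline_wm: float | None = None
    covariate_effects_gm: Mapping[str, float] = field(
        default_factory=lambda: dict(_GM_COVARIATE_EFFECTS))
    covariate_effects_wm: Mapping[str, float] | None = None
    group_effect_gm: float = -0.25
    group_effect_wm: float | None = None
    affected_gm: Sequence[int] | None = None
    affected_wm: Sequence[int] | None = None
    latent_strength: float = 0.5
    latent_support_gm: Sequence[int] | None = None
    latent_support_wm: Sequence[int] | None = None
    latent_groups: Sequence[str] | None = None
    noise_sd_gm: float = 0.25
    noise_sd_wm: float | None = None
    seed: int = 0

    def resolved(self) -> "GeneratorConfig":
        """Return a copy with all metric-dependent defaults filled in."""
        cfg = GeneratorConfig(**asdict(self))
        m = cfg.dti_metric
        if m not in WM_BASELINES:
            raise ValidationError(
                f"unknown DTI metric {m!r}; expected one of {sorted(WM_BASELINES)}")
        if cfg.baseline_wm is None:
            cfg.baseline_wm = WM_BASELINES[m]
        if cfg.noise_sd_wm is None:
            cfg.noise_sd_wm = WM_NOISE_SD[m]
        if cfg.group_effect_wm is None:
            cfg.group_effect_wm = WM_GROUP_EFFECT[m]
        if cfg.covariate_effects_wm is None:
            cfg.covariate_effects_wm = dict(WM_COVARIATE_EFFECTS[m])
        if cfg.affected_gm is None:
            cfg.affected_gm = list(range(max(1, cfg.p_thickness // 5)))
        if cfg.affected_wm is None:
            cfg.affected_wm = list(range(max(1, cfg.p_dti // 5)))
        if cfg.latent_support_gm is None:
            cfg.latent_support_gm = list(range(min(10, cfg.p_thickness)))
        if cfg.latent_support_wm is None:
            cfg.latent_support_wm = list(range(min(10, cfg.p_dti)))
        return cfg

    def validate(self) -> None:
        if self.p_thickness < 1 or self.p_dti < 1:
            raise ValidationError("feature counts must be positive")
        for g in self.groups:
            if g not in GROUPS:
                raise ValidationError(f"unknown group {g!r}")
            if self._n(g) < 2:
                raise ValidationError(
                    f"n_per_group must be >= 2 (group {g!r})")
        if self.latent_strength < 0:
            raise ValidationError("latent_strength must be >= 0")
        if self.noise_sd_gm <= 0 or (self.noise_sd_wm or 1) <= 0:
            raise ValidationError("noise SDs must be > 0")
        for name, support, p in [
                ("latent_support_gm", self.latent_support_gm, self.p_thickness),
                ("latent_support_wm", self.latent_support_wm, self.p_dti),
                ("affected_gm", self.affected_gm, self.p_thickness),
                ("affected_wm", self.affected_wm, self.p_dti)]:
            if support is None:
                continue
            idx = np.asarray(support, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= p):
                raise ValidationError(
                    f"{name} has indices outside [0, {p})")
            if np.unique(idx).size != idx.size:
                raise ValidationError(f"{name} has duplicate indices")
        if self.latent_groups is not None:
            bad = set(self.latent_groups) - set(GROUPS)
            if bad:
                raise ValidationError(f"latent_groups unknown: {sorted(bad)}")

    def _n(self, group: str) -> int:
        if isinstance(self.n_per_group, Mapping):
            try:
                return int(self.n_per_group[group])
            except KeyError:
                raise ValidationError(
                    f"n_per_group mapping has no entry for {group!r}")
        return int(self.n_per_group)


def generate_cohort(
        config: GeneratorConfig,
) -> tuple[pd.DataFrame, FeatureMatrix, FeatureMatrix]:
    """Generate a seeded cohort: covariate table plus both feature matrices.

    Each feature is built as ``baseline + covariate effects + group shift
    (patients only, affected features) + latent_strength * subject_score *
    support indicator + Gaussian noise``, with the same subject score in
    both views.  The draw order is fixed, so an identical seed reproduces
    the output bit for bit.
    """
    cfg = config.resolved()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    rows = []
    for g in cfg.groups:
        prof = COVARIATE_PROFILES[g]
        n = cfg._n(g)
        age = rng.uniform(prof["age_mean"] - prof["age_sd"],
                          prof["age_mean"] + prof["age_sd"], n)
        sex = (rng.random(n) < prof["female"]).astype(int)
        edu = np.clip(rng.uniform(prof["edu_mean"] - prof["edu_sd"],
                                  prof["edu_mean"] + prof["edu_sd"], n), 0, None)
        for i in range(n):
            rows.append((f"{g}{i:03d}", g, age[i], sex[i], edu[i]))
    cohort = pd.DataFrame(
        rows, columns=["subject_id", "group", "age", "sex", "education"])
    validate_cohort(cohort)
    n_total = len(cohort)

    # shared latent subject score (the coupling sCCA should recover)
    z = rng.standard_normal(n_total)
    if cfg.latent_groups is not None:
        z = np.where(cohort["group"].isin(cfg.latent_groups), z, 0.0)
    is_patient = (cohort["group"] != "NC").to_numpy()

    ref = COVARIATE_PROFILES["NC"]
    cov_dev = {
        "age": cohort["age"].to_numpy() - ref["age_mean"],
        "sex": cohort["sex"].to_numpy(dtype=float) - ref["female"],
        "education": cohort["education"].to_numpy() - ref["edu_mean"],
    }

    def build(p, baseline, effects, group_effect, affected, support, noise_sd):
        x = np.full((n_total, p), float(baseline))
        shift = sum(float(effects.get(k, 0.0)) * cov_dev[k] for k in cov_dev)
        x += shift[:, None]
        x[np.ix_(is_patient, np.asarray(affected, int))] += group_effect
        x[:, np.asarray(support, int)] += cfg.latent_strength * z[:, None]
        x += rng.normal(0.0, noise_sd, size=(n_total, p))
        return x

    x_gm = build(cfg.p_thickness, cfg.baseline_gm, cfg.covariate_effects_gm,
                 cfg.group_effect_gm, cfg.affected_gm,
                 cfg.latent_support_gm, cfg.noise_sd_gm)
    x_wm = build(cfg.p_dti, cfg.baseline_wm, cfg.covariate_effects_wm,
                 cfg.group_effect_wm, cfg.affected_wm,
                 cfg.latent_support_wm, cfg.noise_sd_wm)

    ids = cohort["subject_id"]
    gm = FeatureMatrix(
        pd.DataFrame(x_gm, index=ids,
                     columns=[f"v{i:05d}" for i in range(cfg.p_thickness)]),
        modality="thickness", geometry=_lattice(cfg.p_thickness))
    wm = FeatureMatrix(
        pd.DataFrame(x_wm, index=ids,
                     columns=[f"s{i:05d}" for i in range(cfg.p_dti)]),
        modality=cfg.dti_metric, geometry=_lattice(cfg.p_dti))
    return cohort, gm, wm


def _lattice(p: int):
    """Near-square 2D grid with exactly ``p`` cells (toy adjacency)."""
    r = int(np.sqrt(p))
    while p % r:
        r -= 1
    return make_geometry("skeleton", (r, p // r), connectivity=4)
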