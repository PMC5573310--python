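"""End-to-end orchestration: generate/load -> W-score -> group maps -> sCCA.

A run mirrors the per-group, per-DTI-index structure of a gray-matter /
white-matter coupling study: normative models are fitted on the control
group for every modality, every subject is W-scored, each patient group is
compared with controls by permutation ANCOVA + TFCE + FWE, and within each
patient group a sparse CCA couples the thickness W-scores with each
requested DTI metric's W-scores, with a pair-permutation verdict per
(group, metric).

All randomness fans out from one top-level seed through a fixed counter
scheme (:func:`stage_seed`), so any stage can be re-run in isolation and
reproduce the full run's numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .containers import FeatureMatrix
from .errors import ConfigError
from .groupdiff import StatMap, TfceParams, design_from_cohort, permutation_fwe
from .permutation import PermutationScheme, PermutationVerdict, \
    scca_permutation_test
from .scca import SccaParams, SccaResult, fit_scca
from .synthetic import GeneratorConfig, generate_cohort
from .wscore import NormativeModel, WScoreMatrix, compute_wscores, \
    fit_normative_model

log = logging.getLogger(__name__)

#: fixed stage indices of the seed fan-out (documented contract)
_STAGE_INDEX = {"generator": 0, "groupmap": 1, "scca_permutation": 2}


def stage_seed(master_seed: int, stage: str, counter: int = 0) -> int:
    """Derive the seed of one pipeline stage from the top-level seed.

    ``stage`` is one of ``generator``, ``groupmap``, ``scca_permutation``;
    ``counter`` enumerates repeated uses of a stage (one per (group,
    modality) pair, in the order the run visits them).
    """
    idx = _STAGE_INDEX[stage]
    rng = np.random.default_rng([master_seed, idx, counter])
    return int(rng.integers(2 ** 31))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from a YAML file."""

    seed: int = 0
    generator: GeneratorConfig | None = None
    cohort_path: str | None = None
    thickness_path: str | None = None
    dti_paths: dict = field(default_factory=dict)   # metric -> path
    patient_groups: tuple = ("pureADD", "pureSVaD", "mixed")
    dti_metrics: tuple = ("FA",)
    scca: SccaParams = field(default_factory=SccaParams)
    n_permutations_scca: int = 2000
    forbid_fixed_points: bool = True
    tfce: TfceParams = field(default_factory=TfceParams)
    n_permutations_groupmap: int = 5000
    run_groupmaps: bool = True
    outdir: str | None = None

    def validate(self) -> None:
        file_mode = self.generator is None
        if file_mode:
            for label, p in [("cohort", self.cohort_path),
                             ("thickness", self.thickness_path)]:
                if p is None:
                    raise ConfigError(f"no generator and no {label} path")
                if not Path(p).exists():
                    raise ConfigError(f"{label} file not found: {p}")
            for m in self.dti_metrics:
                if m not in self.dti_paths:
                    raise ConfigError(
                        f"DTI metric {m!r} requested but no input provides it")
                if not Path(self.dti_paths[m]).exists():
                    raise ConfigError(
                        f"DTI file not found: {self.dti_paths[m]}")
        else:
            available = {self.generator.dti_metric}
            missing = set(self.dti_metrics) - available
            if missing:
                raise ConfigError(
                    f"DTI metric(s) {sorted(missing)} requested but the "
                    f"generator produces only {sorted(available)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = nio.load_yaml(path)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        try:
            if "generator" in kwargs and kwargs["generator"] is not None:
                kwargs["generator"] = GeneratorConfig(**kwargs["generator"])
            if "scca" in kwargs:
                kwargs["scca"] = SccaParams(**kwargs["scca"])
            if "tfce" in kwargs:
                kwargs["tfce"] = TfceParams(**kwargs["tfce"])
            for key in ("patient_groups", "dti_metrics"):
                if key in kwargs:
                    kwargs[key] = tuple(kwargs[key])
            return cls(**kwargs)
        except TypeError as e:
            raise ConfigError(f"bad config: {e}")

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, np.floating):
                return float(obj)
            return obj

        return listify(dataclasses.asdict(self))

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class ResultsBundle:
    cohort: pd.DataFrame
    normative_models: dict            # modality -> NormativeModel
    wscores: dict                     # modality -> WScoreMatrix
    statmaps: dict                    # (group, modality) -> StatMap
    scca_results: dict                # (group, metric) -> (SccaResult, PermutationVerdict)
    provenance: dict

    def summary(self) -> pd.DataFrame:
        """Per (group, DTI metric): canonical correlation and permutation p."""
        rows = [
            {"group": g, "metric": m,
             "canonical_correlation": res.canonical_correlation,
             "p_value": verdict.p_value,
             "n_permutations": verdict.scheme.n_permutations}
            for (g, m), (res, verdict) in self.scca_results.items()]
        return pd.DataFrame(rows)


def _stage(name, **info):
    log.info("stage=%s %s", name,
             " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: RunConfig) -> ResultsBundle:
    config.validate()
    t0 = time.time()

    # --- inputs -----------------------------------------------------------
    if config.generator is not None:
        gen = dataclasses.replace(
            config.generator,
            seed=stage_seed(config.seed, "generator"))
        cohort, thickness, dti = generate_cohort(gen)
        dti_views = {gen.dti_metric: dti}
        _stage("generate", n=len(cohort), p_gm=thickness.values.shape[1],
               p_wm=dti.values.shape[1], seed=gen.seed)
    else:
        cohort = nio.read_cohort(config.cohort_path)
        thickness = nio.read_feature_matrix(
            config.thickness_path, modality="thickness")
        dti_views = {m: nio.read_feature_matrix(config.dti_paths[m],
                                                modality=m)
                     for m in config.dti_metrics}
        ids = set(cohort["subject_id"])
        for label, fm in [("thickness", thickness)] + list(dti_views.items()):
            if set(fm.subject_ids) != ids:
                raise ConfigError(
                    f"subject ids of {label!r} do not match the cohort")
        _stage("load", n=len(cohort))

    for g in config.patient_groups:
        if g not in set(cohort["group"]):
            raise ConfigError(f"cohort has no subjects in group {g!r}")
    if "NC" not in set(cohort["group"]):
        raise ConfigError("cohort has no control (NC) subjects")

    views = {"thickness": thickness, **{m: dti_views[m]
                                        for m in config.dti_metrics}}
    controls_mask = cohort["group"] == "NC"
    control_ids = cohort.loc[controls_mask, "subject_id"]

    # --- normative models and W-scores ------------------------------------
    models: dict[str, NormativeModel] = {}
    wscores: dict[str, WScoreMatrix] = {}
    for modality, fm in views.items():
        controls = FeatureMatrix(fm.values.loc[control_ids],
                                 modality=modality, geometry=fm.geometry)
        model = fit_normative_model(controls, cohort[controls_mask.to_numpy()])
        models[modality] = model
        wscores[modality] = compute_wscores(model, fm, cohort)
        _stage("wscore", modality=modality,
               n_controls=model.n_controls,
               n_degenerate=int(model.degenerate.sum()))

    # --- group-difference maps --------------------------------------------
    statmaps: dict[tuple[str, str], StatMap] = {}
    counter = 0
    if config.run_groupmaps:
        for group in config.patient_groups:
            for modality, fm in views.items():
                design = design_from_cohort(cohort, group)
                mask = cohort["group"].isin([group, "NC"]).to_numpy()
                sub = FeatureMatrix(
                    fm.values.loc[cohort.loc[mask, "subject_id"]],
                    modality=modality, geometry=fm.geometry)
                sm = permutation_fwe(
                    sub, design, fm.geometry, config.tfce,
                    n_permutations=config.n_permutations_groupmap,
                    seed=stage_seed(config.seed, "groupmap", counter))
                statmaps[(group, modality)] = sm
                _stage("groupmap", group=group, modality=modality,
                       n_significant=int(sm.significant_mask().sum()),
                       elapsed=f"{time.time() - t0:.1f}s")
                counter += 1

    # --- sparse CCA per (group, DTI metric) -------------------------------
    scca_results: dict[tuple[str, str], tuple[SccaResult, PermutationVerdict]] = {}
    counter = 0
    for group in config.patient_groups:
        gmask = cohort["group"] == group
        gids = cohort.loc[gmask, "subject_id"]
        w_gm = wscores["thickness"].values.loc[
            gids, models["thickness"].valid_features]
        for metric in config.dti_metrics:
            w_wm = wscores[metric].values.loc[
                gids, models[metric].valid_features]
            scheme = PermutationScheme(
                n_subjects=len(gids),
                n_permutations=config.n_permutations_scca,
                forbid_fixed_points=config.forbid_fixed_points,
                seed=stage_seed(config.seed, "scca_permutation", counter))
            verdict = scca_permutation_test(
                w_gm, w_wm, config.scca, scheme)
            result = fit_scca(
                WScoreMatrix(w_gm, "thickness"),
                WScoreMatrix(w_wm, metric), config.scca)
            scca_results[(group, metric)] = (result, verdict)
            _stage("scca", group=group, metric=metric,
                   corr=f"{result.canonical_correlation:.4f}",
                   p=f"{verdict.p_value:.4f}")
            counter += 1

    provenance = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "package_version": _version(),
        "elapsed_s": round(time.time() - t0, 2),
    }
    bundle = ResultsBundle(cohort=cohort, normative_models=models,
                           wscores=wscores, statmaps=statmaps,
                           scca_results=scca_results, provenance=provenance)
    if config.outdir:
        _write_bundle(bundle, config)
    return bundle


def _version() -> str:
    from . import __version__
    return __version__


def _write_bundle(bundle: ResultsBundle, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    nio.write_cohort(bundle.cohort, out / "cohort.tsv")
    for modality, w in bundle.wscores.items():
        nio.write_feature_matrix(w, out / f"wscores_{modality}.tsv")
        nio.write_normative_model(bundle.normative_models[modality],
                                  out / f"normative_{modality}.tsv")
    for (group, modality), sm in bundle.statmaps.items():
        nio.write_statmap(sm, out / f"statmap_{group}_{modality}.tsv")
    for (group, metric), (res, verdict) in bundle.scca_results.items():
        header = {"group": group, "metric": metric,
                  "canonical_correlation": res.canonical_correlation,
                  "p_value": verdict.p_value,
                  "n_permutations": verdict.scheme.n_permutations,
                  "seed": verdict.scheme.seed,
                  "config_hash": bundle.provenance["config_hash"]}
        nio.write_weights(res, "x", out / f"weights_{group}_{metric}_gm.tsv",
                          header)
        nio.write_weights(res, "z", out / f"weights_{group}_{metric}_wm.tsv",
                          header)
    bundle.summary().to_csv(out / "summary.tsv", sep="\t", index=False)
    nio.dump_yaml(bundle.provenance, out / "provenance.yaml")
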