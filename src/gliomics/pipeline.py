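"""End-to-end orchestration: simulate -> preprocess -> extract -> map -> fit.

A single master seed deterministically derives one sub-seed per stage (by
hashing the stage name), so identical configurations reproduce identical
reports byte for byte and individual stages can be re-run independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import features as feat
from . import lesionstats as ls
from . import model as mdl
from .preprocess import derive_channels
from .registration import register_affine_mi, resample_to_atlas
from .simulate import CohortSpec, make_toy_atlas, simulate_cohort, write_cohort

__all__ = ["RunConfig", "load_config", "save_config", "run_pipeline",
           "derive_seed", "cohort_feature_table"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "preprocess", "extract", "map", "fit")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    output_dir: str = "gliomics_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    register: bool = False        # cohorts simulated in atlas space skip this
    write_volumes: bool = False
    atlas_paths: dict = field(default_factory=dict)  # optional real label maps
    alpha: float = 0.05
    n_permutations: int = 500
    connectivity: int = 26
    ignore_laterality: bool = False
    z_thresh: float = 2.0
    n_rep: int = 5
    train_fraction: float = mdl.TRAIN_FRACTION_DEFAULT
    n_folds: int = 10
    n_lambdas: int = 30

    def validate(self) -> "RunConfig":
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for s in _STAGES:
            self.stages.setdefault(s, True)
        CohortSpec(**{**self.cohort, "seed": 0}).validate()
        return self


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw).validate()


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return (and write) the run report."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {s: derive_seed(config.seed, s) for s in _STAGES}
    report: dict = {"seeds": seeds, "config": _round_floats(asdict(config))}

    cases = manifest = None
    if config.stages.get("simulate", True):
        spec = CohortSpec(**{**config.cohort, "seed": seeds["simulate"]})
        cases, manifest = simulate_cohort(spec)
        report["n_cases"] = len(cases)
        logger.info("simulated %d cases", len(cases))
        if config.write_volumes:
            manifest = write_cohort(cases, manifest, outdir / "cohort", spec)

    channels = {}
    if config.stages.get("preprocess", True) and cases:
        for case in cases:
            brain = np.asarray(case.channels["T1"].data) > 0
            channels[case.case_id] = derive_channels(case.channels, case.voi, brain)
        report["n_preprocessed"] = len(channels)

    atlas_grid = cases[0].voi.shape if cases else None
    if config.register and cases:
        # co-register any native-space case to the atlas grid via its T2
        template = None
        for case in cases:
            if case.voi.space == "native":
                if template is None:
                    spec = CohortSpec(**{**config.cohort, "seed": seeds["simulate"]})
                    template = make_toy_atlas(spec.grid_shape, "mni10")
                t2 = channels[case.case_id]["T2"]
                transform = register_affine_mi(
                    t2, _template_volume(template), dof=12, seed=seeds["preprocess"]
                )
                case.voi = resample_to_atlas(case.voi, transform, atlas_grid)

    table = None
    if config.stages.get("extract", True) and cases:
        atlas10 = _load_atlas(config, "mni10", atlas_grid)
        atlas49 = _load_atlas(config, "ho49", atlas_grid)
        records = []
        for case in cases:
            chans = channels.get(case.case_id)
            try:
                feats = feat.extract_case_features(
                    chans, case.voi, case.voi, atlas10, atlas49, config.z_thresh
                ) if chans else None
            except KeyError:
                feats = None
            records.append((case.case_id, case.subtype, case.institution, feats))
        table = feat.assemble_feature_table(records)
        table.to_csv(outdir / "features.csv")
        (outdir / "inventory.json").write_text(
            json.dumps(feat.build_default_inventory(), indent=2)
        )
        report["n_features"] = len(feat.feature_columns(table))
        report["n_modeled_cases"] = len(table)
        screen = feat.anova_screen(table)
        report["anova_bins"] = screen["bin"].value_counts().to_dict()

    if config.stages.get("map", True) and cases:
        result = ls.cluster_permutation_correct(
            [c.voi for c in cases], [c.subtype for c in cases],
            n_permutations=config.n_permutations, alpha=config.alpha,
            connectivity=config.connectivity, seed=seeds["map"],
            ignore_laterality=config.ignore_laterality,
        )
        result.clusters.to_csv(outdir / "clusters.csv", index=False)
        report["clusters"] = _round_floats(result.clusters.to_dict(orient="records"))
        report["cluster_size_threshold"] = float(result.size_threshold)
        from .core import VOIMask, save_volume

        spacing = cases[0].voi.spacing
        save_volume(VOIMask(data=result.sig_mask, spacing=spacing, space="atlas"),
                    outdir / "suprathreshold_mask.nii")
        save_volume(VOIMask(data=result.corrected_mask, spacing=spacing, space="atlas"),
                    outdir / "significant_clusters_mask.nii")
        freq = ls.lesion_frequency_maps([c.voi for c in cases],
                                        [c.subtype for c in cases])
        for g, fm in freq.frequencies.items():
            from .core import Volume

            save_volume(Volume(data=fm.astype(np.float32), spacing=spacing),
                        outdir / f"lesion_frequency_{g}.nii")

    if config.stages.get("fit", True) and table is not None and len(table) >= 20:
        n = len(table)
        report["train_size"] = int(round(n * config.train_fraction))
        report["val_size"] = n - report["train_size"]
        idh = mdl.repeat_and_compare(
            table, task="idh_binary", n_rep=config.n_rep, seed=seeds["fit"],
            train_fraction=config.train_fraction, n_folds=config.n_folds,
            n_lambdas=config.n_lambdas,
        )
        three = mdl.repeat_and_compare(
            table, task="subtype_3class", n_rep=config.n_rep,
            seed=seeds["fit"], train_fraction=config.train_fraction,
            n_folds=config.n_folds, n_lambdas=config.n_lambdas, arms=(True,),
        )
        report["idh_binary"] = {
            "summary": _round_floats(idh.summary.to_dict(orient="records")),
            "mcnemar_p": _round_floats(idh.mcnemar_p),
            "location_wins": idh.wins,
        }
        report["subtype_3class"] = {
            "summary": _round_floats(three.summary.to_dict(orient="records")),
            "confusion_pooled": _confusion_sum(three.metrics["location_on"]),
        }
        idh.summary.to_csv(outdir / "metrics_idh.csv", index=False)
        three.summary.to_csv(outdir / "metrics_3class.csv", index=False)

    report_json = json.dumps(_round_floats(report), sort_keys=True, indent=2)
    (outdir / "report.json").write_text(report_json)
    return report


def _confusion_sum(metrics_list) -> dict:
    total = None
    for m in metrics_list:
        total = m.confusion if total is None else total.add(m.confusion, fill_value=0)
    return {str(k): {str(c): int(v) for c, v in row.items()}
            for k, row in total.astype(int).to_dict(orient="index").items()}


def cohort_feature_table(cases, z_thresh: float = 2.0):
    """Preprocess every case and assemble the default 109-feature table.

    Convenience wrapper over derive_channels -> extract_case_features ->
    assemble_feature_table for cohorts already in atlas space.
    """
    if not cases:
        return feat.assemble_feature_table([])
    grid = cases[0].voi.shape
    atlas10 = make_toy_atlas(grid, "mni10")
    atlas49 = make_toy_atlas(grid, "ho49")
    records = []
    for case in cases:
        brain = np.asarray(case.channels["T1"].data) > 0
        chans = derive_channels(case.channels, case.voi, brain)
        feats = feat.extract_case_features(
            chans, case.voi, case.voi, atlas10, atlas49, z_thresh
        )
        records.append((case.case_id, case.subtype, case.institution, feats))
    return feat.assemble_feature_table(records)


def _load_atlas(config: RunConfig, scheme: str, grid):
    """Toy atlas by default; a user-supplied label map when a path is given."""
    path = config.atlas_paths.get(scheme)
    if path is None:
        return make_toy_atlas(grid, scheme)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"atlas file not found: {path}")
    from .core import AtlasLabelMap, load_volume

    atlas = load_volume(path, AtlasLabelMap)
    atlas.labels = {int(k): f"label_{int(k)}" for k in np.unique(atlas.data)}
    return atlas


def _template_volume(atlas):
    from .core import NormalizedVolume

    data = np.clip((atlas.data > 0) * 180.0 + (atlas.data == 0) * 60.0, 0, 255)
    return NormalizedVolume(data=data.astype(np.uint8), spacing=atlas.spacing)
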