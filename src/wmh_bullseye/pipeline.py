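"""Pipeline orchestration: simulate → segment → parcellate → analyse.

A :class:`RunConfig` (YAML-serializable) names the stages to run and their
parameters; every output file is recorded in a JSON manifest with a SHA-256
content hash so reruns can be verified byte-for-byte.  Per-stage seeds are
fanned out deterministically from the global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .mixture import MixtureConfig
from .parcellation import bullseye_parcellation, regional_volumes
from .phantom import CohortSpec, PhantomSpec, generate_cohort_table, \
    generate_phantom
from .segmentation import SegmentationConfig, two_pass_segmentation
from .stats import fit_cross_sectional, fit_longitudinal

log = logging.getLogger("wmh_bullseye")

STAGES = ("simulate", "segment", "parcellate", "analyse")


class MissingInputError(FileNotFoundError):
    pass


class SchemaError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "wmh_run"
    stages: tuple = STAGES
    seed: int = 0
    grid_shape: tuple = (64, 64, 64)
    voxel_size: tuple = (1.0, 1.0, 1.0)
    lesion_count: int = 3
    noise_sd: float = 2.0
    n_subjects: int = 0          # extra cohort rows for the analyse stage
    segmentation: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        return yaml.safe_dump(d, sort_keys=True)


def stage_seed(global_seed: int, stage: str, subject: str = "") -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.sha256(
        f"{global_seed}:{stage}:{subject}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(paths: dict) -> list[str]:
    """Check grids/affines agree across volumes and CSVs carry the schema.

    Returns a list of human-readable failures (empty = valid).
    """
    failures = []
    shapes = {}
    zooms = {}
    for name, p in paths.items():
        p = Path(p)
        if not p.exists():
            failures.append(f"{name}: missing file {p}")
            continue
        if p.suffix in (".nii", ".gz") or str(p).endswith(".nii.gz"):
            try:
                data, vs = wio.load_nifti(p)
            except Exception as exc:  # malformed header
                failures.append(f"{name}: unreadable NIfTI ({exc})")
                continue
            shapes[name] = data.shape
            zooms[name] = vs
        elif p.suffix == ".csv":
            df = pd.read_csv(p)
            required = {"subject_id", "tiv_mm3"}
            missing = required - set(df.columns)
            if missing:
                failures.append(f"{name}: CSV missing columns "
                                f"{sorted(missing)}")
    if len(set(shapes.values())) > 1:
        failures.append(f"grid shapes disagree: {shapes}")
    if len(set(zooms.values())) > 1:
        failures.append(f"voxel sizes disagree: {zooms}")
    return failures


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages; returns the output manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level, "INFO"))
    log.info("run config:\n%s", config.to_yaml())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": yaml.safe_load(config.to_yaml()),
                      "outputs": {}}

    def record(path: Path):
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    spec = PhantomSpec(grid_shape=tuple(config.grid_shape),
                       voxel_size=tuple(config.voxel_size),
                       lesion_count=config.lesion_count,
                       noise_sd=config.noise_sd,
                       rng_seed=stage_seed(config.seed, "simulate"))
    t1 = t2 = truth = None
    if "simulate" in config.stages:
        t1, t2, truth = generate_phantom(spec)
        for name, vol in (("t1", t1), ("t2", t2)):
            record(wio.save_nifti(vol, out / f"{name}.nii.gz",
                                  spec.voxel_size))
        for name, vol in (("tissue_labels", truth.tissue_labels),
                          ("lobe_labels", truth.lobe_labels),
                          ("hemisphere_labels", truth.hemisphere_labels),
                          ("lesion_truth", truth.lesion_mask)):
            record(wio.save_nifti(vol, out / f"{name}.nii.gz",
                                  spec.voxel_size, dtype=np.int16))

    lesions = None
    if "segment" in config.stages:
        if t1 is None:
            for req in ("t1.nii.gz", "t2.nii.gz", "tissue_labels.nii.gz"):
                if not (out / req).exists():
                    raise MissingInputError(f"segment stage needs {req}")
            t1, _ = wio.load_nifti(out / "t1.nii.gz")
            t2, _ = wio.load_nifti(out / "t2.nii.gz")
        seg_cfg = SegmentationConfig(
            seed=stage_seed(config.seed, "segment"),
            mixture=MixtureConfig(seed=stage_seed(config.seed, "segment")),
            **config.segmentation)
        priors = truth.tissue_priors()
        lesions, tissue_labels, _ = two_pass_segmentation(
            t1, t2, priors, truth.brain_mask, truth.ventricle_mask,
            truth.voxel_volume_mm3, seg_cfg)
        record(wio.save_nifti(lesions.mask, out / "lesion_mask.nii.gz",
                              spec.voxel_size, dtype=np.uint8))
        record(wio.save_nifti(tissue_labels, out / "tissue_seg.nii.gz",
                              spec.voxel_size, dtype=np.int16))
        lesions.component_table.to_csv(out / "components.csv", index=False)
        record(out / "components.csv")

    if "parcellate" in config.stages:
        if truth is None:
            raise MissingInputError("parcellate stage needs the simulate "
                                    "stage (ground-truth labels)")
        mask = lesions.mask if lesions is not None else truth.lesion_mask
        lobe, layer_map = bullseye_parcellation(truth, spec.voxel_size)
        table = regional_volumes(mask, truth.gm_mask, lobe,
                                 layer_map.layer_labels,
                                 truth.hemisphere_labels,
                                 truth.voxel_volume_mm3, truth.tiv_mm3)
        table.table.to_csv(out / "regions.csv", index=False)
        record(out / "regions.csv")
        record(wio.save_nifti(lobe, out / "wm_lobes.nii.gz",
                              spec.voxel_size, dtype=np.int16))
        record(wio.save_nifti(layer_map.layer_labels,
                              out / "wm_layers.nii.gz",
                              spec.voxel_size, dtype=np.int16))

    if "analyse" in config.stages:
        n = config.n_subjects or 60
        cspec = CohortSpec(n_per_group={"control": n, "presymptomatic": n,
                                        "symptomatic": max(n // 3, 4)},
                           visits_per_subject=3,
                           rng_seed=stage_seed(config.seed, "analyse"))
        cohort = generate_cohort_table(cspec)
        cohort.to_csv(out / "cohort.csv", index=False)
        record(out / "cohort.csv")
        cross = fit_cross_sectional(cohort)
        longi = fit_longitudinal(cohort)
        results = {
            "cross_sectional": {k: {"percent_excess": v[0],
                                    "ci_percent": list(v[1]),
                                    "p": float(cross.pvalues[k])}
                                for k, v in cross.percent_excess.items()
                                if "group" in k},
            "longitudinal": {k: {"percent_excess": v[0],
                                 "ci_percent": list(v[1])}
                             for k, v in longi.percent_excess.items()
                             if "visit_time" in k},
        }
        (out / "analysis.json").write_text(json.dumps(results, indent=2))
        record(out / "analysis.json")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
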