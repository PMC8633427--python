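"""End-to-end orchestration: simulate/load -> sample -> summarize -> infer.

Every stage consumes and produces documented file formats (NIfTI volumes,
JSON meshes, CSV tables, YAML config, JSON manifest), so stages can also be
run independently through the command-line interface.  A run is a pure
function of its configuration: reruns with the same config and seed produce
byte-identical outputs.
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

from . import atlas
from .cohort import CohortConfig, generate_cohort
from .lmm import run_full_inference
from .sampling import sample_profile
from .summarize import (
    DEFAULT_WEIGHTING,
    average_hemispheres,
    build_long_table,
    summarize_hemisphere,
)
from .mesh import SurfaceMesh
from .volume import MetricVolume

log = logging.getLogger(__name__)

_CSV_FLOAT = "%.12g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    source: str = "synthetic"               # "synthetic" or a fixture directory
    cohort: dict = field(default_factory=dict)
    offsets: tuple[float, ...] = atlas.DEPTH_OFFSETS_MM
    weighting: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTING))
    method: str = "REML"
    distance_coding: str = "standard"
    fdr_alpha: float = 0.05
    out_dir: str = "swmprofile_run"
    seed: int | None = 0

    def validate(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if len(self.offsets) < 2:
            raise ValueError("need at least 2 depth offsets")
        if self.source == "synthetic" and self.seed is None:
            raise ValueError("synthetic source requires a seed")

    def cohort_config(self) -> CohortConfig:
        cc = dict(self.cohort)
        if self.seed is not None:
            cc.setdefault("seed", self.seed)
        if "effect_template" in cc:
            cc["effect_template"] = {
                (m, int(r)): v
                for (m, r), v in _parse_effect_keys(cc["effect_template"]).items()
            }
        return CohortConfig(**cc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**payload)
        cfg.offsets = tuple(cfg.offsets)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        payload = {
            "source": self.source,
            "cohort": _effect_keys_to_str(self.cohort),
            "offsets": list(self.offsets),
            "weighting": dict(self.weighting),
            "method": self.method,
            "distance_coding": self.distance_coding,
            "fdr_alpha": self.fdr_alpha,
            "out_dir": str(self.out_dir),
            "seed": self.seed,
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path


def _parse_effect_keys(effects: dict) -> dict:
    """Accept both ("NDI", 7) tuple keys and "NDI:7" string keys (YAML)."""
    out = {}
    for key, val in effects.items():
        if isinstance(key, str):
            m, r = key.split(":")
            key = (m, int(r))
        if isinstance(val, dict):
            val = {int(k): float(v) for k, v in val.items()}
        else:
            val = tuple(float(v) for v in val)
        out[tuple(key)] = val
    return out


def _effect_keys_to_str(cohort: dict) -> dict:
    cohort = dict(cohort)
    eff = cohort.get("effect_template")
    if eff:
        cohort["effect_template"] = {
            (k if isinstance(k, str) else f"{k[0]}:{k[1]}"): v for k, v in eff.items()
        }
    return cohort


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# -------------------------------------------------------------- cohort loading
def load_cohort_dir(path: str | Path):
    """Load a fixture directory written by make_fixtures.

    Returns (mesh_left, mesh_right, participants, thickness, volume loader).
    """
    path = Path(path)
    mesh_l = SurfaceMesh.from_json(path / "mesh_left.json")
    mesh_r = SurfaceMesh.from_json(path / "mesh_right.json")
    participants = pd.read_csv(path / "participants.csv")
    thickness = pd.read_csv(path / "thickness.csv")

    def volume(pid: str, metric: str) -> MetricVolume:
        return MetricVolume.load(path / f"{pid}_{metric}.nii", metric, pid)

    return mesh_l, mesh_r, participants, thickness, volume


# ------------------------------------------------------------------- pipeline
def extract_long_table(
    mesh_left: SurfaceMesh,
    mesh_right: SurfaceMesh,
    participants: pd.DataFrame,
    thickness: pd.DataFrame,
    volume_loader,
    offsets=atlas.DEPTH_OFFSETS_MM,
    weighting=None,
    metrics=atlas.METRICS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample, summarize and assemble the modelling table for a whole cohort.

    ``volume_loader(participant_id, metric)`` returns a MetricVolume; volumes
    are processed one participant at a time.  Returns (long_table, summaries).
    """
    all_summaries = []
    for pid in participants.participant_id:
        hemi_frames = []
        for mesh in (mesh_left, mesh_right):
            samples = {
                m: sample_profile(volume_loader(pid, m), mesh, offsets) for m in metrics
            }
            hemi_frames.append(summarize_hemisphere(samples, mesh.roi_label, weighting))
        all_summaries.append(average_hemispheres(*hemi_frames))
    summaries = pd.concat(all_summaries, ignore_index=True)
    thickness = thickness.rename(columns={"thickness_mm": "thickness_mm"})
    long_table = build_long_table(summaries, thickness, participants)
    return long_table, summaries


def run_pipeline(config: RunConfig | str | Path) -> dict:
    """Execute all stages and write every artifact to the output directory.

    Returns a manifest dict (also written to manifest.json) with seeds,
    configuration, per-stage record counts and output checksums.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.source == "synthetic":
        bundle = generate_cohort(config.cohort_config())
        mesh_l, mesh_r = bundle.mesh_left, bundle.mesh_right
        participants, thickness = bundle.participants, bundle.thickness
        volume_loader = bundle.metric_volume
        roi_count = bundle.config.roi_count
        log.info("stage simulate: %d participants, %d ROIs, seed %s",
                 len(participants), roi_count, bundle.config.seed)
    else:
        mesh_l, mesh_r, participants, thickness, volume_loader = load_cohort_dir(
            config.source
        )
        roi_count = int(thickness.roi.nunique())
        log.info("stage load: %d participants from %s", len(participants), config.source)

    long_table, summaries = extract_long_table(
        mesh_l, mesh_r, participants, thickness, volume_loader,
        offsets=config.offsets, weighting=config.weighting,
    )
    log.info("stage sample+summarize: %d summary rows, %d table rows",
             len(summaries), len(long_table))

    ame_df, info = run_full_inference(
        long_table,
        method=config.method,
        distance_coding=config.distance_coding,
        alpha=config.fdr_alpha,
    )

    files = {
        "summaries.csv": summaries,
        "long_table.csv": long_table,
        "ame_table.csv": ame_df,
    }
    for name, frame in files.items():
        frame.to_csv(out / name, index=False, float_format=_CSV_FLOAT)
    atlas.write_atlas_json(out / "atlas.json", roi_count)
    # echo the config with a location-independent out_dir so that reruns of
    # the same configuration are byte-identical wherever they land
    echo = RunConfig(**{**config.__dict__, "out_dir": "."})
    echo.to_yaml(out / "config.yaml")

    manifest = {
        "seed": config.seed,
        "config": yaml.safe_load((out / "config.yaml").read_text()),
        "counts": {
            "participants": int(len(participants)),
            "summary_rows": int(len(summaries)),
            "table_rows": int(len(long_table)),
            "missing_y_rows": int((~np.isfinite(long_table.y)).sum()),
            **info,
        },
        "outputs": {
            name: _sha256(out / name) for name in [*files, "atlas.json", "config.yaml"]
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ------------------------------------------------------------------- fixtures
FIXTURE_SIZES = {
    "tiny": {
        "n_control": 4, "n_case": 4, "roi_count": 3,
        "vertices_per_hemi": 200, "radius_mm": 10.0,
    },
    "default": {},
}


def make_fixtures(size: str, seed: int, out_dir: str | Path) -> dict:
    """Write a self-contained miniature dataset for tests and demos.

    ``tiny`` is a 4+4 participant, 3-ROI, 200-vertex-per-hemisphere cohort on
    10 mm spheres; ``default`` reproduces the full study-sized cohort.
    Returns the manifest (also written) listing every file with its checksum.
    """
    if size not in FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(FIXTURE_SIZES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = CohortConfig(seed=seed, **FIXTURE_SIZES[size])
    bundle = generate_cohort(cfg)
    bundle.mesh_left.to_json(out / "mesh_left.json")
    bundle.mesh_right.to_json(out / "mesh_right.json")
    bundle.participants.to_csv(out / "participants.csv", index=False)
    bundle.thickness.to_csv(out / "thickness.csv", index=False, float_format=_CSV_FLOAT)
    for pid in bundle.participants.participant_id:
        for m in atlas.METRICS:
            bundle.metric_volume(pid, m).save(out / f"{pid}_{m}.nii")
    atlas.write_atlas_json(out / "atlas.json", cfg.roi_count)
    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "size": size,
        "seed": seed,
        "files": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
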