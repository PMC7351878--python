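"""Readers and writers for the pipeline's on-disk formats.

Tables are UTF-8 CSV with a header row; images are 8/16-bit grayscale TIFF
or PNG; configuration travels as YAML; results as JSON with sorted keys so
that repeated runs are byte-identical.  Every run directory carries the
fully resolved configuration and its hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import EnFaceAngiogram
from .protocol import PatientCourse

__all__ = [
    "cohort_frames",
    "write_cohort",
    "write_images",
    "read_image",
    "config_hash",
    "write_config",
    "write_json",
]

SCHEMA_VERSION = 1


def cohort_frames(courses: list[PatientCourse]) -> dict[str, pd.DataFrame]:
    """patients / visits / evaluations tables for a simulated cohort."""
    patients, visits, evaluations = [], [], []
    for c in courses:
        patients.append(
            {
                "patient_id": c.patient_id,
                "baseline_bcva": c.baseline_bcva,
                "baseline_cmt": round(c.baseline_cmt, 1),
                "fd_latent": round(c.baseline_traits.get("fd_latent", np.nan), 6),
                "sa_latent_mm2": round(c.baseline_traits.get("sa_latent_mm2", np.nan), 6),
                "completed_12m": c.completed_12m,
                "injection_count": c.injection_count,
            }
        )
        for v in c.visits:
            visits.append(
                {
                    "patient_id": c.patient_id,
                    "week": v.week,
                    "bcva_letters": v.bcva_letters,
                    "cmt_um": round(v.cmt_um, 1),
                    "irf": v.irf,
                    "srf": v.srf,
                    "hemorrhage": v.hemorrhage,
                    "injection": v.injection_given,
                    "active": v.active,
                }
            )
        for week, ev in sorted(c.metrics.get("evaluations", {}).items()):
            evaluations.append(
                {
                    "patient_id": c.patient_id,
                    "week": week,
                    "bcva_letters": ev.bcva_letters,
                    "cmt_um": round(ev.cmt_um, 1),
                    "irf": ev.irf,
                    "srf": ev.srf,
                    "hemorrhage": ev.hemorrhage,
                }
            )
    return {
        "patients": pd.DataFrame(patients),
        "visits": pd.DataFrame(visits),
        "evaluations": pd.DataFrame(evaluations),
    }


def write_cohort(courses: list[PatientCourse], out_dir: Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in cohort_frames(courses).items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def write_images(courses: list[PatientCourse], out_dir: Path, fmt: str = "tiff") -> Path:
    """Write per-evaluation angiograms plus a manifest CSV mapping rows to files."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    ext = {"tiff": "tif", "png": "png"}[fmt]
    rows = []
    for c in courses:
        for week, imgs in sorted(c.metrics.get("images", {}).items()):
            for rep, img in enumerate(imgs):
                fname = f"{c.patient_id}_w{week:02d}_r{rep}.{ext}"
                path = img_dir / fname
                if fmt == "tiff":
                    tifffile.imwrite(path, img.pixels)
                else:
                    iio.imwrite(path, img.pixels)
                rows.append(
                    {
                        "patient_id": c.patient_id,
                        "week": week,
                        "repeat": rep,
                        "path": f"images/{fname}",
                        "pixel_pitch_mm": img.pixel_pitch_mm,
                    }
                )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_image(path: Path, pixel_pitch_mm: float, metadata: dict | None = None) -> EnFaceAngiogram:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = iio.imread(path)
    if pixels.ndim == 3:  # collapse an RGB export to grayscale
        pixels = pixels[..., :3].mean(axis=-1).astype(pixels.dtype)
    return EnFaceAngiogram(
        pixels=np.asarray(pixels), pixel_pitch_mm=pixel_pitch_mm, metadata=metadata or {}
    )


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_config(config: dict, out_dir: Path, name: str = "run_config.yaml") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = dict(config)
    payload["schema_version"] = SCHEMA_VERSION
    payload["config_hash"] = config_hash(config)
    path = out_dir / name
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(payload: dict, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n")
    return path
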