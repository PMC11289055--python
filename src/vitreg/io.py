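"""Manifest, image, checkpoint and run-config I/O.

Conventions, fixed across the package:

* images: 8-bit grayscale PNG, intensities mapped from ``[0, 1]``;
* score manifests: CSV with header
  ``image_id,path,score_type,left_score,right_score,global_score``,
  scores written as decimal strings (``%g``) so round-trips are exact;
  rows may omit the per-lung pair (global-only annotation) and are then
  ineligible for lung replacement;
* augmentation provenance: CSV with header
  ``output_id,parent_a,parent_b,method,score_type,left,right,global,lambda``;
* checkpoints: a directory holding ``weights.npz`` plus ``config.json``
  with the architecture, the seed and the config hash;
* pixel rectangles are half-open with 0-based row/column coordinates.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from PIL import Image

from .augment import AugmentationRecord, MultiScoreImage
from .model import ViTConfig, ViTNetwork
from .rubric import ScoredImage, get_rubric

__all__ = [
    "MANIFEST_HEADER",
    "write_png",
    "read_png",
    "write_manifest",
    "read_manifest",
    "manifest_to_multiscore",
    "write_augmentation_records",
    "save_checkpoint",
    "load_checkpoint",
    "config_hash",
    "load_run_config",
]

MANIFEST_HEADER = [
    "image_id",
    "path",
    "score_type",
    "left_score",
    "right_score",
    "global_score",
]
AUGMENT_HEADER = [
    "output_id",
    "parent_a",
    "parent_b",
    "method",
    "score_type",
    "left",
    "right",
    "global",
    "lambda",
]


def write_png(image: np.ndarray, path) -> None:
    """Write a ``[0, 1]`` float image as 8-bit grayscale PNG."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    data = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def read_png(path) -> np.ndarray:
    """Read an image file as a ``[0, 1]`` float grayscale array."""
    try:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("L"), dtype=np.float64)
    except OSError as exc:
        raise OSError(f"unreadable image {path}: {exc}") from exc
    return arr / 255.0


def _fmt(value: Optional[float]) -> str:
    return "" if value is None else format(float(value), ".10g")


def write_manifest(rows: Sequence[Dict], path) -> None:
    """Write manifest rows (dicts keyed by the manifest header)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_HEADER)
        for row in rows:
            writer.writerow(
                [
                    row["image_id"],
                    row["path"],
                    row["score_type"],
                    _fmt(row.get("left_score")),
                    _fmt(row.get("right_score")),
                    _fmt(row["global_score"]),
                ]
            )


def read_manifest(path, validate: bool = True) -> List[Dict]:
    """Read and validate a manifest; returns one dict per row.

    Per-lung scores parse to ``None`` when blank. With ``validate``,
    scores are checked against the rubric range and the invariant
    ``global = left + right``; all offending row numbers (1-based data
    rows) are reported together.
    """
    rows: List[Dict] = []
    problems: List[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != MANIFEST_HEADER:
            raise ValueError(
                f"bad manifest header {header!r}; expected {MANIFEST_HEADER}"
            )
        for lineno, raw in enumerate(reader, start=1):
            if not raw:
                continue
            if len(raw) != len(MANIFEST_HEADER):
                problems.append(f"row {lineno}: expected 6 fields, got {len(raw)}")
                continue
            image_id, rel_path, score_type, left_s, right_s, global_s = raw
            try:
                left = float(left_s) if left_s else None
                right = float(right_s) if right_s else None
                glob = float(global_s)
            except ValueError:
                problems.append(f"row {lineno}: non-numeric score")
                continue
            row = {
                "image_id": image_id,
                "path": rel_path,
                "score_type": score_type,
                "left_score": left,
                "right_score": right,
                "global_score": glob,
            }
            if validate:
                try:
                    rub = get_rubric(score_type)
                except KeyError as exc:
                    problems.append(f"row {lineno}: {exc.args[0]}")
                    continue
                if (left is None) != (right is None):
                    problems.append(
                        f"row {lineno}: per-lung scores must be given together"
                    )
                    continue
                if left is not None:
                    if not (
                        rub.per_lung_min <= left <= rub.per_lung_max
                        and rub.per_lung_min <= right <= rub.per_lung_max
                    ):
                        problems.append(
                            f"row {lineno}: per-lung score outside "
                            f"[{rub.per_lung_min}, {rub.per_lung_max}]"
                        )
                        continue
                    if abs(glob - (left + right)) > 1e-9:
                        problems.append(
                            f"row {lineno}: global_score {glob} != "
                            f"left + right = {left + right}"
                        )
                        continue
                if not 0.0 <= glob <= rub.global_max:
                    problems.append(
                        f"row {lineno}: global_score {glob} outside "
                        f"[0, {rub.global_max}]"
                    )
                    continue
            rows.append(row)
    if problems:
        raise ValueError("invalid manifest rows:\n  " + "\n  ".join(problems))
    return rows


def manifest_to_multiscore(
    rows: Sequence[Dict], images_dir
) -> Tuple[List[MultiScoreImage], List[str]]:
    """Group manifest rows by image and load pixels.

    Returns the images (only those carrying per-lung scores enter the
    ``scores`` mapping) and the sorted list of score types seen.
    """
    images_dir = Path(images_dir)
    by_id: Dict[str, MultiScoreImage] = {}
    score_types: set = set()
    for row in rows:
        img_id = row["image_id"]
        if img_id not in by_id:
            by_id[img_id] = MultiScoreImage(
                image=read_png(images_dir / row["path"]), image_id=img_id, scores={}
            )
        if row["left_score"] is not None:
            by_id[img_id].scores[row["score_type"]] = (
                row["left_score"],
                row["right_score"],
            )
            score_types.add(row["score_type"])
    return list(by_id.values()), sorted(score_types)


def write_augmentation_records(records: Sequence[AugmentationRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(AUGMENT_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.output_id,
                    rec.parent_a,
                    rec.parent_b,
                    rec.method,
                    rec.score_type,
                    _fmt(rec.left_score),
                    _fmt(rec.right_score),
                    _fmt(rec.global_score),
                    _fmt(rec.lam),
                ]
            )


def config_hash(config: Dict) -> str:
    """Short stable hash identifying a run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_checkpoint(
    directory,
    network: ViTNetwork,
    seed: int,
    extra: Optional[Dict] = None,
) -> Path:
    """Write ``weights.npz`` + ``config.json`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **network.params)
    meta = {
        "vit_config": asdict(network.config),
        "seed": int(seed),
        "config_hash": config_hash(asdict(network.config) | {"seed": int(seed)}),
    }
    if extra:
        meta.update(extra)
    (directory / "config.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_checkpoint(directory) -> Tuple[ViTNetwork, Dict]:
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    config = ViTConfig(**meta["vit_config"])
    with np.load(directory / "weights.npz") as data:
        params = {k: data[k] for k in data.files}
    return ViTNetwork(config, params=params), meta


def load_run_config(path) -> Dict:
    """Load a YAML run configuration as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"run config {path} must be a YAML mapping")
    return cfg
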