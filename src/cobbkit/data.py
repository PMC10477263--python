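"""Dataset manifests, annotation files and ROI cropping.

A dataset directory (as written by :func:`cobbkit.phantom.make_dataset`)
holds ``manifest.json``, ``images/`` and ``annotations/``; annotation
files carry the 17x4 corner coordinates, presence flags, ground-truth ROI
and posture per case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from .core import CORNER_NAMES, LandmarkSet, N_VERTEBRAE, ROIBox, SpineImage


@dataclass
class CaseRecord:
    case_id: str
    image: SpineImage
    landmarks: Optional[LandmarkSet]
    roi: Optional[ROIBox]
    posture: str
    bend_direction: int = 1
    annotation: Optional[dict] = None


def load_manifest(path) -> dict:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    manifest = json.loads(path.read_text())
    manifest["_root"] = str(path.parent)
    return manifest


def iter_cases(manifest: dict, split: Optional[str] = None) -> Iterator[CaseRecord]:
    """Yield cases of one split (or all) with images and ground truth loaded."""
    from .phantom import annotation_to_landmarks, load_image

    root = Path(manifest["_root"])
    for entry in manifest["cases"]:
        if split is not None and entry["split"] != split:
            continue
        ann = json.loads((root / entry["annotation"]).read_text())
        image = load_image(root / entry["image"], posture=entry.get("posture", "standing"))
        yield CaseRecord(
            case_id=entry["id"],
            image=image,
            landmarks=annotation_to_landmarks(ann),
            roi=ROIBox.from_array(ann["roi"]),
            posture=entry.get("posture", "standing"),
            bend_direction=int(ann.get("bend_direction", 1)),
            annotation=ann,
        )


@dataclass
class CropTransform:
    """Affine map between original-image pixels and ROI-crop-resized pixels.

    crop-frame = ((x, y) - (x0, y0)) * (sx, sy); all values in pixels.
    """

    x0: float
    y0: float
    sx: float
    sy: float

    def to_crop(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - np.array([self.x0, self.y0])) * np.array([self.sx, self.sy])

    def to_image(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts / np.array([self.sx, self.sy]) + np.array([self.x0, self.y0])


def crop_to_roi(
    image: SpineImage, box: ROIBox, out_size: tuple[int, int]
) -> tuple[np.ndarray, CropTransform]:
    """Crop the ROI out of a radiograph and resize to (H, W); min–max normalise.

    Returns the float crop in [0, 1] plus the exact pixel transform used,
    so detections can be mapped back to the original frame.
    """
    from skimage.transform import resize

    h, w = image.shape
    x1, y1, x2, y2 = box.to_pixels((h, w))
    ix1, iy1 = int(np.floor(x1)), int(np.floor(y1))
    ix2, iy2 = int(np.ceil(x2)), int(np.ceil(y2))
    ix1, iy1 = max(0, ix1), max(0, iy1)
    ix2, iy2 = min(w, max(ix2, ix1 + 2)), min(h, max(iy2, iy1 + 2))
    crop = np.asarray(image.pixels[iy1:iy2, ix1:ix2], dtype=float)
    rng_ = crop.max() - crop.min()
    if rng_ == 0:
        raise ValueError("ROI crop has zero dynamic range")
    crop = (crop - crop.min()) / rng_
    out_h, out_w = out_size
    resized = resize(crop, (out_h, out_w), order=1, anti_aliasing=True, mode="edge")
    tf = CropTransform(x0=ix1, y0=iy1, sx=out_w / (ix2 - ix1), sy=out_h / (iy2 - iy1))
    return resized, tf


def landmarks_to_csv_rows(case_id: str, landmarks: LandmarkSet) -> list[dict]:
    """One row per corner: case_id, level, corner, x, y, confidence, completed."""
    from .core import LEVELS

    rows = []
    for k in range(N_VERTEBRAE):
        for j, name in enumerate(CORNER_NAMES):
            rows.append(
                {
                    "case_id": case_id,
                    "level": LEVELS[k],
                    "corner": name,
                    "x": landmarks.points[k, j, 0],
                    "y": landmarks.points[k, j, 1],
                    "confidence": landmarks.confidence[k, j],
                    "completed": bool(landmarks.completed[k, j]),
                }
            )
    return rows
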