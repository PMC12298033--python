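"""Dataset export/import: PNG images plus COCO-keypoint-style JSON.

Annotations use the COCO keypoint convention — flat [x, y, v] triplets
per instance with a category declaring the keypoint names (shoulder,
elbow, wrist).  Per-sample PCK normalization lengths are carried in an
extension field of each annotation so exported datasets remain
self-contained for evaluation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .pose import KEYPOINT_NAMES
from .scenes import FederatedDataset, PoseSample

__all__ = ["save_coco_dataset", "load_coco_dataset", "export_federated_dataset"]


def save_coco_dataset(samples: Sequence[PoseSample], out_dir: str | Path,
                      prefix: str = "img") -> Path:
    """Write samples as PNGs plus an annotations.json in COCO keypoint style."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, annotations = [], []
    for i, s in enumerate(samples):
        fname = f"{prefix}_{i:05d}.png"
        arr = np.clip(s.image * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / fname)
        h, w = s.image.shape
        images.append({"id": i, "file_name": fname, "height": h, "width": w})
        kps = np.asarray(s.keypoints, dtype=np.float64)
        annotations.append({
            "id": i,
            "image_id": i,
            "category_id": 1,
            "keypoints": [float(v) for v in kps.ravel()],
            "num_keypoints": int((kps[:, 2] > 0).sum()),
            "norm_lengths": [float(v) for v in s.norm_lengths],
            "viewpoint": s.viewpoint,
        })
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{
            "id": 1,
            "name": "instrumented_arm",
            "keypoints": list(KEYPOINT_NAMES),
            "skeleton": [[1, 2], [2, 3]],
        }],
    }
    path = out / "annotations.json"
    path.write_text(json.dumps(doc))
    return path


def load_coco_dataset(ann_path: str | Path) -> list[PoseSample]:
    """Inverse of :func:`save_coco_dataset`."""
    ann_path = Path(ann_path)
    doc = json.loads(ann_path.read_text())
    by_image = {a["image_id"]: a for a in doc["annotations"]}
    samples = []
    for im in doc["images"]:
        arr = np.asarray(Image.open(ann_path.parent / im["file_name"]),
                         dtype=np.float32) / 255.0
        a = by_image[im["id"]]
        kps = np.asarray(a["keypoints"], dtype=np.float64).reshape(-1, 3)
        norms = np.asarray(a.get("norm_lengths", [np.hypot(*arr.shape), 1.0, 1.0]))
        samples.append(PoseSample(image=arr, keypoints=kps, norm_lengths=norms,
                                  viewpoint=a.get("viewpoint", "anterior")))
    return samples


def export_federated_dataset(dataset: FederatedDataset, out_dir: str | Path) -> None:
    """Per-client directories of PNGs + COCO JSON + the partition plan."""
    out = Path(out_dir)
    for cd in dataset.clients:
        save_coco_dataset(cd.train + cd.val, out / f"client_{cd.client_id:02d}")
    save_coco_dataset(dataset.test, out / "test")
    dataset.plan.to_json(out / "partition_plan.json")
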