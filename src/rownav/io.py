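"""Readers and writers for on-disk formats: images, YOLO labels, reports.

Pixel coordinates are 0-based, continuous, origin top-left, y down.  YOLO
label files carry one box per line, ``class cx cy w h [conf]``, all values
normalized to [0, 1]; the single-class convention fixes class_id = 0.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .illumination import GammaTable
from .rowfit import Detection

__all__ = [
    "read_image",
    "write_image",
    "read_yolo_labels",
    "write_yolo_labels",
    "write_gamma_table_csv",
    "load_yaml_config",
    "write_json_report",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load PNG/JPEG as an HxWx3 float array in [0, 1] (8-bit / 255)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float)
    return arr / 255.0


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 8-bit PNG/JPEG (round(x * 255))."""
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8)).save(path)


def read_yolo_labels(path: str | Path, image_w: float, image_h: float) -> list[Detection]:
    """Parse a YOLO label file into pixel-corner detections.

    Malformed lines or normalized values outside [0, 1] raise with the
    offending line number.
    """
    dets: list[Detection] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}: line {lineno}: expected 5 or 6 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric field") from exc
        if cls != 0:
            raise ValueError(f"{path}: line {lineno}: class_id must be 0 (single class)")
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError(f"{path}: line {lineno}: normalized value outside [0, 1]")
        cx, cy, w, h = vals[:4]
        conf = vals[4] if len(vals) == 5 else 1.0
        dets.append(Detection(
            x1=(cx - w / 2) * image_w, y1=(cy - h / 2) * image_h,
            x2=(cx + w / 2) * image_w, y2=(cy + h / 2) * image_h,
            confidence=conf,
        ))
    return dets


def write_yolo_labels(
    dets: list[Detection],
    image_w: float,
    image_h: float,
    path: str | Path,
    clip: bool = False,
    include_confidence: bool = False,
) -> None:
    """Write detections in the YOLO dialect (6-decimal fixed format).

    Boxes extending outside the image raise unless ``clip`` is set; the
    read(write(x)) round trip preserves coordinates to 1e-6 of the image
    size.
    """
    lines = []
    for i, d in enumerate(dets):
        x1, y1, x2, y2 = d.x1, d.y1, d.x2, d.y2
        if x1 < 0 or y1 < 0 or x2 > image_w or y2 > image_h:
            if not clip:
                raise ValueError(f"box {i} extends outside the {image_w}x{image_h} image; "
                                 "pass clip=True to truncate")
            x1, y1 = max(0.0, x1), max(0.0, y1)
            x2, y2 = min(image_w, x2), min(image_h, y2)
        cx, cy = (x1 + x2) / 2 / image_w, (y1 + y2) / 2 / image_h
        w, h = (x2 - x1) / image_w, (y2 - y1) / image_h
        fields = f"0 {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
        if include_confidence:
            fields += f" {d.confidence:.6f}"
        lines.append(fields)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_gamma_table_csv(tab: GammaTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["level", "n_l", "P", "P_w", "gamma"])
        for lvl in range(tab.bins):
            w.writerow([lvl, int(tab.counts[lvl]), repr(float(tab.pdf[lvl])),
                        repr(float(tab.weights[lvl])), repr(float(tab.gamma[lvl]))])


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
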