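"""Readers and writers: LabelMe point annotations, reports, configs, manifests.

Annotations round-trip through the LabelMe point dialect: one JSON file per
image with one ``point`` shape per landmark, labels taken from the per-view
canonical table, and coordinates stored as (x, y) = (col, row) per the
LabelMe convention (internal coordinates are (row, col) everywhere).

All artifact writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .metrics import MetricReport, SASParams
from .phantoms import VIEW_LANDMARK_LABELS, PhantomSample


class SchemaError(ValueError):
    """Annotation file violates the expected LabelMe point schema."""


# ---------------------------------------------------------------------------
# atomic writes
# ---------------------------------------------------------------------------

def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# LabelMe point annotations
# ---------------------------------------------------------------------------

def export_labelme(sample: PhantomSample, path, image_path=None) -> None:
    """Write one LabelMe JSON with 4 point shapes for a sample's landmarks."""
    h, w = sample.image.shape
    labels = VIEW_LANDMARK_LABELS[sample.view_id]
    shapes = [
        {
            "label": label,
            "points": [[float(c), float(r)]],  # LabelMe stores (x, y)
            "group_id": None,
            "shape_type": "point",
            "flags": {},
        }
        for label, (r, c) in zip(labels, sample.landmarks)
    ]
    doc = {
        "version": "5.2.1",
        "flags": {"view": sample.view_id},
        "shapes": shapes,
        "imagePath": str(image_path) if image_path else "",
        "imageData": None,
        "imageHeight": int(h),
        "imageWidth": int(w),
    }
    atomic_write_text(path, json.dumps(doc, indent=2))


def import_labelme(path, image=None) -> PhantomSample:
    """Read a LabelMe JSON back into a sample (points in canonical order).

    Non-point shapes are ignored with a warning; missing or unexpected
    point labels raise :class:`SchemaError` naming the offenders.  The
    image is loaded from ``imagePath`` when present (relative to the
    annotation file), else a zero image of the recorded size is used.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    view = doc.get("flags", {}).get("view")
    if view not in VIEW_LANDMARK_LABELS:
        raise SchemaError(f"{path}: unknown or missing view flag {view!r}")
    expected = VIEW_LANDMARK_LABELS[view]
    points = {}
    for shape in doc.get("shapes", []):
        if shape.get("shape_type") != "point":
            warnings.warn(
                f"{path}: ignoring non-point shape "
                f"{shape.get('shape_type')!r} ({shape.get('label')!r})",
                stacklevel=2)
            continue
        x, y = shape["points"][0]
        points[shape["label"]] = (float(y), float(x))  # back to (row, col)
    missing = [l for l in expected if l not in points]
    extra = [l for l in points if l not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: landmark labels mismatch; missing={missing}, "
            f"unexpected={extra}")
    landmarks = np.array([points[l] for l in expected])
    if image is None:
        img_path = doc.get("imagePath") or ""
        if img_path and (path.parent / img_path).exists():
            image = np.asarray(
                iio.imread(path.parent / img_path), dtype=np.float32)
        else:
            image = np.zeros((doc["imageHeight"], doc["imageWidth"]),
                             dtype=np.float32)
    return PhantomSample(image=image, landmarks=landmarks, view_id=view)


def export_sample(sample: PhantomSample, image_path, annotation_path) -> None:
    """PNG + LabelMe pair for one sample."""
    image_path, annotation_path = Path(image_path), Path(annotation_path)
    image_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(image_path, np.clip(np.round(sample.image), 0, 255)
                .astype(np.uint8))
    export_labelme(sample, annotation_path,
                   image_path=os.path.relpath(image_path,
                                              annotation_path.parent))


# ---------------------------------------------------------------------------
# metric reports
# ---------------------------------------------------------------------------

def write_report(report: MetricReport, base_path) -> tuple[Path, Path]:
    """Write a report as CSV (per-image + aggregate footer) and JSON.

    Returns (csv_path, json_path); reading the JSON back reproduces the
    report exactly.
    """
    base = Path(base_path)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    per_image = report.per_image.reset_index(drop=True)
    agg = report.aggregate()
    footer = agg.reset_index().rename(columns={"index": "aggregate"})
    csv_text = per_image.to_csv(index_label="image")
    csv_text += "\n" + footer.to_csv(index=False)
    atomic_write_text(csv_path, csv_text)
    payload = {
        "sdr_threshold": report.sdr_threshold,
        "sas_params": {"sas_alpha": report.sas_params.sas_alpha,
                       "sas_beta": report.sas_params.sas_beta},
        "columns": list(per_image.columns),
        "per_image": per_image.to_dict(orient="list"),
        "aggregate": {m: {"mean": float(agg.loc["mean", m]),
                          "sd": float(agg.loc["std", m])}
                      for m in agg.columns},
    }
    atomic_write_text(json_path, json.dumps(payload, indent=2))
    return csv_path, json_path


def read_report(base_path) -> MetricReport:
    json_path = Path(base_path).with_suffix(".json")
    with open(json_path) as fh:
        payload = json.load(fh)
    df = pd.DataFrame(payload["per_image"])[payload["columns"]]
    return MetricReport(
        per_image=df,
        sdr_threshold=payload["sdr_threshold"],
        sas_params=SASParams(**payload["sas_params"]))


# ---------------------------------------------------------------------------
# manifests and configs
# ---------------------------------------------------------------------------

def write_manifest(rows, path) -> None:
    """CSV manifest: image path, view, synthetic subject id, split, k group."""
    df = pd.DataFrame(list(rows))
    required = {"image", "view", "subject", "split"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest rows need columns {sorted(required)}")
    atomic_write_text(path, df.to_csv(index=False))


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_config(config: dict, path) -> None:
    atomic_write_text(path, yaml.safe_dump(config, sort_keys=True))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
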