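"""Evaluation suite for landmark detection: MDE, SDR, MAE, SAS, Dice, pixel accuracy.

* MDE -- mean Euclidean distance (pixels) between matched predicted and
  reference points.
* SDR -- successful detection rate: the fraction of points whose error is
  within a threshold distance.
* MAE -- mean angle error (degrees) between predicted and reference line
  segments; orientations are undirected, so differences fold into [0, 90].
* SAS -- spatial angular similarity,
  ``100 * (alpha * |cos theta| + (1 - alpha) * exp(-beta * d))``,
  combining parallelism (theta, the angle between the lines) with the line
  separation d.  Perfectly parallel lines score at least 100 * alpha
  regardless of separation.  d is the symmetrised midpoint-to-line
  distance, which makes the score invariant to swapping the two segments
  and reduces to the ordinary distance between parallel lines.
* Dice / mean pixel accuracy -- computed on heatmaps binarised at a
  fraction of each channel's own peak.

In the PLAX view the four collinear landmarks define three consecutive
segments: IVS (septum), LVID (internal dimension) and LVPW (posterior
wall).  Other views use generic consecutive-pair segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

PLAX_SEGMENT_LABELS = ("IVS", "LVID", "LVPW")


# ---------------------------------------------------------------------------
# point metrics
# ---------------------------------------------------------------------------

def _as_points(x) -> np.ndarray:
    p = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if p.shape[-1] != 2:
        raise ValueError("points must be (N, 2) (row, col)")
    return p


def mde(pred, ref) -> float:
    """Mean Euclidean distance over matched point pairs, in pixels."""
    p, r = _as_points(pred), _as_points(ref)
    if p.shape != r.shape:
        raise ValueError(f"point count mismatch: {p.shape} vs {r.shape}")
    return float(np.mean(np.linalg.norm(p - r, axis=-1)))


def sdr(pred_sets, ref_sets, threshold: float) -> float:
    """Fraction of all points within ``threshold`` pixels of the reference."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    p = np.asarray(pred_sets, dtype=np.float64).reshape(-1, 2)
    r = np.asarray(ref_sets, dtype=np.float64).reshape(-1, 2)
    if p.shape != r.shape:
        raise ValueError("point count mismatch")
    errs = np.linalg.norm(p - r, axis=-1)
    return float(np.mean(errs <= threshold))


# ---------------------------------------------------------------------------
# line metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineSegment:
    p0: tuple[float, float]
    p1: tuple[float, float]
    label: str = "generic"

    def __post_init__(self):
        if np.allclose(self.p0, self.p1):
            raise ValueError("degenerate segment: endpoints coincide")

    @property
    def direction(self) -> np.ndarray:
        v = np.asarray(self.p1, dtype=np.float64) - np.asarray(self.p0)
        return v / np.linalg.norm(v)

    @property
    def midpoint(self) -> np.ndarray:
        return (np.asarray(self.p0, dtype=np.float64)
                + np.asarray(self.p1)) / 2.0

    @property
    def length(self) -> float:
        return float(np.linalg.norm(
            np.asarray(self.p1, dtype=np.float64) - np.asarray(self.p0)))


def derive_plax_segments(points) -> list[LineSegment]:
    """IVS, LVID, LVPW segments from the four ordered PLAX landmarks."""
    pts = _as_points(points)
    if pts.shape != (4, 2):
        raise ValueError("PLAX segments need exactly 4 ordered points")
    return [LineSegment(tuple(pts[i]), tuple(pts[i + 1]),
                        label=PLAX_SEGMENT_LABELS[i]) for i in range(3)]


def derive_generic_segments(points) -> list[LineSegment]:
    """Consecutive-pair segments for views without named measurement lines."""
    pts = _as_points(points)
    return [LineSegment(tuple(pts[i]), tuple(pts[i + 1]))
            for i in range(len(pts) - 1)]


def _fold_angle(delta_deg: float) -> float:
    d = abs(delta_deg) % 180.0
    return min(d, 180.0 - d)


def mae(pred_seg: LineSegment, ref_seg: LineSegment) -> float:
    """Undirected orientation difference in degrees, folded into [0, 90]."""
    a1 = np.degrees(np.arctan2(*pred_seg.direction))
    a2 = np.degrees(np.arctan2(*ref_seg.direction))
    return _fold_angle(a1 - a2)


@dataclass(frozen=True)
class SASParams:
    """Weights of the spatial angular similarity score.

    sas_alpha in [0, 1] weighs orientation against separation; sas_beta
    (per pixel) sets how fast the separation term decays.
    """

    sas_alpha: float = 0.5
    sas_beta: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.sas_alpha <= 1.0:
            raise ValueError("sas_alpha must lie in [0, 1]")
        if self.sas_beta <= 0:
            raise ValueError("sas_beta must be positive")


def _point_line_distance(point: np.ndarray, seg: LineSegment) -> float:
    v = seg.direction
    w = point - np.asarray(seg.p0, dtype=np.float64)
    return float(abs(v[0] * w[1] - v[1] * w[0]))


def line_separation(a: LineSegment, b: LineSegment) -> float:
    """Symmetrised midpoint-to-infinite-line distance between two segments."""
    return 0.5 * (_point_line_distance(a.midpoint, b)
                  + _point_line_distance(b.midpoint, a))


def sas(pred_seg: LineSegment, ref_seg: LineSegment,
        params: SASParams = SASParams()) -> float:
    """Spatial angular similarity in [0, 100]."""
    theta = np.deg2rad(mae(pred_seg, ref_seg))
    d = line_separation(pred_seg, ref_seg)
    score = params.sas_alpha * abs(np.cos(theta)) \
        + (1.0 - params.sas_alpha) * np.exp(-params.sas_beta * d)
    return float(100.0 * score)


# ---------------------------------------------------------------------------
# heatmap metrics
# ---------------------------------------------------------------------------

def dice_and_pixel_accuracy(pred_heatmap, ref_heatmap,
                            bin_threshold: float = 0.5) -> tuple[float, float]:
    """Channel-averaged Dice and pixel accuracy of binarised heatmaps.

    Each channel is binarised at ``bin_threshold`` times its own peak;
    two empty masks count as Dice 1 by convention.
    """
    p = np.asarray(pred_heatmap, dtype=np.float64)
    r = np.asarray(ref_heatmap, dtype=np.float64)
    if p.ndim == 2:
        p, r = p[None], r[None]
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    if not 0.0 < bin_threshold < 1.0:
        raise ValueError("bin_threshold must lie in (0, 1)")
    dices, accs = [], []
    for pc, rc in zip(p, r):
        pm = pc >= bin_threshold * pc.max() if pc.max() > 0 else np.zeros_like(pc, bool)
        rm = rc >= bin_threshold * rc.max() if rc.max() > 0 else np.zeros_like(rc, bool)
        inter = np.logical_and(pm, rm).sum()
        total = pm.sum() + rm.sum()
        dices.append(1.0 if total == 0 else 2.0 * inter / total)
        accs.append(np.mean(pm == rm))
    return float(np.mean(dices)), float(np.mean(accs))


def mean_pixel_accuracy(pred_heatmap, ref_heatmap,
                        bin_threshold: float = 0.5) -> float:
    return dice_and_pixel_accuracy(pred_heatmap, ref_heatmap, bin_threshold)[1]


# ---------------------------------------------------------------------------
# per-image reports
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ("mde", "sdr", "mae", "sas", "dice", "pixel_accuracy")


@dataclass
class MetricReport:
    """Per-image metric values and their aggregate mean +/- SD."""

    per_image: pd.DataFrame
    sdr_threshold: float = 5.0
    sas_params: SASParams = field(default_factory=SASParams)

    def __post_init__(self):
        if len(self.per_image) == 0:
            raise ValueError("empty metric report")

    def aggregate(self) -> pd.DataFrame:
        cols = [c for c in METRIC_COLUMNS if c in self.per_image.columns]
        agg = self.per_image[cols].agg(["mean", "std"])
        return agg.fillna(0.0)

    def mean(self, metric: str) -> float:
        return float(self.per_image[metric].mean())

    def sd(self, metric: str) -> float:
        v = self.per_image[metric].std()
        return 0.0 if np.isnan(v) else float(v)

    def __eq__(self, other) -> bool:
        return (isinstance(other, MetricReport)
                and self.sdr_threshold == other.sdr_threshold
                and self.sas_params == other.sas_params
                and self.per_image.shape == other.per_image.shape
                and bool(np.allclose(self.per_image.to_numpy(),
                                     other.per_image.to_numpy(), atol=1e-9)))


def image_metrics(pred_points, ref_points, view_id: str = "PLAX",
                  pred_heatmaps=None, ref_heatmaps=None,
                  sdr_threshold: float = 5.0,
                  sas_params: SASParams = SASParams(),
                  bin_threshold: float = 0.5) -> dict:
    """All metrics for one image; segment metrics use the view's convention."""
    row = {
        "mde": mde(pred_points, ref_points),
        "sdr": sdr(pred_points, ref_points, sdr_threshold),
    }
    derive = derive_plax_segments if view_id == "PLAX" else derive_generic_segments
    try:
        psegs, rsegs = derive(pred_points), derive(ref_points)
        row["mae"] = float(np.mean([mae(a, b) for a, b in zip(psegs, rsegs)]))
        row["sas"] = float(np.mean(
            [sas(a, b, sas_params) for a, b in zip(psegs, rsegs)]))
    except ValueError:  # coincident consecutive predictions
        row["mae"] = 90.0
        row["sas"] = 0.0
    if pred_heatmaps is not None and ref_heatmaps is not None:
        d, a = dice_and_pixel_accuracy(pred_heatmaps, ref_heatmaps, bin_threshold)
        row["dice"] = d
        row["pixel_accuracy"] = a
    return row


def build_report(rows: Sequence[dict], sdr_threshold: float = 5.0,
                 sas_params: SASParams = SASParams()) -> MetricReport:
    return MetricReport(per_image=pd.DataFrame(list(rows)),
                        sdr_threshold=sdr_threshold, sas_params=sas_params)


def sdr_sweep(pred_sets, ref_sets, thresholds) -> pd.DataFrame:
    """Tidy long-format SDR-vs-threshold table."""
    return pd.DataFrame(
        [{"threshold": float(t), "sdr": sdr(pred_sets, ref_sets, t)}
         for t in thresholds])
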