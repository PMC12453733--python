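"""Parametric phantom echocardiograms with known landmark ground truth.

Real few-shot landmark studies draw A2C/A4C/PLAX/PSAX frames from clinical
datasets; this module emulates their structure with procedurally rendered
phantoms so the whole framework can be exercised without any external data.
Each view is a family of sector-masked speckle images containing a
chamber-like ellipse with a bright wall, plus a deterministic rule mapping
the sampled geometry to four ground-truth landmarks:

* A2C / A4C -- points on the chamber boundary (apex and basal points), with
  view-specific eccentricity and orientation;
* PLAX -- four collinear points crossing the chamber wall so that the three
  consecutive segments play the roles of IVS, LVID and LVPW;
* PSAX -- four points on a near-circular ring (short-axis cross-section).

Every output is a pure function of (spec, seed); all coordinates are
0-based (row, col).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

VIEWS = ("A2C", "A4C", "PLAX", "PSAX")

#: canonical landmark label order per view (index i = fixed anatomical role)
VIEW_LANDMARK_LABELS = {
    "A2C": ("apex", "basal_anterior", "basal_inferior_mid", "basal_inferior"),
    "A4C": ("apex", "basal_septal", "basal_mid", "basal_lateral"),
    "PLAX": ("ivs_top", "lvid_top", "lvid_bottom", "lvpw_bottom"),
    "PSAX": ("anterior", "lateral", "inferior", "septal"),
}


@dataclass(frozen=True)
class ViewSpec:
    """Geometry and appearance of one phantom view family.

    Fractional quantities are relative to ``image_size``.  ``jitter`` is the
    per-sample relative perturbation of centre and axis lengths, and
    orientation is drawn uniformly from ``orientation_range`` (degrees,
    counter-clockwise in (row, col)).
    """

    view_id: str
    image_size: int = 64
    center: tuple[float, float] = (0.52, 0.50)      # fractional (row, col)
    axes: tuple[float, float] = (0.25, 0.16)        # fractional semi-axes
    orientation_range: tuple[float, float] = (-8.0, 8.0)
    speckle_level: float = 0.35
    sector_angle: float = 80.0
    jitter: float = 0.05
    wall_frac: float = 0.10                          # wall thickness / size
    landmark_angles: Optional[tuple[float, ...]] = None  # boundary views
    plax_wall_fracs: tuple[float, float] = (0.08, 0.08)  # (IVS, LVPW) / size

    def __post_init__(self):
        if self.view_id not in VIEWS:
            raise ValueError(f"unknown view {self.view_id!r}")
        if min(self.axes) <= 0:
            raise ValueError("degenerate geometry: axis lengths must be positive")
        if self.speckle_level < 0:
            raise ValueError("speckle_level must be >= 0")
        if not (0 < self.sector_angle <= 180):
            raise ValueError("sector_angle must lie in (0, 180]")
        if self.image_size < 16:
            raise ValueError("image_size too small")


def default_view_specs(image_size: int = 64, speckle_level: float = 0.35):
    """The four standard view families, pairwise distinct in geometry."""
    common = dict(image_size=image_size, speckle_level=speckle_level)
    return {
        "A2C": ViewSpec(
            view_id="A2C", center=(0.54, 0.47), axes=(0.30, 0.13),
            orientation_range=(4.0, 16.0), sector_angle=72.0,
            landmark_angles=(180.0, 55.0, 0.0, -55.0), **common),
        "A4C": ViewSpec(
            view_id="A4C", center=(0.52, 0.52), axes=(0.26, 0.17),
            orientation_range=(-14.0, -2.0), sector_angle=84.0,
            landmark_angles=(180.0, 60.0, 0.0, -60.0), **common),
        "PLAX": ViewSpec(
            view_id="PLAX", center=(0.50, 0.52), axes=(0.13, 0.27),
            orientation_range=(-8.0, 8.0), sector_angle=96.0,
            plax_wall_fracs=(0.08, 0.08), **common),
        "PSAX": ViewSpec(
            view_id="PSAX", center=(0.55, 0.50), axes=(0.19, 0.19),
            orientation_range=(-4.0, 4.0), sector_angle=90.0,
            landmark_angles=(90.0, 0.0, -90.0, 180.0), **common),
    }


@dataclass
class PhantomSample:
    """One grayscale frame with its four ground-truth landmarks."""

    image: np.ndarray                 # (H, W), values in [0, 255]
    landmarks: np.ndarray             # (4, 2) float (row, col)
    view_id: str

    def __post_init__(self):
        self.landmarks = np.asarray(self.landmarks, dtype=np.float64)
        if self.landmarks.shape != (4, 2):
            raise ValueError("expected exactly 4 (row, col) landmarks")
        if self.image is not None:
            h, w = self.image.shape
            if np.any(self.landmarks < 0) or np.any(
                    self.landmarks >= [h, w]):
                raise ValueError("landmark outside image bounds")


@dataclass
class TaskEpisode:
    """A k-shot learning problem for one view: support + query samples."""

    view_id: str
    support: list
    query: list
    k: int

    def __post_init__(self):
        if self.k <= 0 or len(self.support) != self.k:
            raise ValueError("support size must equal k > 0")
        if not self.query:
            raise ValueError("episode needs at least one query sample")
        for s in list(self.support) + list(self.query):
            if s.view_id != self.view_id:
                raise ValueError("all episode samples must share the view id")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _rotation(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def sector_mask(size: int, sector_angle: float) -> np.ndarray:
    """Ultrasound fan: apex near the top centre, opening downward."""
    apex = np.array([2.0, size / 2.0])
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr, dc = rr - apex[0], cc - apex[1]
    dist = np.hypot(dr, dc)
    ang = np.degrees(np.arctan2(dc, dr))  # 0 = straight down
    half = sector_angle / 2.0
    return (np.abs(ang) <= half) & (dist <= 0.95 * size) & (dr >= 0)


def _landmarks_from_geometry(spec: ViewSpec, center, axes, ori_deg):
    rot = _rotation(ori_deg)
    if spec.view_id == "PLAX":
        # four collinear points along the rotated row axis through the
        # centre: IVS top, cavity top/bottom, posterior-wall bottom
        u = rot @ np.array([1.0, 0.0])
        half_lvid = axes[0]
        ivs = spec.plax_wall_fracs[0] * spec.image_size
        lvpw = spec.plax_wall_fracs[1] * spec.image_size
        pts = [
            center - u * (half_lvid + ivs),
            center - u * half_lvid,
            center + u * half_lvid,
            center + u * (half_lvid + lvpw),
        ]
    else:
        pts = []
        for t in spec.landmark_angles:
            tr = np.deg2rad(t)
            off = np.array([axes[0] * np.cos(tr), axes[1] * np.sin(tr)])
            pts.append(center + rot @ off)
    return np.array(pts)


def _render_template(spec: ViewSpec, center, axes, ori_deg) -> np.ndarray:
    n = spec.image_size
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    d = np.stack([rr - center[0], cc - center[1]])
    rot = _rotation(-ori_deg)
    dr = rot[0, 0] * d[0] + rot[0, 1] * d[1]
    dc = rot[1, 0] * d[0] + rot[1, 1] * d[1]
    q = np.sqrt((dr / axes[0]) ** 2 + (dc / axes[1]) ** 2)  # ellipse radius
    wall = spec.wall_frac * n / min(axes)
    img = np.full((n, n), 70.0)
    img[q < 1.0] = 25.0                       # blood pool (dark)
    img[(q >= 1.0) & (q <= 1.0 + wall)] = 220.0  # bright myocardial wall
    return gaussian_filter(img, sigma=1.0)


def render_phantom(spec: ViewSpec, rng_seed: int) -> PhantomSample:
    """Render one phantom; deterministic given (spec, seed).

    Geometry (centre, axes, orientation) is jittered per sample; draws whose
    landmarks would leave the sector are rejected and deterministically
    resampled from the same stream.
    """
    rng = np.random.default_rng(rng_seed)
    n = spec.image_size
    mask = sector_mask(n, spec.sector_angle)
    for _ in range(64):
        center = (np.array(spec.center)
                  + rng.uniform(-spec.jitter, spec.jitter, 2)) * n
        axes = (np.array(spec.axes)
                * (1.0 + rng.uniform(-spec.jitter, spec.jitter, 2))) * n
        ori = rng.uniform(*spec.orientation_range)
        pts = _landmarks_from_geometry(spec, center, axes, ori)
        ip = np.clip(np.round(pts).astype(int), 0, n - 1)
        inside = (np.all(pts > 0) and np.all(pts < n - 1)
                  and bool(np.all(mask[ip[:, 0], ip[:, 1]])))
        if inside:
            break
    else:
        raise RuntimeError(
            f"could not place landmarks inside the sector for {spec.view_id}")
    img = _render_template(spec, center, axes, ori)
    if spec.speckle_level > 0:
        img = img * (1.0 + spec.speckle_level * rng.uniform(-1, 1, img.shape))
    img = np.clip(img, 0.0, 255.0)
    img[~mask] = 0.0
    return PhantomSample(image=img.astype(np.float32), landmarks=pts,
                         view_id=spec.view_id)


def sample_episode(spec: ViewSpec, k: int, n_query: int,
                   rng_seed: int) -> TaskEpisode:
    """Draw a k-shot episode: k support + n_query query phantoms.

    Child seeds are spawned from the episode seed, so the same episode seed
    reproduces the episode exactly while support and query draws stay
    mutually distinct.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if n_query < 1:
        raise ValueError("n_query must be >= 1")
    seeds = np.random.SeedSequence(rng_seed).generate_state(k + n_query)
    seeds = [int(s) & 0x7FFFFFFF for s in seeds]
    support = [render_phantom(spec, s) for s in seeds[:k]]
    query = [render_phantom(spec, s) for s in seeds[k:]]
    return TaskEpisode(view_id=spec.view_id, support=support, query=query, k=k)
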