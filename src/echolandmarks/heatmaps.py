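"""Landmark <-> Gaussian-heatmap conversion, preprocessing, augmentation.

Detection is cast as segmentation: each landmark becomes one channel whose
target is a 2D Gaussian of standard deviation ``sigma`` (default 7 px)
centred on the point, with peak amplitude 1.  Prediction decodes back to a
point by taking each channel's argmax (ties broken towards the lowest
(row, col) in lexicographic order), with optional subpixel centroid
refinement.  All coordinates are 0-based (row, col); rotation angles are
counter-clockwise positive in that frame.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .phantoms import PhantomSample

DEFAULT_SIGMA = 7.0


def encode_heatmaps(points, shape, sigma: float = DEFAULT_SIGMA,
                    dtype=np.float32) -> np.ndarray:
    """Encode landmark points as per-channel Gaussian heatmaps.

    Channel c holds exp(-d^2 / (2 sigma^2)) where d is the pixel distance
    to point c; the peak value is exactly 1 at the point's pixel when the
    point has integer coordinates.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    h, w = shape
    if np.any(pts < 0) or np.any(pts[:, 0] > h - 1) or np.any(pts[:, 1] > w - 1):
        raise ValueError("point outside the target shape")
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    d2 = ((rows[None, :, None] - pts[:, 0, None, None]) ** 2
          + (cols[None, None, :] - pts[:, 1, None, None]) ** 2)
    return np.exp(-d2 / (2.0 * sigma * sigma)).astype(dtype)


def decode_points(heatmaps: np.ndarray, subpixel: bool = False,
                  smooth_sigma: float = 0.0) -> np.ndarray:
    """Per-channel argmax decoding: heatmaps (C, H, W) -> points (C, 2).

    A flat (all-equal) channel is degenerate: a warning is issued and the
    lexicographic tie-break coordinate (0, 0) is returned for it.  With
    ``subpixel=True`` the argmax is refined by the intensity centroid of
    its 3x3 neighbourhood.  ``smooth_sigma > 0`` applies a Gaussian
    matched filter before the argmax -- the region-centre decode to use on
    noisy maps; the default 0 is the exact, threshold-free argmax.
    """
    hm = np.asarray(heatmaps, dtype=np.float64)
    if smooth_sigma > 0:
        hm = ndimage.gaussian_filter(
            hm, sigma=(0,) * (hm.ndim - 2) + (smooth_sigma, smooth_sigma))
    if hm.ndim == 2:
        hm = hm[None]
    if hm.ndim != 3:
        raise ValueError("expected (C, H, W) heatmaps")
    if not np.all(np.isfinite(hm.max(axis=(1, 2)))):
        raise ValueError("each channel needs at least one finite value")
    c, h, w = hm.shape
    pts = np.empty((c, 2), dtype=np.float64)
    for i in range(c):
        ch = hm[i]
        if np.all(ch == ch.flat[0]):
            warnings.warn(f"flat heatmap channel {i}: degenerate decode",
                          RuntimeWarning, stacklevel=2)
        r, cidx = np.unravel_index(int(np.argmax(ch)), (h, w))
        if subpixel:
            r0, r1 = max(r - 1, 0), min(r + 2, h)
            c0, c1 = max(cidx - 1, 0), min(cidx + 2, w)
            win = ch[r0:r1, c0:c1]
            tot = win.sum()
            if tot > 0:
                rr, cc = np.mgrid[r0:r1, c0:c1]
                pts[i] = (rr * win).sum() / tot, (cc * win).sum() / tot
                continue
        pts[i] = r, cidx
    return pts


def preprocess(image, target_size: int = 256) -> np.ndarray:
    """Resize to target_size x target_size and rescale intensities to [0, 255].

    A constant image (zero intensity range) maps to all zeros.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2D grayscale image")
    if img.shape != (target_size, target_size):
        img = _sk_resize(img, (target_size, target_size), order=1,
                         preserve_range=True, anti_aliasing=False)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) * (255.0 / (hi - lo))


def rescale_points(points, from_shape, to_shape) -> np.ndarray:
    """Map (row, col) points between resolutions along with a resize."""
    pts = np.asarray(points, dtype=np.float64)
    sr = to_shape[0] / from_shape[0]
    sc = to_shape[1] / from_shape[1]
    return pts * np.array([sr, sc])


def _rot_mat(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def rotate_points(points, angle: float, center) -> np.ndarray:
    """Rotate points about ``center`` by ``angle`` degrees (CCW positive),
    matching the image transform of :func:`augment_rotation` exactly."""
    pts = np.asarray(points, dtype=np.float64)
    ctr = np.asarray(center, dtype=np.float64)
    return (pts - ctr) @ _rot_mat(angle) + ctr  # right-multiply == R(-a) @ p


def augment_rotation(sample: PhantomSample, angle: float | None = None,
                     rng_seed: int = 0,
                     max_angle: float = 30.0) -> PhantomSample:
    """Rotate a sample about the image centre; landmarks follow exactly.

    ``angle`` is in degrees within [0, max_angle]; when None it is sampled
    uniformly from that range.  If a rotation carries a landmark out of
    bounds, a sampled draw is rejected and resampled; an explicit angle
    raises instead.
    """
    img = np.asarray(sample.image, dtype=np.float64)
    h, w = img.shape
    ctr = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rng = np.random.default_rng(rng_seed)

    def _apply(a: float) -> PhantomSample | None:
        pts = rotate_points(sample.landmarks, a, ctr)
        if np.any(pts < 0) or np.any(pts >= [h, w]):
            return None
        if a == 0.0:
            return PhantomSample(image=sample.image.copy(),
                                 landmarks=pts, view_id=sample.view_id)
        # inverse map: output pixel o samples input at R(a)(o-c)+c
        mat = _rot_mat(a)
        offset = ctr - mat @ ctr
        out = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                       mode="constant", cval=0.0)
        return PhantomSample(image=out.astype(sample.image.dtype),
                             landmarks=pts, view_id=sample.view_id)

    if angle is not None:
        if not 0.0 <= angle <= max_angle:
            raise ValueError(f"angle must lie in [0, {max_angle}]")
        result = _apply(float(angle))
        if result is None:
            raise ValueError("rotation moved a landmark out of bounds")
        return result
    for _ in range(100):
        result = _apply(float(rng.uniform(0.0, max_angle)))
        if result is not None:
            return result
    raise RuntimeError("could not find an in-bounds rotation")
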