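"""Left-ventricular mass (LVM) estimation from detected landmarks.

Two clinical formulas are provided in their standard (ASE-convention)
forms, with the constants exposed for variant conventions:

* Devereux (PLAX linear measurements, cm -> grams):
      LVM = 0.8 * 1.04 * ((IVS + LVID + LVPW)^3 - LVID^3) + 0.6
* Area-length (cross-sectional areas + long-axis lengths):
      LVM = 1.05 * ((5/6) * A1 * (a + d + t) - (5/6) * A2 * (a + d))

Both are homogeneous of degree 3 in linear dimensions (up to the additive
0.6 g constant).  Pixel-to-centimetre calibration is a required explicit
input: phantom and open echo datasets carry no physical spacing, so no
default exists on purpose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import derive_plax_segments


@dataclass(frozen=True)
class PlaxMeasurements:
    """PLAX linear measurements in centimetres."""

    ivs: float
    lvid: float
    lvpw: float
    pixel_spacing: float = float("nan")  # cm/px used to derive the lengths

    def __post_init__(self):
        if min(self.ivs, self.lvid, self.lvpw) <= 0:
            raise ValueError("all PLAX lengths must be positive (cm)")


@dataclass(frozen=True)
class AreaLengthMeasurements:
    """Area-length inputs: areas in cm^2, lengths in cm."""

    a1: float  # epicardial area
    a2: float  # endocardial area
    a: float   # apex to short-axis plane
    d: float   # short-axis plane to mitral plane
    t: float   # mean wall thickness

    def __post_init__(self):
        if self.a1 < self.a2:
            raise ValueError("epicardial area A1 cannot be below endocardial A2")
        if self.a2 <= 0 or self.a <= 0 or self.d <= 0 or self.t < 0:
            raise ValueError("areas and lengths must be positive")


def devereux_lvm(m: PlaxMeasurements, *, scale: float = 0.8,
                 density: float = 1.04, offset: float = 0.6) -> float:
    """Devereux LVM in grams from PLAX linear measurements (cm)."""
    cube = (m.ivs + m.lvid + m.lvpw) ** 3 - m.lvid ** 3
    return float(scale * density * cube + offset)


def area_length_lvm(m: AreaLengthMeasurements, *,
                    density: float = 1.05) -> float:
    """Area-length LVM in grams."""
    outer = (5.0 / 6.0) * m.a1 * (m.a + m.d + m.t)
    inner = (5.0 / 6.0) * m.a2 * (m.a + m.d)
    return float(density * (outer - inner))


def segments_to_measurements(points, pixel_spacing: float) -> PlaxMeasurements:
    """PLAX landmark points -> calibrated IVS/LVID/LVPW lengths (cm)."""
    if not np.isfinite(pixel_spacing) or pixel_spacing <= 0:
        raise ValueError(
            "pixel_spacing (cm/px) is required: image data carries no "
            "physical calibration")
    segs = derive_plax_segments(points)
    ivs, lvid, lvpw = (s.length * pixel_spacing for s in segs)
    return PlaxMeasurements(ivs=ivs, lvid=lvid, lvpw=lvpw,
                            pixel_spacing=pixel_spacing)
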