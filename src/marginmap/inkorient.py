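"""Edge-ink detection and clock-angle tissue orientation.

Mohs sections are inked at agreed clock positions (blue = 12 o'clock,
red = 6 o'clock) before sectioning.  Recovering the blue->red line from
the stained slide re-orients the section relative to the patient.

Clock-angle convention (used repo-wide, all angles in degrees):

* image coordinates: x right, y down, origin top-left;
* 0 deg points "up" on screen (toward -y), angles increase clockwise;
* a correctly laid section (blue at top, red at bottom) therefore has a
  blue->red line angle of 180 deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import color as skcolor
from skimage import filters, measure, morphology

__all__ = [
    "InkMap",
    "OrientationLine",
    "DEFAULT_HSV_RANGES",
    "clock_angle",
    "relative_angle",
    "rotation_matrix",
    "rotate_points",
    "tissue_edge_band",
    "detect_inks",
    "ink_centroid",
    "orientation_line",
]


class MissingInkError(KeyError):
    """Requested ink color was not detected on the section."""


class DegenerateLineError(ValueError):
    """Blue and red centroids coincide; orientation undefined."""


# ---------------------------------------------------------------------------
# angle arithmetic


def clock_angle(vec_xy) -> float:
    """Clock angle of a 2-D image-coordinate vector, degrees in [0, 360).

    0 = up (-y), 90 = right (+x), 180 = down (+y), 270 = left (-x).
    """
    dx, dy = float(vec_xy[0]), float(vec_xy[1])
    if dx == 0.0 and dy == 0.0:
        raise DegenerateLineError("zero vector has no clock angle")
    return float(np.degrees(np.arctan2(dx, -dy)) % 360.0)


def relative_angle(a: float, b: float) -> float:
    """Signed smallest rotation (degrees, in [-180, 180)) taking angle ``b`` onto ``a``."""
    return float((a - b + 180.0) % 360.0 - 180.0)


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """2x2 matrix rotating image-coordinate points clockwise on screen by ``angle_deg``.

    In y-down coordinates a clockwise-on-screen rotation is the standard
    counter-clockwise matrix.
    """
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


def rotate_points(points: np.ndarray, angle_deg: float, center=(0.0, 0.0)) -> np.ndarray:
    """Rotate (n,2) image-coordinate points clockwise on screen about ``center``."""
    pts = np.asarray(points, dtype=float)
    ctr = np.asarray(center, dtype=float)
    return (pts - ctr) @ rotation_matrix(angle_deg).T + ctr


# ---------------------------------------------------------------------------
# data containers


@dataclass
class InkMap:
    """Per-color edge-ink pixel sets of one section.

    ``pixels`` maps color name -> (n, 2) array of (x, y) pixel coordinates
    restricted to the tissue-edge band; ``n_components`` maps color name ->
    number of surviving connected components.  Colors with no surviving
    pixels are recorded in ``absent``.
    """

    pixels: dict[str, np.ndarray] = field(default_factory=dict)
    n_components: dict[str, int] = field(default_factory=dict)
    absent: list[str] = field(default_factory=list)

    def present(self, col: str) -> bool:
        return col in self.pixels

    def to_record(self) -> dict:
        rec = {}
        for col, pix in self.pixels.items():
            rec[col] = {
                "n_pixels": int(len(pix)),
                "n_components": int(self.n_components[col]),
                "centroid": [float(v) for v in pix.mean(axis=0)],
            }
        for col in self.absent:
            rec[col] = None
        return rec


@dataclass
class OrientationLine:
    """Blue->red orientation line of a section under the clock convention."""

    blue_xy: tuple[float, float]
    red_xy: tuple[float, float]
    theta: float  # degrees in [0, 360)

    def to_record(self) -> dict:
        return {
            "blue_xy": [float(v) for v in self.blue_xy],
            "red_xy": [float(v) for v in self.red_xy],
            "theta": float(self.theta),
        }


# ---------------------------------------------------------------------------
# detection

#: HSV detection ranges; hue in degrees [0, 360).  Each entry is a list of
#: (hue_lo, hue_hi) intervals plus minimum saturation and value.
DEFAULT_HSV_RANGES: dict[str, dict] = {
    "blue": {"hue": [(200.0, 260.0)], "s_min": 0.35, "v_min": 0.2},
    "red": {"hue": [(0.0, 15.0), (345.0, 360.0)], "s_min": 0.35, "v_min": 0.2},
    "yellow": {"hue": [(45.0, 70.0)], "s_min": 0.35, "v_min": 0.2},
    "green": {"hue": [(90.0, 150.0)], "s_min": 0.35, "v_min": 0.2},
    "orange": {"hue": [(16.0, 44.0)], "s_min": 0.35, "v_min": 0.2},
    "purple": {"hue": [(261.0, 320.0)], "s_min": 0.35, "v_min": 0.2},
    "black": {"hue": [(0.0, 360.0)], "s_min": 0.0, "v_min": 0.0, "v_max": 0.15},
}


def tissue_edge_band(raster, mask, band_px: int = 16) -> np.ndarray:
    """Band of width ~``band_px`` around the tissue-mask boundary.

    The boundary is localized with a Sobel gradient of the mask, thickened by
    morphological dilation and cleaned with an opening.  Ink is only credited
    inside this band: inks are applied to the specimen edge, so interior
    color (pen, stain artifact) must never count.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    if not mask.any():
        return np.zeros_like(mask)
    grad = filters.sobel(mask.astype(float))
    edge = grad > 1e-6
    band = morphology.dilation(edge, morphology.disk(max(1, band_px // 2)))
    band = morphology.opening(band, morphology.disk(1))
    return band


def _hsv(raster: np.ndarray) -> np.ndarray:
    img = np.asarray(raster)
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    hsv = skcolor.rgb2hsv(img)
    hsv[..., 0] *= 360.0
    return hsv


def detect_inks(
    raster,
    edge_band,
    colors=("blue", "red"),
    hsv_ranges: dict | None = None,
    min_component_px: int = 50,
) -> InkMap:
    """Detect edge inks by HSV thresholding + connected-component denoising.

    Per color: pixels inside the HSV range AND inside the edge band are
    labelled; components smaller than ``min_component_px`` are discarded as
    spurious applications (seepage, specks).  Colors with nothing surviving
    are recorded as absent.  Output is independent of the order of
    ``colors``.
    """
    ranges = dict(DEFAULT_HSV_RANGES)
    if hsv_ranges:
        ranges.update(hsv_ranges)
    hsv = _hsv(raster)
    band = np.asarray(edge_band).astype(bool)
    out = InkMap()
    for col in sorted(colors):
        spec = ranges[col]
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        in_hue = np.zeros(h.shape, dtype=bool)
        for lo, hi in spec["hue"]:
            in_hue |= (h >= lo) & (h <= hi)
        cand = in_hue & (s >= spec["s_min"]) & (v >= spec["v_min"])
        if "v_max" in spec:
            cand &= v <= spec["v_max"]
        cand &= band
        lbl = measure.label(cand, connectivity=2)
        keep = np.zeros_like(cand)
        n_comp = 0
        for region in measure.regionprops(lbl):
            if region.area >= min_component_px:
                keep[lbl == region.label] = True
                n_comp += 1
        if n_comp == 0:
            out.absent.append(col)
            continue
        yy, xx = np.nonzero(keep)
        out.pixels[col] = np.column_stack([xx, yy]).astype(float)
        out.n_components[col] = n_comp
    return out


def ink_centroid(inkmap: InkMap, color: str, method: str = "mean", trim: float = 0.1):
    """Center of mass of one ink color: ``mean``, coordinatewise ``median``,
    or ``trimmed`` mean (``trim`` fraction cut from each tail per coordinate)."""
    if not inkmap.present(color):
        raise MissingInkError(f"ink color {color!r} not detected")
    pix = inkmap.pixels[color]
    if method == "mean":
        c = pix.mean(axis=0)
    elif method == "median":
        c = np.median(pix, axis=0)
    elif method == "trimmed":
        c = np.array([stats.trim_mean(pix[:, 0], trim), stats.trim_mean(pix[:, 1], trim)])
    else:
        raise ValueError(f"unknown centroid method {method!r}")
    return float(c[0]), float(c[1])


def orientation_line(blue_xy, red_xy) -> OrientationLine:
    """Blue->red line and its clock angle."""
    b = np.asarray(blue_xy, dtype=float)
    r = np.asarray(red_xy, dtype=float)
    if np.allclose(b, r):
        raise DegenerateLineError("blue and red centroids coincide")
    theta = clock_angle(r - b)
    return OrientationLine(blue_xy=(b[0], b[1]), red_xy=(r[0], r[1]), theta=theta)


def orient_section(raster, mask, band_px=16, colors=("blue", "red"),
                   hsv_ranges=None, min_component_px=50, method="mean"):
    """Full orientation of one section raster: edge band -> inks -> line.

    Returns ``(InkMap, OrientationLine | None)``; the line is ``None`` when
    either blue or red is absent (section flagged unoriented downstream).
    """
    band = tissue_edge_band(raster, mask, band_px=band_px)
    inks = detect_inks(raster, band, colors=colors, hsv_ranges=hsv_ranges,
                       min_component_px=min_component_px)
    if not (inks.present("blue") and inks.present("red")):
        warnings.warn("blue/red ink missing; section left unoriented")
        return inks, None
    line = orientation_line(ink_centroid(inks, "blue", method),
                            ink_centroid(inks, "red", method))
    return inks, line
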