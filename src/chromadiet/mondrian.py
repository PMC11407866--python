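"""Axis-constrained chromatic Mondrian stimulus generation and validation.

A Mondrian is built by dropping random rectangles onto an oversized canvas
until a central crop is fully painted, then extracting the crop (so no edge
or background artefacts survive).  Every element's chromaticity lies on a
single axis through the white point of the scaled chromaticity diagram: its
hue is one of the axis's two complementary poles, its saturation is uniform
on [0, s_max] and its luminance is jittered uniformly within +-50% of the
mean.  Element edge lengths are uniform between 2% and 17% of the crop size
(occlusion by later elements can leave smaller visible fragments).

The rendered image is *chromaticity-referenced*: channels are the scaled
diagram coordinates (x, y) and luminance in cd/m^2.  ``preview_rgb`` maps it
to a display-referred 8-bit RGB for inspection only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "AXIS_ANGLES_DEG",
    "MondrianParams",
    "Element",
    "MondrianSpec",
    "MondrianReport",
    "CoverageError",
    "generate_mondrian",
    "validate_mondrian",
    "preview_rgb",
]

# Pole hue angle of each stimulus axis, 1-based ids 1..8.
AXIS_ANGLES_DEG = {k: 22.5 * (k - 1) for k in range(1, 9)}


class CoverageError(RuntimeError):
    def __init__(self, message: str, coverage: float):
        super().__init__(message)
        self.coverage = coverage


@dataclass(frozen=True)
class MondrianParams:
    crop_size: int = 256
    canvas_factor: float = 1.5  # canvas edge = factor * crop edge
    min_frac: float = 0.02  # element edge, fraction of crop size
    max_frac: float = 0.17
    s_max: float = 0.8  # gamut-limited saturation ceiling
    mean_luminance: float = 55.0  # cd/m^2
    lum_jitter: float = 0.5  # +-50% of the mean
    max_elements: int = 5000  # hard cap before CoverageError

    def __post_init__(self) -> None:
        if not (0 < self.min_frac <= self.max_frac < 1):
            raise ValueError("element size fractions must satisfy 0 < min <= max < 1")
        if self.s_max < 0 or self.crop_size < 8 or self.canvas_factor < 1:
            raise ValueError("invalid Mondrian parameters")


@dataclass(frozen=True)
class Element:
    x0: int  # canvas coordinates of the top-left corner
    y0: int
    width: int
    height: int
    hue_deg: float  # one of the axis's two poles
    saturation: float
    luminance: float


@dataclass
class MondrianSpec:
    axis_id: int
    pole_deg: float
    crop_size: int
    canvas_size: int
    seed: int
    params: MondrianParams
    elements: list[Element] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        d = {
            "axis_id": self.axis_id,
            "pole_deg": self.pole_deg,
            "crop_size": self.crop_size,
            "canvas_size": self.canvas_size,
            "seed": self.seed,
            "params": asdict(self.params),
            "elements": [asdict(e) for e in self.elements],
        }
        Path(path).write_text(json.dumps(d, indent=1))


def generate_mondrian(
    axis_id: int, params: MondrianParams = MondrianParams(), seed: int = 0
) -> tuple[MondrianSpec, np.ndarray]:
    """Generate one Mondrian stimulus.

    Returns the element-list spec and the rendered crop, an
    ``(crop, crop, 3)`` float array with channels (x, y, luminance) in the
    scaled chromaticity diagram.  Fully reproducible from ``seed``.  Raises
    :class:`CoverageError` if the element cap is reached before the crop is
    completely painted.
    """
    if axis_id not in AXIS_ANGLES_DEG:
        raise ValueError("axis_id must be 1..8")
    p = params
    pole = AXIS_ANGLES_DEG[axis_id]
    crop = p.crop_size
    canvas = int(round(p.canvas_factor * crop))
    if canvas <= crop:
        raise ValueError("canvas must strictly contain the crop")
    off = (canvas - crop) // 2

    wmin = math.ceil(p.min_frac * crop)
    wmax = math.floor(p.max_frac * crop)
    if wmin > wmax or wmin < 1:
        raise ValueError("crop too small for the element size bounds")

    rng = np.random.default_rng(seed)
    img = np.zeros((canvas, canvas, 3), dtype=float)
    painted = np.zeros((canvas, canvas), dtype=bool)
    crop_sl = (slice(off, off + crop), slice(off, off + crop))

    spec = MondrianSpec(
        axis_id=axis_id, pole_deg=pole, crop_size=crop, canvas_size=canvas,
        seed=seed, params=p,
    )
    while True:
        if len(spec.elements) >= p.max_elements:
            cov = float(painted[crop_sl].mean())
            raise CoverageError(
                f"element cap {p.max_elements} reached at crop coverage {cov:.4f}",
                cov,
            )
        w = int(rng.integers(wmin, wmax + 1))
        h = int(rng.integers(wmin, wmax + 1))
        x0 = int(rng.integers(0, canvas - w + 1))
        y0 = int(rng.integers(0, canvas - h + 1))
        hue = pole if rng.random() < 0.5 else (pole + 180.0) % 360.0
        sat = float(rng.uniform(0.0, p.s_max))
        lum = float(p.mean_luminance * rng.uniform(1 - p.lum_jitter, 1 + p.lum_jitter))
        spec.elements.append(Element(x0, y0, w, h, hue, sat, lum))
        rad = math.radians(hue)
        img[y0 : y0 + h, x0 : x0 + w, 0] = sat * math.cos(rad)
        img[y0 : y0 + h, x0 : x0 + w, 1] = sat * math.sin(rad)
        img[y0 : y0 + h, x0 : x0 + w, 2] = lum
        painted[y0 : y0 + h, x0 : x0 + w] = True
        if painted[crop_sl].all():
            break
    return spec, img[crop_sl].copy()


@dataclass(frozen=True)
class MondrianReport:
    axis_purity: float  # fraction of pixels whose hue is on-axis (or achromatic)
    n_size_violations: int
    n_luminance_violations: int
    n_saturation_violations: int
    coverage: float  # fraction of crop pixels painted (luminance > 0)
    ok: bool


def validate_mondrian(
    spec: MondrianSpec, image: np.ndarray, angle_tol_deg: float = 1e-6
) -> MondrianReport:
    """Check a stimulus against its declared constraints (report, never raises).

    Verifies: every pixel's hue angle is at one of the axis's two poles
    (within tolerance) or achromatic; element edges within [min_frac,
    max_frac] of the crop size; luminances within the jitter band; saturations
    within [0, s_max]; full crop coverage.
    """
    p = spec.params
    if image.shape[:2] != (spec.crop_size, spec.crop_size):
        raise ValueError("image and spec sizes are inconsistent")
    x, y, lum = image[..., 0], image[..., 1], image[..., 2]
    sat = np.hypot(x, y)
    hue = np.degrees(np.arctan2(y, x)) % 360.0
    # angular distance to the axis line (either pole)
    d = np.abs((hue - spec.pole_deg + 90.0) % 180.0 - 90.0)
    on_axis = (sat <= 1e-12) | (d <= angle_tol_deg)
    purity = float(on_axis.mean())

    lo, hi = p.min_frac * spec.crop_size, p.max_frac * spec.crop_size
    size_bad = sum(
        1 for e in spec.elements
        if not (lo <= e.width <= hi and lo <= e.height <= hi)
    )
    lmin = p.mean_luminance * (1 - p.lum_jitter)
    lmax = p.mean_luminance * (1 + p.lum_jitter)
    lum_bad = sum(1 for e in spec.elements if not (lmin <= e.luminance <= lmax))
    sat_bad = sum(1 for e in spec.elements if not (0 <= e.saturation <= p.s_max))
    coverage = float((lum > 0).mean())
    ok = (
        purity == 1.0
        and size_bad == 0
        and lum_bad == 0
        and sat_bad == 0
        and coverage == 1.0
    )
    return MondrianReport(purity, size_bad, lum_bad, sat_bad, coverage, ok)


def preview_rgb(image: np.ndarray, params: MondrianParams = MondrianParams()) -> np.ndarray:
    """Display-referred 8-bit preview of a rendered Mondrian.

    A deliberately simple visualisation map (not a colorimetric rendering):
    lightness from luminance, opponent channels from the scaled chromaticity
    coordinates.
    """
    x, y, lum = image[..., 0], image[..., 1], image[..., 2]
    L = lum / (params.mean_luminance * (1 + params.lum_jitter))
    cx = np.zeros_like(x) if params.s_max == 0 else x / params.s_max
    cy = np.zeros_like(y) if params.s_max == 0 else y / params.s_max
    r = L + 0.35 * cx - 0.20 * cy
    g = L - 0.35 * cx - 0.20 * cy
    b = L + 0.45 * cy
    rgb = np.clip(np.stack([r, g, b], axis=-1), 0.0, 1.0)
    return (rgb * 255).astype(np.uint8)
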