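"""Colour-space conversions between camera RGB, LMS cone excitations and the
MacLeod-Boynton (MB) chromaticity diagram.

The MB diagram represents a light at constant luminance by two cone-opponent
coordinates, ``l = L/(L+M)`` and ``s = S/(L+M)``, matching the tuning of the
two retinogeniculate colour pathways.  A *scaled* chromaticity diagram is an
affine re-centring of the MB diagram on a chosen white point, with per-axis
contrast-equating scale factors; in that diagram polar angle is hue and
eccentricity from the white point is saturation.

All conversions are vectorised: functions accept arrays whose last axis holds
the channel triple (RGB or LMS) or coordinate pair, and preserve leading axes.
Angles are degrees in [0, 360) externally; an achromatic point (saturation 0)
has hue NaN (sentinel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "CalibrationMatrix",
    "DiagramConfig",
    "rgb_to_lms",
    "lms_to_mb",
    "mb_to_scaled",
    "scaled_to_mb",
    "hue_saturation",
    "load_diagram_configs",
]

# Maximum condition number accepted for a calibration matrix: beyond this the
# inverse mapping back to camera RGB (used to render synthetic scenes) is
# numerically meaningless.
_MAX_CONDITION = 1e12


@dataclass(frozen=True)
class CalibrationMatrix:
    """3x3 linear map from camera RGB to LMS cone excitations.

    Parameters
    ----------
    m : (3, 3) array_like
        The RGB -> LMS matrix.  Must be finite and invertible so that
        synthetic chromaticities can be rendered back to RAW-like RGB.
    tag : str
        Free-form label recording provenance (device, cone fundamentals).
    """

    m: np.ndarray
    tag: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"calibration matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("calibration matrix has non-finite entries")
        if np.linalg.cond(m) > _MAX_CONDITION:
            raise ValueError("calibration matrix is singular or near-singular")
        object.__setattr__(self, "m", m)

    @property
    def inverse(self) -> np.ndarray:
        """LMS -> camera RGB matrix."""
        return np.linalg.inv(self.m)

    @classmethod
    def identity(cls, tag: str = "identity") -> "CalibrationMatrix":
        return cls(np.eye(3), tag=tag)

    def to_dict(self) -> dict:
        return {"m": self.m.tolist(), "tag": self.tag}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationMatrix":
        return cls(np.asarray(d["m"], dtype=float), tag=d.get("tag", ""))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationMatrix":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class DiagramConfig:
    """White point, per-axis scalings and provenance of a chromaticity diagram.

    Two diagram conventions coexist in practice: a discrimination space
    centred on equal-energy white, and a stimulus (Mondrian) space centred on
    Illuminant C with contrast-equating axis scalings.  Both are instances of
    this one class; the calibration matrix absorbs the choice of cone
    fundamentals, recorded in ``cone_fundamental_tag``.
    """

    white_point: tuple[float, float]  # (l, s) in MB coordinates
    axis_scale_x: float = 1.0
    axis_scale_y: float = 1.0
    cone_fundamental_tag: str = ""

    def __post_init__(self) -> None:
        if not (self.axis_scale_x > 0 and self.axis_scale_y > 0):
            raise ValueError("axis scales must be positive")
        wl, ws = self.white_point
        if not (np.isfinite(wl) and np.isfinite(ws)):
            raise ValueError("white point must be finite")

    def to_dict(self) -> dict:
        return {
            "white_point": list(self.white_point),
            "axis_scale_x": self.axis_scale_x,
            "axis_scale_y": self.axis_scale_y,
            "cone_fundamental_tag": self.cone_fundamental_tag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiagramConfig":
        return cls(
            white_point=tuple(d["white_point"]),
            axis_scale_x=d.get("axis_scale_x", 1.0),
            axis_scale_y=d.get("axis_scale_y", 1.0),
            cone_fundamental_tag=d.get("cone_fundamental_tag", ""),
        )


def rgb_to_lms(rgb: np.ndarray, cal: CalibrationMatrix) -> np.ndarray:
    """Map linear camera RGB to LMS cone excitations.

    ``rgb`` has shape (..., 3); the result has the same shape.  The map is
    linear: ``lms = cal.m @ rgb`` applied along the last axis.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("rgb must have 3 channels on the last axis")
    if not np.all(np.isfinite(rgb)):
        raise ValueError("rgb contains non-finite values")
    if np.any(rgb < 0):
        raise ValueError("rgb contains negative values")
    return rgb @ cal.m.T


def lms_to_mb(lms: np.ndarray) -> np.ndarray:
    """LMS -> MacLeod-Boynton chromaticity (l, s) = (L/(L+M), S/(L+M)).

    Invariant under uniform scaling of (L, M, S).  Points with L+M <= 0 have
    no defined chromaticity; they are returned as NaN rows (flagged, never
    silently dropped) so that callers can count them.
    """
    lms = np.asarray(lms, dtype=float)
    if lms.shape[-1] != 3:
        raise ValueError("lms must have 3 channels on the last axis")
    lum = lms[..., 0] + lms[..., 1]
    valid = lum > 0
    out = np.full(lms.shape[:-1] + (2,), np.nan)
    safe = np.where(valid, lum, 1.0)
    out[..., 0] = np.where(valid, lms[..., 0] / safe, np.nan)
    out[..., 1] = np.where(valid, lms[..., 2] / safe, np.nan)
    return out


def mb_to_scaled(mb: np.ndarray, cfg: DiagramConfig) -> np.ndarray:
    """MB chromaticity -> white-point-relative scaled coordinates (x, y).

    ``x = axis_scale_x * (l - white.l)``; ``y = axis_scale_y * (s - white.s)``.
    """
    mb = np.asarray(mb, dtype=float)
    wl, ws = cfg.white_point
    out = np.empty_like(mb)
    out[..., 0] = cfg.axis_scale_x * (mb[..., 0] - wl)
    out[..., 1] = cfg.axis_scale_y * (mb[..., 1] - ws)
    return out


def scaled_to_mb(xy: np.ndarray, cfg: DiagramConfig) -> np.ndarray:
    """Inverse of :func:`mb_to_scaled`."""
    xy = np.asarray(xy, dtype=float)
    wl, ws = cfg.white_point
    out = np.empty_like(xy)
    out[..., 0] = xy[..., 0] / cfg.axis_scale_x + wl
    out[..., 1] = xy[..., 1] / cfg.axis_scale_y + ws
    return out


def hue_saturation(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polar decomposition of scaled chromaticity: (hue degrees, saturation).

    Hue is atan2(y, x) mapped to [0, 360); saturation is the eccentricity
    sqrt(x^2 + y^2) from the white point.  Achromatic points (saturation
    exactly 0) get hue NaN.
    """
    xy = np.asarray(xy, dtype=float)
    x, y = xy[..., 0], xy[..., 1]
    sat = np.hypot(x, y)
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    ang = np.where(sat == 0, np.nan, ang)
    return ang, sat


def load_diagram_configs(path: str | Path | None = None) -> dict[str, DiagramConfig]:
    """Load named diagram configurations (plus calibration defaults) from JSON.

    With no path, loads the packaged defaults: ``discrimination`` (equal-energy
    white) and ``mondrian`` (Illuminant C, contrast-equating scalings).
    """
    if path is None:
        text = (
            resources.files("chromadiet").joinpath("data/default_diagram.json").read_text()
        )
        raw = json.loads(text)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    return {name: DiagramConfig.from_dict(d) for name, d in raw["diagrams"].items()}
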