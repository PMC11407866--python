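"""Synthetic inputs with the statistical structure the analysis assumes.

Real head-camera acquisitions cannot be redistributed, so every pipeline
stage is exercised on generated data with known ground truth:

* **scenes** — per-image clouds of MacLeod-Boynton chromaticities drawn from
  a bivariate normal with a planted 2x2 covariance, rendered back to
  RAW-like 14-bit RGB through the inverse calibration at random in-range
  intensities, with controllable fractions of injected under-/over-exposed
  pixels to exercise the RAW-value filters.  The analysis consumes only
  second moments and wedge means, both analytic under normality, so planted
  parameters have closed-form recovered values.
* **observers** — a ground-truth discrimination ellipse plus psychometric
  slope and lapse, converted to the per-axis generative thresholds of
  :class:`~chromadiet.psychophysics.Observer`.
* **preference populations** — repeated noisy best-choice ranking sessions
  around a planted strength curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chromaticity import CalibrationMatrix
from .psychophysics import HueAxisSet, Observer, ellipse_radius
from .preference import simulate_ranking_session
from .scene_stats import RAW_MAX

__all__ = [
    "SceneGroundTruth",
    "ObserverGroundTruth",
    "UnrenderableError",
    "default_scene_calibration",
    "gen_scene_chromaticities",
    "render_to_raw",
    "gen_scene_image",
    "ellipse_form",
    "gen_observer",
    "random_observer_ground_truth",
    "gen_preference_population",
]


class UnrenderableError(ValueError):
    """Raised when a planted chromaticity cloud cannot be rendered in-range."""


@dataclass(frozen=True)
class SceneGroundTruth:
    """Planted parameters of one synthetic scene image."""

    mean: tuple[float, float] = (0.66, 1.0)  # (l, s), s in arbitrary MB-like units
    cov: tuple[tuple[float, float], tuple[float, float]] = (
        (4e-4, 0.0),
        (0.0, 4e-4),
    )
    dark_fraction: float = 0.0
    saturated_fraction: float = 0.0
    site: str = "synthetic"

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        if not np.allclose(c, c.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(c) < -1e-15):
            raise ValueError("covariance must be positive semidefinite")
        if not (0 <= self.dark_fraction < 1 and 0 <= self.saturated_fraction < 1):
            raise ValueError("injected fractions must lie in [0, 1)")
        if self.dark_fraction + self.saturated_fraction >= 1:
            raise ValueError("injected fractions must sum below 1")


def default_scene_calibration() -> CalibrationMatrix:
    """A well-conditioned RGB->LMS matrix used for synthetic scenes.

    Chosen so that chromaticities near the default scene mean map back to
    comfortably in-range RAW values; it stands in for a measured camera
    calibration, which is an input in real use.
    """
    m = np.array(
        [
            [0.90, 0.08, 0.02],
            [0.08, 0.90, 0.02],
            [0.02, 0.08, 0.90],
        ]
    )
    return CalibrationMatrix(m, tag="synthetic-default")


def gen_scene_chromaticities(
    gt: SceneGroundTruth, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n (l, s) points from the planted bivariate normal."""
    return rng.multivariate_normal(np.asarray(gt.mean), np.asarray(gt.cov), size=n)


def render_to_raw(
    points: np.ndarray,
    cal: CalibrationMatrix,
    rng: np.random.Generator,
    intensity_range: tuple[float, float] = (500.0, 8000.0),
    low: int = 15,
    high: int = 15000,
    quantize: bool = True,
) -> np.ndarray:
    """Render (l, s) chromaticities to RAW-like RGB rows via the inverse
    calibration at random in-range luminances L+M.

    With ``quantize`` the values are rounded to the 14-bit integer grid (the
    physical sensor behaviour, which limits chromaticity round-trip accuracy);
    without it the exact float values are returned.  Raises
    :class:`UnrenderableError` if any rendered value falls outside the kept
    range [low, high], reporting the extent of the excursion.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lum = rng.uniform(*intensity_range, size=pts.shape[0])
    L = pts[:, 0] * lum
    M = (1.0 - pts[:, 0]) * lum
    S = pts[:, 1] * lum
    rgb = np.stack([L, M, S], axis=1) @ cal.inverse.T
    if rgb.min() < low or rgb.max() > high:
        raise UnrenderableError(
            f"rendered RGB spans [{rgb.min():.1f}, {rgb.max():.1f}] outside "
            f"[{low}, {high}]; shrink the covariance or the intensity range"
        )
    if quantize:
        rgb = np.clip(np.rint(rgb), 0, RAW_MAX).astype(np.uint16)
    return rgb


def gen_scene_image(
    gt: SceneGroundTruth,
    shape: tuple[int, int],
    cal: CalibrationMatrix,
    rng: np.random.Generator,
    intensity_range: tuple[float, float] = (500.0, 8000.0),
    low: int = 15,
    high: int = 15000,
    quantize: bool = True,
) -> np.ndarray:
    """Synthesise one RAW-like (H, W, 3) image from planted ground truth.

    The stated fractions of pixels are overwritten with under-exposed
    (some channel < low) and over-exposed (some channel > high) values so the
    RAW filters have work to do; the remaining pixels carry the planted
    chromaticity distribution.
    """
    H, W = shape
    n = H * W
    pts = gen_scene_chromaticities(gt, n, rng)
    rgb = render_to_raw(
        pts, cal, rng, intensity_range=intensity_range, low=low, high=high,
        quantize=quantize,
    ).astype(float)
    n_dark = int(round(gt.dark_fraction * n))
    n_sat = int(round(gt.saturated_fraction * n))
    if n_dark + n_sat:
        idx = rng.choice(n, size=n_dark + n_sat, replace=False)
        dark_idx, sat_idx = idx[:n_dark], idx[n_dark:]
        rgb[dark_idx, 0] = rng.integers(0, low, size=n_dark)  # one channel too dark
        rgb[sat_idx, 0] = rng.integers(high + 1, RAW_MAX + 1, size=n_sat)
    img = rgb.reshape(H, W, 3)
    return img.astype(np.uint16) if quantize else img


def ellipse_form(major: float, minor: float, orientation_deg: float) -> np.ndarray:
    """Positive-definite form A with radii (major, minor) at an orientation."""
    if not (major >= minor > 0):
        raise ValueError("need major >= minor > 0")
    rad = math.radians(orientation_deg)
    R = np.array([[math.cos(rad), -math.sin(rad)], [math.sin(rad), math.cos(rad)]])
    D = np.diag([1.0 / major**2, 1.0 / minor**2])
    return R @ D @ R.T


@dataclass(frozen=True)
class ObserverGroundTruth:
    """Planted discrimination model behind one simulated participant."""

    form: np.ndarray  # (2, 2) positive definite; x^T form x = 1 is the ellipse
    slope: float = 3.5
    lapse: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.form, dtype=float)
        if f.shape != (2, 2) or not np.allclose(f, f.T):
            raise ValueError("form must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(f) <= 0):
            raise ValueError("form must be positive definite")
        object.__setattr__(self, "form", f)


def gen_observer(
    gt: ObserverGroundTruth, axes: HueAxisSet = HueAxisSet(), guess: float = 0.25
) -> Observer:
    """Observer whose per-axis threshold is the ground-truth ellipse radius
    along that axis direction."""
    thr = [ellipse_radius(gt.form, a) for a in axes.angles_deg]
    return Observer(
        thresholds=tuple(thr), slope=gt.slope, guess_rate=guess, lapse_rate=gt.lapse
    )


def random_observer_ground_truth(
    rng: np.random.Generator,
    mean_radius: float = 0.08,
    radius_sigma: float = 0.2,
    max_axis_ratio: float = 2.5,
    slope: float = 3.5,
    lapse_max: float = 0.05,
) -> ObserverGroundTruth:
    """Draw a plausible participant: log-normal overall sensitivity, axis
    ratio uniform on [1, max], orientation uniform, small uniform lapse."""
    g = mean_radius * math.exp(radius_sigma * rng.standard_normal())
    ratio = rng.uniform(1.0, max_axis_ratio)
    major, minor = g * math.sqrt(ratio), g / math.sqrt(ratio)
    ori = rng.uniform(0.0, 180.0)
    return ObserverGroundTruth(
        form=ellipse_form(major, minor, ori),
        slope=slope,
        lapse=float(rng.uniform(0.0, lapse_max)),
    )


def gen_preference_population(
    curve: np.ndarray,
    noise_sd: float,
    n_participants: int,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rank array (participants, trials, stimuli) from a planted strength curve."""
    curve = np.asarray(curve, dtype=float)
    out = np.empty((n_participants, n_trials, curve.size), dtype=int)
    for p in range(n_participants):
        for t in range(n_trials):
            out[p, t] = simulate_ranking_session(curve, noise_sd, rng)
    return out
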