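"""Per-image chromatic statistics of a visual diet.

Pipeline for a single RAW-style image: exclude unreliable pixels (too dark
for a trustworthy chromaticity estimate, or close to sensor saturation),
convert the kept pixels to MacLeod-Boynton chromaticities, then summarise the
resulting point cloud:

* the **s.d. ellipse** — centre at the cloud mean, axes along the covariance
  eigenvectors, radii the square roots of the eigenvalues;
* the **log axis ratio** — after normalising the variance along each cardinal
  axis to 1, the natural log of the cloud's s.d. along the negative diagonal
  over its s.d. along the positive diagonal.  Positive values mean the cloud
  is elongated along the (roughly blue-yellow) negative diagonal;
* **wedge mean saturations** — the mean eccentricity from the white point of
  pixels falling in each of 8 opponent pairs of 22.5 degree hue wedges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chromaticity import CalibrationMatrix, hue_saturation, lms_to_mb, rgb_to_lms

__all__ = [
    "RAW_MAX",
    "ChromaticityCloud",
    "SDEllipse",
    "AxisRatioResult",
    "EmptyCloudError",
    "ZeroVarianceError",
    "subsample_every_kth",
    "valid_pixel_mask",
    "image_chromaticity_cloud",
    "fit_sd_ellipse",
    "normalize_cardinal_variances",
    "pooled_cardinal_scales",
    "log_axis_ratio",
    "wedge_mean_saturations",
]

RAW_MAX = 16383  # 14-bit sensor scale

# Unit directions of the diagonals of the chromaticity diagram.  The negative
# diagonal (x up, y down) is the roughly blue-yellow direction.
_NEG_DIAG = np.array([1.0, -1.0]) / np.sqrt(2.0)
_POS_DIAG = np.array([1.0, 1.0]) / np.sqrt(2.0)


class EmptyCloudError(ValueError):
    """Raised when every pixel of an image was excluded."""


class ZeroVarianceError(ValueError):
    """Raised when a cloud has no variance along a required axis."""


@dataclass
class ChromaticityCloud:
    """Chromaticities of the kept pixels of one image, with filter bookkeeping."""

    points: np.ndarray  # (N, 2) -- (l, s) or scaled (x, y)
    n_excluded_dark: int = 0
    n_excluded_saturated: int = 0
    n_invalid: int = 0  # kept by the RAW filter but L+M <= 0
    source: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[-1] != 2:
            raise ValueError("cloud points must be (N, 2)")
        if min(self.n_excluded_dark, self.n_excluded_saturated, self.n_invalid) < 0:
            raise ValueError("exclusion counts must be nonnegative")
        if np.isnan(self.points).any():
            raise ValueError("cloud points must all be valid (no NaN)")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class SDEllipse:
    """1-s.d. ellipse of a 2-D distribution (or of 8 discrimination thresholds)."""

    centre: tuple[float, float]
    radii: tuple[float, float]  # (major, minor), sqrt of covariance eigenvalues
    orientation_deg: float  # major-axis angle in [0, 180)
    degenerate: bool = False

    def __post_init__(self) -> None:
        major, minor = self.radii
        if minor > major:
            raise ValueError("major radius must be >= minor radius")


@dataclass(frozen=True)
class AxisRatioResult:
    """Blue-yellow bias summary of a normalised cloud or ellipse."""

    log_axis_ratio: float  # ln(neg_diag_radius / pos_diag_radius)
    neg_diag_radius: float
    pos_diag_radius: float


def subsample_every_kth(n_items: int, k: int) -> np.ndarray:
    """Indices of every k-th item: k-1, 2k-1, ... (floor(n/k) of them).

    This is the rule that keeps exactly ``floor(n/k)`` items: the last image
    of each block of k, so a sequence shorter than k yields nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_items < 0:
        raise ValueError("n_items must be >= 0")
    return np.arange(k - 1, n_items, k)


def valid_pixel_mask(
    img: np.ndarray, low: int = 15, high: int = 15000
) -> tuple[np.ndarray, int, int]:
    """Boolean keep-mask for a RAW image plus per-reason exclusion counts.

    A pixel is excluded when *any* channel is strictly below ``low`` (too dark:
    chromaticity dominated by sensor noise) or strictly above ``high``
    (approaching sensor saturation: chromaticity clipped by the camera gamut).
    Values equal to the thresholds are kept.  A pixel failing both tests is
    counted once, as dark.

    Returns ``(mask, n_dark, n_saturated)`` where ``mask`` has shape (H, W).
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("image must be (H, W, 3)")
    if not (0 <= low <= RAW_MAX and 0 <= high <= RAW_MAX):
        raise ValueError("thresholds must lie within the 14-bit range")
    dark = (img < low).any(axis=-1)
    saturated = (img > high).any(axis=-1) & ~dark
    mask = ~dark & ~saturated
    return mask, int(dark.sum()), int(saturated.sum())


def image_chromaticity_cloud(
    img: np.ndarray,
    cal: CalibrationMatrix,
    low: int = 15,
    high: int = 15000,
    source: str = "",
) -> ChromaticityCloud:
    """Convert the kept pixels of a RAW image to an MB chromaticity cloud.

    Pixels surviving the RAW-value filter are mapped through the calibration
    to LMS and then to (l, s).  Pixels whose L+M is non-positive after
    calibration are counted in ``n_invalid``.  Raises
    :class:`EmptyCloudError` when nothing survives.
    """
    mask, n_dark, n_sat = valid_pixel_mask(img, low=low, high=high)
    kept_rgb = np.asarray(img, dtype=float)[mask]
    if kept_rgb.size == 0:
        raise EmptyCloudError(
            f"all {mask.size} pixels excluded (dark={n_dark}, saturated={n_sat})"
        )
    mb = lms_to_mb(rgb_to_lms(kept_rgb, cal))
    invalid = np.isnan(mb[:, 0])
    n_invalid = int(invalid.sum())
    points = mb[~invalid]
    if points.shape[0] == 0:
        raise EmptyCloudError("no pixel has positive L+M after calibration")
    return ChromaticityCloud(
        points=points,
        n_excluded_dark=n_dark,
        n_excluded_saturated=n_sat,
        n_invalid=n_invalid,
        source=source,
    )


def _as_points(cloud: ChromaticityCloud | np.ndarray) -> np.ndarray:
    if isinstance(cloud, ChromaticityCloud):
        return cloud.points
    return np.atleast_2d(np.asarray(cloud, dtype=float))


def fit_sd_ellipse(
    cloud: ChromaticityCloud | np.ndarray, degenerate_tol: float = 1e-12
) -> SDEllipse:
    """Fit the 1-s.d. ellipse: covariance eigendecomposition of the cloud.

    Centre is the mean; radii are the square roots of the covariance
    eigenvalues (major first); orientation is the major eigenvector's angle in
    [0, 180).  A collinear cloud yields minor radius 0 and ``degenerate=True``.
    """
    pts = _as_points(cloud)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points to fit an s.d. ellipse")
    centre = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.clip(evals, 0.0, None)
    major, minor = np.sqrt(evals[1]), np.sqrt(evals[0])
    vec = evecs[:, 1]
    orientation = np.degrees(np.arctan2(vec[1], vec[0])) % 180.0
    degenerate = minor <= degenerate_tol * max(major, 1.0)
    return SDEllipse(
        centre=(float(centre[0]), float(centre[1])),
        radii=(float(major), float(minor)),
        orientation_deg=float(orientation),
        degenerate=bool(degenerate),
    )


def _cardinal_sds(pts: np.ndarray) -> np.ndarray:
    sds = pts.std(axis=0, ddof=1)
    if np.any(sds <= 0) or not np.all(np.isfinite(sds)):
        raise ZeroVarianceError("cloud has zero variance along a cardinal axis")
    return sds


def normalize_cardinal_variances(
    cloud: ChromaticityCloud | np.ndarray, scales: np.ndarray | None = None
) -> np.ndarray:
    """Rescale each cardinal axis so the sample variance is 1 (about the mean).

    ``scales`` may supply externally computed per-axis s.d.s (e.g. pooled over
    a whole location, see :func:`pooled_cardinal_scales`); by default the
    cloud's own s.d.s are used, which is the per-image convention.
    """
    pts = _as_points(cloud)
    mean = pts.mean(axis=0)
    sds = _cardinal_sds(pts) if scales is None else np.asarray(scales, dtype=float)
    if np.any(sds <= 0):
        raise ZeroVarianceError("normalization scales must be positive")
    return mean + (pts - mean) / sds


def pooled_cardinal_scales(clouds: list[ChromaticityCloud | np.ndarray]) -> np.ndarray:
    """Per-axis s.d.s pooled over several clouds (for pooled normalization)."""
    allpts = np.vstack([_as_points(c) for c in clouds])
    return _cardinal_sds(allpts)


def log_axis_ratio(cloud_normalized: ChromaticityCloud | np.ndarray) -> AxisRatioResult:
    """Blue-yellow bias of a (cardinal-variance-normalised) cloud.

    The two diagonal radii are the s.d.s of the centred cloud projected onto
    the -45 and +45 degree unit directions; the statistic is their natural
    log ratio (negative over positive).  For a Gaussian cloud with unit
    cardinal variances and correlation c this equals 0.5*ln((1-c)/(1+c)).
    """
    pts = _as_points(cloud_normalized)
    centred = pts - pts.mean(axis=0)
    neg = (centred @ _NEG_DIAG).std(ddof=1)
    pos = (centred @ _POS_DIAG).std(ddof=1)
    if neg <= 0 or pos <= 0:
        raise ZeroVarianceError("zero projected s.d. along a diagonal")
    return AxisRatioResult(
        log_axis_ratio=float(np.log(neg / pos)),
        neg_diag_radius=float(neg),
        pos_diag_radius=float(pos),
    )


def wedge_mean_saturations(
    cloud_scaled: ChromaticityCloud | np.ndarray,
    n_axis_pairs: int = 8,
    wedge_halfwidth_deg: float = 11.25,
) -> np.ndarray:
    """Mean saturation in each opponent pair of hue wedges.

    Axis k (1-based) has poles at ``(k-1) * 180/n_axis_pairs`` degrees and 180
    degrees opposite.  A chromatic pixel belongs to axis k when its hue lies
    within [pole - halfwidth, pole + halfwidth) of either pole (half-open on
    the upper edge so adjacent wedges tile the circle exactly).  Achromatic
    pixels (saturation 0) belong to no wedge.  An axis with no pixels yields
    NaN with a warning rather than 0, so location means are not biased.

    Input points are *scaled-diagram* coordinates (white point at the origin).
    """
    step = 180.0 / n_axis_pairs
    if not np.isclose(wedge_halfwidth_deg, step / 2):
        raise ValueError("wedges must tile the circle: halfwidth = 90/n_axis_pairs")
    pts = _as_points(cloud_scaled)
    hue, sat = hue_saturation(pts)
    chromatic = sat > 0
    # Fold opponent poles together and bin: axis index 0..n-1.
    idx = np.floor(((hue[chromatic] + wedge_halfwidth_deg) % 180.0) / step).astype(int)
    means = np.full(n_axis_pairs, np.nan)
    satc = sat[chromatic]
    for k in range(n_axis_pairs):
        sel = idx == k
        if sel.any():
            means[k] = satc[sel].mean()
    if np.isnan(means).any():
        empty = [k + 1 for k in range(n_axis_pairs) if np.isnan(means[k])]
        warnings.warn(f"empty wedge pair(s) for axis {empty}; mean set to NaN")
    return means
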