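"""End-to-end orchestration of the two analysis pathways.

``run_scene_pipeline`` takes a directory (or in-memory list) of RAW-style
images per site and produces a per-image statistics table (filter counts,
s.d.-ellipse parameters, log axis ratio, 8 wedge mean saturations) plus a
per-site summary with means and 95% confidence intervals.

``run_experiment_pipeline`` takes simulated observers (or a trial-log table)
and produces per-observer 45% thresholds, discrimination-ellipse log axis
ratios and the CVD threshold-ratio screen, with unfittable axes flagged and
observers excluded when no ellipse can be fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chromaticity import CalibrationMatrix, DiagramConfig, mb_to_scaled
from .mondrian import MondrianParams
from .psychophysics import (
    HueAxisSet,
    Observer,
    StaircaseParams,
    cvd_threshold_ratio,
    discrimination_log_axis_ratio,
    fit_psychometric,
    run_session,
    tukey_outliers,
)
from .scene_stats import (
    EmptyCloudError,
    fit_sd_ellipse,
    image_chromaticity_cloud,
    log_axis_ratio,
    normalize_cardinal_variances,
    pooled_cardinal_scales,
    subsample_every_kth,
    wedge_mean_saturations,
)

__all__ = ["StudyConfig", "run_scene_pipeline", "run_experiment_pipeline", "mean_ci"]


@dataclass
class StudyConfig:
    """Resolved configuration of one analysis run; always emitted verbatim
    alongside outputs so every run is auditable."""

    filter_low: int = 15
    filter_high: int = 15000
    subsample_k: int = 5
    normalize: str = "per-image"  # or "pooled" (per site)
    discrimination_diagram: DiagramConfig = field(
        default_factory=lambda: DiagramConfig(white_point=(0.699, 0.0233))
    )
    mondrian_diagram: DiagramConfig = field(
        default_factory=lambda: DiagramConfig(white_point=(0.657, 0.0184))
    )
    staircase: StaircaseParams = field(default_factory=StaircaseParams)
    mondrian: MondrianParams = field(default_factory=MondrianParams)
    n_permutations: int = 10000
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["discrimination_diagram"] = self.discrimination_diagram.to_dict()
        d["mondrian_diagram"] = self.mondrian_diagram.to_dict()
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        d = json.loads(Path(path).read_text())
        d["discrimination_diagram"] = DiagramConfig.from_dict(d["discrimination_diagram"])
        d["mondrian_diagram"] = DiagramConfig.from_dict(d["mondrian_diagram"])
        d["staircase"] = StaircaseParams(**d["staircase"])
        d["mondrian"] = MondrianParams(**d["mondrian"])
        return cls(**d)


def mean_ci(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """Mean and t-based (1-alpha) confidence interval, NaN-aware."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    m = float(v.mean())
    if v.size < 2:
        return m, np.nan, np.nan
    half = sps.t.ppf(1 - alpha / 2, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return m, m - float(half), m + float(half)


def _load_site_images(image_dir: Path) -> dict[str, list[Path]]:
    """Site subdirectories of TIFFs; a flat directory becomes one site."""
    import tifffile  # local import: only needed for on-disk runs

    image_dir = Path(image_dir)
    subdirs = [d for d in sorted(image_dir.iterdir()) if d.is_dir()]
    if not subdirs:
        subdirs = [image_dir]
    out = {}
    for d in subdirs:
        files = sorted(p for p in d.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if files:
            out[d.name] = files
    if not out:
        raise FileNotFoundError(f"no TIFF images under {image_dir}")
    return out


def run_scene_pipeline(
    images: Path | dict[str, list[np.ndarray]],
    cal: CalibrationMatrix,
    cfg: StudyConfig = StudyConfig(),
    subsample: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scene-statistics pathway over one or more sites.

    ``images`` is either a directory (site subdirectories of 16-bit TIFFs) or
    a mapping site -> list of (H, W, 3) arrays.  Per image: RAW filtering,
    chromaticity cloud, s.d. ellipse, normalised-diagram log axis ratio and
    wedge mean saturations (in the Mondrian-space scaled diagram).  Unreadable
    or fully excluded images are skipped and logged in the per-image table.

    Returns (per_image, per_site_summary).
    """
    import tifffile

    if isinstance(images, (str, Path)):
        site_files = _load_site_images(Path(images))
        site_items: dict[str, list] = {s: list(f) for s, f in site_files.items()}
        loader = lambda item: tifffile.imread(item)  # noqa: E731
        namer = lambda item: Path(item).name  # noqa: E731
    else:
        site_items = {s: list(arrs) for s, arrs in images.items()}
        loader = lambda item: item  # noqa: E731
        namer = lambda item: ""  # noqa: E731

    rows = []
    clouds_by_site: dict[str, list] = {}
    for site, items in site_items.items():
        if subsample:
            keep = subsample_every_kth(len(items), cfg.subsample_k)
            items = [items[i] for i in keep]
        for j, item in enumerate(items):
            row = {"site": site, "image": namer(item) or f"{site}_{j:05d}", "skipped": ""}
            try:
                img = loader(item)
                cloud = image_chromaticity_cloud(
                    img, cal, low=cfg.filter_low, high=cfg.filter_high,
                    source=row["image"],
                )
            except (EmptyCloudError, ValueError, OSError) as e:
                row["skipped"] = str(e)
                rows.append(row)
                continue
            ell = fit_sd_ellipse(cloud)
            row.update(
                n_kept=cloud.n,
                n_dark=cloud.n_excluded_dark,
                n_saturated=cloud.n_excluded_saturated,
                n_invalid=cloud.n_invalid,
                centre_l=ell.centre[0],
                centre_s=ell.centre[1],
                radius_major=ell.radii[0],
                radius_minor=ell.radii[1],
                orientation_deg=ell.orientation_deg,
            )
            clouds_by_site.setdefault(site, []).append((row, cloud))
            rows.append(row)

    # log axis ratio: per-image normalisation by default, pooled per site optional
    for site, entries in clouds_by_site.items():
        scales = (
            pooled_cardinal_scales([c for _, c in entries])
            if cfg.normalize == "pooled"
            else None
        )
        for row, cloud in entries:
            norm = normalize_cardinal_variances(cloud, scales=scales)
            row["log_axis_ratio"] = log_axis_ratio(norm).log_axis_ratio
            scaled = mb_to_scaled(cloud.points, cfg.mondrian_diagram)
            wedges = wedge_mean_saturations(scaled)
            for k in range(wedges.size):
                row[f"wedge_{k + 1}"] = wedges[k]

    per_image = pd.DataFrame(rows)
    summaries = []
    ok = per_image[per_image["skipped"] == ""] if len(per_image) else per_image
    for site, grp in ok.groupby("site", sort=True):
        s = {"site": site, "n_images": len(grp)}
        m, lo, hi = mean_ci(grp["log_axis_ratio"].to_numpy())
        s.update(log_axis_ratio_mean=m, log_axis_ratio_lo=lo, log_axis_ratio_hi=hi)
        for k in range(1, 9):
            m, lo, hi = mean_ci(grp[f"wedge_{k}"].to_numpy())
            s[f"wedge_{k}_mean"], s[f"wedge_{k}_lo"], s[f"wedge_{k}_hi"] = m, lo, hi
        summaries.append(s)
    return per_image, pd.DataFrame(summaries)


def run_experiment_pipeline(
    observers: list[Observer],
    cfg: StudyConfig = StudyConfig(),
    axes: HueAxisSet = HueAxisSet(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Discrimination pathway: staircase sessions, psychometric fits, ellipse
    log axis ratios and the CVD threshold-ratio screen, one row per observer.

    An observer whose cardinal or diagonal structure cannot be fit (too few
    fittable axes) is retained as an excluded row with a reason, mirroring
    participant-level exclusion when psychometric functions cannot be fit.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    rows = []
    for i, obs in enumerate(observers):
        log = run_session(obs, axes, cfg.staircase, rng)
        row: dict = {"observer": i, "n_trials": len(log), "excluded": "", }
        thresholds = np.full(axes.n, np.nan)
        for a in range(axes.n):
            tr = [t for t in log if t.axis == a]
            fit = fit_psychometric(
                np.array([t.saturation for t in tr]),
                np.array([t.correct for t in tr]),
            )
            if fit.fittable:
                thresholds[a] = fit.threshold
            row[f"threshold_{a + 1}"] = thresholds[a]
            row[f"fittable_{a + 1}"] = fit.fittable
        try:
            lar = discrimination_log_axis_ratio(thresholds, axes)
            row["log_axis_ratio"] = lar.log_axis_ratio
        except ValueError as e:
            row["log_axis_ratio"] = np.nan
            row["excluded"] = f"psychometric/ellipse fit failed: {e}"
        try:
            row["cvd_ratio"] = cvd_threshold_ratio(thresholds, axes)
        except ValueError:
            row["cvd_ratio"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    ratios = df["cvd_ratio"].to_numpy()
    if np.isfinite(ratios).sum() >= 4:
        df["cvd_outlier"] = tukey_outliers(ratios)
    else:
        df["cvd_outlier"] = False
    return df
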