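"""Study-level constants of the visual-diet acquisition design.

Head-mounted timelapse cameras (one frame / 30 s) were worn at three sites;
the analysis keeps every fifth frame (one point of view / 2.5 min) and
filters RAW pixel values outside [15, 15000] on the 14-bit sensor scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scene_stats import subsample_every_kth

__all__ = ["Site", "SITES", "SUBSAMPLE_K", "FILTER_LOW", "FILTER_HIGH", "total_images_acquired"]

SUBSAMPLE_K = 5
FILTER_LOW = 15
FILTER_HIGH = 15000


@dataclass(frozen=True)
class Site:
    name: str
    n_images_acquired: int

    @property
    def n_subsampled(self) -> int:
        """Number of images retained by the every-fifth-frame rule."""
        return int(subsample_every_kth(self.n_images_acquired, SUBSAMPLE_K).size)


SITES: dict[str, Site] = {
    "esmeraldas": Site("esmeraldas", 4690),
    "quito": Site("quito", 8250),
    "sussex": Site("sussex", 5391),
}


def total_images_acquired() -> int:
    return sum(s.n_images_acquired for s in SITES.values())
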