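"""24-sector polar partition of the papilla and per-sector Hb aggregation.

The disc is split into eight 45° radial wedges crossed with three
concentric rings whose boundaries sit at 1/3 and 2/3 of the local disc
radius, giving 24 sectors plus the overall mean.  Rings are scaled copies
of the fitted ellipse (normalized elliptical radius ρ), so oblique discs
keep the exact 1/9 : 3/9 : 5/9 area split; wedges are measured in the same
normalized coordinates.

Numbering convention (documented, testable, and applied consistently by
both the generator and the analysis):

* sector index = 3·(wedge − 1) + ring, with ring 1 = inner (ρ ≤ 1/3),
  2 = middle, 3 = outer — so the outer ring is exactly the indices
  divisible by 3: {3, 6, 9, 12, 15, 18, 21, 24};
* wedge 1 starts at the horizontal meridian on the temporal side and
  wedges advance clockwise in image coordinates for right eyes,
  counterclockwise for left eyes (mirror symmetry, as with clock-hour
  conventions), so a given index is anatomically comparable across eyes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from onhcolor.exceptions import ConsistencyError
from onhcolor.hb import HbMap
from onhcolor.segmentation import DiscGeometry

__all__ = [
    "N_SECTORS",
    "OUTER_RING_SECTORS",
    "SectorMap",
    "SectorProfile",
    "sector_labels",
    "build_sector_map",
    "aggregate_sectors",
    "mirror_profile",
    "mirror_permutation",
]

N_SECTORS = 24
N_WEDGES = 8
RING_BOUNDS = (1.0 / 3.0, 2.0 / 3.0)
OUTER_RING_SECTORS = tuple(range(3, N_SECTORS + 1, 3))

NUMBERING = "wedge-major/ring-minor, temporal start, eye-mirrored"


@dataclass(frozen=True)
class SectorMap:
    """Per-pixel sector labels: 0 outside the disc, 1..24 inside."""

    labels: np.ndarray
    geometry: DiscGeometry
    numbering: str = NUMBERING


@dataclass(frozen=True)
class SectorProfile:
    """Mean Hb plus the 24 per-sector Hb percentages for one subject.

    ``sector_hb[s-1]`` is the tissue-mean Hb of sector s; a sector with no
    tissue pixels carries NaN.  ``mean_hb`` is the mean over *all* tissue
    pixels, which equals the pixel-count-weighted mean of the sectors.
    """

    mean_hb: float
    sector_hb: np.ndarray          # shape (24,)
    sector_pixel_counts: np.ndarray  # shape (24,), tissue pixels per sector
    subject_id: str = ""
    eye: str = "right"

    def __post_init__(self) -> None:
        if self.sector_hb.shape != (N_SECTORS,) or self.sector_pixel_counts.shape != (N_SECTORS,):
            raise ConsistencyError("sector arrays must have length 24")


def sector_labels(
    disc: DiscGeometry,
    shape: tuple[int, int],
    clip: bool = True,
    margin: int = 0,
) -> np.ndarray:
    """Per-pixel sector labels over an (H, W) grid.

    With ``clip=True`` pixels outside the disc get label 0; with
    ``clip=False`` the outer ring extends ``margin`` pixels beyond the
    disc border (and pixels farther out get the placeholder label 1),
    which the synthetic generator uses to build a seamless Hb field up to
    and past the border.  Labels are only ever consumed inside the disc
    plus a small smoothing margin, so the computation is confined to that
    bounding box.
    """
    h, w = shape
    cx, cy = disc.center
    x0 = max(int(cx - disc.radius_x) - margin - 1, 0)
    x1 = min(int(cx + disc.radius_x) + margin + 2, w)
    y0 = max(int(cy - disc.radius_y) - margin - 1, 0)
    y1 = min(int(cy + disc.radius_y) + margin + 2, h)
    y, x = np.ogrid[y0:y1, x0:x1]
    dx = (x - cx) / disc.radius_x
    dy = (y - cy) / disc.radius_y
    rho = np.sqrt(dx * dx + dy * dy)
    # clockwise-from-+x angle in image coordinates (y grows downward)
    theta = np.degrees(np.arctan2(dy, dx))
    theta = np.mod(np.broadcast_to(theta, rho.shape), 360.0)
    if disc.eye == "left":
        theta = np.mod(360.0 - theta, 360.0)
    wedge = np.minimum((theta / 45.0).astype(np.int32), N_WEDGES - 1)  # 0..7
    ring = np.where(rho <= RING_BOUNDS[0], 0, np.where(rho <= RING_BOUNDS[1], 1, 2))
    box = (3 * wedge + ring + 1).astype(np.int32)
    if clip:
        box[rho > 1.0] = 0
        labels = np.zeros(shape, dtype=np.int32)
    else:
        labels = np.ones(shape, dtype=np.int32)
    labels[y0:y1, x0:x1] = box
    return labels


def build_sector_map(disc: DiscGeometry, shape: tuple[int, int]) -> SectorMap:
    """Label every disc-interior pixel with its sector index 1..24.

    Raises
    ------
    ConsistencyError
        If the disc ellipse is clipped by the image border.
    """
    if not disc.inside(shape):
        raise ConsistencyError("disc ellipse clipped by the image border")
    return SectorMap(labels=sector_labels(disc, shape, clip=True), geometry=disc)


def aggregate_sectors(hb: HbMap, smap: SectorMap) -> SectorProfile:
    """Tissue-mean Hb per sector and overall (vessel pixels excluded).

    The weighted-mean identity holds exactly up to floating error:
    ``mean_hb == Σ count_s · sector_hb_s / Σ count_s``.
    """
    if hb.values.shape != smap.labels.shape:
        raise ConsistencyError("Hb map and sector map are not congruent")
    tissue = hb.regions.tissue
    labels = smap.labels[tissue]
    vals = hb.values[tissue].astype(np.float64)
    counts = np.bincount(labels, minlength=N_SECTORS + 1)[1:]
    sums = np.bincount(labels, weights=vals, minlength=N_SECTORS + 1)[1:]
    with np.errstate(invalid="ignore"):
        sector_hb = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mean_hb = float(vals.mean()) if vals.size else float("nan")
    return SectorProfile(
        mean_hb=mean_hb,
        sector_hb=sector_hb,
        sector_pixel_counts=counts,
        subject_id="",  # filled by callers that know it
        eye=smap.geometry.eye,
    )


def mirror_permutation() -> np.ndarray:
    """0-based permutation mapping sector s to its horizontal mirror.

    Reflection across the horizontal meridian sends wedge w to 9−w and
    leaves the ring unchanged: sector 3(w−1)+r ↦ 3(8−w)+r.  Applying it
    twice is the identity.
    """
    perm = np.empty(N_SECTORS, dtype=np.int64)
    for w in range(1, N_WEDGES + 1):
        for r in (1, 2, 3):
            perm[3 * (w - 1) + r - 1] = 3 * (N_WEDGES - w) + r - 1
    return perm


def mirror_profile(p: SectorProfile) -> SectorProfile:
    """Re-index a left-eye profile to right-eye orientation (involution).

    Profiles produced through :func:`build_sector_map` are already
    eye-mirrored at the labeling stage and need no further conversion;
    this operation is for profiles computed with a fixed clockwise map
    (e.g. imported from elsewhere).  Right-eye profiles are returned
    unchanged.
    """
    if p.eye == "right":
        return p
    perm = mirror_permutation()
    return replace(
        p,
        sector_hb=p.sector_hb[perm],
        sector_pixel_counts=p.sector_pixel_counts[perm],
        eye="right",
    )
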