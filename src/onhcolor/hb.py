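"""Vessel-referenced hemoglobin estimation and pseudoimage rendering.

The Hb index of a pixel is its red–green contrast normalized by red,

    h = (r − g̃) / max(r, ε),        g̃ = lens-compensated green,

and the Hb percentage is the pixel's index relative to the central-vessel
reference, ``Hb% = 100 · h / h_vessel``, where ``h_vessel`` is computed
from the per-channel medians over vessel pixels.  Whole blood in the
vessels defines 100% by construction; an achromatic pixel (r = g̃) scores 0.
Because vessels and tissue sit in the same eye, under the same light and
behind the same lens, the reference cancels illumination intensity and
spectral drifts — the property that makes the measurement comparable
across cameras and subjects.

Lens (cataract) yellowing attenuates blue strongly and green about half as
much.  The attenuation factor κ is estimated from the vessels' blue/green
ratio against a clear-lens calibration constant, and the green channel is
rescaled accordingly before the index is formed.  Blue enters only this
compensation, never the Hb index itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from onhcolor.exceptions import VesselReferenceError
from onhcolor.segmentation import DiscRegions
from onhcolor.io import FundusImage

__all__ = [
    "HbConfig",
    "LensCompensation",
    "HbMap",
    "estimate_lens_compensation",
    "estimate_hb_map",
    "render_pseudoimage",
    "decode_pseudoimage",
    "save_pseudoimage",
]

logger = logging.getLogger(__name__)

HB_RANGE = (0.0, 120.0)


@dataclass(frozen=True)
class HbConfig:
    eps: float = 1e-3               # guards the division by red
    clear_lens_bg_ratio: float = 0.55  # vessel blue/green ratio behind a clear lens
    kappa_min: float = 0.05         # lower clamp for the estimated attenuation
    min_vessel_pixels: int = 50


@dataclass(frozen=True)
class LensCompensation:
    """Estimated lens attenuation and the green-channel correction it implies.

    ``kappa_hat`` is the blue attenuation factor in (0, 1] (1 = clear lens);
    green is attenuated by (κ+1)/2, so the compensation multiplies green by
    ``green_gain = 2/(κ̂+1)``.  For a clear lens the compensation is the
    identity.  ``flagged`` marks a degenerate estimate clamped at a bound.
    """

    kappa_hat: float
    green_gain: float
    flagged: bool = False

    @classmethod
    def identity(cls) -> "LensCompensation":
        return cls(kappa_hat=1.0, green_gain=1.0)


@dataclass
class HbMap:
    """Per-pixel Hb percentage over the disc.

    ``values`` is NaN outside the disc interior; vessel pixels carry the
    defined value 100; tissue values lie in [0, 120] (values above 100 —
    tissue redder than the vessel median, possible under noise — are
    retained rather than destroyed).  ``vessel_reference`` holds the
    (red, compensated-green) vessel medians; it must be red-dominant.
    """

    values: np.ndarray
    vessel_reference: tuple[float, float]
    regions: DiscRegions
    compensation: LensCompensation

    @property
    def tissue_values(self) -> np.ndarray:
        return self.values[self.regions.tissue]

    @property
    def mean_tissue_hb(self) -> float:
        return float(self.tissue_values.mean())


def estimate_lens_compensation(
    img: FundusImage,
    regions: DiscRegions,
    config: HbConfig = HbConfig(),
) -> LensCompensation:
    """Estimate lens blue/green attenuation from the vessel pixels.

    The vessels' observed blue/green median ratio, divided by the
    clear-lens calibration ratio, equals κ/((κ+1)/2) under the attenuation
    model (blue ×κ, green ×(κ+1)/2); solving gives κ̂ = ρ/(2−ρ).  The
    estimate is clamped to [kappa_min, 1] and flagged when clamping was
    needed (e.g. an all-zero blue channel).
    """
    vmask = regions.vessels.mask
    if int(vmask.sum()) < config.min_vessel_pixels:
        raise VesselReferenceError(
            f"need >= {config.min_vessel_pixels} vessel pixels for the lens "
            f"reference, got {int(vmask.sum())}"
        )
    g_v = float(np.median(img.green[vmask]))
    b_v = float(np.median(img.blue[vmask]))
    if g_v <= 0:
        logger.warning("vessel green median non-positive; lens compensation disabled")
        return LensCompensation(kappa_hat=1.0, green_gain=1.0, flagged=True)
    rho = (b_v / g_v) / config.clear_lens_bg_ratio
    rho = min(rho, 1.0)
    kappa = rho / (2.0 - rho) if rho < 2.0 else 1.0
    flagged = False
    if kappa < config.kappa_min:
        kappa, flagged = config.kappa_min, True
    if kappa > 1.0:
        kappa, flagged = 1.0, True
    return LensCompensation(
        kappa_hat=float(kappa),
        green_gain=float(2.0 / (kappa + 1.0)),
        flagged=flagged,
    )


def estimate_hb_map(
    img: FundusImage,
    regions: DiscRegions,
    comp: LensCompensation | None = None,
    config: HbConfig = HbConfig(),
) -> HbMap:
    """Per-pixel Hb percentage with the vessels as internal 100% reference.

    Raises
    ------
    VesselReferenceError
        If the vessel reference is not red-dominant (h_vessel <= 0) or has
        too few pixels.
    """
    if comp is None:
        comp = LensCompensation.identity()
    vmask = regions.vessels.mask
    if int(vmask.sum()) < config.min_vessel_pixels:
        raise VesselReferenceError(
            f"need >= {config.min_vessel_pixels} vessel pixels for the Hb "
            f"reference, got {int(vmask.sum())}"
        )
    r_v = float(np.median(img.red[vmask]))
    g_v = float(np.median(img.green[vmask])) * comp.green_gain
    if r_v <= g_v:
        raise VesselReferenceError(
            f"vessel reference not red-dominant (r={r_v:.3f} <= g̃={g_v:.3f})"
        )
    h_vessel = (r_v - g_v) / max(r_v, config.eps)

    values = np.full(img.shape, np.nan, dtype=np.float32)
    tissue = regions.tissue
    r = img.red[tissue]
    g = img.green[tissue] * comp.green_gain
    h = (r - g) / np.maximum(r, config.eps)
    values[tissue] = np.clip(100.0 * h / h_vessel, *HB_RANGE)
    values[vmask] = 100.0
    return HbMap(values=values, vessel_reference=(r_v, g_v), regions=regions, compensation=comp)


# ---------------------------------------------------------------------------
# pseudoimage rendering

_N_LEVELS = 256


def _palette_lut(palette: str) -> np.ndarray:
    """(256, 3) float LUT over Hb values 0..120."""
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap(palette, _N_LEVELS)
    return cmap(np.arange(_N_LEVELS))[:, :3]


def render_pseudoimage(hb: HbMap, palette: str = "inferno") -> np.ndarray:
    """False-color rendering of the Hb map.

    Values in [0, 120] map deterministically onto a 256-level perceptually
    ordered palette; pixels outside the disc render neutral gray; vessel
    pixels render at the 100% palette entry.  Returns an (H, W, 3) uint8
    array.  Use :func:`save_pseudoimage` for an annotated figure with a
    0–120 colorbar.
    """
    lut = _palette_lut(palette)
    rgb = np.full(hb.values.shape + (3,), 0.5, dtype=np.float64)
    inside = np.isfinite(hb.values)
    idx = np.round(hb.values[inside] / HB_RANGE[1] * (_N_LEVELS - 1)).astype(int)
    rgb[inside] = lut[np.clip(idx, 0, _N_LEVELS - 1)]
    return np.round(rgb * 255.0).astype(np.uint8)


def decode_pseudoimage(rgb: np.ndarray, palette: str = "inferno") -> np.ndarray:
    """Invert a rendered pseudoimage back to Hb values (nearest palette entry).

    Exact to within one palette step (120/255 < 0.5 Hb units) on pixels
    inside the disc; returns NaN where the pixel color is closer to the
    neutral background than to any palette entry.
    """
    lut = np.round(_palette_lut(palette) * 255.0).astype(np.int64)
    flat = rgb.reshape(-1, 3).astype(np.int64)
    d2 = ((flat[:, None, :] - lut[None, :, :]) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    values = best * (HB_RANGE[1] / (_N_LEVELS - 1))
    bg = np.array([128, 128, 128], dtype=np.int64)
    d2_bg = ((flat - bg) ** 2).sum(axis=1)
    values = np.where(d2_bg < d2[np.arange(len(flat)), best], np.nan, values)
    return values.reshape(rgb.shape[:2])


def save_pseudoimage(hb: HbMap, path, palette: str = "inferno") -> None:
    """Save the pseudoimage with an annotated 0–120 colorbar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(render_pseudoimage(hb, palette))
    ax.set_axis_off()
    norm = colors.Normalize(vmin=HB_RANGE[0], vmax=HB_RANGE[1])
    sm = cm.ScalarMappable(norm=norm, cmap=palette)
    cbar = fig.colorbar(sm, ax=ax, fraction=0.046)
    cbar.set_label("Hb (%)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
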