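"""Fundus image input/output and pre-analysis quality control.

Images are held internally as float32 arrays in [0, 1], shape (H, W, 3),
in the channel order red, green, blue.  Values are the stored (gamma-encoded)
sRGB intensities; no linearization is applied, because the downstream Hb
index is a within-pixel channel ratio referenced to the vessels and any
monotone per-channel encoding cancels out of that reference.

Quality control is a gate, not an enhancement: images that are too dark,
too bright or clipped are rejected, but pixel values are never altered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from onhcolor.exceptions import FundusFormatError

__all__ = [
    "FundusImage",
    "QCGates",
    "QCReport",
    "load_fundus",
    "save_fundus",
    "qc_check",
    "load_annotation",
]


@dataclass
class FundusImage:
    """An RGB fundus photograph normalized to [0, 1].

    Parameters
    ----------
    pixels : ndarray of float32, shape (H, W, 3)
        Red, green, blue reflectance values in [0, 1].
    bit_depth : {8, 16}
        Bit depth of the source raster (metadata only; pixels are float).
    eye : {"right", "left"}
        Laterality; drives the sector numbering orientation.
    subject_id : str
        Opaque subject label.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    eye: str = "right"
    subject_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FundusFormatError(f"expected (H, W, 3) RGB array, got shape {px.shape}")
        if px.shape[0] < 128 or px.shape[1] < 128:
            raise FundusFormatError(f"image too small: {px.shape[1]}x{px.shape[0]} (min 128x128)")
        if self.bit_depth not in (8, 16):
            raise FundusFormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.eye not in ("right", "left"):
            raise FundusFormatError(f"eye must be 'right' or 'left', got {self.eye!r}")
        if float(px.min()) < 0.0 or float(px.max()) > 1.0:
            raise FundusFormatError("channel values outside [0, 1] after normalization")
        self.pixels = px

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def red(self) -> np.ndarray:
        return self.pixels[..., 0]

    @property
    def green(self) -> np.ndarray:
        return self.pixels[..., 1]

    @property
    def blue(self) -> np.ndarray:
        return self.pixels[..., 2]


@dataclass(frozen=True)
class QCGates:
    """Quality-control thresholds.

    lum_lo, lum_hi : acceptable band for the image mean luminance
        (mean over pixels of the per-pixel channel mean).
    sat_max : maximum tolerated fraction of saturated pixels per channel.
    eps : a pixel counts as saturated when its value >= 1 - eps.
    """

    lum_lo: float = 0.15
    lum_hi: float = 0.85
    sat_max: float = 0.01
    eps: float = 1.0 / 255.0


@dataclass
class QCReport:
    passed: bool
    mean_luminance: float
    saturated_fraction_per_channel: tuple[float, float, float]
    reasons: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "mean_luminance": self.mean_luminance,
                "saturated_fraction_per_channel": list(self.saturated_fraction_per_channel),
                "reasons": self.reasons,
            },
            indent=2,
        )


def load_fundus(path: str | Path, eye: str = "right", subject_id: str | None = None) -> FundusImage:
    """Read an 8- or 16-bit RGB raster (PNG/TIFF/JPEG) as a :class:`FundusImage`.

    Channels are normalized to [0, 1] by the full scale of the stored bit
    depth; no resampling or color transformation is applied.  Grayscale and
    paletted images are rejected.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder failure
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if raw.ndim == 3 and raw.shape[2] == 4:  # drop alpha
        raw = raw[..., :3]
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise FundusFormatError(f"{path}: not an RGB image (shape {raw.shape})")
    if raw.dtype == np.uint8:
        depth, scale = 8, 255.0
    elif raw.dtype == np.uint16:
        depth, scale = 16, 65535.0
    else:
        raise FundusFormatError(f"{path}: unsupported dtype {raw.dtype} (need uint8/uint16)")
    px = raw.astype(np.float32) / scale
    return FundusImage(px, bit_depth=depth, eye=eye, subject_id=subject_id or path.stem)


def save_fundus(img: FundusImage, path: str | Path) -> Path:
    """Write the image to PNG/TIFF at its stored bit depth (lossless formats only)."""
    path = Path(path)
    scale = 255.0 if img.bit_depth == 8 else 65535.0
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    raw = np.round(img.pixels.astype(np.float64) * scale).astype(dtype)
    iio.imwrite(path, raw)
    return path


def qc_check(img: FundusImage, gates: QCGates = QCGates()) -> QCReport:
    """Gate an image on exposure and clipping before any analysis.

    The report is always returned; ``passed`` is true iff the mean luminance
    lies inside ``[lum_lo, lum_hi]`` and every channel's saturated fraction
    is at most ``sat_max``.
    """
    px = img.pixels
    mean_lum = float(px.mean())
    sat = tuple(float(np.mean(px[..., c] >= 1.0 - gates.eps)) for c in range(3))
    reasons: list[str] = []
    if mean_lum < gates.lum_lo:
        reasons.append("underexposed")
    elif mean_lum > gates.lum_hi:
        reasons.append("overexposed")
    if any(s > gates.sat_max for s in sat):
        reasons.append("saturated")
    return QCReport(
        passed=not reasons,
        mean_luminance=mean_lum,
        saturated_fraction_per_channel=sat,  # type: ignore[arg-type]
        reasons=reasons,
    )


def load_annotation(path: str | Path) -> dict:
    """Read a sidecar annotation JSON: {subject_id, eye, disc_seed: [x, y]?}."""
    with open(path) as fh:
        ann = json.load(fh)
    if "eye" in ann and ann["eye"] not in ("right", "left"):
        raise FundusFormatError(f"annotation eye must be right/left, got {ann['eye']!r}")
    if "disc_seed" in ann and ann["disc_seed"] is not None:
        seed = ann["disc_seed"]
        if len(seed) != 2:
            raise FundusFormatError("disc_seed must be a 2-element [x, y]")
        ann["disc_seed"] = (float(seed[0]), float(seed[1]))
    return ann
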