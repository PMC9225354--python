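"""Oil-Red-O (ORO) positive-area morphometry by fixed HSB colour thresholding.

ORO stains neutral lipid red; the positive area fraction of a stained section
is a histological readout of intramuscular fat.  Pixels are classified by
closed-interval thresholds on hue, saturation and brightness, all on the
0-255 scale used by ImageJ's colour thresholder (hue 0-255 spans 0-360 deg).
Protocol defaults: hue 228-255, saturation 167-255, brightness 0-255, with
the per-specimen value averaged over four fields of view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor

__all__ = [
    "HistologyImage",
    "HSBThreshold",
    "AreaFractionResult",
    "rgb_to_hsb",
    "oro_positive_mask",
    "area_fraction",
    "specimen_average",
]


@dataclass
class HistologyImage:
    """8-bit RGB micrograph with an optional physical scale."""

    pixels: np.ndarray  # (H, W, 3) uint8
    scale_um_per_px: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) RGB image")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)


@dataclass
class HSBThreshold:
    """Closed HSB intervals on the 0-255 scale; hue is non-wrapping by default."""

    hue: tuple[int, int] = (228, 255)
    saturation: tuple[int, int] = (167, 255)
    brightness: tuple[int, int] = (0, 255)
    hue_wraps: bool = False

    def __post_init__(self) -> None:
        for name in ("hue", "saturation", "brightness"):
            lo, hi = getattr(self, name)
            if name == "hue" and self.hue_wraps:
                continue
            if lo > hi:
                raise ValueError(f"{name} interval inverted: {(lo, hi)}")


@dataclass
class AreaFractionResult:
    per_image_pct: list[float]
    specimen_mean_pct: float


def rgb_to_hsb(img: HistologyImage) -> np.ndarray:
    """Per-pixel HSB triples on the 0-255 scale (hexcone HSV model).

    Hue is scaled from [0, 360) degrees to 0-255 and rounded, matching the
    ImageJ colour-threshold convention; saturation and brightness scale
    0-1 -> 0-255.
    """
    hsv = skcolor.rgb2hsv(img.pixels.astype(float) / 255.0)
    out = np.rint(hsv * 255.0)
    return np.clip(out, 0, 255).astype(np.uint8)


def oro_positive_mask(img: HistologyImage, thr: HSBThreshold | None = None,
                      roi: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of ORO-positive pixels: all three HSB channels inside
    their closed intervals, intersected with ``roi`` when given."""
    thr = thr or HSBThreshold()
    hsb = rgb_to_hsb(img)
    h, s, b = hsb[..., 0].astype(int), hsb[..., 1].astype(int), hsb[..., 2].astype(int)
    if thr.hue_wraps and thr.hue[0] > thr.hue[1]:
        h_ok = (h >= thr.hue[0]) | (h <= thr.hue[1])
    else:
        h_ok = (h >= thr.hue[0]) & (h <= thr.hue[1])
    mask = (
        h_ok
        & (s >= thr.saturation[0]) & (s <= thr.saturation[1])
        & (b >= thr.brightness[0]) & (b <= thr.brightness[1])
    )
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != mask.shape:
            raise ValueError(
                f"roi shape {roi.shape} does not match image shape {mask.shape}"
            )
        mask &= roi
    return mask


def area_fraction(mask: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Positive area as a percentage of the ROI (whole image if no ROI)."""
    mask = np.asarray(mask, dtype=bool)
    if roi is None:
        denom = mask.size
    else:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != mask.shape:
            raise ValueError("roi shape does not match mask shape")
        denom = int(roi.sum())
        if denom == 0:
            raise ValueError("empty ROI")
        mask = mask & roi
    return 100.0 * int(mask.sum()) / denom


def specimen_average(per_image_pct: list[float]) -> AreaFractionResult:
    """Arithmetic mean over fields of view; the protocol expects four."""
    vals = [float(v) for v in per_image_pct]
    if not vals:
        raise ValueError("no per-image values to average")
    if len(vals) != 4:
        warnings.warn(
            f"specimen averaged over {len(vals)} images (protocol uses 4)",
            stacklevel=2,
        )
    return AreaFractionResult(vals, float(np.mean(vals)))
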