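"""Core volume handling: I/O, Hounsfield calibration, denoising, downscaling.

Both imaging workflows (ex-vivo micro-CT at 8.4 um and in-vivo HR-pQCT at
82 um) share these primitives.  Volumes are kept as 3-D float arrays in
Hounsfield units (HU; air ~ -1000, water ~ 0) with an isotropic voxel size.

Supported on-disk formats: NIfTI (.nii/.nii.gz), multi-page TIFF with a
``<file>.meta.yaml`` sidecar, and flat binary ``.raw`` with the same sidecar.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
import tifffile
import yaml
from scipy import ndimage

__all__ = [
    "CTVolume",
    "HUCalibration",
    "FilterSpec",
    "read_volume",
    "write_volume",
    "apply_calibration",
    "gaussian_filter",
    "downscale",
]

MODALITY_TAGS = ("microCT", "HRpQCT", "synthetic")


@dataclass
class CTVolume:
    """A 3-D scalar field in HU with isotropic voxel geometry.

    Parameters
    ----------
    values
        3-D array of attenuation values in HU.
    voxel_size_mm
        Isotropic voxel edge length in millimetres (> 0).
    origin
        Physical position of voxel (0, 0, 0) in mm.
    modality_tag
        One of ``microCT``, ``HRpQCT``, ``synthetic``.
    """

    values: np.ndarray
    voxel_size_mm: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    modality_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 + 1:
            raise ValueError(
                f"expected 3-D volume, got {self.values.ndim}-D data"
            )
        if not all(s >= 1 for s in self.values.shape):
            raise ValueError("every dimension must have size >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if not (self.voxel_size_mm > 0):
            raise ValueError("voxel_size_mm must be positive")
        if self.modality_tag not in MODALITY_TAGS:
            raise ValueError(f"unknown modality_tag {self.modality_tag!r}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3

    def with_values(self, values: np.ndarray) -> "CTVolume":
        """Same geometry, new voxel data."""
        return CTVolume(values, self.voxel_size_mm, self.origin.copy(), self.modality_tag)


@dataclass
class HUCalibration:
    """Linear map from raw scanner integers to HU.

    ``mgha_slope``/``mgha_intercept`` optionally describe the scanner's
    hydroxyapatite-density scale (mgHA/cm^3); they are carried as metadata
    only, since HU is the canonical internal unit.
    """

    slope: float = 1.0
    intercept: float = 0.0
    mgha_slope: float | None = None
    mgha_intercept: float | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")


@dataclass
class FilterSpec:
    """Truncated Gaussian denoising kernel.

    ``sigma`` is in voxels; ``support`` is the truncation radius in voxels,
    so each separable axis kernel has ``2*support + 1`` taps, renormalised
    to unit sum.  The protocol default is sigma 2.5, support 5.
    """

    sigma: float = 2.5
    support: int = 5

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")
        if int(self.support) < 1:
            raise ValueError("support must be >= 1")
        self.support = int(self.support)

    def kernel(self) -> np.ndarray:
        x = np.arange(-self.support, self.support + 1, dtype=float)
        w = np.exp(-0.5 * (x / self.sigma) ** 2)
        return w / w.sum()


def apply_calibration(raw: np.ndarray, cal: HUCalibration,
                      voxel_size_mm: float = 1.0,
                      modality_tag: str = "synthetic") -> CTVolume:
    """Convert raw scanner integers to a HU-calibrated :class:`CTVolume`."""
    raw = np.asarray(raw)
    values = cal.slope * raw.astype(float) + cal.intercept
    return CTVolume(values, voxel_size_mm, modality_tag=modality_tag)


def gaussian_filter(vol: CTVolume, spec: FilterSpec | None = None) -> CTVolume:
    """Separable truncated-Gaussian denoising with mirror-reflected borders.

    The kernel is truncated at ``spec.support`` voxels per side and
    renormalised, so constant regions are preserved exactly.
    """
    spec = spec or FilterSpec()
    k = spec.kernel()
    out = vol.values.astype(float)
    for axis in range(3):
        out = ndimage.correlate1d(out, k, axis=axis, mode="reflect")
    return vol.with_values(out)


def downscale(vol: CTVolume, factor: int) -> CTVolume:
    """Block-average downscaling by an integer factor (e.g. 82 -> 164 um).

    Non-overlapping ``factor^3`` blocks are replaced by their mean; trailing
    voxels that do not fill a complete block are dropped.  The voxel size is
    multiplied by ``factor``.
    """
    if int(factor) != factor or factor < 2:
        raise ValueError("downscale factor must be an integer >= 2")
    factor = int(factor)
    v = vol.values
    trimmed = tuple((s // factor) * factor for s in v.shape)
    if any(t == 0 for t in trimmed):
        raise ValueError("volume smaller than one block at this factor")
    v = v[: trimmed[0], : trimmed[1], : trimmed[2]].astype(float)
    new_shape = tuple(t // factor for t in trimmed)
    v = v.reshape(new_shape[0], factor, new_shape[1], factor, new_shape[2], factor)
    out = v.mean(axis=(1, 3, 5))
    return CTVolume(out, vol.voxel_size_mm * factor, vol.origin.copy(), vol.modality_tag)


# ---------------------------------------------------------------------------
# I/O

def _sidecar_path(path: str) -> str:
    return path + ".meta.yaml"


def _write_sidecar(path: str, vol: CTVolume, extra: dict | None = None) -> None:
    meta = {
        "voxel_size_mm": float(vol.voxel_size_mm),
        "modality_tag": vol.modality_tag,
        "origin_mm": [float(x) for x in vol.origin],
        "shape": [int(s) for s in vol.shape],
        "dtype": str(vol.values.dtype),
    }
    if extra:
        meta.update(extra)
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def _read_sidecar(path: str) -> dict:
    sp = _sidecar_path(path)
    if not os.path.exists(sp):
        raise FileNotFoundError(
            f"missing sidecar {sp}: voxel_size_mm is required metadata"
        )
    with open(sp) as fh:
        meta = yaml.safe_load(fh)
    if "voxel_size_mm" not in meta:
        raise ValueError(f"sidecar {sp} lacks required field 'voxel_size_mm'")
    return meta


def write_volume(vol: CTVolume, path: str) -> None:
    """Write a volume to NIfTI, multi-page TIFF + sidecar, or raw + sidecar."""
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        aff = np.diag([vol.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = vol.origin
        img = nib.Nifti1Image(np.asarray(vol.values), aff)
        # the header stores the affine as float32; keep the exact voxel size
        # in descrip so a round-trip is lossless
        img.header["descrip"] = (
            f"modality={vol.modality_tag};voxel={vol.voxel_size_mm!r}".encode()[:79]
        )
        nib.save(img, path)
    elif lower.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, np.asarray(vol.values), photometric="minisblack")
        _write_sidecar(path, vol)
    elif lower.endswith(".raw"):
        np.asarray(vol.values).tofile(path)
        _write_sidecar(path, vol)
    else:
        raise ValueError(f"unsupported volume format: {path}")


def read_volume(path: str, format_hint: str | None = None) -> CTVolume:
    """Read a volume from disk; voxel size must be present in the metadata."""
    fmt = format_hint
    lower = path.lower()
    if fmt is None:
        if lower.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif lower.endswith((".tif", ".tiff")):
            fmt = "tiff"
        elif lower.endswith(".raw"):
            fmt = "raw"
        else:
            raise ValueError(f"cannot infer format of {path}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if fmt == "nifti":
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {data.ndim}-D data")
        voxel = float(np.abs(img.affine[0, 0]))
        descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="ignore")
        modality = "synthetic"
        for part in descrip.split(";"):
            if part.startswith("modality=") and part[9:] in MODALITY_TAGS:
                modality = part[9:]
            elif part.startswith("voxel="):
                try:
                    voxel = float(part[6:])
                except ValueError:
                    pass
        if voxel <= 0:
            raise ValueError("NIfTI header lacks a positive voxel size")
        origin = img.affine[:3, 3]
        return CTVolume(data, voxel, origin, modality)

    meta = _read_sidecar(path)
    if fmt == "tiff":
        data = tifffile.imread(path)
    elif fmt == "raw":
        shape = tuple(meta["shape"])
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(shape)
    else:
        raise ValueError(f"unknown format hint {fmt!r}")
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D data")
    return CTVolume(
        data,
        float(meta["voxel_size_mm"]),
        np.asarray(meta.get("origin_mm", [0.0, 0.0, 0.0])),
        meta.get("modality_tag", "synthetic"),
    )


def write_mask(mask: np.ndarray, voxel_size_mm: float, path: str) -> None:
    """Write a binary mask as uint8 NIfTI with 0/1 values."""
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), path)
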