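"""Synthetic ground-truth generators: leg CT phantoms, ORO micrographs, and
an ageing-cohort simulator.

The CT phantom is a concentric-cylinder leg cross-section (bone core, muscle
annulus with ellipsoidal intramuscular fat inclusions, subcutaneous fat ring,
skin shell, surrounding air) voxelised at acquisition resolution (82 um by
default, matching the in-vivo scanner), with Gaussian HU noise added per
acquired voxel.  Tissue means sit inside the segmentation protocol's HU
bands (muscle 300, fat -400), i.e. on the scanner's effective HU-like scale
rather than diagnostic-CT soft-tissue values.

Inclusion centres are sampled uniformly over a neighbourhood of the muscle
compartment and their voxels clipped to it, so the expected fat density is
uniform across the compartment and the fraction measured inside a peeled ROI
is unbiased — except for a thin fat-free margin at the muscle/subcutaneous
interface (``fascia_clearance_vox``) emulating the fascia that encloses
intramuscular fat in vivo; without it the inclusions would merge seamlessly
into the subcutaneous compartment, which no contour-based segmentation (and
no real anatomy) exhibits.  Default inclusion semi-axes (7-11 acquisition
voxels, i.e. 0.6-0.9 mm) keep the inclusions large relative to the denoising
kernel; sub-kernel fat streaks are undetectable by any band threshold, which
is a physical property of the imaging protocol, not of this generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_core import CTVolume
from .segmentation import LABELS
from .histology import HistologyImage
from .imat import SoftTissueMetrics

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "IMAT_LABEL",
    "generate_ct_phantom",
    "generate_oro_image",
    "generate_cohort",
]

# ground-truth label volumes extend the segmentation code table with IMAT
IMAT_LABEL = 6

DEFAULT_HU_MEANS = {
    "air": -1000.0,
    "skin": 0.0,
    "subcut_fat": -400.0,
    "muscle": 300.0,
    "imat": -400.0,
    "bone": 1500.0,
}


@dataclass
class PhantomSpec:
    """Geometry and intensity model of a synthetic leg cross-section.

    ``fat_fraction`` is the target IMAT voxel fraction of the muscle
    compartment (inclusions included); the generator places inclusions until
    the achieved fraction is within 0.002 of the target.
    """

    shape_vox: tuple[int, int, int] = (96, 384, 384)
    voxel_size_mm: float = 0.082
    leg_radius_frac: float = 0.92        # of half the smallest in-plane extent
    bone_radius_frac: float = 0.12       # of the leg radius
    skin_thickness_vox: int = 4
    subcut_fat_thickness_frac: float = 0.08  # of the leg radius
    fat_fraction: float = 0.0
    inclusion_radius_vox: tuple[int, int] = (7, 11)
    fascia_clearance_vox: int = 5  # IMAT kept clear of the subcutaneous interface
    hu_means: dict = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    hu_noise_sd: float = 30.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError("fat_fraction must lie in [0, 1]")
        if not (0 < self.bone_radius_frac < 1 and 0 < self.leg_radius_frac <= 1):
            raise ValueError("radius fractions must lie in (0, 1]")
        if self.inclusion_radius_vox[0] > self.inclusion_radius_vox[1]:
            raise ValueError("inclusion_radius_vox must be (min, max)")
        if self.hu_noise_sd < 0:
            raise ValueError("hu_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """True tissue labels and derived reference quantities for a phantom."""

    labels: np.ndarray          # segmentation codes, plus IMAT_LABEL
    true_fat_fraction: float
    voxel_size_mm: float

    def mask(self, name: str) -> np.ndarray:
        if name == "imat":
            return self.labels == IMAT_LABEL
        return self.labels == LABELS[name]

    def muscle_roi_mask(self) -> np.ndarray:
        """The anatomical muscle compartment: lean muscle plus IMAT."""
        return self.mask("muscle") | self.mask("imat")

    def true_metrics(self) -> SoftTissueMetrics:
        """Reference metrics computed directly from the label volume using
        the nominal tissue HU means (no peel, no noise)."""
        vx = self.voxel_size_mm ** 3
        roi = self.muscle_roi_mask()
        n_roi = int(roi.sum())
        n_imat = int(self.mask("imat").sum())
        soft = ~(self.mask("air") | self.mask("bone"))
        stack_h = self.labels.shape[0] * self.voxel_size_mm
        md = (
            DEFAULT_HU_MEANS["muscle"] * (n_roi - n_imat)
            + DEFAULT_HU_MEANS["imat"] * n_imat
        ) / max(n_roi, 1)
        mv = n_roi * vx
        tv = float(soft.sum()) * vx
        return SoftTissueMetrics(
            TV=tv, MV=mv, MD=md, FD=DEFAULT_HU_MEANS["subcut_fat"],
            IMAT_V=n_imat * vx,
            IMAT_pct=100.0 * n_imat / max(n_roi, 1),
            IMAT_over_MV=n_imat / (n_roi - n_imat) if n_roi > n_imat else math.inf,
            MCSA=mv / stack_h, stack_height_mm=stack_h,
            MV_TV=mv / tv if tv > 0 else math.nan,
            MD_lean=DEFAULT_HU_MEANS["muscle"],
        )


def _ellipsoid_voxels(center: np.ndarray, semi: np.ndarray,
                      shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    """Integer voxel coordinates inside an ellipsoid, clipped to the array."""
    lo = np.maximum(np.floor(center - semi).astype(int), 0)
    hi = np.minimum(np.ceil(center + semi).astype(int) + 1, np.asarray(shape))
    if np.any(lo >= hi):
        return (np.empty(0, int), np.empty(0, int), np.empty(0, int))
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    d = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    inside = d <= 1.0
    return zz[inside], yy[inside], xx[inside]


def generate_ct_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Build a leg phantom volume and its ground truth, deterministically
    for a given ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    nz, ny, nx = spec.shape_vox
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    r = np.hypot(yy - cy, xx - cx)

    leg_radius = spec.leg_radius_frac * (min(ny, nx) / 2.0 - 2)
    bone_radius = spec.bone_radius_frac * leg_radius
    subcut_outer = leg_radius - spec.skin_thickness_vox
    subcut_inner = subcut_outer - spec.subcut_fat_thickness_frac * leg_radius
    if not (bone_radius < subcut_inner < subcut_outer < leg_radius):
        raise ValueError("phantom radii are not nested; adjust the spec")

    plane = np.full((ny, nx), LABELS["air"], dtype=np.uint8)
    plane[r <= leg_radius] = LABELS["skin"]
    plane[r <= subcut_outer] = LABELS["subcutaneous_fat"]
    plane[r <= subcut_inner] = LABELS["muscle"]
    plane[r <= bone_radius] = LABELS["bone"]
    labels = np.broadcast_to(plane, (nz, ny, nx)).copy()

    muscle = labels == LABELS["muscle"]
    n_muscle = int(muscle.sum())
    # inclusions stay clear of the muscle/subcutaneous interface: real IMAT
    # is enclosed by the fascia, and the clearance keeps the muscle contour
    # closed for the segmentation stage
    core = muscle & (r <= subcut_inner - spec.fascia_clearance_vox)[None, :, :]
    target = int(round(spec.fat_fraction * n_muscle))
    tol = max(int(math.ceil(0.002 * n_muscle)), 1)

    if target > 0:
        rmin, rmax = spec.inclusion_radius_vox
        min_blob = 4.0 / 3.0 * math.pi * rmin ** 3
        if min_blob > 2 * tol and target < min_blob:
            # a single smallest inclusion cannot land within tolerance
            raise ValueError(
                "fat_fraction unachievable with this inclusion geometry"
            )
        imat = np.zeros_like(muscle)
        placed = 0
        attempts = 0
        max_attempts = 20000
        while target - placed > tol:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    "fat_fraction unachievable: inclusion placement did not "
                    f"converge within {max_attempts} attempts"
                )
            semi = rng.integers(rmin, rmax + 1, size=3).astype(float)
            # centre sampled over a neighbourhood of the annulus so clipped
            # inclusions keep the fat density uniform up to the boundary
            cz = rng.uniform(-rmax, nz - 1 + rmax)
            # uniform areal density: sample radius as sqrt of a uniform variate
            r_lo = max(bone_radius - rmax, 0.0)
            r_hi = subcut_inner + rmax
            rad = math.sqrt(rng.uniform(r_lo ** 2, r_hi ** 2))
            ang = rng.uniform(0.0, 2.0 * math.pi)
            center = np.array([cz, cy + rad * math.sin(ang), cx + rad * math.cos(ang)])
            z, y, x = _ellipsoid_voxels(center, semi, (nz, ny, nx))
            if z.size == 0:
                continue
            new = core[z, y, x] & ~imat[z, y, x]
            n_new = int(new.sum())
            if n_new == 0:
                continue
            if placed + n_new > target + tol:
                continue
            imat[z[new], y[new], x[new]] = True
            placed += n_new
        labels[imat] = IMAT_LABEL
        achieved = placed / n_muscle
    else:
        achieved = 0.0

    means = spec.hu_means
    code_to_hu = np.zeros(IMAT_LABEL + 1)
    code_to_hu[LABELS["air"]] = means["air"]
    code_to_hu[LABELS["skin"]] = means["skin"]
    code_to_hu[LABELS["subcutaneous_fat"]] = means["subcut_fat"]
    code_to_hu[LABELS["muscle"]] = means["muscle"]
    code_to_hu[LABELS["bone"]] = means["bone"]
    code_to_hu[IMAT_LABEL] = means["imat"]
    values = code_to_hu[labels]
    if spec.hu_noise_sd > 0:
        values = values + rng.normal(0.0, spec.hu_noise_sd, size=values.shape)

    vol = CTVolume(values, spec.voxel_size_mm, modality_tag="synthetic")
    truth = GroundTruth(labels, achieved, spec.voxel_size_mm)
    return vol, truth


# ---------------------------------------------------------------------------
# ORO micrograph generator

def generate_oro_image(positive_fraction: float, shape: tuple[int, int] = (256, 256),
                       rng_seed: int = 0) -> tuple[HistologyImage, float]:
    """Synthetic ORO-stained field with an exact known positive-pixel fraction.

    A smoothed random field is thresholded at the exact pixel count, giving
    blob-shaped lipid droplets; positive pixels receive HSB colours sampled
    strictly inside the default ORO bands (with margin for 8-bit rounding),
    the background strictly outside (low saturation).  Returns the image and
    the true positive percentage.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    h, w = shape
    n = h * w
    n_pos = int(round(positive_fraction * n))

    fld = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=6.0)
    order = np.argsort(fld, axis=None)[::-1]
    mask = np.zeros(n, dtype=bool)
    mask[order[:n_pos]] = True
    mask = mask.reshape(h, w)

    hsv = np.empty((h, w, 3))
    # background: pale pinkish tissue, saturation far below the 167 cutoff
    hsv[..., 0] = rng.uniform(0.90, 0.99, size=(h, w))
    hsv[..., 1] = rng.uniform(0.0, 100 / 255, size=(h, w))
    hsv[..., 2] = rng.uniform(150 / 255, 1.0, size=(h, w))
    # droplets: deep ORO red inside hue 228-255, saturation 167-255
    hsv[..., 0][mask] = rng.uniform(232 / 255, 252 / 255, size=n_pos)
    hsv[..., 1][mask] = rng.uniform(180 / 255, 240 / 255, size=n_pos)
    hsv[..., 2][mask] = rng.uniform(120 / 255, 230 / 255, size=n_pos)

    from skimage import color as skcolor

    rgb = np.rint(skcolor.hsv2rgb(hsv) * 255.0).astype(np.uint8)
    return HistologyImage(rgb), 100.0 * n_pos / n


# ---------------------------------------------------------------------------
# ageing-cohort simulator

@dataclass
class CohortSpec:
    """Linear-Gaussian generative model of an ageing cohort.

    Each outcome is ``intercept + slope * driver + Gaussian noise``:
    MD, IMAT% and MV are driven by age; chair-rise time by IMAT%; quadriceps
    strength by MD.  Slopes and noise SDs default to values whose implied
    population correlations match the observed ageing structure (MD falling
    and IMAT% rising with age, IMAT% slowing the chair rise, MD tracking
    strength); :meth:`closed_form_correlations` gives the analytic r for
    every modelled pair.  Ages are uniform over ``age_range``.
    """

    n_subjects: int = 30
    age_range: tuple[float, float] = (18.0, 81.0)
    md_age_slope: float = -1.2        # HU / year
    imat_age_slope: float = 0.15      # percentage points / year
    mv_age_slope: float = -250.0      # mm^3 / year
    rise_imat_slope: float = 0.35     # s per IMAT percentage point
    strength_md_slope: float = 0.9    # N per HU
    md_intercept: float = 320.0       # HU at age 0
    imat_intercept: float = 2.0       # % at age 0
    mv_intercept: float = 80000.0     # mm^3 at age 0
    rise_time_intercept: float = 6.0  # s
    strength_intercept: float = 150.0  # N
    noise_sds: dict = field(default_factory=lambda: {
        "md": 18.5, "imat_pct": 4.05, "mv": 8400.0,
        "rise_time": 2.1, "strength": 210.0,
    })
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be increasing")

    def _age_sd(self) -> float:
        lo, hi = self.age_range
        return (hi - lo) / math.sqrt(12.0)

    def closed_form_correlations(self) -> dict[tuple[str, str], float]:
        """Population correlations implied by the generative equations.

        For a chain X -> Y -> Z with independent noises,
        r(X, Z) = r(X, Y) * r(Y, Z).
        """
        sd_age = self._age_sd()

        def _r(slope: float, sd_driver: float, sd_noise: float) -> float:
            s = slope * sd_driver
            return s / math.sqrt(s * s + sd_noise * sd_noise)

        ns = self.noise_sds
        r_age_md = _r(self.md_age_slope, sd_age, ns["md"])
        r_age_imat = _r(self.imat_age_slope, sd_age, ns["imat_pct"])
        r_age_mv = _r(self.mv_age_slope, sd_age, ns["mv"])
        sd_md = math.hypot(self.md_age_slope * sd_age, ns["md"])
        sd_imat = math.hypot(self.imat_age_slope * sd_age, ns["imat_pct"])
        r_imat_rise = _r(self.rise_imat_slope, sd_imat, ns["rise_time"])
        r_md_strength = _r(self.strength_md_slope, sd_md, ns["strength"])
        return {
            ("age", "MD"): r_age_md,
            ("age", "IMAT_pct"): r_age_imat,
            ("age", "MV"): r_age_mv,
            ("MD", "IMAT_pct"): r_age_md * r_age_imat,
            ("IMAT_pct", "rise_time"): r_imat_rise,
            ("MD", "quadriceps_strength"): r_md_strength,
            ("age", "rise_time"): r_age_imat * r_imat_rise,
            ("age", "quadriceps_strength"): r_age_md * r_md_strength,
            ("IMAT_pct", "quadriceps_strength"): r_age_md * r_age_imat * r_md_strength,
        }


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate the cohort table (one row per subject), deterministically."""
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_subjects
    ns = spec.noise_sds
    age = rng.uniform(*spec.age_range, size=n)
    md = spec.md_intercept + spec.md_age_slope * age + rng.normal(0, ns["md"], n)
    imat = spec.imat_intercept + spec.imat_age_slope * age + rng.normal(0, ns["imat_pct"], n)
    mv = spec.mv_intercept + spec.mv_age_slope * age + rng.normal(0, ns["mv"], n)
    rise = spec.rise_time_intercept + spec.rise_imat_slope * imat + rng.normal(0, ns["rise_time"], n)
    strength = spec.strength_intercept + spec.strength_md_slope * md + rng.normal(0, ns["strength"], n)
    return pd.DataFrame({
        "subject_id": np.arange(n),
        "age": age,
        "MD": md,
        "IMAT_pct": imat,
        "MV": mv,
        "rise_time": rise,
        "quadriceps_strength": strength,
    })
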