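"""Whole-body uptake quantification from SPECT/CT volumes.

Implements the threshold-based total-uptake index used to summarise
whole-body radiopharmaceutical retention: a spherical reference VOI is
placed in skeletal muscle, a threshold of ``SUVmean + k*SD`` (default
``k = 2``) is derived from it, every voxel at or above the threshold is
segmented (no connected-component filtering — physiological uptake in
kidneys, spleen and urinary tract is deliberately retained), and the
total-uptake index is ``segmented SUVmean x segmented volume [mL]``
(SUV*mL), analogous to total lesion glycolysis in FDG-PET.  The same
procedure yields LUTtotal on a post-therapy Lu-177 DOTATATE scan and
OCTtotal on a pretreatment In-111 pentetreotide scan.

Conventions (fixed throughout the package):

* world coordinates in mm; a voxel's world position is
  ``origin_mm + index * voxel_spacing_mm`` (axis order of the array);
* membership of a voxel in any region (sphere, segmentation) is decided
  by its *center* — no partial-volume weighting;
* masks must share the volume's grid exactly; no resampling here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import nibabel as nib
from scipy import ndimage

#: physical half-lives, hours
LU177_HALF_LIFE_H = 6.647 * 24.0
IN111_HALF_LIFE_H = 2.805 * 24.0

#: regulatory cap on the background sphere: 5 cm maximum diameter
MAX_SPHERE_DIAMETER_MM = 50.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectVolume:
    """A 3D activity grid with voxel geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values, either activity concentration (Bq/mL) or SUV,
        stated by ``units``.
    voxel_spacing_mm : 3-sequence of float
        Voxel edge lengths per axis, mm. All > 0.
    origin_mm : 3-sequence of float
        World position of voxel (0, 0, 0), mm.
    units : {"SUV", "Bq/mL"}
    """

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "SUV"

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        spacing = tuple(float(s) for s in self.voxel_spacing_mm)
        if any(s <= 0 for s in spacing) or len(spacing) != 3:
            raise ValueError(f"voxel spacing must be 3 positive values, got {spacing}")
        object.__setattr__(self, "voxel_spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if self.units not in ("SUV", "Bq/mL"):
            raise ValueError(f"unknown units {self.units!r}")
        if np.any(self.values < 0):
            raise ValueError("voxel values must be non-negative")

    @property
    def voxel_volume_mL(self) -> float:
        """Volume of one voxel in mL (= mm^3 / 1000)."""
        return float(np.prod(self.voxel_spacing_mm)) / 1000.0

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers (open grids)."""
        return tuple(
            self.origin_mm[a] + np.arange(self.values.shape[a]) * self.voxel_spacing_mm[a]
            for a in range(3)
        )


@dataclass(frozen=True)
class SphereVOI:
    """Spherical volume of interest in world mm coordinates."""

    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self):
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))
        if not 0 < self.radius_mm <= MAX_SPHERE_DIAMETER_MM / 2:
            raise ValueError(
                f"radius must be in (0, {MAX_SPHERE_DIAMETER_MM / 2}] mm, "
                f"got {self.radius_mm}"
            )


@dataclass(frozen=True)
class BackgroundStats:
    """Reference-region statistics and the derived segmentation threshold."""

    suv_mean: float
    suv_sd: float
    n_voxels: int
    threshold: float

    def __post_init__(self):
        if self.suv_sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_voxels < 1:
            raise ValueError("need at least one voxel")
        if self.threshold < self.suv_mean:
            raise ValueError("threshold below mean")


@dataclass(frozen=True)
class UptakeMetrics:
    """Segmentation summary: volume, mean SUV, and their product.

    ``total_uptake = segmented_suv_mean * segmented_volume_mL`` (SUV*mL);
    an empty segmentation yields all zeros.
    """

    segmented_volume_mL: float
    segmented_suv_mean: float
    total_uptake: float

    def __post_init__(self):
        for name in ("segmented_volume_mL", "segmented_suv_mean", "total_uptake"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isclose(
            self.total_uptake,
            self.segmented_suv_mean * self.segmented_volume_mL,
            rtol=1e-9, atol=1e-12,
        ):
            raise ValueError("total_uptake != suv_mean * volume")


# ---------------------------------------------------------------------------
# SUV conversion
# ---------------------------------------------------------------------------

def to_suv(
    volume: SpectVolume,
    injected_activity_MBq: float,
    body_weight_kg: float,
    decay_interval_h: float = 0.0,
    half_life_h: float = LU177_HALF_LIFE_H,
) -> SpectVolume:
    """Convert an activity-concentration volume (Bq/mL) to body-weight SUV.

    SUV = concentration [Bq/mL] * body weight [g] / injected activity [Bq],
    with the injected activity decay-corrected to the acquisition time:
    ``A(t) = A0 * 2**(-t / T_half)``.  Tissue density 1 g/mL is implied by
    the body-weight normalisation.
    """
    if volume.units != "Bq/mL":
        raise ValueError(f"expected a Bq/mL volume, got units {volume.units!r}")
    if injected_activity_MBq <= 0:
        raise ValueError("injected activity must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    if half_life_h <= 0:
        raise ValueError("half-life must be positive")
    activity_bq = injected_activity_MBq * 1e6 * 2.0 ** (-decay_interval_h / half_life_h)
    suv = volume.values * (body_weight_kg * 1000.0) / activity_bq
    return replace(volume, values=suv, units="SUV")


# ---------------------------------------------------------------------------
# background sphere
# ---------------------------------------------------------------------------

def place_background_sphere(
    mask: np.ndarray,
    voxel_spacing_mm,
    max_diameter_mm: float = MAX_SPHERE_DIAMETER_MM,
    origin_mm=(0.0, 0.0, 0.0),
) -> SphereVOI:
    """Place the largest sphere that fits inside a (muscle) mask.

    The sphere is centered on the voxel maximising the Euclidean distance
    to the mask exterior (grid boundary counts as exterior), with radius
    ``min(max_diameter_mm / 2, that distance)``.  Ties are broken by the
    lowest linear (C-order) voxel index, which makes placement
    deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("mask is empty; cannot place a background sphere")
    spacing = tuple(float(s) for s in voxel_spacing_mm)
    # pad so that voxels beyond the grid register as exterior
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=spacing)
    dist = dist[1:-1, 1:-1, 1:-1]
    best = int(np.argmax(dist))  # argmax returns the first (lowest) index on ties
    idx = np.unravel_index(best, mask.shape)
    radius = min(max_diameter_mm / 2.0, float(dist[idx]))
    center = tuple(origin_mm[a] + idx[a] * spacing[a] for a in range(3))
    return SphereVOI(center_mm=center, radius_mm=radius)


def _sphere_member_mask(volume: SpectVolume, sphere: SphereVOI) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside the sphere (<= radius)."""
    cx, cy, cz = volume.voxel_centers_mm()
    d2 = (
        (cx[:, None, None] - sphere.center_mm[0]) ** 2
        + (cy[None, :, None] - sphere.center_mm[1]) ** 2
        + (cz[None, None, :] - sphere.center_mm[2]) ** 2
    )
    return d2 <= sphere.radius_mm ** 2


def background_stats(
    volume: SpectVolume,
    sphere: SphereVOI,
    k: float = 2.0,
) -> BackgroundStats:
    """Mean/SD of SUV over the sphere and the threshold ``mean + k*SD``.

    The SD is the sample SD (ddof=1).  Fewer than two voxel centers
    inside the sphere is an error — the SD would be undefined.
    """
    if volume.units != "SUV":
        raise ValueError("background statistics require an SUV volume")
    if k < 0:
        raise ValueError("threshold multiplier must be >= 0")
    inside = _sphere_member_mask(volume, sphere)
    n = int(inside.sum())
    if n < 2:
        raise ValueError(
            f"sphere contains {n} voxel center(s); need >= 2 for an SD"
        )
    vals = volume.values[inside]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return BackgroundStats(suv_mean=mean, suv_sd=sd, n_voxels=n,
                           threshold=mean + k * sd)


# ---------------------------------------------------------------------------
# segmentation and the total-uptake index
# ---------------------------------------------------------------------------

def segment_above_threshold(
    volume: SpectVolume,
    threshold: float,
    body_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of voxels with SUV >= threshold (inclusive).

    No connected-component filtering: all supra-threshold voxels are
    retained, including physiological uptake.  If ``body_mask`` is given
    the segmentation is restricted to it.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    seg = volume.values >= threshold
    if body_mask is not None:
        body_mask = np.asarray(body_mask, dtype=bool)
        if body_mask.shape != volume.values.shape:
            raise ValueError("body mask shape does not match volume")
        seg &= body_mask
    return seg


def total_uptake(
    volume: SpectVolume,
    segmentation: np.ndarray,
    voxel_spacing_mm=None,
) -> UptakeMetrics:
    """Total-uptake index over a segmentation mask.

    volume_mL = voxel count x voxel volume / 1000;
    suv_mean  = mean SUV over the mask;
    total     = suv_mean * volume_mL  (== sum(SUV) * voxel volume).
    An empty mask returns zeros.
    """
    segmentation = np.asarray(segmentation, dtype=bool)
    if segmentation.shape != volume.values.shape:
        raise ValueError("segmentation shape does not match volume")
    spacing = voxel_spacing_mm if voxel_spacing_mm is not None else volume.voxel_spacing_mm
    vox_mL = float(np.prod(spacing)) / 1000.0
    n = int(segmentation.sum())
    if n == 0:
        return UptakeMetrics(0.0, 0.0, 0.0)
    vol_mL = n * vox_mL
    mean = float(volume.values[segmentation].mean())
    return UptakeMetrics(
        segmented_volume_mL=vol_mL,
        segmented_suv_mean=mean,
        total_uptake=mean * vol_mL,
    )


def quantify_volume(
    volume: SpectVolume,
    muscle_mask: np.ndarray,
    body_mask: np.ndarray | None = None,
    k: float = 2.0,
    max_sphere_diameter_mm: float = MAX_SPHERE_DIAMETER_MM,
) -> tuple[UptakeMetrics, BackgroundStats, SphereVOI, np.ndarray]:
    """Run the full quantification chain on one SUV volume.

    Sphere placement in the muscle mask -> background statistics ->
    ``mean + k*SD`` threshold -> whole-volume segmentation -> total-uptake
    index.  Returns (metrics, stats, sphere, segmentation mask).
    """
    sphere = place_background_sphere(
        muscle_mask, volume.voxel_spacing_mm,
        max_diameter_mm=max_sphere_diameter_mm, origin_mm=volume.origin_mm,
    )
    stats = background_stats(volume, sphere, k=k)
    seg = segment_above_threshold(volume, stats.threshold, body_mask=body_mask)
    metrics = total_uptake(volume, seg)
    return metrics, stats, sphere, seg


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_volume(volume: SpectVolume, path) -> None:
    """Write a volume (or mask) as NIfTI with a diagonal affine."""
    affine = np.diag(list(volume.voxel_spacing_mm) + [1.0])
    affine[:3, 3] = volume.origin_mm
    img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_volume(path, units: str = "SUV") -> SpectVolume:
    """Read a NIfTI volume; the units flag is supplied by the caller
    (NIfTI has no radioactivity-unit field)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    affine = img.affine
    spacing = tuple(float(abs(affine[a, a])) for a in range(3))
    origin = tuple(float(affine[a, 3]) for a in range(3))
    return SpectVolume(values=data, voxel_spacing_mm=spacing,
                       origin_mm=origin, units=units)


def write_mask(mask: np.ndarray, voxel_spacing_mm, path, origin_mm=(0.0, 0.0, 0.0)) -> None:
    affine = np.diag(list(voxel_spacing_mm) + [1.0])
    affine[:3, 3] = origin_mm
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def metrics_row(
    subject: str,
    tracer: str,
    metrics: UptakeMetrics,
    stats: BackgroundStats,
) -> dict:
    """One tabular record of a quantification result, keyed by subject
    and tracer ("LUT" for the therapy scan, "OCT" for the pretreatment
    scan)."""
    if tracer not in ("LUT", "OCT"):
        raise ValueError("tracer must be 'LUT' or 'OCT'")
    return {
        "subject": subject,
        "tracer": tracer,
        "background_suv_mean": stats.suv_mean,
        "background_suv_sd": stats.suv_sd,
        "threshold": stats.threshold,
        "segmented_volume_mL": metrics.segmented_volume_mL,
        "segmented_suv_mean": metrics.segmented_suv_mean,
        "total_uptake": metrics.total_uptake,
    }
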