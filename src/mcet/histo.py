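"""Quantitative scoring of stacked frozen sections.

The pipeline mirrors how treated hearts are assessed: segment the
Evans-blue-positive blobs on each section, register the sections into a 3-D
stack, merge blob cross-sections into 3-D microlesions, fit the therapy
beam axis as the total-least-squares line through the lesion cloud, reslice
the cloud into coaxial disks whose radii contain 95 % of the local
microlesion volume, and summarise the resulting radially symmetric
macrolesion (volume, length, mean radius, lesion density and the auto
score, i.e. the estimated killed-cell count).

Units: mm for geometry, uL for volumes (1 mm^3 = 1 uL), um^2 for section
areas.  Image pixel (0, 0) is top-left and the physical in-plane origin is
the image centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .field import PressureField
from .synthlesion import MicrolesionSet, RigidOffset, SectionStack

__all__ = [
    "SectionLesion",
    "BeamAxisFit",
    "Disk",
    "DiskStack",
    "Macrolesion",
    "AxisUndefinedError",
    "NoMacrolesionError",
    "segment_sections",
    "register_stack",
    "reconstruct_cloud",
    "fit_beam_axis",
    "reslice_disks",
    "macrolesion_metrics",
    "disk_dose_response",
]


class AxisUndefinedError(ValueError):
    """Too few microlesions to define a beam axis."""


class NoMacrolesionError(ValueError):
    """No occupied disks; macrolesion metrics are undefined."""


@dataclass(frozen=True)
class SectionLesion:
    """A single connected stained component on one section."""

    centroid_um: tuple[float, float]  # (x, y) relative to the image centre
    area_um2: float


@dataclass(frozen=True)
class BeamAxisFit:
    """Total-least-squares 3-D line through the microlesion cloud."""

    point: np.ndarray  # volume-weighted centroid, mm
    direction: np.ndarray  # unit vector
    rms_residual: float  # perpendicular-distance RMS, mm

    def axial_radial(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial coordinate along and radial distance from the axis."""
        rel = np.atleast_2d(pts) - self.point
        axial = rel @ self.direction
        radial = np.linalg.norm(rel - np.outer(axial, self.direction), axis=1)
        return axial, radial

    def angle_to(self, direction) -> float:
        """Unsigned angle (degrees) between this axis and a direction."""
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        return float(np.degrees(np.arccos(np.clip(abs(self.direction @ d), -1.0, 1.0))))


@dataclass(frozen=True)
class Disk:
    """One coaxial volume element of the macrolesion."""

    z_center_mm: float  # along the fitted axis, relative to the axis point
    radius_95_mm: float
    lesion_count: int
    microlesion_volume_ul: float  # lesion volume contained within radius_95


@dataclass(frozen=True)
class DiskStack:
    """Coaxially stacked containment disks along the fitted beam axis."""

    disks: tuple[Disk, ...]
    disk_thickness_mm: float
    axis: BeamAxisFit

    def __post_init__(self) -> None:
        centers = [d.z_center_mm for d in self.disks]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("disk centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.disks)


@dataclass(frozen=True)
class Macrolesion:
    """Radially symmetric composite lesion formed by the stacked disks."""

    volume_ul: float
    length_mm: float
    mean_radius_mm: float
    lesion_density_pct: float
    microlesion_volume_ul: float
    auto_score: int

    def report(self) -> dict:
        return {
            "macrolesion_volume_uL": self.volume_ul,
            "length_mm": self.length_mm,
            "mean_radius_mm": self.mean_radius_mm,
            "lesion_density_pct": self.lesion_density_pct,
            "microlesion_volume_uL": self.microlesion_volume_ul,
            "auto_score": self.auto_score,
        }


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_sections(
    stack: SectionStack, min_area_um2: float = 0.0
) -> list[list[SectionLesion]]:
    """Connected-component lesion lists per section.

    Input images must be binary (or integer label) images; grayscale input
    needs prior thresholding.  Centroids are physical (x, y) in um relative
    to the image centre, areas in um^2; components below ``min_area_um2``
    are dropped.
    """
    px = stack.pixel_size_um
    out: list[list[SectionLesion]] = []
    for img in stack.images:
        if img.dtype.kind == "f" and not np.isin(np.unique(img), (0.0, 1.0)).all():
            raise ValueError(
                "grayscale sections require thresholding before segmentation"
            )
        labels, n = ndimage.label(img > 0)
        lesions: list[SectionLesion] = []
        if n:
            idx = np.arange(1, n + 1)
            counts = ndimage.sum_labels(np.ones_like(labels), labels, idx)
            centroids = ndimage.center_of_mass(img > 0, labels, idx)
            h, w = img.shape
            for cnt, (row, col) in zip(counts, centroids):
                area = cnt * px**2
                if area < min_area_um2:
                    continue
                x = (col - (w - 1) / 2.0) * px
                y = (row - (h - 1) / 2.0) * px
                lesions.append(SectionLesion((float(x), float(y)), float(area)))
        out.append(lesions)
    return out


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _warp_rigid(img: np.ndarray, offset: RigidOffset) -> np.ndarray:
    """Resample ``img`` so that content placed at ``offset`` returns to its
    reference position (i.e. applies the offset as an inverse map)."""
    m = offset.matrix(img.shape)
    out = ndimage.affine_transform(
        img.astype(float), m[:2, :2], offset=m[:2, 2], order=1, mode="constant"
    )
    return (out > 0.5).astype(img.dtype)


def _warp_rigid_float(img: np.ndarray, offset: RigidOffset) -> np.ndarray:
    m = offset.matrix(img.shape)
    return ndimage.affine_transform(
        img.astype(float), m[:2, :2], offset=m[:2, 2], order=1, mode="constant"
    )


def _cc_peak(a: np.ndarray, b: np.ndarray) -> float:
    """Normalised peak of the circular cross-correlation of two images."""
    fa, fb = np.fft.rfft2(a), np.fft.rfft2(b)
    cc = np.fft.irfft2(fa * np.conj(fb), s=a.shape)
    norm = np.sqrt((a**2).sum() * (b**2).sum()) + 1e-30
    return float(cc.max() / norm)


def _estimate_rigid(
    ref: np.ndarray,
    mov: np.ndarray,
    max_angle_deg: float,
    coarse_step_deg: float,
    fine_step_deg: float,
    smooth_sigma_px: float = 2.0,
) -> RigidOffset:
    """Coarse-to-fine rotation search + subpixel correlation translation.

    Binary sections are smoothed before correlation so that the rotation
    score varies smoothly and partial content changes between adjacent
    sections do not dominate the match.
    """
    from skimage.registration import phase_cross_correlation

    ref_s = ndimage.gaussian_filter(ref.astype(float), smooth_sigma_px)
    cache: dict[float, float] = {}

    def score(angle: float) -> float:
        angle = round(angle, 4)
        if angle not in cache:
            cand = _warp_rigid_float(mov, RigidOffset(angle_deg=angle)) if angle else mov.astype(float)
            cache[angle] = _cc_peak(ref_s, ndimage.gaussian_filter(cand, smooth_sigma_px))
        return cache[angle]

    best_angle = 0.0
    best = -np.inf
    for a in np.arange(-max_angle_deg, max_angle_deg + 1e-9, coarse_step_deg):
        v = score(a)
        if v > best:
            best, best_angle = v, a
    for a in np.arange(
        best_angle - coarse_step_deg, best_angle + coarse_step_deg + 1e-9, fine_step_deg
    ):
        v = score(a)
        if v > best:
            best, best_angle = v, round(a, 4)

    cand = _warp_rigid_float(mov, RigidOffset(angle_deg=best_angle))
    shift, _, _ = phase_cross_correlation(
        ref_s,
        ndimage.gaussian_filter(cand, smooth_sigma_px),
        upsample_factor=20,
        normalization=None,
    )
    # un-rotating mov by best_angle leaves a residual shift of R^-1 t, where
    # t is the content translation: rotate the recovered shift back
    theta = np.deg2rad(best_angle)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    trans = rot @ (-np.asarray(shift, float))
    return RigidOffset(float(best_angle), float(trans[0]), float(trans[1]))


def register_stack(
    stack: SectionStack,
    max_angle_deg: float = 8.0,
    coarse_step_deg: float = 1.0,
    fine_step_deg: float = 0.1,
) -> tuple[SectionStack, list[RigidOffset]]:
    """Rigidly align successive sections and report the recovered offsets.

    Each section is registered to its aligned predecessor with a coarse-to-
    fine rotation search and subpixel phase correlation.  Recovered offsets
    are absolute (relative to the first section, which is taken as the
    reference frame); blank sections pass through with an identity
    transform and a warning.  Requires at least two non-empty sections.
    """
    n = stack.n_sections
    if sum(bool(img.any()) for img in stack.images) < 2:
        raise ValueError("registration requires at least two non-empty sections")
    shape = stack.image_shape
    recovered: list[RigidOffset] = [RigidOffset()]
    aligned = [stack.images[0]]
    # chain each section to its most recent non-blank predecessor so that a
    # blank section does not sever the accumulated alignment
    prev: np.ndarray | None = stack.images[0] if stack.images[0].any() else None
    prev_acc = RigidOffset()
    accumulated = RigidOffset()
    for k in range(1, n):
        img = stack.images[k]
        if not img.any():
            warnings.warn(f"section {k} is blank; passing through unaligned", stacklevel=2)
            recovered.append(accumulated)
            aligned.append(img)
            continue
        if prev is None:
            prev, prev_acc = img, accumulated
            recovered.append(accumulated)
            aligned.append(_warp_rigid(img, accumulated))
            continue
        rel = _estimate_rigid(prev, img, max_angle_deg, coarse_step_deg, fine_step_deg)
        accumulated = rel.compose(prev_acc, shape)
        recovered.append(accumulated)
        aligned.append(_warp_rigid(img, accumulated))
        prev, prev_acc = img, accumulated
    aligned_stack = SectionStack(
        np.stack(aligned),
        stack.section_thickness_um,
        stack.section_spacing_um,
        stack.pixel_size_um,
        stack.z_start_mm,
        stack.true_offsets,
    )
    return aligned_stack, recovered


# ---------------------------------------------------------------------------
# 3-D reconstruction
# ---------------------------------------------------------------------------

def reconstruct_cloud(stack: SectionStack) -> MicrolesionSet:
    """Merge section components into 3-D microlesions.

    Components in adjacent sections belong to the same lesion when they
    overlap in-plane by at least one pixel.  Lesion volume is the summed
    component area times the section thickness; z positions come from the
    section index times the section spacing.
    """
    if stack.section_spacing_um is None or stack.section_spacing_um <= 0:
        raise ValueError("section spacing metadata is required for reconstruction")
    binary = stack.images > 0
    structure = np.zeros((3, 3, 3), bool)
    structure[1] = True  # 8-connectivity in-plane
    structure[0, 1, 1] = structure[2, 1, 1] = True  # direct overlap across sections
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return MicrolesionSet(np.empty((0, 3)), np.empty(0))
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    centroids = np.array(ndimage.center_of_mass(binary, labels, idx))  # (sec, row, col)
    px = stack.pixel_size_um
    h, w = stack.image_shape
    volumes = counts * px**2 * stack.section_thickness_um
    x_mm = (centroids[:, 2] - (w - 1) / 2.0) * px / 1000.0
    y_mm = (centroids[:, 1] - (h - 1) / 2.0) * px / 1000.0
    z_mm = stack.section_z_mm(centroids[:, 0])
    return MicrolesionSet(np.stack([x_mm, y_mm, z_mm], axis=1), volumes)


# ---------------------------------------------------------------------------
# beam-axis fit and reslicing
# ---------------------------------------------------------------------------

def fit_beam_axis(lesions: MicrolesionSet) -> BeamAxisFit:
    """Volume-weighted total-least-squares line through the lesion cloud.

    The axis passes through the volume-weighted centroid along the first
    principal direction; the residual is the weighted RMS perpendicular
    distance.  At least three lesions are required.
    """
    if len(lesions) < 3:
        raise AxisUndefinedError("at least three microlesions are needed to fit an axis")
    pts = lesions.centroids_mm
    wts = lesions.volumes_um3 / lesions.volumes_um3.sum()
    centroid = wts @ pts
    centred = (pts - centroid) * np.sqrt(wts)[:, None]
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    if direction[2] < 0 or (direction[2] == 0 and direction[0] < 0):
        direction = -direction
    rel = pts - centroid
    axial = rel @ direction
    perp = rel - np.outer(axial, direction)
    rms = float(np.sqrt(wts @ (perp**2).sum(axis=1)))
    return BeamAxisFit(centroid, direction, rms)


def _containment_radius(
    radii: np.ndarray, weights: np.ndarray, fraction: float
) -> float:
    """Nearest-rank weighted containment radius."""
    order = np.argsort(radii)
    cum = np.cumsum(weights[order])
    target = fraction * cum[-1]
    pos = int(np.searchsorted(cum, target, side="left"))
    return float(radii[order][min(pos, len(radii) - 1)])


def reslice_disks(
    lesions: MicrolesionSet,
    axis: BeamAxisFit,
    disk_thickness_mm: float = 0.5,
    min_count: int = 3,
    containment: float = 0.95,
    weighting: str = "volume",
) -> DiskStack:
    """Bin lesions into coaxial disks of 95 % containment radius.

    Lesions are binned by their axial coordinate; per bin the containment
    radius is the nearest-rank weighted 95th percentile of radial distances
    from the axis (volume-weighted by default, count-weighted with
    ``weighting='count'``).  Bins holding fewer than ``min_count`` lesions
    are omitted.
    """
    if disk_thickness_mm <= 0:
        raise ValueError("disk thickness must be positive")
    if weighting not in ("volume", "count"):
        raise ValueError("weighting must be 'volume' or 'count'")
    if len(lesions) == 0:
        return DiskStack((), disk_thickness_mm, axis)
    axial, radial = axis.axial_radial(lesions.centroids_mm)
    start = np.floor(axial.min() / disk_thickness_mm) * disk_thickness_mm
    bins = np.floor((axial - start) / disk_thickness_mm).astype(int)
    disks = []
    for b in np.unique(bins):
        sel = bins == b
        if int(sel.sum()) < min_count:
            continue
        radii = radial[sel]
        vols = lesions.volumes_um3[sel]
        weights = vols if weighting == "volume" else np.ones_like(vols)
        r95 = _containment_radius(radii, weights, containment)
        contained = float(vols[radii <= r95].sum()) / 1e9  # um^3 -> uL
        z_center = start + (b + 0.5) * disk_thickness_mm
        disks.append(Disk(float(z_center), r95, int(sel.sum()), contained))
    disks.sort(key=lambda d: d.z_center_mm)
    return DiskStack(tuple(disks), disk_thickness_mm, axis)


def macrolesion_metrics(
    disks: DiskStack,
    lesions: MicrolesionSet,
    cell_volume_um3=31_416.0,
) -> Macrolesion:
    """Summarise the macrolesion formed by the occupied disks.

    Volume is the summed disk-cylinder volume, length the axial span of the
    occupied disks, mean radius the unweighted mean of disk radii.  The
    microlesion volume counts the lesions inside the disk cylinders; lesion
    density is its percentage of the macrolesion volume, and the auto score
    divides it by the per-cardiomyocyte volume (rounded down).
    """
    if hasattr(cell_volume_um3, "cell_volume_um3"):  # accept a LesionModel
        cell_volume_um3 = cell_volume_um3.cell_volume_um3
    if len(disks) == 0:
        raise NoMacrolesionError("no occupied disks; no macrolesion to characterise")
    dz = disks.disk_thickness_mm
    radii = np.array([d.radius_95_mm for d in disks.disks])
    volume = float(np.pi * (radii**2).sum() * dz)
    centers = np.array([d.z_center_mm for d in disks.disks])
    length = float(centers.max() - centers.min() + dz)
    mean_radius = float(radii.mean())

    axial, radial = disks.axis.axial_radial(lesions.centroids_mm)
    micro_ul = 0.0
    for d in disks.disks:
        sel = (
            (axial >= d.z_center_mm - dz / 2)
            & (axial < d.z_center_mm + dz / 2)
            & (radial <= d.radius_95_mm)
        )
        micro_ul += float(lesions.volumes_um3[sel].sum()) / 1e9
    density = 100.0 * micro_ul / volume if volume > 0 else 0.0
    auto_score = int(np.floor(micro_ul * 1e9 / cell_volume_um3))
    return Macrolesion(volume, length, mean_radius, density, micro_ul, auto_score)


def disk_dose_response(
    disks: DiskStack, fld: PressureField, peak_mpa: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-disk (on-axis pressure, lesion density) pairs for dose-response fits.

    Maps each disk centre to the lab frame, reads the on-axis field
    amplitude at that depth (optionally rescaled to a different focal
    peak), and pairs it with the disk's lesion density.
    """
    f = fld if peak_mpa is None else fld.scaled(peak_mpa)
    pressures, densities = [], []
    dz = disks.disk_thickness_mm
    for d in disks.disks:
        pos = disks.axis.point + d.z_center_mm * disks.axis.direction
        pressures.append(float(f.at(0.0, pos[2])))
        vol = np.pi * d.radius_95_mm**2 * dz
        densities.append(100.0 * d.microlesion_volume_ul / vol if vol > 0 else 0.0)
    return np.asarray(pressures), np.asarray(densities)
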