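"""Vertebral inclination estimation and correction.

A vertebral body is rarely aligned with the scanner's axial planes: seen in
the mid-sagittal view its inferior endplate makes an angle with the
horizontal.  This module estimates that angle from the segmentation mask
alone — the inferior edge of the mid-sagittal mask slice is extracted and a
straight-line Hough transform finds the dominant edge orientation — and
corrects it by rotating the cropped vertebra about the horizontal axis
through its center of mass.

Sign convention (package-wide): a *positive* inclination means the ventral
(anterior) end of the vertebra points inferior.  The convention only has to
be self-consistent: ``rotate_vertebra(roi, estimate.angle_deg)`` always
levels the inferior edge.

All angle work happens on millimetre-scaled points so anisotropic voxels
(thick slices) cannot bias the estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._grid import nearest_index, spacing_zyx
from .errors import EmptyMaskError, GeometryError, LabelError
from .volume_io import LabelVolume3D, ScalarVolume3D

log = logging.getLogger("vertemap.inclination")

__all__ = [
    "VertebraROI", "InclinationEstimate", "extract_vertebra_roi",
    "detect_inferior_edge", "estimate_inclination",
    "estimate_roi_inclination", "rotate_vertebra",
]


@dataclass
class VertebraROI:
    """One vertebra's cropped scalar + mask sub-volume.

    ``com`` is the unweighted centroid of the mask in (z, y, x) voxel
    coordinates of the cropped grid.
    """

    scalar: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float, float]
    com: np.ndarray
    label_name: str = ""

    def __post_init__(self) -> None:
        self.scalar = np.asarray(self.scalar, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.scalar.shape != self.mask.shape:
            raise GeometryError("scalar and mask shapes differ")
        if not self.mask.any():
            raise EmptyMaskError("ROI mask is empty")
        self.com = np.asarray(self.com, dtype=float)


@dataclass(frozen=True)
class InclinationEstimate:
    """Result of the Hough inclination search.

    ``valid`` is False when too few edge points were found; the angle is
    then 0 and no correction is applied.
    """

    angle_deg: float
    hough_votes: int
    n_edge_points: int
    valid: bool
    corrected: bool = False


def extract_vertebra_roi(
    scalar: ScalarVolume3D,
    labels: LabelVolume3D,
    label: int,
    *,
    margin_voxels: int = 2,
) -> VertebraROI:
    """Crop one vertebra to its bounding box plus a margin.

    If the label splits into several connected components (stray islands
    from imperfect segmentation), only the largest is kept, with a warning.
    """
    if label not in labels.label_map:
        raise LabelError(f"label {label} not in label map")
    mask = labels.data == label
    if not mask.any():
        raise LabelError(f"label {label} ({labels.label_map[label]}) absent")

    comp, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n_comp + 1))
        keep = int(np.argmax(sizes)) + 1
        log.warning(
            "label %d: %d connected components, keeping largest (%d voxels)",
            label, n_comp, int(sizes.max()),
        )
        mask = comp == keep

    idx = np.nonzero(mask)
    lo = [max(0, int(i.min()) - margin_voxels) for i in idx]
    hi = [min(s, int(i.max()) + margin_voxels + 1)
          for i, s in zip(idx, mask.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_mask = mask[sl]
    com = np.array(ndimage.center_of_mass(sub_mask), dtype=float)
    return VertebraROI(
        scalar=scalar.data[sl],
        mask=sub_mask,
        spacing_mm=scalar.spacing_mm,
        com=com,
        label_name=labels.label_map[label],
    )


def detect_inferior_edge(roi: VertebraROI) -> np.ndarray:
    """Inferior edge of the mid-sagittal mask slice, in mm.

    The mid-sagittal plane is the slice at the horizontal index nearest the
    center of mass.  For every dorsoventral column containing mask, the most
    inferior (lowest z) masked pixel center is emitted.  Returns an array of
    shape (k, 2) with columns ``(y_mm, z_mm)``.
    """
    sx, sy, sz = roi.spacing_mm
    x0 = nearest_index(roi.com[2])
    x0 = int(np.clip(x0, 0, roi.mask.shape[2] - 1))
    sag = roi.mask[:, :, x0]  # (nz, ny)
    cols = np.flatnonzero(sag.any(axis=0))
    if cols.size == 0:
        return np.empty((0, 2), dtype=float)
    z_idx = sag[:, cols].argmax(axis=0)  # first True along z = most inferior
    return np.column_stack([cols * sy, z_idx * sz]).astype(float)


def estimate_inclination(
    edge_points: np.ndarray,
    *,
    half_range_deg: float = 30.0,
    resolution_deg: float = 0.5,
    offset_bin_mm: float | None = None,
    min_edge_points: int = 5,
) -> InclinationEstimate:
    """Dominant edge angle via a straight-line Hough transform.

    Each candidate angle θ on the grid ``[-half_range, +half_range]``
    (step ``resolution_deg``) defines a family of lines
    ``z = -tan(θ)·y + c``; every edge point votes for the offsets ``c``
    within half an offset bin of its own.  The accumulator is scanned with a
    sliding offset window of width ``offset_bin_mm`` so votes never split
    across a fixed bin edge.  The window should match the longitudinal
    quantization of the edge points (the slice pitch): edge z-coordinates
    cannot deviate from the true endplate line by more than one slice, so a
    matching window captures every inlier without admitting the staircase
    of a wrong orientation.  Use :func:`estimate_roi_inclination` to wire
    the pitch in automatically; with ``None`` a 1 mm window is used.
    """
    pts = np.asarray(edge_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < min_edge_points:
        return InclinationEstimate(0.0, 0, 0 if pts.ndim != 2 else pts.shape[0],
                                   valid=False)
    y, z = pts[:, 0], pts[:, 1]
    if offset_bin_mm is None:
        offset_bin_mm = 1.0  # unknown slice pitch; see estimate_roi_inclination
    n_steps = int(round(half_range_deg / resolution_deg))
    angles = np.arange(-n_steps, n_steps + 1) * resolution_deg

    votes = np.empty(angles.size, dtype=int)
    for k, theta in enumerate(angles):
        m = -np.tan(np.deg2rad(theta))
        offs = np.sort(z - m * y)
        # widest point set inside any window of width offset_bin_mm
        j = np.searchsorted(offs, offs + offset_bin_mm, side="right")
        votes[k] = int((j - np.arange(offs.size)).max())

    # The voxelized edge supports a plateau of equally-voted angles around
    # the true orientation; its median is an unbiased pick, whereas taking
    # an extreme of the plateau systematically shrinks the angle.  Remaining
    # two-way ties go to the smaller |angle| (prefer no correction).
    best = int(votes.max())
    plateau = angles[votes == best]
    mid = plateau.size // 2
    if plateau.size % 2 == 1:
        angle = float(plateau[mid])
    else:
        lo, hi = float(plateau[mid - 1]), float(plateau[mid])
        angle = lo if abs(lo) <= abs(hi) else hi
    return InclinationEstimate(angle, best, int(pts.shape[0]), valid=True)


def estimate_roi_inclination(roi: VertebraROI, **kwargs) -> InclinationEstimate:
    """Inferior-edge Hough estimate for one ROI.

    Convenience wrapper around :func:`detect_inferior_edge` +
    :func:`estimate_inclination` that defaults the Hough offset window to
    the ROI's slice spacing (the quantization of the detected edge).
    """
    if kwargs.get("offset_bin_mm") is None:
        kwargs["offset_bin_mm"] = roi.spacing_mm[2]
    return estimate_inclination(detect_inferior_edge(roi), **kwargs)


def rotate_vertebra(roi: VertebraROI, angle_deg: float) -> VertebraROI:
    """Rotate the ROI about the horizontal axis through its center of mass
    so that an inclination of ``angle_deg`` is removed.

    Resampling happens in millimetre space (anisotropic voxels respected):
    linear interpolation for the PDFF scalar, nearest neighbour for the
    mask.  The output grid is padded so no masked voxel can rotate out of
    frame.  ``angle_deg == 0`` returns the input unchanged.
    """
    if abs(angle_deg) > 45.0:
        raise GeometryError("|rotation angle| must be <= 45 degrees")
    if angle_deg == 0.0:
        return roi

    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    # maps output-frame mm offsets (Z, Y, X) to input-frame mm offsets;
    # chosen so an edge of slope -tan(angle) becomes horizontal
    R = np.array([[c, -s, 0.0],
                  [s, c, 0.0],
                  [0.0, 0.0, 1.0]])
    sp = spacing_zyx(roi.spacing_mm)

    shape = np.array(roi.mask.shape, dtype=float)
    corners = np.array([[z, y, x]
                        for z in (0.0, shape[0] - 1)
                        for y in (0.0, shape[1] - 1)
                        for x in (0.0, shape[2] - 1)])
    corners_mm = (corners - roi.com) * sp
    out_corners = corners_mm @ R  # = R.T applied to each row = inverse map
    mn, mx = out_corners.min(axis=0), out_corners.max(axis=0)
    out_shape = tuple(int(np.ceil((b - a_) / s_)) + 1
                      for a_, b, s_ in zip(mn, mx, sp))
    c_out = -mn / sp

    S = np.diag(sp)
    M = np.linalg.inv(S) @ R @ S
    offset = roi.com - M @ c_out

    scalar = ndimage.affine_transform(
        roi.scalar, M, offset=offset, output_shape=out_shape, order=1,
        mode="constant", cval=0.0)
    # mask: linear interpolation of the indicator + majority threshold —
    # keeps the label crisp but is partial-volume aware at the boundary,
    # which loses far fewer surface voxels than nearest-neighbour sampling
    mask = ndimage.affine_transform(
        roi.mask.astype(np.float32), M, offset=offset,
        output_shape=out_shape, order=1, mode="constant", cval=0.0) >= 0.5
    if not mask.any():
        raise GeometryError("mask lost during rotation")
    com = np.array(ndimage.center_of_mass(mask), dtype=float)
    return VertebraROI(scalar=scalar, mask=mask, spacing_mm=roi.spacing_mm,
                       com=com, label_name=roi.label_name)
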