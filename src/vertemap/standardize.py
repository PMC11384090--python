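"""Mapping vertebrae onto the standardized elliptical-cylinder template.

Vertebral bodies differ in size and shape between levels and between
subjects, which makes their voxel-wise fat-fraction distributions hard to
compare directly.  The standardization maps every vertebra onto one fixed
elliptical cylinder: an elliptical base area sampled with 20 points on the
major (horizontal) semi-axis and 16 on the minor (dorsoventral) semi-axis,
and 20 sampling points along the longitudinal axis.  From the mapped
vertebra, three perpendicular distribution maps are extracted at the planes
through the center of mass: mid-transverse, mid-sagittal and mid-coronal.

The resampling is purely one-dimensional linear interpolation applied
axis by axis:

* transverse: every mask-crossing image row is resampled along the
  horizontal axis to the template width, the stacked rows are resampled
  dorsoventrally to the template height, and each template row is finally
  compressed to the elliptical chord width of the template, centered;
* sagittal / coronal: per axial slice the masked run at the mid-plane is
  resampled to the template width, then the slice stack is resampled
  head–feet to the longitudinal sampling count.

Because each output pixel is a convex combination of masked input voxels,
map values can never exceed the volumetric extrema — the template smooths:
the map minimum is an overestimate and the map maximum an underestimate of
their volumetric counterparts, by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import cached_property

import numpy as np

from .errors import EmptyMaskError, EmptyRunError, GeometryError
from .inclination import (VertebraROI, estimate_roi_inclination,
                          rotate_vertebra)

__all__ = [
    "TemplateGeometry", "StandardizedMaps", "resample_masked_run",
    "map_transverse_slice", "build_standardized_maps",
]


@dataclass(frozen=True)
class TemplateGeometry:
    """Sampling-point counts defining the standardized cylinder.

    ``n_major`` / ``n_minor`` count sampling points per semi-axis, so the
    transverse grid spans ``2·n+1`` nodes per direction (both semi-axis
    endpoints plus a well-defined center node).  ``n_long`` is the total
    number of longitudinal rows.
    """

    n_major: int = 20
    n_minor: int = 16
    n_long: int = 20

    def __post_init__(self) -> None:
        if min(self.n_major, self.n_minor, self.n_long) < 2:
            raise ValueError("all sampling-point counts must be >= 2")

    @property
    def n_cols(self) -> int:
        """Transverse grid width (horizontal direction)."""
        return 2 * self.n_major + 1

    @property
    def n_rows(self) -> int:
        """Transverse grid height (dorsoventral direction)."""
        return 2 * self.n_minor + 1

    @cached_property
    def ellipse_mask(self) -> np.ndarray:
        """Boolean validity mask of the elliptical footprint, (n_rows, n_cols).

        A node with centered indices (i, j) is valid iff
        ``(i/n_major)² + (j/n_minor)² <= 1``; symmetric under both mirrors.
        """
        i = np.arange(-self.n_major, self.n_major + 1)
        j = np.arange(-self.n_minor, self.n_minor + 1)
        jj, ii = np.meshgrid(j, i, indexing="ij")
        return (ii / self.n_major) ** 2 + (jj / self.n_minor) ** 2 <= 1.0 + 1e-12

    def chord_width(self, row: int) -> int:
        """Number of valid nodes in template row ``row`` (0-based)."""
        return int(self.ellipse_mask[row].sum())


@dataclass
class StandardizedMaps:
    """The three mid-plane distribution maps of one vertebra.

    Invalid pixels (outside the elliptical footprint, or rows the template
    could not be filled for) are NaN in the arrays and False in the
    corresponding validity mask.
    """

    transverse: np.ndarray          # (2·n_minor+1, 2·n_major+1)
    sagittal: np.ndarray            # (n_long, 2·n_minor+1)
    coronal: np.ndarray             # (n_long, 2·n_major+1)
    transverse_valid: np.ndarray
    sagittal_valid: np.ndarray
    coronal_valid: np.ndarray
    label_name: str = ""
    inclination_corrected: bool = False
    inclination_deg: float = 0.0

    def planes(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return {
            "transverse": (self.transverse, self.transverse_valid),
            "sagittal": (self.sagittal, self.sagittal_valid),
            "coronal": (self.coronal, self.coronal_valid),
        }

    def valid_values(self) -> np.ndarray:
        """All valid pixels of the three maps, pooled into one 1D array."""
        return np.concatenate([arr[ok] for arr, ok in self.planes().values()])


# ---------------------------------------------------------------------------
# 1D primitive


def resample_masked_run(values, n_out: int) -> np.ndarray:
    """Linearly resample a contiguous masked run to ``n_out`` samples.

    The first and last input samples map exactly onto the first and last
    output samples; interior samples are linearly interpolated at uniform
    fractional positions.  A single-sample run broadcasts its value.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1:
        raise ValueError("expected a 1D run")
    if vals.size == 0:
        raise EmptyRunError("empty run")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    if vals.size == 1:
        return np.full(n_out, vals[0])
    pos = np.linspace(0.0, vals.size - 1.0, n_out)
    return np.interp(pos, np.arange(vals.size), vals)


def _masked_run(values: np.ndarray, mask: np.ndarray) -> np.ndarray | None:
    """Extract the run between the first and last masked sample.

    Interior unmasked gaps (concavities at slice scale) are filled by
    linear interpolation between the flanking masked values, so background
    voxels never leak into the template.
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    lo, hi = idx[0], idx[-1]
    vals = np.asarray(values[lo:hi + 1], dtype=float).copy()
    m = np.asarray(mask[lo:hi + 1], dtype=bool)
    if not m.all():
        pos = np.arange(vals.size)
        vals[~m] = np.interp(pos[~m], pos[m], vals[m])
    return vals


# ---------------------------------------------------------------------------
# Transverse template mapping


def map_transverse_slice(
    scalar_slice: np.ndarray,
    mask_slice: np.ndarray,
    geom: TemplateGeometry,
) -> np.ndarray:
    """Map one axial slice onto the elliptical template.

    Steps: (1) each image row intersecting the mask is resampled along the
    horizontal axis to the template width; (2) the stacked rows are
    resampled dorsoventrally to the template height; (3) each template row
    is compressed to its elliptical chord width and centered.  Pixels
    outside the ellipse are NaN.
    """
    scalar_slice = np.asarray(scalar_slice, dtype=float)
    mask_slice = np.asarray(mask_slice, dtype=bool)
    if scalar_slice.shape != mask_slice.shape:
        raise GeometryError("scalar/mask slice shapes differ")
    if not mask_slice.any():
        raise EmptyMaskError("transverse slice has no masked voxels")

    rows = [
        resample_masked_run(run, geom.n_cols)
        for y in range(mask_slice.shape[0])
        if (run := _masked_run(scalar_slice[y], mask_slice[y])) is not None
    ]
    stacked = np.vstack(rows)  # (m, n_cols)

    full = np.empty((geom.n_rows, geom.n_cols))
    for col in range(geom.n_cols):
        full[:, col] = resample_masked_run(stacked[:, col], geom.n_rows)

    out = np.full((geom.n_rows, geom.n_cols), np.nan)
    center = geom.n_major
    for j in range(geom.n_rows):
        w = geom.chord_width(j)
        if w == 0:
            continue
        if w == 1:
            out[j, center] = full[j, center]
            continue
        half = (w - 1) // 2
        out[j, center - half:center + half + 1] = \
            resample_masked_run(full[j], w)
    return out


# ---------------------------------------------------------------------------
# Full three-plane construction


def _fractional_plane(
    scalar: np.ndarray, mask: np.ndarray, axis: int, coord: float
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the plane at a fractional coordinate along ``axis``.

    The scalar is a mask-weighted linear blend of the two bracketing voxel
    planes; a pixel is inside the blended mask if either bracketing plane
    is masked there (its value then comes from the masked side only).
    Sampling the plane at the exact center of mass instead of the nearest
    voxel index removes a gradient-dependent bias of order
    (voxel size / extent) from every mid-plane map.
    """
    coord = float(np.clip(coord, 0.0, scalar.shape[axis] - 1))
    lo = int(np.floor(coord))
    hi = min(lo + 1, scalar.shape[axis] - 1)
    t = coord - lo
    s_lo = np.take(scalar, lo, axis=axis).astype(float)
    s_hi = np.take(scalar, hi, axis=axis).astype(float)
    m_lo = np.take(mask, lo, axis=axis).astype(bool)
    m_hi = np.take(mask, hi, axis=axis).astype(bool)
    den = (1.0 - t) * m_lo + t * m_hi
    num = (1.0 - t) * np.where(m_lo, s_lo, 0.0) + t * np.where(m_hi, s_hi, 0.0)
    out_mask = den > 0.0
    vals = np.zeros_like(num)
    vals[out_mask] = num[out_mask] / den[out_mask]
    return vals, out_mask


def _longitudinal_map(
    scalar_plane: np.ndarray,
    mask_plane: np.ndarray,
    n_wide: int,
    n_long: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal or coronal map from one longitudinal plane (nz × width).

    Per axial slice, the masked run is resampled to ``n_wide``; slices with
    no mask in this plane are skipped; the remaining slice stack is
    resampled head–feet to ``n_long`` rows.
    """
    rows = []
    for z in range(mask_plane.shape[0]):
        run = _masked_run(scalar_plane[z], mask_plane[z])
        if run is not None:
            rows.append(resample_masked_run(run, n_wide))
    if len(rows) < 2:
        raise GeometryError(
            "mask thinner than 2 slices longitudinally at the mid-plane; "
            "cannot build sagittal/coronal maps"
        )
    stacked = np.vstack(rows)
    out = np.empty((n_long, n_wide))
    for col in range(n_wide):
        out[:, col] = resample_masked_run(stacked[:, col], n_long)
    return out, np.ones((n_long, n_wide), dtype=bool)


def build_standardized_maps(
    roi: VertebraROI,
    geom: TemplateGeometry | None = None,
    *,
    correct_inclination: bool = False,
    hough_kwargs: dict | None = None,
) -> StandardizedMaps:
    """Build the three standardized mid-plane distribution maps of one ROI.

    With ``correct_inclination`` the inferior-edge Hough estimate is applied
    first (rotation about the horizontal axis through the center of mass);
    the angle used is recorded on the result.  Mid-planes are sampled at
    the exact (possibly rotated) center-of-mass coordinate by linear
    interpolation between the two bracketing voxel planes.
    """
    geom = geom or TemplateGeometry()
    angle = 0.0
    corrected = False
    if correct_inclination:
        est = estimate_roi_inclination(roi, **(hough_kwargs or {}))
        if est.valid and est.angle_deg != 0.0:
            roi = rotate_vertebra(roi, est.angle_deg)
        angle = est.angle_deg if est.valid else 0.0
        corrected = est.valid

    t_scalar, t_mask = _fractional_plane(roi.scalar, roi.mask, 0, roi.com[0])
    s_scalar, s_mask = _fractional_plane(roi.scalar, roi.mask, 2, roi.com[2])
    c_scalar, c_mask = _fractional_plane(roi.scalar, roi.mask, 1, roi.com[1])

    transverse = map_transverse_slice(t_scalar, t_mask, geom)
    sagittal, sag_valid = _longitudinal_map(s_scalar, s_mask, geom.n_rows,
                                            geom.n_long)
    coronal, cor_valid = _longitudinal_map(c_scalar, c_mask, geom.n_cols,
                                           geom.n_long)
    return StandardizedMaps(
        transverse=transverse,
        sagittal=sagittal,
        coronal=coronal,
        transverse_valid=geom.ellipse_mask.copy(),
        sagittal_valid=sag_valid,
        coronal_valid=cor_valid,
        label_name=roi.label_name,
        inclination_corrected=corrected,
        inclination_deg=angle,
    )
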