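"""Reading, writing and axis canonicalization of PDFF and label volumes.

Every volume entering the geometry pipeline is first brought into one
canonical frame (see :mod:`vertemap._grid`): arrays indexed ``(z, y, x)``
with ``z`` the longitudinal (head–feet) axis, ``y`` dorsoventral and ``x``
horizontal.  NIfTI files carry their orientation in the affine; axis-aligned
inputs are reoriented losslessly, oblique inputs are resampled onto the
nearest canonical grid (logged, linear interpolation for scalars, nearest
for labels).

PDFF is a percentage: finite values outside ``[0, 100]`` — routine in
reconstructed fat-fraction maps because of noise — are clipped on read and
the clip count is kept on the volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from ._grid import CANONICAL_AXES
from .errors import EmptyMaskError, OrientationError, VolumeFormatError

log = logging.getLogger("vertemap.volume_io")

#: label coding used when none is supplied; the on-disk convention is a
#: package default, overridable everywhere a label map is accepted
DEFAULT_LABEL_MAP: dict[int, str] = {1: "L1", 2: "L2", 3: "L3", 4: "L4", 5: "L5"}


@dataclass
class ScalarVolume3D:
    """A 3D PDFF grid in canonical axes.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``, PDFF in percent.
    spacing_mm
        Voxel size ``(x, y, z)`` in millimetres.
    n_clipped
        Number of voxels clipped into ``[0, 100]`` on ingestion.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    n_clipped: int = 0
    axes: str = CANONICAL_AXES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"scalar volume must be 3D, got ndim={self.data.ndim}"
            )
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise VolumeFormatError(f"invalid spacing {self.spacing_mm!r}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm³)."""
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0


@dataclass
class LabelVolume3D:
    """Integer vertebra mask aligned with a companion :class:`ScalarVolume3D`."""

    data: np.ndarray
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axes: str = CANONICAL_AXES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"label volume must be 3D, got ndim={self.data.ndim}"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            raise VolumeFormatError("label volume must hold integers")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    def present_labels(self) -> list[int]:
        """Mapped labels that actually occur in the volume."""
        found = set(np.unique(self.data).tolist())
        return sorted(v for v in self.label_map if v in found)


# ---------------------------------------------------------------------------
# NIfTI ingestion


def _check_affine(img: nib.Nifti1Image, path: Path) -> None:
    aff = img.affine
    if aff is None or not np.all(np.isfinite(aff[:3, :3])):
        raise OrientationError(
            f"{path}: orientation metadata missing/non-finite; re-save the file "
            "with a valid affine or construct the volume manually with "
            "ScalarVolume3D(data, spacing_mm) in canonical (z, y, x) axes"
        )
    if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
        raise OrientationError(
            f"{path}: degenerate (singular) affine; cannot infer axes — "
            "specify axes manually by constructing the volume from an array"
        )


def _is_oblique(img: nib.Nifti1Image, tol_rad: float = 1e-3) -> bool:
    return bool(np.max(nib.affines.obliquity(img.affine)) > tol_rad)


def _to_canonical(img: nib.Nifti1Image, path: Path, order: int) -> nib.Nifti1Image:
    """Reorient to RAS; resample if the acquisition is oblique."""
    _check_affine(img, path)
    if _is_oblique(img):
        from nibabel.processing import resample_to_output

        log.warning(
            "%s: oblique acquisition — resampling to the nearest canonical "
            "orientation (interpolation order %d)", path, order,
        )
        img = resample_to_output(img, voxel_sizes=img.header.get_zooms()[:3],
                                 order=order)
    return nib.as_closest_canonical(img)


def read_scalar_volume(path: str | Path) -> ScalarVolume3D:
    """Read a PDFF map from a NIfTI-1 file into canonical axes.

    Values are clipped into ``[0, 100]``; the number of clipped voxels is
    recorded on the returned volume and logged.
    """
    path = Path(path)
    img = nib.load(path)
    if len(img.shape) != 3:
        raise VolumeFormatError(f"{path}: expected 3 spatial dims, got {img.shape}")
    img = _to_canonical(img, path, order=1)
    data_ras = np.asarray(img.get_fdata(), dtype=np.float64)
    # RAS (x, y, z) -> canonical array order (z, y, x)
    data = np.ascontiguousarray(data_ras.transpose(2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[0]), float(zooms[1]), float(zooms[2]))
    finite = np.isfinite(data)
    out_of_range = finite & ((data < 0.0) | (data > 100.0))
    n_clipped = int(out_of_range.sum())
    if n_clipped:
        log.info("%s: clipped %d voxel(s) into [0, 100]", path, n_clipped)
        data = np.clip(data, 0.0, 100.0, out=data)
    return ScalarVolume3D(data=data, spacing_mm=spacing, n_clipped=n_clipped)


def read_label_volume(
    path: str | Path, label_map: dict[int, str] | None = None
) -> LabelVolume3D:
    """Read an integer vertebra mask; unknown labels are zeroed with a warning."""
    label_map = dict(DEFAULT_LABEL_MAP) if label_map is None else dict(label_map)
    if not label_map:
        raise ValueError("label_map must be non-empty")
    path = Path(path)
    img = nib.load(path)
    if len(img.shape) != 3:
        raise VolumeFormatError(f"{path}: expected 3 spatial dims, got {img.shape}")
    img = _to_canonical(img, path, order=0)
    raw = np.asarray(img.get_fdata())
    rounded = np.rint(raw)
    if np.max(np.abs(raw - rounded)) > 1e-3:
        raise VolumeFormatError(f"{path}: non-integer label values")
    data = np.ascontiguousarray(rounded.transpose(2, 1, 0)).astype(np.int32)
    known = set(label_map) | {0}
    stray = sorted(set(np.unique(data).tolist()) - known)
    if stray:
        log.warning("%s: zeroing stray label(s) %s", path, stray)
        data[np.isin(data, stray)] = 0
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[0]), float(zooms[1]), float(zooms[2]))
    return LabelVolume3D(data=data, label_map=label_map, spacing_mm=spacing)


# ---------------------------------------------------------------------------
# Output


def _canonical_affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    sx, sy, sz = spacing_mm
    return np.diag([sx, sy, sz, 1.0])


def write_scalar_volume(vol: ScalarVolume3D, path: str | Path) -> None:
    """Write a canonical-axis volume as NIfTI-1 (RAS, diagonal affine)."""
    path = Path(path)
    try:
        data_ras = np.ascontiguousarray(vol.data.transpose(2, 1, 0))
        img = nib.Nifti1Image(data_ras.astype(np.float32),
                              _canonical_affine(vol.spacing_mm))
        img.header.set_zooms(vol.spacing_mm)
        nib.save(img, path)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"failed writing scalar volume to {path}: {exc}") from exc


def write_label_volume(vol: LabelVolume3D, path: str | Path) -> None:
    path = Path(path)
    data_ras = np.ascontiguousarray(vol.data.transpose(2, 1, 0))
    img = nib.Nifti1Image(data_ras.astype(np.int16), _canonical_affine(vol.spacing_mm))
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, path)


def write_map_nifti(map2d: np.ndarray, path: str | Path) -> None:
    """Write one standardized map as a 2D NIfTI; invalid pixels stay NaN."""
    arr = np.asarray(map2d, dtype=np.float32)
    img = nib.Nifti1Image(arr.T[..., None], np.eye(4))
    nib.save(img, Path(path))


def write_maps_png(maps, path: str | Path, *, cmap: str = "inferno",
                   vmin: float = 0.0, vmax: float = 100.0) -> None:
    """Render the three standardized distribution maps as one PNG.

    Invalid template pixels (outside the elliptical footprint) are drawn
    transparent.  Raises :class:`EmptyMaskError` if no map has a valid pixel.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("transverse", maps.transverse), ("sagittal", maps.sagittal),
              ("coronal", maps.coronal)]
    if all(np.all(np.isnan(arr)) for _, arr in panels):
        raise EmptyMaskError("standardized maps contain no valid pixels")
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad(alpha=0.0)
    for ax, (name, arr) in zip(axes, panels):
        im = ax.imshow(arr, cmap=cm, vmin=vmin, vmax=vmax, origin="lower",
                       interpolation="nearest")
        ax.set_title(name, fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.colorbar(im, ax=axes, shrink=0.8, label="PDFF (%)")
    fig.savefig(path, dpi=150, transparent=True)
    plt.close(fig)
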