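"""Volume and raster I/O with voxel geometry carried through the pipeline.

3-D parameter maps and masks travel as NIfTI-1; 2-D histology rasters as
TIFF/PNG; tables as CSV. All volumes of one study share a single grid —
no resampling happens here. Missing data is encoded as NaN on disk and as
an unset ``valid_mask`` bit in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

#: Canonical modality identifiers, in the order of the abnormality table.
MODALITIES = ("postgd_t1w", "t1_time", "t2_time", "cbv", "cbf", "adc")

#: Physical units of each parameter map.
MODALITY_UNITS = {
    "postgd_t1w": "a.u.",
    "t1_time": "s",
    "t2_time": "s",
    "cbv": "%",
    "cbf": "mL/100 g/min",
    "adc": "um^2/ms",
}


class FormatError(ValueError):
    """A file could not be parsed as the expected volumetric format."""


class GeometryError(ValueError):
    """Volumes or masks of one study disagree on grid geometry."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Acquisition grid: in-plane spacing, slice thickness, and shape.

    Parameters
    ----------
    in_plane_spacing : float
        Edge length of a voxel within a slice, in mm.
    slice_thickness : float
        Slice thickness, in mm.
    grid_shape : tuple of int
        (rows, cols, slices).
    """

    in_plane_spacing: float
    slice_thickness: float
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.in_plane_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("voxel spacings must be positive")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three entries, each >= 1")
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))

    @property
    def voxel_volume_ul(self) -> float:
        """Volume of one voxel in microlitres (1 mm^3 == 1 uL)."""
        return self.in_plane_spacing**2 * self.slice_thickness

    def affine(self) -> np.ndarray:
        return np.diag(
            [self.in_plane_spacing, self.in_plane_spacing, self.slice_thickness, 1.0]
        )


@dataclass
class ParameterVolume:
    """One co-registered 3-D map of a single MRI modality."""

    modality: str
    values: np.ndarray
    geometry: VoxelGeometry
    units: str | None = None
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.grid_shape:
            raise GeometryError(
                f"values shape {self.values.shape} != geometry {self.geometry.grid_shape}"
            )
        if self.units is None:
            self.units = MODALITY_UNITS[self.modality]
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise GeometryError("valid_mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite values inside valid_mask")


@dataclass
class BinaryMask:
    """A strictly binary 3-D mask on the study grid."""

    values: np.ndarray
    geometry: VoxelGeometry
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be strictly binary")
        self.values = arr.astype(bool)
        if self.values.shape != self.geometry.grid_shape:
            raise GeometryError(
                f"mask shape {self.values.shape} != geometry {self.geometry.grid_shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


def _geometry_from_nifti(img: nib.Nifti1Image) -> VoxelGeometry:
    zooms = img.header.get_zooms()[:3]
    if abs(zooms[0] - zooms[1]) > 1e-6:
        raise FormatError("anisotropic in-plane spacing is not supported")
    return VoxelGeometry(float(zooms[0]), float(zooms[2]), tuple(img.shape[:3]))


def read_volume(
    path: str | Path,
    modality: str,
    *,
    expected_geometry: VoxelGeometry | None = None,
) -> ParameterVolume:
    """Read a NIfTI-1 parameter map; NaN voxels are flagged invalid.

    ``expected_geometry`` enforces grid consistency across a study's
    volumes; a mismatch raises :class:`GeometryError`.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    geom = _geometry_from_nifti(img)
    if expected_geometry is not None and geom != expected_geometry:
        raise GeometryError(
            f"{path}: geometry {geom} inconsistent with study geometry {expected_geometry}"
        )
    return ParameterVolume(modality=modality, values=data, geometry=geom)


def write_volume(volume: ParameterVolume, path: str | Path) -> None:
    """Write a parameter map as NIfTI-1; invalid voxels become NaN."""
    data = volume.values.copy()
    data[~volume.valid_mask] = np.nan
    img = nib.Nifti1Image(data, volume.geometry.affine())
    img.header.set_zooms(
        (
            volume.geometry.in_plane_spacing,
            volume.geometry.in_plane_spacing,
            volume.geometry.slice_thickness,
        )
    )
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str = "") -> BinaryMask:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    return BinaryMask(values=data > 0.5, geometry=_geometry_from_nifti(img), label=label)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.geometry.affine())
    img.header.set_zooms(
        (mask.geometry.in_plane_spacing, mask.geometry.in_plane_spacing, mask.geometry.slice_thickness)
    )
    nib.save(img, str(path))


def volume_from_mask(mask: BinaryMask) -> float:
    """Volume of a binary mask in microlitres."""
    return mask.n_voxels * mask.geometry.voxel_volume_ul


def read_raster(path: str | Path) -> np.ndarray:
    """Read a single-channel 2-D raster (TIFF/PNG) as a binary array."""
    arr = iio.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel 2-D raster")
    return arr > 0


def write_raster(mask2d: np.ndarray, path: str | Path) -> None:
    iio.imwrite(str(path), (np.asarray(mask2d, bool) * np.uint8(255)))


@dataclass
class StudyConfig:
    """File-to-modality mapping plus mask paths, loadable from JSON."""

    volumes: dict[str, str] = field(default_factory=dict)  # modality -> path
    masks: dict[str, str] = field(default_factory=dict)  # role -> path
    units: dict[str, str] = field(default_factory=dict)
    midline_column: int | list[int] | None = None
    tumor_side: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            volumes=raw.get("volumes", {}),
            masks=raw.get("masks", {}),
            units=raw.get("units", {}),
            midline_column=raw.get("midline_column"),
            tumor_side=raw.get("tumor_side"),
        )

    def load_volumes(self) -> dict[str, ParameterVolume]:
        out: dict[str, ParameterVolume] = {}
        geom: VoxelGeometry | None = None
        for modality, path in self.volumes.items():
            vol = read_volume(path, modality, expected_geometry=geom)
            geom = vol.geometry
            if modality in self.units:
                vol.units = self.units[modality]
            out[modality] = vol
        return out
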