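"""Histology stain rasters → fraction maps → image-space volumes → gold standard.

Binary stain masks (EpCAM marking carcinoma cells, pimonidazole marking
hypoxia, cresyl violet marking nuclei, collagen IV marking vessels) are
reduced to percentage-staining maps on the MRI voxel grid. Sections are
assumed pre-registered to their image slice; several thin sections
(typically 5, 200 μm apart) contribute to each 1 mm slice and are
averaged. Pixels of damaged or missing tissue are masked out and the
voxels they would have fed are excluded from all downstream analyses.

The histologic gold-standard tumor map marks a voxel tumor when it is
either >0.001% EpCAM-positive or >1% pimonidazole-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BinaryMask, VoxelGeometry
from .delineation import TumorMask

STAINS = ("epcam", "pimonidazole", "cresyl_violet", "collagen_iv")

#: Gold-standard thresholds, in percent staining.
EPCAM_THRESHOLD_PCT = 0.001
PIMO_THRESHOLD_PCT = 1.0


class EmptyVolumeError(ValueError):
    """No histology section maps into any slice of the target geometry."""


@dataclass
class StainSection:
    """One binary-thresholded stain raster with its usable-tissue mask."""

    stain: str
    binary_mask: np.ndarray
    pixel_size_um: float
    position_um: float
    tissue_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.stain not in STAINS:
            raise ValueError(f"unknown stain {self.stain!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.binary_mask = np.asarray(self.binary_mask, bool)
        if self.tissue_mask is None:
            self.tissue_mask = np.ones_like(self.binary_mask)
        else:
            self.tissue_mask = np.asarray(self.tissue_mask, bool)
        if self.tissue_mask.shape != self.binary_mask.shape:
            raise ValueError("tissue_mask and binary_mask must be congruent")


@dataclass
class HistologyStack:
    """Ordered stain sections targeted at one MRI volume geometry."""

    sections: list[StainSection]
    target_geometry: VoxelGeometry
    section_spacing_um: float = 200.0

    def __post_init__(self) -> None:
        if self.section_spacing_um <= 0:
            raise ValueError("section spacing must be positive")
        self.sections = sorted(self.sections, key=lambda s: s.position_um)


@dataclass
class FractionVolume:
    """Percent-staining per voxel; NaN wherever no tissue contributed."""

    values: np.ndarray
    coverage_mask: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        on = self.values[self.coverage_mask]
        if on.size and (np.nanmin(on) < 0 or np.nanmax(on) > 100):
            raise ValueError("fractions must lie in [0, 100] on coverage")


def _pad_to_multiple(arr: np.ndarray, block: int, fill=False) -> np.ndarray:
    r = (-arr.shape[0]) % block
    c = (-arr.shape[1]) % block
    if r or c:
        arr = np.pad(arr, ((0, r), (0, c)), constant_values=fill)
    return arr


def _block_sum(arr: np.ndarray, block: int) -> np.ndarray:
    a = _pad_to_multiple(arr.astype(np.int64), block)
    h, w = a.shape
    return a.reshape(h // block, block, w // block, block).sum(axis=(1, 3))


def staining_fraction_map(section: StainSection, block_size_px: int) -> np.ndarray:
    """Percent staining per block: 100 × positive / tissue pixels.

    Blocks containing no tissue pixels are NaN (missing).
    """
    if block_size_px < 1:
        raise ValueError("block_size_px must be >= 1")
    pos = _block_sum(section.binary_mask & section.tissue_mask, block_size_px)
    tis = _block_sum(section.tissue_mask, block_size_px)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = 100.0 * pos / tis
    frac[tis == 0] = np.nan
    return frac


def downscale_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor subsampling by an integer factor; output stays binary.

    If the factor does not divide the raster, the raster is zero-padded
    (padding counts as non-tissue/background) before sampling.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    m = _pad_to_multiple(np.asarray(mask, bool), factor)
    return m[::factor, ::factor]


def stack_to_volume(stack: HistologyStack) -> FractionVolume:
    """Average a stack of sections into an image-space fraction volume.

    Each section is reduced to the voxel grid (tissue-weighted block
    fractions), assigned to the slice containing its axial position, and
    slices are averaged over their contributing sections, ignoring
    missing blocks. Coverage marks voxels with at least one contributing
    tissue pixel.
    """
    geom = stack.target_geometry
    n_rows, n_cols, n_slices = geom.grid_shape
    thickness_um = geom.slice_thickness * 1000.0
    in_plane_um = geom.in_plane_spacing * 1000.0

    sums = np.zeros(geom.grid_shape)
    counts = np.zeros(geom.grid_shape, dtype=np.int32)
    any_mapped = False
    for sec in stack.sections:
        z = int(np.floor(sec.position_um / thickness_um))
        if z < 0 or z >= n_slices:
            continue
        block = in_plane_um / sec.pixel_size_um
        if abs(block - round(block)) > 1e-9 or block < 1:
            raise ValueError(
                f"voxel edge ({in_plane_um} um) must be an integer multiple "
                f"of section pixel size ({sec.pixel_size_um} um)"
            )
        frac = staining_fraction_map(sec, int(round(block)))[:n_rows, :n_cols]
        fr, fc = frac.shape
        ok = np.isfinite(frac)
        sums[:fr, :fc, z][ok] += frac[ok]
        counts[:fr, :fc, z][ok] += 1
        any_mapped = True
    if not any_mapped:
        raise EmptyVolumeError("no section maps into any slice of the target")
    coverage = counts > 0
    with np.errstate(invalid="ignore"):
        values = sums / counts
    values[~coverage] = np.nan
    return FractionVolume(values=values, coverage_mask=coverage, geometry=geom)


def coverage_union(*volumes: FractionVolume) -> BinaryMask:
    """Voxels with histology coverage in at least one fraction volume."""
    geom = volumes[0].geometry
    out = np.zeros(geom.grid_shape, bool)
    for v in volumes:
        if v.geometry != geom:
            raise ValueError("fraction volumes must share one geometry")
        out |= v.coverage_mask
    return BinaryMask(out, geom, label="histology_coverage")


def gold_standard_map(
    epcam: FractionVolume,
    pimo: FractionVolume,
    epcam_threshold_pct: float = EPCAM_THRESHOLD_PCT,
    pimo_threshold_pct: float = PIMO_THRESHOLD_PCT,
) -> TumorMask:
    """Histologic gold standard: EpCAM > 0.001% or pimonidazole > 1%.

    Thresholds are strict. Voxels without coverage on a stain do not
    trigger that stain's criterion; voxels covered by neither stain are
    outside the gold standard's valid domain (see :func:`coverage_union`).
    """
    if epcam.geometry != pimo.geometry:
        raise ValueError("fraction volumes must share one geometry")
    ep = epcam.coverage_mask & (np.nan_to_num(epcam.values, nan=-1.0) > epcam_threshold_pct)
    pi = pimo.coverage_mask & (np.nan_to_num(pimo.values, nan=-1.0) > pimo_threshold_pct)
    return TumorMask(
        mask=BinaryMask(ep | pi, epcam.geometry, label="gold_standard"),
        method="gold_standard",
        parameters={
            "epcam_threshold_pct": epcam_threshold_pct,
            "pimo_threshold_pct": pimo_threshold_pct,
        },
    )
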