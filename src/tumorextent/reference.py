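"""Contralateral reference region and per-modality normal statistics.

The normal reference for each animal is the hemisphere opposite the
tumor: every brain voxel beyond the midline on the tumor-free side,
excluding ventricles. The region is pooled — not subdivided by slice or
tissue class — and per-modality mean and sample SD over it define what
"abnormal" means downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BinaryMask, ParameterVolume


class DegenerateReferenceError(ValueError):
    """The contralateral region is empty or too small to estimate stats."""


@dataclass(frozen=True)
class ModalityStats:
    mean: float
    sd: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n_voxels < 2:
            raise DegenerateReferenceError("fewer than 2 usable reference voxels")


@dataclass
class ReferenceStats:
    """Per-modality normal statistics over the contralateral region."""

    stats: dict[str, ModalityStats]

    def __getitem__(self, modality: str) -> ModalityStats:
        return self.stats[modality]

    def __contains__(self, modality: str) -> bool:
        return modality in self.stats

    def to_frame(self) -> pd.DataFrame:
        """One row per modality: mean, sd, n_voxels."""
        return pd.DataFrame(
            [
                {"modality": m, "mean": s.mean, "sd": s.sd, "n_voxels": s.n_voxels}
                for m, s in self.stats.items()
            ]
        ).set_index("modality")


def build_contralateral_mask(
    brain_mask: BinaryMask,
    midline_column: int | np.ndarray,
    tumor_side: str,
    ventricle_mask: BinaryMask | None = None,
) -> BinaryMask:
    """Brain voxels strictly beyond the midline on the tumor-free side.

    Parameters
    ----------
    midline_column : int or array of int
        Column index of the midline plane, either one value for the whole
        volume or one per slice (accommodating tumor-induced midline
        shift; supplied, not estimated).
    tumor_side : {"left", "right"}
        Side (in column space: left = lower column indices) holding the
        tumor. The returned region lies on the opposite side.
    ventricle_mask : BinaryMask, optional
        Voxels to exclude (ventricles, defined on T2-weighted imaging).
    """
    if tumor_side not in ("left", "right"):
        raise ValueError("tumor_side must be 'left' or 'right'")
    geom = brain_mask.geometry
    n_rows, n_cols, n_slices = geom.grid_shape
    midline = np.broadcast_to(np.asarray(midline_column, dtype=int), (n_slices,))
    if midline.min() < 0 or midline.max() >= n_cols:
        raise ValueError("midline column outside grid")

    cols = np.arange(n_cols)[None, :, None]
    plane = midline[None, None, :]
    side = cols > plane if tumor_side == "left" else cols < plane
    out = brain_mask.values & side
    if ventricle_mask is not None:
        out &= ~ventricle_mask.values
    if not out.any():
        raise DegenerateReferenceError("contralateral region is empty")
    return BinaryMask(values=out, geometry=geom, label="contralateral")


def compute_reference_stats(
    volumes: dict[str, ParameterVolume],
    contralateral: BinaryMask,
) -> ReferenceStats:
    """Mean and sample SD (n−1) per modality over contralateral ∩ valid."""
    stats: dict[str, ModalityStats] = {}
    for modality, vol in volumes.items():
        if vol.geometry != contralateral.geometry:
            raise ValueError(f"{modality}: geometry differs from contralateral mask")
        sel = contralateral.values & vol.valid_mask
        n = int(sel.sum())
        if n < 2:
            raise DegenerateReferenceError(
                f"{modality}: only {n} usable contralateral voxels"
            )
        vals = vol.values[sel]
        stats[modality] = ModalityStats(
            mean=float(vals.mean()), sd=float(vals.std(ddof=1)), n_voxels=n
        )
    return ReferenceStats(stats=stats)
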