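"""Tumor delineation: voxel-wise abnormality channels and their combination.

A voxel is abnormal on a channel when its value lies strictly more than
k standard deviations from the contralateral mean in the channel's
direction (default k = 1). The seven channels are:

====================  =========  =========================================
channel               direction  abnormality
====================  =========  =========================================
postgd_high           above      post-Gd T1-weighted enhancement
t1_high               above      prolonged baseline T1 time
t2_low                below      shortened baseline T2 time
cbv_low               below      reduced cerebral blood volume
cbf_low               below      reduced cerebral blood flow
adc_high              above      elevated apparent diffusion coefficient
adc_low               below      reduced apparent diffusion coefficient
====================  =========  =========================================

The multimodal rule marks a voxel tumor when it is abnormal on at least
``min_count`` channels (default 2): for a fixed pair of independent
channels at k = 1 the chance a normal voxel trips both is Φ(−1)² ≈ 0.025,
keeping the per-pair false-positive rate below 5%. Two single-modality
automated comparators (a plain >2 SD threshold and a "refined" morphology
pipeline) and the independent-observer consensus rule live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage

from .io import BinaryMask, ParameterVolume, VoxelGeometry
from .reference import ReferenceStats

logger = logging.getLogger(__name__)

#: Channel order used everywhere ranks need a deterministic tie-break.
CHANNEL_ORDER = (
    "postgd_high",
    "t1_high",
    "t2_low",
    "cbv_low",
    "cbf_low",
    "adc_high",
    "adc_low",
)

#: channel -> (modality, direction)
CHANNEL_DEFS = {
    "postgd_high": ("postgd_t1w", "above"),
    "t1_high": ("t1_time", "above"),
    "t2_low": ("t2_time", "below"),
    "cbv_low": ("cbv", "below"),
    "cbf_low": ("cbf", "below"),
    "adc_high": ("adc", "above"),
    "adc_low": ("adc", "below"),
}


class ConfigurationError(ValueError):
    """A required modality volume is missing from the study."""


@dataclass
class AbnormalityChannelSet:
    """Named binary abnormality channels plus the reference they used."""

    channels: dict[str, np.ndarray]
    threshold_multiplier: float
    reference: ReferenceStats | None
    geometry: VoxelGeometry

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n in CHANNEL_ORDER if n in self.channels)

    def count_map(self, include: Iterable[str] | None = None) -> np.ndarray:
        """Per-voxel count of set channels (optionally a subset)."""
        names = self.names if include is None else tuple(include)
        counts = np.zeros(self.geometry.grid_shape, dtype=np.int8)
        for name in names:
            counts += self.channels[name]
        return counts

    def stacked(self) -> np.ndarray:
        """Channels as one (n_channels, rows, cols, slices) boolean array."""
        return np.stack([self.channels[n] for n in self.names])


@dataclass
class TumorMask:
    """A binary delineation plus how it was produced."""

    mask: BinaryMask
    method: str
    parameters: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.mask.values


def abnormality_channel(
    volume: ParameterVolume,
    stats: ReferenceStats,
    direction: str,
    k: float = 1.0,
) -> np.ndarray:
    """Binary grid of voxels strictly beyond mean ± k·sd.

    Strict inequalities: a voxel exactly at the threshold is normal.
    A zero reference SD is degenerate (every deviation from the mean
    triggers); the channel is still computed, with a warning.
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    if k <= 0:
        raise ValueError("threshold multiplier k must be positive")
    if volume.modality not in stats:
        raise ConfigurationError(f"no reference stats for {volume.modality}")
    s = stats[volume.modality]
    if s.sd == 0:
        logger.warning(
            "degenerate threshold: reference SD is 0 for %s", volume.modality
        )
    if direction == "above":
        hit = volume.values > s.mean + k * s.sd
    else:
        hit = volume.values < s.mean - k * s.sd
    return hit & volume.valid_mask


def build_channel_set(
    volumes: dict[str, ParameterVolume],
    stats: ReferenceStats,
    k: float = 1.0,
    channels: Iterable[str] | None = None,
) -> AbnormalityChannelSet:
    """Compute the abnormality channels (all 7 unless a subset is named).

    A modality missing from ``volumes`` raises :class:`ConfigurationError`
    unless its channels were explicitly left out of ``channels`` (a reduced
    protocol).
    """
    wanted = CHANNEL_ORDER if channels is None else tuple(channels)
    unknown = set(wanted) - set(CHANNEL_DEFS)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    out: dict[str, np.ndarray] = {}
    geometry = None
    for name in CHANNEL_ORDER:
        if name not in wanted:
            continue
        modality, direction = CHANNEL_DEFS[name]
        if modality not in volumes:
            raise ConfigurationError(
                f"channel {name} needs modality {modality}, not provided"
            )
        vol = volumes[modality]
        geometry = vol.geometry if geometry is None else geometry
        if vol.geometry != geometry:
            raise ValueError(f"{modality}: geometry differs within study")
        out[name] = abnormality_channel(vol, stats, direction, k)
    return AbnormalityChannelSet(
        channels=out, threshold_multiplier=k, reference=stats, geometry=geometry
    )


def multimodal_combine(
    channels: AbnormalityChannelSet, min_count: int = 2
) -> TumorMask:
    """Voxels abnormal on at least ``min_count`` channels are tumor."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    mask = channels.count_map() >= min_count
    return TumorMask(
        mask=BinaryMask(mask, channels.geometry, label="multimodal"),
        method="multimodal",
        parameters={
            "min_count": min_count,
            "k": channels.threshold_multiplier,
            "channels": list(channels.names),
        },
    )


def sd2_method(postgd: ParameterVolume, stats: ReferenceStats) -> TumorMask:
    """Plain automated comparator: post-Gd intensity > 2 SD above the mean."""
    mask = abnormality_channel(postgd, stats, "above", k=2.0)
    return TumorMask(
        mask=BinaryMask(mask, postgd.geometry, label="sd2"),
        method="sd2",
        parameters={"k": 2.0},
    )


@dataclass(frozen=True)
class RefinedSettings:
    """Settings for the refined single-modality pipeline."""

    k: float = 2.0
    closing_radius: int = 1
    tumor_side: str = "left"
    midline_column: int | None = None


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    z, y, x = np.ogrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (x * x + y * y + z * z) <= r * r


def refined_method(
    postgd: ParameterVolume,
    stats: ReferenceStats,
    settings: RefinedSettings = RefinedSettings(),
) -> TumorMask:
    """Morphology pipeline emulating the steps a human makes intuitively.

    Threshold at mean + k·sd → morphological closing → keep the largest
    26-connected component intersecting the tumor-side hemisphere → fill
    enclosed holes. Every step and its parameters are logged and recorded
    on the returned mask.
    """
    log: list[str] = []
    thresh = abnormality_channel(postgd, stats, "above", k=settings.k)
    log.append(f"threshold k={settings.k}: {int(thresh.sum())} voxels")
    if not thresh.any():
        logger.warning("refined method: threshold produced an empty mask")
        log.append("empty after threshold; returning empty mask")
        return TumorMask(
            mask=BinaryMask(thresh, postgd.geometry, label="refined"),
            method="refined",
            parameters={"settings": settings, "log": log, "empty": True},
        )
    closed = ndimage.binary_closing(thresh, structure=_ball(settings.closing_radius))
    closed |= thresh  # closing must not discard original detections
    log.append(f"closing radius={settings.closing_radius}: {int(closed.sum())} voxels")

    labels, n = ndimage.label(closed, structure=np.ones((3, 3, 3), dtype=bool))
    n_cols = postgd.geometry.grid_shape[1]
    mid = settings.midline_column if settings.midline_column is not None else n_cols // 2
    cols = np.arange(n_cols)[None, :, None]
    hemi = cols < mid if settings.tumor_side == "left" else cols > mid
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    in_hemi = [
        lab
        for lab in range(1, n + 1)
        if np.any((labels == lab) & hemi)
    ]
    candidates = in_hemi if in_hemi else list(range(1, n + 1))
    best = max(candidates, key=lambda lab: sizes[lab - 1])
    comp = labels == best
    log.append(f"largest 26-connected tumor-side component: {int(comp.sum())} voxels")
    filled = ndimage.binary_fill_holes(comp)
    log.append(f"hole fill: {int(filled.sum())} voxels")
    for line in log:
        logger.info("refined: %s", line)
    return TumorMask(
        mask=BinaryMask(filled, postgd.geometry, label="refined"),
        method="refined",
        parameters={"settings": settings, "log": log, "empty": False},
    )


def observer_consensus(observer_masks: list[BinaryMask]) -> TumorMask:
    """Consensus: keep voxels delineated by at least two observers."""
    if len(observer_masks) < 2:
        raise ValueError("observer consensus needs at least 2 masks")
    geometry = observer_masks[0].geometry
    votes = np.zeros(geometry.grid_shape, dtype=np.int16)
    for m in observer_masks:
        if m.geometry != geometry:
            raise ValueError("observer masks must share one grid")
        votes += m.values
    return TumorMask(
        mask=BinaryMask(votes >= 2, geometry, label="observer_consensus"),
        method="observer_consensus",
        parameters={"n_observers": len(observer_masks)},
    )
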