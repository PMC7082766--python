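"""Model/Results interface over the delineation pipeline.

:class:`TumorDelineationModel` is built from a study's co-registered
parameter volumes and anatomical masks; :meth:`fit` estimates the
contralateral normal statistics, derives the abnormality channels, and
combines them into the multimodal tumor mask, returning a
:class:`DelineationResults` that carries the estimates and exposes
evaluation, importance and occult-rim analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluation as ev
from .delineation import (
    AbnormalityChannelSet,
    TumorMask,
    build_channel_set,
    multimodal_combine,
    observer_consensus,
    refined_method,
    sd2_method,
    RefinedSettings,
)
from .io import BinaryMask, ParameterVolume, VoxelGeometry, volume_from_mask
from .reference import ReferenceStats, build_contralateral_mask, compute_reference_stats


class TumorDelineationModel:
    """Voxel-wise multimodal abnormality model for one study.

    Parameters
    ----------
    volumes : dict of modality -> ParameterVolume
        The co-registered parameter maps.
    brain_mask : BinaryMask
    contralateral_mask : BinaryMask, optional
        If omitted, it is built from ``midline_column``, ``tumor_side``
        and ``ventricle_mask``.
    threshold_multiplier : float
        k in the mean ± k·SD abnormality thresholds (default 1).
    min_abnormal : int
        Channels that must be abnormal for a voxel to be tumor (default 2).
    channels : iterable of str, optional
        Restrict to a reduced protocol.
    """

    def __init__(
        self,
        volumes: dict[str, ParameterVolume],
        brain_mask: BinaryMask,
        *,
        contralateral_mask: BinaryMask | None = None,
        midline_column=None,
        tumor_side: str | None = None,
        ventricle_mask: BinaryMask | None = None,
        threshold_multiplier: float = 1.0,
        min_abnormal: int = 2,
        channels=None,
    ) -> None:
        self.volumes = volumes
        self.brain_mask = brain_mask
        self.contralateral_mask = contralateral_mask
        self.midline_column = midline_column
        self.tumor_side = tumor_side
        self.ventricle_mask = ventricle_mask
        self.threshold_multiplier = threshold_multiplier
        self.min_abnormal = min_abnormal
        self.channel_subset = channels

    @classmethod
    def from_phantom(cls, phantom, **kwargs) -> "TumorDelineationModel":
        """Build a model from a synthetic phantom's volumes and masks."""
        return cls(
            phantom.volumes,
            phantom.brain_mask,
            contralateral_mask=phantom.contralateral_mask,
            **kwargs,
        )

    @property
    def geometry(self) -> VoxelGeometry:
        return next(iter(self.volumes.values())).geometry

    def fit(self) -> "DelineationResults":
        """Estimate the reference, compute channels, combine to a mask."""
        contra = self.contralateral_mask
        if contra is None:
            if self.midline_column is None or self.tumor_side is None:
                raise ValueError(
                    "provide contralateral_mask, or midline_column and tumor_side"
                )
            contra = build_contralateral_mask(
                self.brain_mask, self.midline_column, self.tumor_side, self.ventricle_mask
            )
        stats = compute_reference_stats(self.volumes, contra)
        channels = build_channel_set(
            self.volumes, stats, self.threshold_multiplier, self.channel_subset
        )
        # restrict abnormality to brain tissue
        for name in channels.names:
            channels.channels[name] &= self.brain_mask.values
        tumor = multimodal_combine(channels, self.min_abnormal)
        return DelineationResults(
            model=self, contralateral_mask=contra, reference_stats=stats,
            channels=channels, tumor_mask=tumor,
        )


@dataclass
class DelineationResults:
    """Fitted delineation: reference estimates, channels, tumor mask."""

    model: TumorDelineationModel
    contralateral_mask: BinaryMask
    reference_stats: ReferenceStats
    channels: AbnormalityChannelSet
    tumor_mask: TumorMask

    @property
    def tumor_volume_ul(self) -> float:
        return volume_from_mask(self.tumor_mask.mask)

    def channel_counts(self) -> pd.Series:
        """Abnormal voxel count per channel."""
        return pd.Series(
            {n: int(self.channels.channels[n].sum()) for n in self.channels.names},
            name="n_abnormal_voxels",
        )

    # --- comparators -----------------------------------------------------
    def sd2_mask(self) -> TumorMask:
        return sd2_method(self.model.volumes["postgd_t1w"], self.reference_stats)

    def refined_mask(self, settings: RefinedSettings | None = None) -> TumorMask:
        if settings is None:
            mid = self.model.midline_column
            settings = RefinedSettings(
                tumor_side=self.model.tumor_side or "left",
                midline_column=int(np.median(mid)) if mid is not None else None,
            )
        return refined_method(
            self.model.volumes["postgd_t1w"], self.reference_stats, settings
        )

    @staticmethod
    def consensus_mask(observer_masks: list[BinaryMask]) -> TumorMask:
        return observer_consensus(observer_masks)

    # --- evaluation ------------------------------------------------------
    def evaluate(self, gold, valid) -> ev.EvaluationReport:
        """Score the multimodal mask against a gold standard."""
        return ev.evaluate(self.tumor_mask, gold, valid, self.model.geometry)

    def ablation_importance(self, gold, valid) -> pd.DataFrame:
        return ev.ablation_importance(self.channels, gold, valid, self.model.min_abnormal)

    def addition_order(self, gold, valid, orders="exhaustive", rng=None):
        return ev.addition_order_analysis(
            self.channels, gold, valid, self.model.min_abnormal, orders=orders, rng=rng
        )

    def occult_rim(self, gold, consensus, valid, orders="exhaustive", rng=None):
        return ev.occult_rim_analysis(
            gold, consensus, self.channels, valid, self.model.min_abnormal,
            orders=orders, rng=rng,
        )

    # --- presentation ----------------------------------------------------
    def summary(self) -> str:
        """Text summary: reference estimates, channels, tumor volume."""
        ref = self.reference_stats.to_frame()
        counts = self.channel_counts()
        lines = [
            "Multimodal tumor delineation",
            "=" * 60,
            f"grid: {self.model.geometry.grid_shape}, "
            f"voxel: {self.model.geometry.in_plane_spacing} x "
            f"{self.model.geometry.in_plane_spacing} x "
            f"{self.model.geometry.slice_thickness} mm",
            f"threshold: mean ± {self.model.threshold_multiplier:g} SD, "
            f"tumor if ≥ {self.model.min_abnormal} channels abnormal",
            "",
            "Contralateral reference (mean, sample SD, n):",
            ref.to_string(float_format=lambda v: f"{v:.4g}"),
            "",
            "Abnormal voxels per channel:",
            counts.to_string(),
            "",
            f"Tumor volume: {self.tumor_volume_ul:.1f} uL "
            f"({self.tumor_mask.mask.n_voxels} voxels)",
        ]
        return "\n".join(lines)

    def plot_slice(self, z: int, ax=None, modality: str = "postgd_t1w"):
        """Overlay the tumor mask on one slice of a parameter map."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vol = self.model.volumes[modality]
        ax.imshow(vol.values[:, :, z], cmap="gray")
        overlay = np.ma.masked_where(
            ~self.tumor_mask.values[:, :, z], self.tumor_mask.values[:, :, z]
        )
        ax.imshow(overlay, cmap="autumn", alpha=0.5, vmin=0, vmax=1)
        ax.set_title(f"{modality} slice {z} + multimodal mask")
        ax.axis("off")
        return ax
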