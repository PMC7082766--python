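"""Voxel-wise scoring against the histologic gold standard.

Delineations are compared voxel-by-voxel over the valid domain (voxels
with histologic data). Alongside sensitivity, specificity, accuracy and
the Jaccard overlap, the Youden index Y = sensitivity + specificity − 1
summarises net classification benefit.

Modality importance is assessed two ways: leave-one-out ablation (drop a
channel, recombine, measure the accuracy change) and addition-order
analysis (add channels one at a time in every order and record the
accuracy gained at each step). Because the multimodal rule depends only
on which channels are present — not the order they were added — per-step
accuracies are precomputed once per channel subset and each permutation
reads from that table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .delineation import CHANNEL_ORDER, AbnormalityChannelSet, TumorMask
from .io import BinaryMask, VoxelGeometry

logger = logging.getLogger(__name__)


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, TumorMask):
        return mask.mask.values
    if isinstance(mask, BinaryMask):
        return mask.values
    return np.asarray(mask, bool)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvaluationReport:
    """Voxel-wise classification scores; NaN where a denominator is 0."""

    sensitivity: float
    specificity: float
    accuracy: float
    jaccard: float
    youden: float
    counts: ConfusionCounts
    volume_pred_ul: float | None = None
    volume_gold_ul: float | None = None

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "jaccard": self.jaccard,
            "youden": self.youden,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "volume_pred_ul": self.volume_pred_ul,
            "volume_gold_ul": self.volume_gold_ul,
        }


def confusion(pred, gold, valid) -> ConfusionCounts:
    """Confusion counts over the valid domain only."""
    p, g, v = _as_bool(pred), _as_bool(gold), _as_bool(valid)
    if not (p.shape == g.shape == v.shape):
        raise ValueError("pred, gold and valid must share one grid")
    if not v.any():
        raise ValueError("valid mask is empty")
    p, g = p & v, g & v
    tp = int((p & g).sum())
    fp = int((p & ~g & v).sum())
    fn = int((~p & g & v).sum())
    tn = int(v.sum()) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.info("undefined %s: zero denominator", what)
        return float("nan")
    return num / den


def youden_index(sensitivity: float, specificity: float) -> float:
    """Y = sensitivity + specificity − 1."""
    return sensitivity + specificity - 1.0


def report(
    counts: ConfusionCounts, geometry: VoxelGeometry | None = None
) -> EvaluationReport:
    """Scores from confusion counts; volumes in μL if geometry is given."""
    sens = _safe_div(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = _safe_div(counts.tn, counts.tn + counts.fp, "specificity")
    acc = _safe_div(counts.tp + counts.tn, counts.total, "accuracy")
    jac = _safe_div(counts.tp, counts.tp + counts.fp + counts.fn, "jaccard")
    vol_pred = vol_gold = None
    if geometry is not None:
        vol_pred = (counts.tp + counts.fp) * geometry.voxel_volume_ul
        vol_gold = (counts.tp + counts.fn) * geometry.voxel_volume_ul
    return EvaluationReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        jaccard=jac,
        youden=youden_index(sens, spec),
        counts=counts,
        volume_pred_ul=vol_pred,
        volume_gold_ul=vol_gold,
    )


def evaluate(pred, gold, valid, geometry: VoxelGeometry | None = None) -> EvaluationReport:
    """confusion + report in one call."""
    return report(confusion(pred, gold, valid), geometry)


def jaccard_pair(a, b) -> float:
    """|a ∩ b| / |a ∪ b|; raises if both masks are empty."""
    av, bv = _as_bool(a), _as_bool(b)
    if av.shape != bv.shape:
        raise ValueError("masks must share one grid")
    union = int((av | bv).sum())
    if union == 0:
        raise ValueError("Jaccard undefined: both masks are empty")
    return int((av & bv).sum()) / union


@dataclass
class InterobserverResult:
    jaccard: pd.DataFrame
    volume_error_pct: pd.DataFrame
    summary: dict


def interobserver_metrics(
    observer_masks: list[BinaryMask], geometry: VoxelGeometry | None = None
) -> InterobserverResult:
    """Pairwise Jaccard and percent volume differences between observers.

    Volume error per pair is |V_i − V_j| / mean(V_i, V_j) × 100; a pair
    with an empty mask has undefined volume error (NaN, logged).
    """
    n = len(observer_masks)
    if n < 2:
        raise ValueError("need at least 2 observer masks")
    geom = geometry or observer_masks[0].geometry
    vols = [m.n_voxels * geom.voxel_volume_ul for m in observer_masks]
    names = [f"obs{i + 1}" for i in range(n)]
    jmat = pd.DataFrame(np.eye(n), index=names, columns=names)
    vmat = pd.DataFrame(np.zeros((n, n)), index=names, columns=names)
    jvals, vvals = [], []
    for i, j in combinations(range(n), 2):
        jv = jaccard_pair(observer_masks[i], observer_masks[j])
        if vols[i] == 0 or vols[j] == 0:
            logger.info("volume error undefined for pair (%d, %d): empty mask", i, j)
            ve = float("nan")
        else:
            ve = abs(vols[i] - vols[j]) / ((vols[i] + vols[j]) / 2.0) * 100.0
        jmat.iloc[i, j] = jmat.iloc[j, i] = jv
        vmat.iloc[i, j] = vmat.iloc[j, i] = ve
        jvals.append(jv)
        vvals.append(ve)
    summary = {
        "jaccard_mean": float(np.mean(jvals)),
        "jaccard_sd": float(np.std(jvals, ddof=1)) if len(jvals) > 1 else 0.0,
        "volume_error_pct_mean": float(np.nanmean(vvals)),
        "volume_error_pct_sd": float(np.nanstd(vvals, ddof=1)) if len(vvals) > 1 else 0.0,
        "n_pairs": len(jvals),
    }
    return InterobserverResult(jaccard=jmat, volume_error_pct=vmat, summary=summary)


# ---------------------------------------------------------------------------
# modality importance


def _flatten_channels(
    channels: AbnormalityChannelSet, valid
) -> tuple[tuple[str, ...], np.ndarray]:
    v = _as_bool(valid)
    names = channels.names
    flat = np.stack([channels.channels[n][v] for n in names])
    return names, flat


def subset_accuracies(
    channels: AbnormalityChannelSet, gold, valid, min_count: int = 2
) -> dict[frozenset, float]:
    """Accuracy of the ≥ min_count rule for every subset of channels."""
    names, flat = _flatten_channels(channels, valid)
    g = _as_bool(gold)[_as_bool(valid)]
    n = len(names)
    out: dict[frozenset, float] = {}
    for bits in range(1 << n):
        members = [names[i] for i in range(n) if bits >> i & 1]
        counts = flat[[i for i in range(n) if bits >> i & 1]].sum(axis=0) if members else 0
        mask = counts >= min_count if members else np.zeros_like(g)
        out[frozenset(members)] = float((mask == g).mean())
    return out


def ablation_importance(
    channels: AbnormalityChannelSet, gold, valid, min_count: int = 2
) -> pd.DataFrame:
    """Leave-one-out channel importance for the multimodal rule.

    For each channel the multimodal mask is recomputed without it and the
    changes in sensitivity, specificity and accuracy recorded. The
    relative contribution is each channel's accuracy drop, floored at 0
    and normalised to sum to 1 (raw signed deltas are kept alongside);
    ranks break ties by the fixed channel order.
    """
    names, flat = _flatten_channels(channels, valid)
    if len(names) < 2:
        raise ValueError("ablation needs at least 2 channels")
    g = _as_bool(gold)[_as_bool(valid)]
    counts_full = flat.sum(axis=0)
    full = counts_full >= min_count

    def scores(mask: np.ndarray) -> tuple[float, float, float]:
        tp = float((mask & g).sum())
        fn = float((~mask & g).sum())
        fp = float((mask & ~g).sum())
        tn = float((~mask & ~g).sum())
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        return sens, spec, (tp + tn) / g.size

    sens_f, spec_f, acc_f = scores(full)
    rows = []
    for i, name in enumerate(names):
        reduced = (counts_full - flat[i]) >= min_count
        sens, spec, acc = scores(reduced)
        rows.append(
            {
                "channel": name,
                "delta_sensitivity": sens_f - sens,
                "delta_specificity": spec_f - spec,
                "delta_accuracy": acc_f - acc,
            }
        )
    df = pd.DataFrame(rows)
    floored = df["delta_accuracy"].clip(lower=0.0)
    if (df["delta_accuracy"] < 0).any():
        logger.info(
            "negative ablation deltas floored at 0 for contribution shares: %s",
            df.loc[df["delta_accuracy"] < 0, "channel"].tolist(),
        )
    total = floored.sum()
    df["contribution"] = floored / total if total > 0 else 0.0
    order_idx = {n: i for i, n in enumerate(CHANNEL_ORDER)}
    df["_tie"] = df["channel"].map(order_idx)
    df = df.sort_values(["contribution", "_tie"], ascending=[False, True])
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="_tie").set_index("channel")


@dataclass
class AdditionOrderResult:
    """Per-order accuracy trajectories and their (channel, position) view."""

    deltas: pd.DataFrame  # columns: order, position, channel, accuracy, delta
    baseline_accuracy: float
    n_orders: int

    def aggregate(self) -> pd.DataFrame:
        """Mean delta accuracy by (channel, position)."""
        return (
            self.deltas.groupby(["channel", "position"])["delta"]
            .mean()
            .unstack("position")
        )


def addition_order_analysis(
    channels: AbnormalityChannelSet,
    gold,
    valid,
    min_count: int = 2,
    orders: str | int = "exhaustive",
    rng: np.random.Generator | None = None,
) -> AdditionOrderResult:
    """Accuracy gained as channels are added one at a time, per order.

    With fewer than ``min_count`` channels added the mask is empty under
    the counting rule, so the baseline accuracy is that of the empty
    delineation. ``orders`` is "exhaustive" (all n! permutations; n ≤ 7
    gives at most 5040) or an integer sample size drawn with ``rng``.
    """
    names = channels.names
    table = subset_accuracies(channels, gold, valid, min_count)
    baseline = table[frozenset()]
    if orders == "exhaustive":
        all_orders = list(permutations(names))
    else:
        if rng is None:
            raise ValueError("sampled orders require an rng")
        n_sample = int(orders)
        all_orders = [tuple(rng.permutation(names)) for _ in range(n_sample)]
    rows = []
    for oi, order in enumerate(all_orders):
        prev = baseline
        added: set = set()
        for pos, ch in enumerate(order, start=1):
            added.add(ch)
            acc = table[frozenset(added)]
            rows.append(
                {
                    "order": oi,
                    "position": pos,
                    "channel": ch,
                    "accuracy": acc,
                    "delta": acc - prev,
                }
            )
            prev = acc
    return AdditionOrderResult(
        deltas=pd.DataFrame(rows), baseline_accuracy=baseline, n_orders=len(all_orders)
    )


@dataclass
class OccultRimResult:
    rim: BinaryMask
    empty: bool
    report: EvaluationReport | None = None
    ablation: pd.DataFrame | None = None
    addition_order: AdditionOrderResult | None = None


def occult_rim_analysis(
    gold,
    consensus,
    channels: AbnormalityChannelSet,
    valid,
    min_count: int = 2,
    orders: str | int = "exhaustive",
    rng: np.random.Generator | None = None,
) -> OccultRimResult:
    """Characterise histologic tumor missed by the observer consensus.

    The occult rim is gold ∖ consensus. All importance analyses are
    re-run with the evaluation domain restricted to valid ∖ consensus
    and the rim as the positive class. An empty rim is flagged and the
    analyses skipped.
    """
    g, c, v = _as_bool(gold), _as_bool(consensus), _as_bool(valid)
    rim = g & ~c & v
    geom = channels.geometry
    rim_mask = BinaryMask(rim, geom, label="occult_rim")
    if not rim.any():
        logger.info("occult rim is empty (consensus covers the gold standard)")
        return OccultRimResult(rim=rim_mask, empty=True)
    domain = v & ~c
    mm = channels.count_map() >= min_count
    return OccultRimResult(
        rim=rim_mask,
        empty=False,
        report=evaluate(mm, rim, domain, geom),
        ablation=ablation_importance(channels, rim, domain, min_count),
        addition_order=addition_order_analysis(
            channels, rim, domain, min_count, orders=orders, rng=rng
        ),
    )


def region_histology_summary(
    parameter_maps: dict[str, np.ndarray],
    regions: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Voxel-weighted mean ± SD of each parameter within each region.

    ``parameter_maps`` holds arrays with NaN marking missing coverage
    (stain-fraction volumes, vessel maps resampled to the grid, ...);
    ``regions`` holds disjoint boolean masks on the same grid (e.g.
    contralateral / tumor core / occult rim). Regions with no covered
    voxels for a parameter are reported as missing and logged.
    """
    names = list(regions)
    for a, b in combinations(names, 2):
        if (np.asarray(regions[a], bool) & np.asarray(regions[b], bool)).any():
            raise ValueError(f"regions {a!r} and {b!r} overlap")
    rows = []
    for pname, pmap in parameter_maps.items():
        arr = np.asarray(pmap, float)
        for rname in names:
            sel = np.asarray(regions[rname], bool)
            vals = arr[sel]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                logger.info("no covered voxels for %s in region %s", pname, rname)
                rows.append(
                    {"region": rname, "parameter": pname, "mean": float("nan"),
                     "sd": float("nan"), "n_voxels": 0}
                )
                continue
            rows.append(
                {
                    "region": rname,
                    "parameter": pname,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n_voxels": int(vals.size),
                }
            )
    return pd.DataFrame(rows)
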