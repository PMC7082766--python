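"""Synthetic phantoms with the statistical structure the pipeline assumes.

A phantom emulates one animal's study: six co-registered parameter maps
on a 64×64×10 grid (0.5×0.5×1 mm voxels, matching the acquisition
matrix), normal tissue drawn i.i.d. Gaussian per modality, an ellipsoidal
tumor core whose channels are shifted in the directions the abnormality
table expects, a thin invasive rim with attenuated shifts, imperfect
observer delineations (observers under-draw: erosion plus boundary
jitter), histology stacks (5 sections per 1 mm slice, 200 μm apart) whose
stain fractions are consistent with the gold-standard thresholds, and
per-slice vessel rasters.

Histologic coverage is deliberately narrow — the tumor plus a small
margin and a contralateral reference patch — mirroring studies in which
voxels without histologic data are excluded from all analyses, so the
valid evaluation domain holds tumor and a comparable amount of normal
tissue rather than the whole brain.

Everything is deterministic under the master seed; the manifest records
every parameter and child seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import (
    MODALITIES,
    BinaryMask,
    ParameterVolume,
    VoxelGeometry,
    write_mask,
    write_raster,
    write_volume,
)
from .histology import HistologyStack, StainSection
from .reference import build_contralateral_mask

#: Signed default tumor-core effect sizes in contralateral-SD units.
#: Signs follow the abnormality directions: enhancement, prolonged T1 and
#: elevated ADC go up; T2, CBV and CBF go down.
DEFAULT_EFFECTS_SD = {
    "postgd_t1w": 3.0,
    "t1_time": 2.5,
    "t2_time": -2.5,
    "cbv": -2.5,
    "cbf": -2.5,
    "adc": 2.5,
}

#: Modality means/SDs in physical units (rodent brain at high field).
DEFAULT_NORMAL_PARAMS = {
    "postgd_t1w": (100.0, 10.0),  # a.u.
    "t1_time": (1.8, 0.12),  # s
    "t2_time": (0.045, 0.003),  # s
    "cbv": (3.0, 0.4),  # %
    "cbf": (120.0, 18.0),  # mL/100 g/min
    "adc": (0.75, 0.07),  # um^2/ms
}

_REQUIRED_SIGN = {
    "postgd_t1w": +1,
    "t1_time": +1,
    "t2_time": -1,
    "cbv": -1,
    "cbf": -1,
    "adc": 0,  # either direction
}


class PhantomSpecError(ValueError):
    """The phantom specification is internally inconsistent."""


@dataclass(frozen=True)
class ObserverModel:
    n_observers: int = 4
    erosion_radius_px: int = 1  # in-plane erosion (observers under-draw)
    jitter_prob: float = 0.1  # per boundary voxel flip probability

    def __post_init__(self) -> None:
        if not 0 <= self.jitter_prob <= 1:
            raise PhantomSpecError("jitter_prob must be a probability")


@dataclass(frozen=True)
class HistologyModel:
    sections_per_slice: int = 5
    section_spacing_um: float = 200.0
    pixel_size_um: float = 50.0
    #: percent staining by (stain, region); regions are normal/rim/core
    stain_levels_pct: tuple = (
        ("epcam", (0.0, 2.0, 20.0)),
        ("pimonidazole", (0.2, 3.0, 15.0)),
        ("cresyl_violet", (25.0, 40.0, 60.0)),
    )
    missing_blobs_per_section: float = 1.0  # Poisson mean
    missing_blob_radius_px: tuple[int, int] = (3, 8)


@dataclass(frozen=True)
class VesselModel:
    pixel_size_um: float = 10.0
    #: tube density per mm² of tissue, by region
    density_per_mm2: tuple = (("normal", 6.0), ("rim", 3.0), ("core", 2.0))
    #: tube width range in px, by region (rim/core vessels are dilated)
    width_px: tuple = (("normal", (2, 3)), ("rim", (4, 7)), ("core", (5, 9)))
    length_px: tuple[int, int] = (8, 30)
    speckles_per_slice: int = 30


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of one synthetic study."""

    geometry: VoxelGeometry = VoxelGeometry(0.5, 1.0, (64, 64, 10))
    normal_params: tuple = tuple(sorted(DEFAULT_NORMAL_PARAMS.items()))
    midline_column: int = 32
    tumor_side: str = "left"
    brain_inplane_radii: tuple[float, float] = (29.0, 26.0)
    ventricle_radii: tuple[float, float, float] = (2.5, 2.5, 2.0)
    core_center: tuple[float, float, float] | None = (32.0, 18.0, 5.0)
    core_radii: tuple[float, float, float] = (6.0, 4.0, 3.0)
    rim_thickness_vox: float = 1.0
    effects_sd: tuple = tuple(sorted(DEFAULT_EFFECTS_SD.items()))
    rim_attenuation: float = 0.6
    noise_scale: float = 1.0
    coverage_margin_vox: float = 1.0
    patch_center: tuple[float, float, float] = (32.0, 46.0, 5.0)
    patch_radii: tuple[float, float, float] = (6.0, 6.0, 3.0)
    observer_model: ObserverModel = ObserverModel()
    histology_model: HistologyModel = HistologyModel()
    vessel_model: VesselModel = VesselModel()
    include_histology: bool = True
    include_vessels: bool = True

    def __post_init__(self) -> None:
        for modality, effect in dict(self.effects_sd).items():
            want = _REQUIRED_SIGN[modality]
            if want and effect and np.sign(effect) != want:
                raise PhantomSpecError(
                    f"{modality}: effect sign {np.sign(effect):+.0f} contradicts "
                    f"its abnormality direction"
                )
        if not 0 <= self.rim_attenuation <= 1:
            raise PhantomSpecError("rim_attenuation must be in [0, 1]")
        if self.noise_scale < 0:
            raise PhantomSpecError("noise_scale must be >= 0")

    @property
    def normal(self) -> dict[str, tuple[float, float]]:
        return dict(self.normal_params)

    @property
    def effects(self) -> dict[str, float]:
        return dict(self.effects_sd)

    def without_tumor(self) -> "PhantomSpec":
        """A pure-noise variant: no tumor, no histology or vessels."""
        return replace(
            self, core_center=None, include_histology=False, include_vessels=False
        )

    def noiseless(self) -> "PhantomSpec":
        return replace(self, noise_scale=0.0)


@dataclass
class Phantom:
    """One generated study: volumes, masks, histology, vessels, manifest."""

    spec: PhantomSpec
    seed: int
    volumes: dict[str, ParameterVolume]
    brain_mask: BinaryMask
    ventricle_mask: BinaryMask
    contralateral_mask: BinaryMask
    core_mask: BinaryMask
    rim_mask: BinaryMask
    truth_mask: BinaryMask  # core ∪ rim: the generator's ground truth
    observer_masks: list[BinaryMask]
    coverage_target: BinaryMask
    histology: dict[str, HistologyStack]
    vessel_rasters: dict[int, np.ndarray]
    vessel_tables: dict[int, pd.DataFrame]
    manifest: dict

    @property
    def geometry(self) -> VoxelGeometry:
        return self.spec.geometry


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def _inplane_structure(radius: int) -> np.ndarray:
    d = 2 * radius + 1
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    disk = (x * x + y * y) <= radius * radius
    return disk[:, :, None]


def _make_masks(spec: PhantomSpec):
    shape = spec.geometry.grid_shape
    n_rows, n_cols, n_slices = shape
    center_rc = ((n_rows - 1) / 2.0, (n_cols - 1) / 2.0)
    rows = np.arange(n_rows, dtype=float)[:, None]
    cols = np.arange(n_cols, dtype=float)[None, :]
    ellipse = (
        ((rows - center_rc[0]) / spec.brain_inplane_radii[0]) ** 2
        + ((cols - center_rc[1]) / spec.brain_inplane_radii[1]) ** 2
    ) <= 1.0
    brain = np.repeat(ellipse[:, :, None], n_slices, axis=2)

    mid_z = (n_slices - 1) / 2.0
    vent = np.zeros(shape, bool)
    for dc in (-8, 8):  # paired ventricles flanking the midline
        vent |= _ellipsoid(
            shape,
            (center_rc[0], spec.midline_column + dc, mid_z),
            spec.ventricle_radii,
        )
    vent &= brain

    if spec.core_center is not None:
        core = _ellipsoid(shape, spec.core_center, spec.core_radii) & brain
        dist = ndimage.distance_transform_edt(~core)
        rim = (dist <= spec.rim_thickness_vox) & ~core & brain
    else:
        core = np.zeros(shape, bool)
        rim = np.zeros(shape, bool)
    truth = core | rim

    cols3 = np.arange(n_cols)[None, :, None]
    contra_side = cols3 > spec.midline_column if spec.tumor_side == "left" else cols3 < spec.midline_column
    if (truth & contra_side).any():
        raise PhantomSpecError("tumor overlaps the contralateral region")
    return brain, vent, core, rim, truth


def _generate_volumes(spec: PhantomSpec, core, rim, rng) -> dict[str, ParameterVolume]:
    shape = spec.geometry.grid_shape
    shift = {
        m: spec.effects.get(m, 0.0) * (core + spec.rim_attenuation * rim)
        for m in MODALITIES
    }
    volumes = {}
    for modality in MODALITIES:
        mean, sd = spec.normal[modality]
        noise = rng.standard_normal(shape) * spec.noise_scale
        values = mean + sd * (shift[modality] + noise)
        volumes[modality] = ParameterVolume(
            modality=modality, values=values, geometry=spec.geometry
        )
    return volumes


def _generate_observers(spec: PhantomSpec, core, brain, rng) -> list[BinaryMask]:
    om = spec.observer_model
    masks = []
    for _ in range(om.n_observers):
        base = core
        if om.erosion_radius_px > 0:
            base = ndimage.binary_erosion(
                core, structure=_inplane_structure(om.erosion_radius_px)
            )
        shell = ndimage.binary_dilation(base, structure=_inplane_structure(1)) & ~(
            ndimage.binary_erosion(base, structure=_inplane_structure(1))
        )
        flips = shell & (rng.random(core.shape) < om.jitter_prob)
        masks.append(
            BinaryMask((base ^ flips) & brain, spec.geometry, label="observer")
        )
    return masks


def _coverage_target(spec: PhantomSpec, truth, brain) -> np.ndarray:
    cov = np.zeros(spec.geometry.grid_shape, bool)
    if truth.any():
        dist = ndimage.distance_transform_edt(~truth)
        cov |= dist <= spec.coverage_margin_vox
    cov |= _ellipsoid(spec.geometry.grid_shape, spec.patch_center, spec.patch_radii)
    return cov & brain


def _generate_histology(
    spec: PhantomSpec, core, rim, coverage, rng
) -> dict[str, HistologyStack]:
    hm = spec.histology_model
    geom = spec.geometry
    px = geom.in_plane_spacing * 1000.0 / hm.pixel_size_um
    if abs(px - round(px)) > 1e-9:
        raise PhantomSpecError("voxel edge must be an integer number of pixels")
    px = int(round(px))
    thickness_um = geom.slice_thickness * 1000.0
    region = np.zeros(geom.grid_shape, np.int8)
    region[rim] = 1
    region[core] = 2
    covered_slices = [z for z in range(geom.grid_shape[2]) if coverage[:, :, z].any()]

    stacks: dict[str, HistologyStack] = {}
    for stain, levels in hm.stain_levels_pct:
        sections = []
        for z in covered_slices:
            region_px = np.repeat(np.repeat(region[:, :, z], px, 0), px, 1)
            cover_px = np.repeat(np.repeat(coverage[:, :, z], px, 0), px, 1)
            p_map = np.asarray(levels, float)[region_px] / 100.0
            offset = (thickness_um - (hm.sections_per_slice - 1) * hm.section_spacing_um) / 2.0
            for i in range(hm.sections_per_slice):
                tissue = cover_px.copy()
                n_blobs = rng.poisson(hm.missing_blobs_per_section)
                for _ in range(n_blobs):
                    r0 = rng.integers(0, tissue.shape[0])
                    c0 = rng.integers(0, tissue.shape[1])
                    rad = rng.integers(*hm.missing_blob_radius_px)
                    rr, cc = np.ogrid[: tissue.shape[0], : tissue.shape[1]]
                    tissue[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = False
                binary = (rng.random(tissue.shape) < p_map) & tissue
                sections.append(
                    StainSection(
                        stain=stain,
                        binary_mask=binary,
                        pixel_size_um=hm.pixel_size_um,
                        position_um=z * thickness_um + offset + i * hm.section_spacing_um,
                        tissue_mask=tissue,
                    )
                )
        stacks[stain] = HistologyStack(
            sections=sections,
            target_geometry=geom,
            section_spacing_um=hm.section_spacing_um,
        )
    return stacks


def generate_vessel_raster(
    shape: tuple[int, int],
    n_tubes: int,
    width_range: tuple[int, int],
    length_range: tuple[int, int],
    rng: np.random.Generator,
    rotated_fraction: float = 0.0,
    n_speckles: int = 0,
    allowed: np.ndarray | None = None,
    max_retries: int = 50,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Binary raster of rectangular tubes plus sub-threshold speckle noise.

    Tubes are placed without overlap (bounded retries; placements that
    keep failing are skipped). Speckles are 1–4 px components, below the
    5 px size-filter cut. The returned table lists each tube's position,
    width, length, angle and painted pixel count.
    """
    from skimage.draw import polygon

    gap = 2  # empty pixels kept between placed entities
    mask = np.zeros(shape, bool)
    occupied = np.zeros(shape, bool)
    rows = []

    def try_place(local: np.ndarray, r0: int, c0: int) -> bool:
        """Place a local footprint at (r0, c0) if it fits and is free."""
        h, w_ = local.shape
        if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w_ > shape[1]:
            return False
        rlo, clo = max(0, r0 - gap), max(0, c0 - gap)
        rhi, chi = min(shape[0], r0 + h + gap), min(shape[1], c0 + w_ + gap)
        if occupied[rlo:rhi, clo:chi].any():
            return False
        view = (slice(r0, r0 + h), slice(c0, c0 + w_))
        if allowed is not None and (local & ~allowed[view]).any():
            return False
        mask[view] |= local
        occupied[rlo:rhi, clo:chi] = True
        return True

    for _ in range(n_tubes):
        for _attempt in range(max_retries):
            w = int(rng.integers(width_range[0], width_range[1] + 1))
            ln = int(rng.integers(length_range[0], length_range[1] + 1))
            angle = 0.0
            if rng.random() < rotated_fraction:
                angle = float(rng.uniform(0.0, 180.0))
            if angle == 0.0:
                h, wd = (w, ln) if rng.random() < 0.5 else (ln, w)
                local = np.ones((h, wd), bool)
            else:
                theta = np.deg2rad(angle)
                d = np.array([np.cos(theta), np.sin(theta)])
                nv = np.array([-d[1], d[0]])
                cr = np.array([ln / 2.0, ln / 2.0])
                half = (ln / 2.0) * d
                corners = [
                    cr - half - (w / 2.0) * nv,
                    cr - half + (w / 2.0) * nv,
                    cr + half + (w / 2.0) * nv,
                    cr + half - (w / 2.0) * nv,
                ]
                rr, cc = polygon(
                    [p[0] for p in corners], [p[1] for p in corners], shape=(ln + 1, ln + 1)
                )
                if len(rr) == 0:
                    continue
                local = np.zeros((ln + 1, ln + 1), bool)
                local[rr, cc] = True
                # trim to tight bbox
                nz = np.nonzero(local)
                local = local[nz[0].min() : nz[0].max() + 1, nz[1].min() : nz[1].max() + 1]
            r0 = int(rng.integers(0, max(1, shape[0] - local.shape[0])))
            c0 = int(rng.integers(0, max(1, shape[1] - local.shape[1])))
            if try_place(local, r0, c0):
                fr, fc = np.nonzero(local)
                rows.append(
                    {
                        "row": float(fr.mean() + r0),
                        "col": float(fc.mean() + c0),
                        "width_px": w,
                        "length_px": ln,
                        "angle_deg": angle,
                        "pixel_count": int(local.sum()),
                    }
                )
                break
    for _ in range(n_speckles):
        n_px = int(rng.integers(1, 5))
        local = np.zeros((3, 3), bool)
        local[1, 1] = True
        for _k in range(n_px - 1):
            rr, cc = np.nonzero(local)
            i = rng.integers(len(rr))
            dr, dc = rng.integers(-1, 2, size=2)
            local[int(np.clip(rr[i] + dr, 0, 2)), int(np.clip(cc[i] + dc, 0, 2))] = True
        r0 = int(rng.integers(0, shape[0] - 3))
        c0 = int(rng.integers(0, shape[1] - 3))
        try_place(local, r0, c0)
    return mask, pd.DataFrame(rows)


def _generate_vessels(spec: PhantomSpec, core, rim, coverage, rng):
    vm = spec.vessel_model
    geom = spec.geometry
    px = int(round(geom.in_plane_spacing * 1000.0 / vm.pixel_size_um))
    density = dict(vm.density_per_mm2)
    widths = dict(vm.width_px)
    rasters: dict[int, np.ndarray] = {}
    tables: dict[int, pd.DataFrame] = {}
    region = np.zeros(geom.grid_shape, np.int8)
    region[rim] = 1
    region[core] = 2
    region_names = {0: "normal", 1: "rim", 2: "core"}
    for z in range(geom.grid_shape[2]):
        if not coverage[:, :, z].any():
            continue
        shape_px = (geom.grid_shape[0] * px, geom.grid_shape[1] * px)
        mask = np.zeros(shape_px, bool)
        parts = []
        for code, name in region_names.items():
            sel = (region[:, :, z] == code) & coverage[:, :, z]
            if not sel.any():
                continue
            area_mm2 = sel.sum() * geom.in_plane_spacing**2
            n_tubes = max(0, int(round(density[name] * area_mm2)))
            allowed = np.repeat(np.repeat(sel, px, 0), px, 1)
            m, tab = generate_vessel_raster(
                shape_px,
                n_tubes,
                widths[name],
                vm.length_px,
                rng,
                rotated_fraction=0.3,
                allowed=allowed,
            )
            tab["region"] = name
            mask |= m
            parts.append(tab)
        sp_mask, _ = generate_vessel_raster(
            shape_px, 0, (1, 1), (1, 1), rng, n_speckles=vm.speckles_per_slice
        )
        mask |= sp_mask
        rasters[z] = mask
        tables[z] = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    return rasters, tables


def generate_phantom(spec: PhantomSpec, seed: int) -> Phantom:
    """Generate one fully deterministic synthetic study."""
    master = np.random.default_rng(seed)
    child_seeds = {
        name: int(master.integers(2**31))
        for name in ("volumes", "observers", "histology", "vessels")
    }
    brain, vent, core, rim, truth = _make_masks(spec)
    geom = spec.geometry
    brain_mask = BinaryMask(brain, geom, label="brain")
    vent_mask = BinaryMask(vent, geom, label="ventricles")
    contra = build_contralateral_mask(
        brain_mask, spec.midline_column, spec.tumor_side, vent_mask
    )
    volumes = _generate_volumes(
        spec, core, rim, np.random.default_rng(child_seeds["volumes"])
    )
    observers = (
        _generate_observers(
            spec, core, brain, np.random.default_rng(child_seeds["observers"])
        )
        if core.any()
        else []
    )
    coverage = _coverage_target(spec, truth, brain)
    histology = (
        _generate_histology(
            spec, core, rim, coverage, np.random.default_rng(child_seeds["histology"])
        )
        if spec.include_histology
        else {}
    )
    vessels, vtables = (
        _generate_vessels(
            spec, core, rim, coverage, np.random.default_rng(child_seeds["vessels"])
        )
        if spec.include_vessels
        else ({}, {})
    )
    manifest = {
        "seed": seed,
        "child_seeds": child_seeds,
        "spec": asdict(spec),
        "n_core_voxels": int(core.sum()),
        "n_rim_voxels": int(rim.sum()),
        "n_truth_voxels": int(truth.sum()),
    }
    return Phantom(
        spec=spec,
        seed=seed,
        volumes=volumes,
        brain_mask=brain_mask,
        ventricle_mask=vent_mask,
        contralateral_mask=contra,
        core_mask=BinaryMask(core, geom, label="core"),
        rim_mask=BinaryMask(rim, geom, label="rim"),
        truth_mask=BinaryMask(truth, geom, label="truth"),
        observer_masks=observers,
        coverage_target=BinaryMask(coverage, geom, label="coverage"),
        histology=histology,
        vessel_rasters=vessels,
        vessel_tables=vtables,
        manifest=manifest,
    )


def write_phantom(phantom: Phantom, outdir: str | Path) -> None:
    """Write a phantom to disk: NIfTI volumes/masks, TIFF rasters, manifest."""
    import json

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for modality, vol in phantom.volumes.items():
        write_volume(vol, out / f"{modality}.nii.gz")
    for name in (
        "brain_mask",
        "ventricle_mask",
        "contralateral_mask",
        "core_mask",
        "rim_mask",
        "truth_mask",
        "coverage_target",
    ):
        write_mask(getattr(phantom, name), out / f"{name}.nii.gz")
    for i, obs in enumerate(phantom.observer_masks, start=1):
        write_mask(obs, out / f"observer_{i}.nii.gz")
    for stain, stack in phantom.histology.items():
        for j, sec in enumerate(stack.sections):
            write_raster(sec.binary_mask, out / f"{stain}_{j:03d}.tif")
            write_raster(sec.tissue_mask, out / f"{stain}_{j:03d}_tissue.tif")
    for z, raster in phantom.vessel_rasters.items():
        write_raster(raster, out / f"collagen_iv_z{z:02d}.tif")
        phantom.vessel_tables[z].to_csv(out / f"vessels_z{z:02d}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(phantom.manifest, fh, indent=2, default=str)
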