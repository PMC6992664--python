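"""Final chronic-lesion mask assembly and the end-to-end segmentation pipeline.

Two candidate masks are fused: (1) an intensity-driven mask from a
lesion-sensitive MFMC pass with the non-lesion maps subtracted and
paraventricular midline-crossing clusters removed, and (2) an anomaly-driven
mask from thresholding the zeta map outside sulci and ventricles. Their union
is regularised against the slice-wise watershed partition of the CT image
(whole regions kept at >= 50% occupancy) and cleaned of small clusters and of
large single-slice clusters (typically streak or partial-volume artefacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage as ndi

from .mfmc import MFMCConfig, binarize, mfmc_cluster
from .preprocess import PreprocessConfig, clamp_and_strip, csf_contrast_transform, tophat_healthy_map, tv_denoise
from .region_maps import (
    LabelPartition,
    NonLesionMaps,
    cluster_by_watershed,
    sulci_map,
    ventricle_map,
    watershed_partition,
)
from .volume_io import AXIAL_AXIS, LR_AXIS, BinaryMask, CTVolume, GridSpec, _check_lattice, resample_to_grid
from .zeta import ReferenceCohort, ZetaConfig, ZetaMap, calibrate_zeta_threshold, zeta_map, zeta_mask

__all__ = [
    "LesionConfig",
    "LesionResult",
    "candidate_lesion_map",
    "subtract_nonlesion",
    "remove_paraventricular",
    "combine_masks",
    "denoise_clusters",
    "segment_chronic_lesions",
]


@dataclass
class LesionConfig:
    """Constants of the mask-assembly stages.

    ``lesion_guides`` place two MFMC classes in the encephalomalacia/gliosis
    intensity range and the highest at normal parenchyma; the candidate map is
    the union of all classes below the parenchyma guide. Sizes are voxel
    counts on the native grid.
    """

    lesion_guides: tuple[float, ...] = (10.0, 20.0, 34.0)
    occupancy: float = 0.5
    min_cluster_voxels: int = 5
    single_plane_max_voxels: int = 100
    paraventricular_margin_mm: float = 4.0
    analysis_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self) -> None:
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must lie in (0, 1]")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")


@dataclass
class LesionResult:
    """Native-grid lesion mask plus the coarse analysis-grid representations."""

    mask: BinaryMask
    mask_mni4: BinaryMask
    zeta_mni4: ZetaMap
    volume_ml: float
    provenance: list[dict[str, Any]] = field(default_factory=list)


def candidate_lesion_map(
    tv_vol: CTVolume,
    domain: BinaryMask,
    cfg: LesionConfig | None = None,
    mfmc_cfg: MFMCConfig | None = None,
    provenance: list | None = None,
) -> BinaryMask:
    """Lesion-sensitive MFMC pass: union of all sub-parenchymal classes."""
    cfg = cfg or LesionConfig()
    mcfg = mfmc_cfg or MFMCConfig(guide_values=cfg.lesion_guides)
    maps = mfmc_cluster(tv_vol, domain, mcfg, provenance)
    top = max(mcfg.guide_values)
    out = np.zeros(tv_vol.shape, dtype=bool)
    for g in mcfg.guide_values:
        if g < top:
            out |= binarize(maps, g, mcfg).data
    return BinaryMask(out, tv_vol.spacing)


def subtract_nonlesion(candidate: BinaryMask, maps: NonLesionMaps) -> BinaryMask:
    """Set difference: candidate minus (healthy | sulci | ventricles)."""
    _check_lattice(candidate, maps.healthy, "subtract_nonlesion")
    return BinaryMask(candidate.data & ~maps.union().data, candidate.spacing)


def remove_paraventricular(
    mask: BinaryMask,
    ventricles: BinaryMask,
    vol: CTVolume,
    cfg: LesionConfig | None = None,
) -> BinaryMask:
    """Drop clusters hugging the medial ventricular wall that cross the midline.

    A connected component (26-connectivity) is removed when (a) some of its
    voxels lie within the paraventricular margin of the ventricle mask on the
    medial side — closer to the mid-sagittal plane than the nearest ventricle
    voxel — and (b) the component has voxels in both hemispheres.
    """
    cfg = cfg or LesionConfig()
    _check_lattice(mask, ventricles, "remove_paraventricular")
    if not mask.data.any() or not ventricles.data.any():
        return mask
    dist, nearest = ndi.distance_transform_edt(
        ~ventricles.data, sampling=vol.spacing, return_indices=True
    )
    near = dist <= cfg.paraventricular_margin_mm
    mid = vol.midsagittal_index
    lr = np.arange(mask.shape[LR_AXIS])[:, None, None]
    own_off = np.abs(np.broadcast_to(lr, mask.shape) - mid)
    vent_off = np.abs(nearest[LR_AXIS] - mid)
    medial_zone = near & (own_off < vent_off)

    comp, ncomp = ndi.label(mask.data, structure=np.ones((3, 3, 3)))
    if ncomp == 0:
        return mask
    drop = np.zeros(ncomp + 1, dtype=bool)
    touches = np.unique(comp[medial_zone & (comp > 0)])
    lr_idx = np.broadcast_to(lr, mask.shape)
    for c in touches:
        sel = comp == c
        cols = lr_idx[sel]
        if cols.min() < mid and cols.max() > mid:
            drop[c] = True
    return BinaryMask(mask.data & ~drop[comp], mask.spacing)


def combine_masks(
    m1: BinaryMask,
    m2: BinaryMask,
    vol: CTVolume,
    cfg: LesionConfig | None = None,
    domain: BinaryMask | None = None,
    part: "LabelPartition | None" = None,
) -> BinaryMask:
    """Union of the two lesion masks, watershed-regularised at the occupancy rule."""
    cfg = cfg or LesionConfig()
    _check_lattice(m1, m2, "combine_masks")
    union = BinaryMask(m1.data | m2.data, m1.spacing)
    if part is None:
        dom = domain if domain is not None else BinaryMask(np.ones(vol.shape, bool), vol.spacing)
        part = watershed_partition(vol, dom)
    return cluster_by_watershed(union, part, cfg.occupancy)


def denoise_clusters(mask: BinaryMask, cfg: LesionConfig | None = None) -> BinaryMask:
    """Remove small clusters and large clusters confined to one axial plane."""
    cfg = cfg or LesionConfig()
    comp, ncomp = ndi.label(mask.data, structure=np.ones((3, 3, 3)))
    if ncomp == 0:
        return mask
    keep = np.zeros(ncomp + 1, dtype=bool)
    sizes = np.bincount(comp.ravel(), minlength=ncomp + 1)
    ax = np.indices(mask.shape)[AXIAL_AXIS]
    for c in range(1, ncomp + 1):
        if sizes[c] < cfg.min_cluster_voxels:
            continue
        planes = np.unique(ax[comp == c])
        if planes.size == 1 and sizes[c] > cfg.single_plane_max_voxels:
            continue
        keep[c] = True
    return BinaryMask(keep[comp], mask.spacing)


def segment_chronic_lesions(
    vol: CTVolume,
    cohort: ReferenceCohort,
    pre_cfg: PreprocessConfig | None = None,
    lesion_cfg: LesionConfig | None = None,
    zeta_cfg: ZetaConfig | None = None,
    sulci_cfg: MFMCConfig | None = None,
    ventricle_cfg: MFMCConfig | None = None,
    lesion_mfmc_cfg: MFMCConfig | None = None,
) -> LesionResult:
    """Run the full chronic-lesion segmentation pipeline on one volume.

    Stages: clamp/bone-strip -> CSF contrast transform -> TV denoise ->
    non-lesion maps (top-hat healthy, MFMC sulci, MFMC+symmetry ventricles) ->
    lesion-sensitive candidate map -> subtraction and paraventricular removal
    (mask 1) -> zeta map vs the cohort -> threshold outside sulci/ventricles
    (mask 2) -> watershed-regularised union -> cluster denoising. The cohort
    receives the identical intensity conditioning before zeta scoring. An
    empty final mask is a valid outcome (lesion-free scan).
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    lesion_cfg = lesion_cfg or LesionConfig()
    zeta_cfg = zeta_cfg or ZetaConfig()
    prov: list[dict[str, Any]] = []

    def log(stage: str, **info):
        prov.append({"stage": stage, **info})

    try:
        clamped, domain = clamp_and_strip(vol, pre_cfg)
        log("clamp_and_strip", domain_voxels=domain.count())
        transformed = csf_contrast_transform(clamped, pre_cfg)
        log("csf_contrast_transform")
        tv = tv_denoise(transformed, pre_cfg, domain, prov)

        healthy = tophat_healthy_map(tv, pre_cfg)
        healthy = BinaryMask(healthy.data & domain.data, healthy.spacing)
        log("tophat_healthy_map", voxels=healthy.count())
        sul = sulci_map(tv, domain, sulci_cfg, prov)
        log("sulci_map", voxels=sul.count())
        vent = ventricle_map(tv, domain, vol, ventricle_cfg, prov)
        log("ventricle_map", voxels=vent.count())
        # regularise each non-lesion map to whole watershed regions
        part = watershed_partition(transformed, domain)
        healthy = cluster_by_watershed(healthy, part, lesion_cfg.occupancy)
        sul_c = cluster_by_watershed(sul, part, lesion_cfg.occupancy)
        vent_c = cluster_by_watershed(vent, part, lesion_cfg.occupancy)
        log("cluster_nonlesion_maps", healthy=healthy.count(), sulci=sul_c.count(), ventricles=vent_c.count())
        nonlesion = NonLesionMaps(healthy=healthy, sulci=sul_c, ventricles=vent_c)

        candidate = candidate_lesion_map(tv, domain, lesion_cfg, lesion_mfmc_cfg, prov)
        log("candidate_lesion_map", voxels=candidate.count())
        mask1 = subtract_nonlesion(candidate, nonlesion)
        mask1 = remove_paraventricular(mask1, vent_c, vol, lesion_cfg)
        log("mask1", voxels=mask1.count())

        cohort_tv = ReferenceCohort(
            [
                tv_denoise(csf_contrast_transform(clamp_and_strip(v, pre_cfg)[0], pre_cfg), pre_cfg)
                for v in cohort.volumes
            ]
        )
        zmap = zeta_map(tv, cohort_tv, domain, zeta_cfg)
        thr = (
            zeta_cfg.zeta_threshold
            if zeta_cfg.zeta_threshold is not None
            else calibrate_zeta_threshold(cohort_tv, domain, zeta_cfg)
        )
        log("zeta_map", threshold=thr)
        mask2 = zeta_mask(zmap, sul_c, vent_c, zeta_cfg, threshold=thr)
        log("mask2", voxels=mask2.count())

        combined = combine_masks(mask1, mask2, transformed, lesion_cfg, domain, part=part)
        log("combine_masks", voxels=combined.count())
        final = denoise_clusters(combined, lesion_cfg)
        final = BinaryMask(final.data & domain.data, final.spacing)
        log("denoise_clusters", voxels=final.count())
    except Exception as err:
        stage = prov[-1]["stage"] if prov else "init"
        raise RuntimeError(f"segmentation failed after stage '{stage}': {err}") from err

    grid = GridSpec(shape=None, spacing=lesion_cfg.analysis_spacing)
    mask4 = resample_to_grid(final, grid)
    z4 = resample_to_grid(CTVolume(zmap.data, vol.spacing), grid)
    volume_ml = final.volume_ml()
    log("result", volume_ml=volume_ml)
    return LesionResult(
        mask=final,
        mask_mni4=mask4,
        zeta_mni4=ZetaMap(z4.data, z4.spacing, zeta_cfg),
        volume_ml=volume_ml,
        provenance=prov,
    )
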