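"""Non-lesion maps (healthy tissue, sulci, ventricles) and watershed clustering.

The sulci and ventricle maps come from MFMC clustering of the denoised image
at fixed guide intensities (14/24/34 HU for the three-class sulci pass,
20/27 HU for the two-class ventricle pass). Ventricles additionally pass a
mirror-congruence filter: the ventricular system is symmetric about the
mid-sagittal plane, so unilateral hypodensities at ventricle-like intensity
(typically chronic lesions) are rejected. Cluster-level operations use a
slice-wise 2-D watershed of the in-plane gradient magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import h_minima
from skimage.segmentation import watershed

from .mfmc import MFMCConfig, binarize, mfmc_cluster
from .volume_io import AXIAL_AXIS, BinaryMask, CTVolume, _check_lattice, mirror_lr

__all__ = [
    "LabelPartition",
    "NonLesionMaps",
    "sulci_map",
    "ventricle_map",
    "symmetry_filter",
    "watershed_partition",
    "cluster_by_watershed",
    "SULCI_GUIDES",
    "VENTRICLE_GUIDES",
]

#: Guide intensities (HU) for the three-class sulci clustering.
SULCI_GUIDES = (14.0, 24.0, 34.0)
#: Guide intensities (HU) for the two-class ventricle clustering.
VENTRICLE_GUIDES = (20.0, 27.0)


@dataclass
class LabelPartition:
    """Slice-wise region labels: 0 outside the domain, positive ids per slice."""

    labels: np.ndarray
    per_slice: bool = True
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class NonLesionMaps:
    healthy: BinaryMask
    sulci: BinaryMask
    ventricles: BinaryMask

    def union(self) -> BinaryMask:
        return BinaryMask(
            self.healthy.data | self.sulci.data | self.ventricles.data, self.healthy.spacing
        )


def sulci_map(
    tv_vol: CTVolume,
    domain: BinaryMask,
    cfg: MFMCConfig | None = None,
    provenance: list | None = None,
) -> BinaryMask:
    """Binarized lowest-guide (14 HU) class of the three-class clustering."""
    cfg = cfg or MFMCConfig(guide_values=SULCI_GUIDES)
    maps = mfmc_cluster(tv_vol, domain, cfg, provenance)
    return binarize(maps, min(cfg.guide_values), cfg)


def ventricle_map(
    tv_vol: CTVolume,
    domain: BinaryMask,
    vol: CTVolume,
    cfg: MFMCConfig | None = None,
    provenance: list | None = None,
) -> BinaryMask:
    """Binarized lower-guide (20 HU) class of the two-class clustering,
    mirror-congruence filtered about the mid-sagittal plane of ``vol``."""
    cfg = cfg or MFMCConfig(guide_values=VENTRICLE_GUIDES)
    maps = mfmc_cluster(tv_vol, domain, cfg, provenance)
    raw = binarize(maps, min(cfg.guide_values), cfg)
    return symmetry_filter(raw, vol)


def symmetry_filter(mask: BinaryMask, vol: CTVolume) -> BinaryMask:
    """Keep a voxel only if its mirror-pair is inside the grid and also set.

    The output is mirror-symmetric and the operation is idempotent.
    """
    _check_lattice(mask, vol, "symmetry_filter")
    mirrored = mirror_lr(mask.data, vol.midsagittal_index)
    return BinaryMask(mask.data & mirrored, mask.spacing)


def watershed_partition(
    vol: CTVolume,
    domain: BinaryMask,
    h: float = 1.0,
) -> LabelPartition:
    """Slice-wise 2-D watershed of the in-plane gradient magnitude.

    Each axial slice is partitioned independently; seeds are the regional
    minima of the gradient image after h-minima suppression (depth ``h`` HU,
    about half the expected CT noise amplitude) so pure-noise basins merge
    while genuine tissue boundaries keep their own catchments. Region ids are positive and
    contiguous within each slice; 0 marks out-of-domain voxels.
    """
    _check_lattice(vol, domain, "watershed_partition")
    labels = np.zeros(vol.shape, dtype=np.int32)
    for k in range(vol.shape[AXIAL_AXIS]):
        sl = vol.data[:, :, k]
        dm = domain.data[:, :, k]
        if not dm.any():
            continue
        gx, gy = np.gradient(sl, vol.spacing[0], vol.spacing[1])
        grad = np.sqrt(gx * gx + gy * gy)
        suppressed = h_minima(grad, h) if h > 0 else None
        if suppressed is not None and suppressed.any():
            markers, _ = ndi.label(suppressed)
        else:
            markers = None
        lab = watershed(grad, markers=markers, mask=dm)
        # watershed may leave mask voxels unreached when markers fall outside
        # the domain; assign them to the nearest labelled region
        missing = dm & (lab == 0)
        if missing.any():
            filled = watershed(grad, markers=lab, mask=dm)
            lab = np.where(dm, filled, 0)
            still = dm & (lab == 0)
            if still.any():
                extra, _ = ndi.label(still)
                lab = np.where(still, extra + lab.max(), lab)
        # contiguous ids per slice
        ids = np.unique(lab[lab > 0])
        remap = np.zeros(int(lab.max()) + 1, dtype=np.int32)
        remap[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
        labels[:, :, k] = remap[lab]
    return LabelPartition(labels=labels, per_slice=True, spacing=vol.spacing)


def cluster_by_watershed(
    mask: BinaryMask,
    part: LabelPartition,
    occupancy: float = 0.5,
) -> BinaryMask:
    """Keep or drop whole watershed regions by occupancy.

    A region is kept in full when the fraction of its voxels set in ``mask``
    is at least ``occupancy`` (default 50%); otherwise it is dropped in full.
    """
    if mask.shape != part.shape:
        raise ValueError("mask and partition lattice mismatch")
    out = np.zeros(mask.shape, dtype=bool)
    for k in range(mask.shape[AXIAL_AXIS]):
        lab = part.labels[:, :, k]
        nmax = int(lab.max())
        if nmax == 0:
            continue
        sizes = np.bincount(lab.ravel(), minlength=nmax + 1)
        hits = np.bincount(lab.ravel(), weights=mask.data[:, :, k].ravel(), minlength=nmax + 1)
        keep = np.zeros(nmax + 1, dtype=bool)
        nz = sizes > 0
        keep[nz] = hits[nz] / sizes[nz] >= occupancy
        keep[0] = False
        out[:, :, k] = keep[lab]
    return BinaryMask(out, mask.spacing)
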