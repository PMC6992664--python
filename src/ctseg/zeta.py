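"""Nonparametric zeta anomaly scoring against a lesion-free reference cohort.

For a feature vector x and reference vectors r_1..r_n, the zeta score is the
mean distance from x to its k nearest references minus the mean pairwise
distance among those k neighbours. A point inside a tight cluster scores near
zero (possibly negative); a point far from the cohort scores high. Applied
voxel-wise with intensity-patch features, this indexes each location of a
test brain by how abnormal it is relative to the spatially normalised cohort,
picking up both focal lesions and diffuse change such as atrophy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume_io import BinaryMask, CTVolume, _check_lattice

__all__ = [
    "ReferenceCohort",
    "ZetaConfig",
    "ZetaMap",
    "zeta_score",
    "zeta_map",
    "zeta_mask",
    "calibrate_zeta_threshold",
]


@dataclass
class ReferenceCohort:
    """Lesion-free volumes on a common lattice."""

    volumes: list[CTVolume]

    def __post_init__(self) -> None:
        if len(self.volumes) < 3:
            raise ValueError("reference cohort needs at least 3 volumes")
        first = self.volumes[0]
        for v in self.volumes[1:]:
            if v.shape != first.shape or not np.allclose(v.spacing, first.spacing):
                raise ValueError("cohort volumes must share shape and spacing")

    @property
    def count(self) -> int:
        return len(self.volumes)

    @property
    def spacing(self):
        return self.volumes[0].spacing

    @property
    def shape(self):
        return self.volumes[0].shape

    def leave_one_out(self, i: int) -> tuple[CTVolume, "ReferenceCohort"]:
        rest = [v for j, v in enumerate(self.volumes) if j != i]
        return self.volumes[i], ReferenceCohort(rest)


@dataclass
class ZetaConfig:
    """Neighbour count, patch geometry and thresholding for the zeta map."""

    k: int = 5
    patch_radius: int = 1
    metric: str = "euclidean"
    zeta_threshold: float | None = None  # None -> cohort-calibrated (99th pct of LOO scores)
    threshold_percentile: float = 99.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("zeta needs at least 2 neighbours")
        if self.patch_radius < 0:
            raise ValueError("patch_radius must be >= 0")
        if self.metric != "euclidean":
            raise ValueError("only the Euclidean patch metric is implemented")


@dataclass
class ZetaMap:
    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    config: ZetaConfig = field(default_factory=ZetaConfig)

    @property
    def shape(self):
        return self.data.shape


def zeta_score(x: np.ndarray, refs: np.ndarray, k: int) -> float:
    """Zeta anomaly score of one feature vector against reference vectors.

    Mean distance from ``x`` to its ``k`` nearest references minus the mean
    pairwise distance among those ``k`` neighbours. May be negative.
    """
    if k < 2:
        raise ValueError("zeta needs at least 2 neighbours")
    refs = np.asarray(refs, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64).ravel()
    if refs.ndim == 1:
        refs = refs[:, None]
        x = x[:1] if x.size == 1 else x
    if k >= refs.shape[0]:
        raise ValueError(f"k={k} must be smaller than the number of references {refs.shape[0]}")
    d = np.sqrt(((refs - x[None, :]) ** 2).sum(axis=1))
    nn = np.argsort(d, kind="stable")[:k]
    to_x = float(d[nn].mean())
    sub = refs[nn]
    pair = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2))
    iu = np.triu_indices(k, 1)
    within = float(pair[iu].mean())
    return to_x - within


def _patch_sq_dist(a: np.ndarray, b: np.ndarray, radius: int) -> np.ndarray:
    """Voxel-wise squared Euclidean distance between intensity patches.

    Box-sums the squared difference over the (2r+1)^3 patch; edges use
    symmetric (reflect) padding, matching ``np.pad(mode='symmetric')``.
    """
    sq = (a - b) ** 2
    if radius == 0:
        return sq
    size = 2 * radius + 1
    return ndi.uniform_filter(sq, size=size, mode="reflect") * size**3


def zeta_map(
    vol: CTVolume,
    cohort: ReferenceCohort,
    domain: BinaryMask,
    cfg: ZetaConfig | None = None,
) -> ZetaMap:
    """Voxel-wise zeta scores of a test volume against the cohort.

    The feature at each voxel is the cubic intensity patch of the configured
    radius; the reference set is the corresponding patch from each cohort
    volume, so anomaly is judged location-by-location.
    """
    cfg = cfg or ZetaConfig()
    if vol.shape != cohort.shape or not np.allclose(vol.spacing, cohort.spacing):
        raise ValueError("test volume and cohort lattice mismatch")
    _check_lattice(vol, domain, "zeta_map")
    n = cohort.count
    k = cfg.k
    if k >= n:
        raise ValueError(f"k={k} requires a cohort larger than k")
    dom = domain.data
    nd = int(dom.sum())

    # distances test -> each reference, restricted to the domain
    d_test = np.empty((n, nd))
    for i, ref in enumerate(cohort.volumes):
        d_test[i] = np.sqrt(_patch_sq_dist(vol.data, ref.data, cfg.patch_radius)[dom])

    # k nearest references per voxel
    nn = np.argsort(d_test, axis=0, kind="stable")[:k]  # [k, nd]
    to_x = np.take_along_axis(d_test, nn, axis=0).mean(axis=0)

    # pairwise distances among cohort members, gathered at the selected pairs
    pair = np.empty((n, n, nd))
    for i in range(n):
        pair[i, i] = 0.0
        for j in range(i + 1, n):
            pij = np.sqrt(
                _patch_sq_dist(cohort.volumes[i].data, cohort.volumes[j].data, cfg.patch_radius)[dom]
            )
            pair[i, j] = pij
            pair[j, i] = pij
    cols = np.arange(nd)
    within = np.zeros(nd)
    npairs = k * (k - 1) // 2
    for a in range(k):
        for b in range(a + 1, k):
            within += pair[nn[a], nn[b], cols]
    within /= npairs

    out = np.zeros(vol.shape)
    out[dom] = to_x - within
    return ZetaMap(out, vol.spacing, cfg)


def calibrate_zeta_threshold(
    cohort: ReferenceCohort,
    domain: BinaryMask,
    cfg: ZetaConfig | None = None,
) -> float:
    """Cohort-calibrated threshold: pooled leave-one-out self-scores' percentile.

    Each cohort member is scored against the remaining members; the threshold
    is the configured percentile (default 99th) of the pooled in-domain
    scores. This fixes the operating point from lesion-free data alone.
    """
    cfg = cfg or ZetaConfig()
    if cohort.count <= cfg.k + 1:
        raise ValueError("cohort too small for leave-one-out calibration at this k")
    pooled = []
    for i in range(cohort.count):
        test, rest = cohort.leave_one_out(i)
        zm = zeta_map(test, rest, domain, cfg)
        pooled.append(zm.data[domain.data])
    return float(np.percentile(np.concatenate(pooled), cfg.threshold_percentile))


def zeta_mask(
    zmap: ZetaMap,
    sulci: BinaryMask,
    ventricles: BinaryMask,
    cfg: ZetaConfig | None = None,
    threshold: float | None = None,
) -> BinaryMask:
    """Threshold the zeta map and subtract the sulci and ventricle maps."""
    cfg = cfg or zmap.config
    thr = threshold if threshold is not None else cfg.zeta_threshold
    if thr is None:
        raise ValueError("zeta threshold not set; pass one or calibrate from the cohort")
    if zmap.shape != sulci.shape or zmap.shape != ventricles.shape:
        raise ValueError("zeta map and non-lesion masks lattice mismatch")
    return BinaryMask((zmap.data >= thr) & ~sulci.data & ~ventricles.data, zmap.spacing)
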