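"""Intensity conditioning of head CT before segmentation.

The stages mirror standard chronic-lesion preprocessing for non-contrast CT:
negative HU values (air, artefact) are clamped to zero, bone is excluded at
100 HU, a monotone window transform stretches the tissue-CSF band, the result
is denoised with a total-variation (ROF) model, and a morphological white
top-hat flags locally bright healthy parenchyma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import white_tophat

from .volume_io import BinaryMask, CTVolume

__all__ = [
    "PreprocessConfig",
    "clamp_and_strip",
    "csf_contrast_transform",
    "tv_denoise",
    "tophat_healthy_map",
    "total_variation",
    "ball_footprint",
]


@dataclass
class PreprocessConfig:
    """Constants of the intensity-conditioning stages.

    ``csf_window`` is the HU band whose contrast is expanded by a factor
    ``csf_gain``; values above the window are compressed linearly toward the
    fixed point at ``bone_threshold`` so the map stays monotone. ``tv_weight``
    is the ROF regularisation strength on intensities normalised by
    ``bone_threshold``.
    """

    bone_threshold: float = 100.0
    clamp_floor: float = 0.0
    csf_window: tuple[float, float] = (0.0, 40.0)
    csf_gain: float = 1.5
    tv_weight: float = 0.02
    tv_max_iter: int = 200
    tv_tol: float = 1e-4
    tophat_radius_mm: float = 10.0
    tophat_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.bone_threshold <= self.clamp_floor:
            raise ValueError("bone_threshold must exceed clamp_floor")
        if self.tv_weight <= 0 or self.tv_max_iter < 1 or self.tv_tol <= 0:
            raise ValueError("invalid TV parameters")


def clamp_and_strip(vol: CTVolume, cfg: PreprocessConfig | None = None) -> tuple[CTVolume, BinaryMask]:
    """Clamp sub-floor HU values and build the bone-free brain domain mask.

    Returns the clamped volume and the mask of voxels strictly below the bone
    threshold; all later stages operate inside this domain.
    """
    cfg = cfg or PreprocessConfig()
    clamped = np.maximum(vol.data, cfg.clamp_floor)
    domain = clamped < cfg.bone_threshold
    if not domain.any():
        raise ValueError("no intracranial voxels: entire volume at or above the bone threshold")
    return vol.with_data(clamped), BinaryMask(domain, vol.spacing)


def _transform_lut(x: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    lo, hi = cfg.csf_window
    if lo >= hi:
        raise ValueError(f"degenerate CSF window ({lo}, {hi})")
    ceil_in = cfg.bone_threshold
    ceil_out = lo + (hi - lo) * cfg.csf_gain  # window ceiling in output units
    y = np.empty_like(x, dtype=np.float64)
    below = x <= lo
    inside = (x > lo) & (x <= hi)
    above = x > hi
    y[below] = x[below]
    y[inside] = lo + (x[inside] - lo) * cfg.csf_gain
    if ceil_in > hi:
        slope = (ceil_in - ceil_out) / (ceil_in - hi)  # compress toward fixed point
        slope = max(slope, 0.0)
        y[above] = ceil_out + (x[above] - hi) * slope
    else:
        y[above] = ceil_out
    return y


def csf_contrast_transform(vol: CTVolume, cfg: PreprocessConfig | None = None) -> CTVolume:
    """Monotone piecewise-linear remap emphasising the tissue-CSF contrast.

    The CSF window (default 0-40 HU) is expanded by ``csf_gain``; intensities
    above it are linearly compressed so the bone threshold maps to itself.
    The map is monotone non-decreasing everywhere.
    """
    cfg = cfg or PreprocessConfig()
    return vol.with_data(_transform_lut(vol.data, cfg))


# ---------------------------------------------------------------------------
# Total-variation (ROF) denoising — Chambolle dual projection, 6-neighbour
# forward-difference gradients on the voxel grid.


def _grad(u: np.ndarray) -> list[np.ndarray]:
    g = []
    for ax in range(3):
        d = np.zeros_like(u)
        sl = [slice(None)] * 3
        sr = [slice(None)] * 3
        sl[ax] = slice(0, -1)
        sr[ax] = slice(1, None)
        d[tuple(sl)] = u[tuple(sr)] - u[tuple(sl)]
        g.append(d)
    return g


def _div(p: list[np.ndarray]) -> np.ndarray:
    out = np.zeros_like(p[0])
    for ax in range(3):
        d = np.zeros_like(p[ax])
        sl = [slice(None)] * 3
        sr = [slice(None)] * 3
        sl[ax] = slice(1, None)
        sr[ax] = slice(0, -1)
        d[tuple(sl)] = p[ax][tuple(sl)] - p[ax][tuple(sr)]
        first = [slice(None)] * 3
        first[ax] = slice(0, 1)
        d[tuple(first)] = p[ax][tuple(first)]
        out += d
    return out


def total_variation(data: np.ndarray) -> float:
    """Isotropic total variation with forward differences."""
    g = _grad(np.asarray(data, dtype=np.float64))
    return float(np.sqrt(sum(d * d for d in g)).sum())


def tv_denoise(
    vol: CTVolume,
    cfg: PreprocessConfig | None = None,
    domain: BinaryMask | None = None,
    provenance: list | None = None,
) -> CTVolume:
    """ROF denoising: minimise ``0.5||u - f||^2 + w TV(u)``.

    Solved with Chambolle's dual projection scheme on intensities normalised
    by the bone threshold. When a domain mask is given, out-of-domain voxels
    (bone) are replaced by the bone-threshold value for the solve — so the
    dense skull edge does not bleed halo into parenchyma — and restored
    afterwards.
    """
    cfg = cfg or PreprocessConfig()
    scale = cfg.bone_threshold
    f_raw = vol.data
    if domain is not None:
        f = np.where(domain.data, f_raw, cfg.bone_threshold) / scale
    else:
        f = f_raw / scale
    w = cfg.tv_weight

    p = [np.zeros_like(f) for _ in range(3)]
    tau = 1.0 / 12.0  # stable step for the 3-D dual scheme
    u = f.copy()
    obj_prev = np.inf
    objectives: list[float] = []
    converged = False
    for it in range(cfg.tv_max_iter):
        u = f - w * _div(p)
        g = _grad(u)
        norm = np.sqrt(sum(d * d for d in g))
        denom = 1.0 + (tau / w) * norm
        for ax in range(3):
            p[ax] = (p[ax] - (tau / w) * g[ax]) / denom
        obj = 0.5 * float(((u - f) ** 2).sum()) + w * total_variation(u)
        objectives.append(obj)
        if obj_prev < np.inf and abs(obj_prev - obj) < cfg.tv_tol * max(abs(obj), 1e-12):
            converged = True
            obj_prev = obj
            break
        obj_prev = obj
    if provenance is not None:
        provenance.append(
            {
                "stage": "tv_denoise",
                "iterations": len(objectives),
                "converged": converged,
                "objective": objectives[-1] if objectives else None,
            }
        )
        if not converged:
            provenance.append({"stage": "tv_denoise", "warning": "did not converge within tv_max_iter"})
    u = f - w * _div(p)
    out = u * scale
    if domain is not None:
        out = np.where(domain.data, out, f_raw)
    return vol.with_data(out)


def tv_objective_trace(vol: CTVolume, cfg: PreprocessConfig) -> list[float]:
    """Per-iteration ROF objective values (diagnostic; same scheme as tv_denoise)."""
    scale = cfg.bone_threshold
    f = vol.data / scale
    w = cfg.tv_weight
    p = [np.zeros_like(f) for _ in range(3)]
    tau = 1.0 / 12.0
    trace = []
    for _ in range(cfg.tv_max_iter):
        u = f - w * _div(p)
        g = _grad(u)
        norm = np.sqrt(sum(d * d for d in g))
        denom = 1.0 + (tau / w) * norm
        for ax in range(3):
            p[ax] = (p[ax] - (tau / w) * g[ax]) / denom
        trace.append(0.5 * float(((u - f) ** 2).sum()) + w * total_variation(u))
    return trace


# ---------------------------------------------------------------------------
# Top-hat healthy-tissue map


def ball_footprint(radius_mm: float, spacing) -> np.ndarray:
    """Anisotropy-aware ellipsoidal footprint for a radius given in mm."""
    radii = [max(1, int(round(radius_mm / s))) for s in spacing]
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii)]
    dist = sum((g / r) ** 2 for g, r in zip(grids, radii))
    return dist <= 1.0


def tophat_healthy_map(tv_vol: CTVolume, cfg: PreprocessConfig | None = None) -> BinaryMask:
    """White top-hat of the denoised image thresholded into a healthy-tissue map.

    Flags structures locally brighter than their surroundings at the scale of
    the structuring ball (default radius 10 mm in native millimetres).
    """
    cfg = cfg or PreprocessConfig()
    fp = ball_footprint(cfg.tophat_radius_mm, tv_vol.spacing)
    if any(f > n for f, n in zip(fp.shape, tv_vol.shape)):
        raise ValueError("top-hat structuring element larger than the volume")
    response = white_tophat(tv_vol.data, footprint=fp)
    return BinaryMask(response > cfg.tophat_threshold, tv_vol.spacing)
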