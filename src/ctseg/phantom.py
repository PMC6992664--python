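"""Synthetic head-CT phantoms with recorded ground truth.

The phantom is an ellipsoidal head: a bright skull shell around parenchyma
(a gray-matter shell over a white-matter core), bilaterally symmetric
CSF-filled lateral ventricles, radial sulcal CSF bands in the cortical
shell, and optional hypodense ellipsoidal chronic-lesion inserts stamped
into parenchyma. Gaussian noise is added to the emitted volume only; truth
masks are recorded pre-noise. Default HU levels sit inside the intensity
ranges the segmentation guides target (CSF 8, lesion 15, white 28, gray 36,
skull 800 HU) so the default pipeline parameters are exercised directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_io import BinaryMask, CTVolume
from .zeta import ReferenceCohort

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "LesionSpec",
    "make_phantom",
    "make_cohort",
    "make_outcome_table",
]


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal lesion: centre offset from the head centre (mm),
    per-axis radii (mm), and optionally its own HU level."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    hu: float | None = None


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    hu_skull: float = 800.0
    hu_gray: float = 36.0
    hu_white: float = 28.0
    hu_csf: float = 8.0
    hu_lesion: float = 15.0
    lesion_specs: tuple[LesionSpec, ...] = ()
    noise_sd: float = 2.0
    asymmetry_jitter_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.hu_skull > 100 > self.hu_gray > self.hu_white > self.hu_lesion >= self.hu_csf >= 0):
            raise ValueError("HU levels must satisfy skull > 100 > gray > white > lesion >= csf >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhantomTruth:
    lesion_mask: BinaryMask
    ventricle_mask: BinaryMask
    sulci_mask: BinaryMask
    gray_fraction: np.ndarray
    white_fraction: np.ndarray


def _coords_mm(cfg: PhantomConfig):
    """Voxel-centre coordinates relative to the head centre, in mm.

    The centre is pinned to the voxel column ``n // 2`` on every axis so the
    phantom is mirror-symmetric about the default mid-sagittal *column*, not
    about an inter-voxel plane (which would break voxel-level congruence
    tests on even grids).
    """
    axes = [(np.arange(n) - n // 2) * s for n, s in zip(cfg.shape, cfg.spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(x, y, z, center, radii):
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def make_phantom(cfg: PhantomConfig | None = None) -> tuple[CTVolume, PhantomTruth]:
    """Build one phantom volume and its ground-truth masks."""
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    x, y, z = _coords_mm(cfg)
    extent = [(n - 1) / 2 * s for n, s in zip(cfg.shape, cfg.spacing)]
    head_radii = [0.92 * e for e in extent]

    jit = (
        rng.normal(0.0, cfg.asymmetry_jitter_mm, 3)
        if cfg.asymmetry_jitter_mm > 0
        else np.zeros(3)
    )

    outer = _ellipsoid(x, y, z, (0, 0, 0), head_radii)
    inner_radii = [r - 6.0 for r in head_radii]  # 6 mm skull shell
    inner = _ellipsoid(x, y, z, (0, 0, 0), inner_radii)
    skull = outer & ~inner

    # parenchyma: gray cortical shell over white core
    white_radii = [0.72 * r for r in inner_radii]
    white = _ellipsoid(x, y, z, (0, 0, 0), white_radii)
    gray = inner & ~white

    # bilaterally symmetric lateral ventricles (mirrored ellipsoids)
    vent_off = 0.22 * inner_radii[0]
    vr = (0.14 * inner_radii[0], 0.38 * inner_radii[1], 0.22 * inner_radii[2])
    vents = _ellipsoid(x, y, z, (vent_off + jit[0], jit[1], jit[2]), vr) | _ellipsoid(
        x, y, z, (-vent_off + jit[0], jit[1], jit[2]), vr
    )
    vents &= inner

    # radial sulcal CSF bands in the outer cortical band, LR-symmetric
    theta = np.arctan2(y, np.where(np.abs(x) < 1e-9, 1e-9, x))
    rho = np.sqrt((x / inner_radii[0]) ** 2 + (y / inner_radii[1]) ** 2 + (z / inner_radii[2]) ** 2)
    phase = jit[1] / max(inner_radii[1], 1.0)
    bands = np.abs(np.sin(4 * (theta + phase))) < 0.10
    sulci = gray & bands & (rho > 0.62)
    sulci &= ~vents

    vol = np.zeros(cfg.shape)
    vol[gray] = cfg.hu_gray
    vol[white] = cfg.hu_white
    vol[sulci] = cfg.hu_csf
    vol[vents] = cfg.hu_csf
    vol[skull] = cfg.hu_skull

    parenchyma = (gray | white) & ~sulci & ~vents
    lesion = np.zeros(cfg.shape, dtype=bool)
    for i, spec in enumerate(cfg.lesion_specs):
        ell = _ellipsoid(x, y, z, spec.center_mm, spec.radii_mm)
        stamped = ell & parenchyma
        if not stamped.any():
            raise ValueError(f"lesion spec {i} at {spec.center_mm} lies outside parenchyma")
        vol[stamped] = spec.hu if spec.hu is not None else cfg.hu_lesion
        lesion |= stamped

    truth = PhantomTruth(
        lesion_mask=BinaryMask(lesion, cfg.spacing),
        ventricle_mask=BinaryMask(vents & ~lesion, cfg.spacing),
        sulci_mask=BinaryMask(sulci & ~lesion, cfg.spacing),
        gray_fraction=(gray & ~sulci & ~lesion).astype(np.float64),
        white_fraction=(white & ~vents & ~lesion).astype(np.float64),
    )
    if cfg.noise_sd > 0:
        vol = vol + rng.normal(0.0, cfg.noise_sd, cfg.shape)
    return CTVolume(vol, cfg.spacing), truth


def make_cohort(n: int, cfg: PhantomConfig | None = None, seed: int = 0) -> ReferenceCohort:
    """n lesion-free phantoms with per-subject geometry jitter and noise."""
    if n < 3:
        raise ValueError("cohort needs at least 3 members")
    base = cfg or PhantomConfig()
    rng = np.random.default_rng(seed)
    vols = []
    for _ in range(n):
        sub = PhantomConfig(
            shape=base.shape,
            spacing=base.spacing,
            hu_skull=base.hu_skull,
            hu_gray=base.hu_gray,
            hu_white=base.hu_white,
            hu_csf=base.hu_csf,
            hu_lesion=base.hu_lesion,
            lesion_specs=(),
            noise_sd=base.noise_sd,
            asymmetry_jitter_mm=base.asymmetry_jitter_mm if base.asymmetry_jitter_mm > 0 else 1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vols.append(make_phantom(sub)[0])
    return ReferenceCohort(vols)


# Comorbidity prevalences of an acute ischemic stroke population (fractions).
ACUTE_COHORT_PREVALENCE = {
    "diabetes": 0.276,
    "hypertension": 0.648,
    "atrial_fibrillation": 0.248,
    "chf": 0.072,
    "male": 0.500,
}
AGE_MEAN, AGE_SD = 73.0, 15.0


def make_outcome_table(
    n: int,
    volume_effect: float = 0.1,
    seed: int = 0,
    age_effect: float = 0.05,
    lesion_volume_ml: np.ndarray | None = None,
) -> pd.DataFrame:
    """Synthetic clinical table with a planted logistic outcome model.

    Ages are Normal(73, 15) truncated to [18, 100]; comorbidities follow the
    prevalences of an acute stroke cohort. The binary outcome is drawn from
    ``logit p = b0 + age_effect (age - 73) + volume_effect volume_ml``;
    ``volume_effect`` is the log-odds per ml of lesion volume. Lesion volumes
    default to a right-skewed lognormal (median ~5 ml) unless provided.
    """
    if n < 20:
        raise ValueError("need n >= 20 subjects")
    rng = np.random.default_rng(seed)
    age = rng.normal(AGE_MEAN, AGE_SD, n)
    while True:
        bad = (age < 18) | (age > 100)
        if not bad.any():
            break
        age[bad] = rng.normal(AGE_MEAN, AGE_SD, int(bad.sum()))
    if lesion_volume_ml is None:
        lesion_volume_ml = rng.lognormal(mean=np.log(5.0), sigma=0.8, size=n)
    vols = np.asarray(lesion_volume_ml, dtype=np.float64)
    logit = age_effect * (age - AGE_MEAN) + volume_effect * (vols - np.median(vols))
    p = 1.0 / (1.0 + np.exp(-logit))
    outcome = (rng.uniform(size=n) < p).astype(int)
    table = pd.DataFrame(
        {
            "age": age,
            "sex": (rng.uniform(size=n) < ACUTE_COHORT_PREVALENCE["male"]).astype(int),
            "diabetes": (rng.uniform(size=n) < ACUTE_COHORT_PREVALENCE["diabetes"]).astype(int),
            "hypertension": (rng.uniform(size=n) < ACUTE_COHORT_PREVALENCE["hypertension"]).astype(int),
            "atrial_fibrillation": (
                rng.uniform(size=n) < ACUTE_COHORT_PREVALENCE["atrial_fibrillation"]
            ).astype(int),
            "chf": (rng.uniform(size=n) < ACUTE_COHORT_PREVALENCE["chf"]).astype(int),
            "lesion_volume_ml": vols,
            "outcome": outcome,
        }
    )
    table.attrs["generator"] = {
        "volume_effect": volume_effect,
        "age_effect": age_effect,
        "seed": seed,
    }
    return table
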