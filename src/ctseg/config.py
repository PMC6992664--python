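"""Pipeline configuration: nested dataclass sections loaded from YAML/JSON.

Unknown keys are rejected so typos fail loudly, and every run can echo the
fully resolved configuration into its provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .lesion_mask import LesionConfig
from .mfmc import MFMCConfig
from .phantom import PhantomConfig
from .preprocess import PreprocessConfig
from .region_maps import SULCI_GUIDES, VENTRICLE_GUIDES
from .zeta import ZetaConfig

__all__ = ["PipelineConfig", "load_config"]


def _build(cls, section: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown config keys under '{where}': {sorted(unknown)}")
    kwargs = dict(section)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    mfmc_sulci: MFMCConfig = field(default_factory=lambda: MFMCConfig(guide_values=SULCI_GUIDES))
    mfmc_ventricles: MFMCConfig = field(
        default_factory=lambda: MFMCConfig(guide_values=VENTRICLE_GUIDES)
    )
    mfmc_lesion: MFMCConfig | None = None  # defaults to LesionConfig.lesion_guides
    zeta: ZetaConfig = field(default_factory=ZetaConfig)
    lesion: LesionConfig = field(default_factory=LesionConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        mfmc = raw.pop("mfmc", {}) or {}
        known = {"preprocess", "zeta", "lesion", "phantom", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        unknown_m = set(mfmc) - {"sulci", "ventricles", "lesion"}
        if unknown_m:
            raise ValueError(f"unknown config keys under 'mfmc': {sorted(unknown_m)}")
        kwargs = {}
        if "preprocess" in raw:
            kwargs["preprocess"] = _build(PreprocessConfig, raw["preprocess"], "preprocess")
        if "sulci" in mfmc:
            kwargs["mfmc_sulci"] = _build(MFMCConfig, {"guide_values": SULCI_GUIDES, **mfmc["sulci"]}, "mfmc.sulci")
        if "ventricles" in mfmc:
            kwargs["mfmc_ventricles"] = _build(
                MFMCConfig, {"guide_values": VENTRICLE_GUIDES, **mfmc["ventricles"]}, "mfmc.ventricles"
            )
        if "lesion" in mfmc:
            kwargs["mfmc_lesion"] = _build(
                MFMCConfig, {"guide_values": LesionConfig().lesion_guides, **mfmc["lesion"]}, "mfmc.lesion"
            )
        if "zeta" in raw:
            kwargs["zeta"] = _build(ZetaConfig, raw["zeta"], "zeta")
        if "lesion" in raw:
            kwargs["lesion"] = _build(LesionConfig, raw["lesion"], "lesion")
        if "phantom" in raw:
            section = dict(raw["phantom"])
            lesions = section.pop("lesion_specs", None)
            cfg = _build(PhantomConfig, section, "phantom")
            if lesions:
                from .phantom import LesionSpec

                specs = tuple(
                    LesionSpec(tuple(d["center_mm"]), tuple(d["radii_mm"]), d.get("hu"))
                    for d in lesions
                )
                cfg = dataclasses.replace(cfg, lesion_specs=specs)
            kwargs["phantom"] = cfg
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "preprocess": enc(self.preprocess),
            "mfmc": {
                "sulci": enc(self.mfmc_sulci),
                "ventricles": enc(self.mfmc_ventricles),
                "lesion": enc(self.mfmc_lesion) if self.mfmc_lesion else None,
            },
            "zeta": enc(self.zeta),
            "lesion": enc(self.lesion),
            "phantom": enc(self.phantom),
            "seed": self.seed,
        }


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return PipelineConfig.from_dict(raw or {})
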