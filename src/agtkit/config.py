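"""Pipeline configuration: a YAML-serialisable description of a full run.

Every stage of the pipeline draws its parameters (and every seed) from one
PipelineConfig, so a run is fully described by its config file.  The
round-trip through YAML is lossless.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .choice_models import ModelSpec, OfferCoding
from .inference import PriorScheme, SamplerSettings
from .synthetic_cohort import DEFAULT_GROUP_SIZES, GroupSpec, default_group_specs
from .task_design import DesignGrid

__all__ = ["PipelineConfig"]


def _group_to_dict(spec: GroupSpec) -> dict:
    d = asdict(spec)
    d["age_bounds"] = list(d["age_bounds"])
    d["symptom_shifts"] = list(d["symptom_shifts"])
    return d


@dataclass
class PipelineConfig:
    """Complete, serialisable configuration of a pipeline run."""

    seed: int = 0
    output_dir: str = "agt_out"
    design: Dict = field(default_factory=lambda: {
        "reward_levels": [3, 6, 9, 12],
        "effort_levels": [0.2, 0.4, 0.6, 0.8],
        "repetitions": 5,
    })
    groups: Dict[str, Dict] = field(default_factory=lambda: {
        g: {"size": DEFAULT_GROUP_SIZES[g], **_group_to_dict(s)}
        for g, s in default_group_specs().items()
    })
    model: Dict = field(default_factory=lambda: {
        "free_terms": ["K", "LinR", "E2"],
        "constraints": {"LinE": -15.0},
        "reward_max": 12.0,
    })
    scheme: Dict = field(default_factory=lambda: {"mode": "pooled",
                                                  "parameter": None})
    mcmc: Dict = field(default_factory=lambda: {
        "chains": 4, "warmup": 1000, "draws": 1000, "thin": 5,
    })
    analysis: Dict = field(default_factory=lambda: {
        "sphericity_alpha": 0.05, "n_factors": 4, "n_miscalibrated": 0,
    })

    # -- object builders -------------------------------------------------
    def design_grid(self) -> DesignGrid:
        return DesignGrid(
            reward_levels=tuple(self.design["reward_levels"]),
            effort_levels=tuple(self.design["effort_levels"]),
            repetitions=int(self.design["repetitions"]),
        )

    def group_specs(self) -> Dict[str, GroupSpec]:
        out = {}
        for label, d in self.groups.items():
            d = dict(d)
            d.pop("size", None)
            d["age_bounds"] = tuple(d.get("age_bounds", (18, 60)))
            d["symptom_shifts"] = tuple(d.get("symptom_shifts", (0, 0, 0, 0)))
            out[label] = GroupSpec(**d)
        return out

    def group_sizes(self) -> List[int]:
        return [int(self.groups[g]["size"]) for g in self.groups]

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            free_terms=tuple(self.model["free_terms"]),
            constraints=dict(self.model.get("constraints", {})),
            coding=OfferCoding(reward_max=float(self.model.get("reward_max", 12.0))),
        )

    def prior_scheme(self) -> PriorScheme:
        return PriorScheme(mode=self.scheme.get("mode", "pooled"),
                           parameter=self.scheme.get("parameter"))

    def sampler_settings(self) -> SamplerSettings:
        return SamplerSettings(
            chains=int(self.mcmc.get("chains", 4)),
            warmup=int(self.mcmc.get("warmup", 1000)),
            draws=int(self.mcmc.get("draws", 1000)),
            thin=int(self.mcmc.get("thin", 5)),
        )

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
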