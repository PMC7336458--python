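"""YAML pipeline configuration.

One file gathers every tunable of the workflow: the restriction enzyme, the
optical-map alignment scoring, the read-coloring options (match-fraction
threshold t, tail extension, color adjustment, minimum s-score), the graph
guidance parameters (color step d, propagation limit L) and, optionally, the
synthetic-data generator.  Parameter invariants are enforced by the
component types; unknown keys are an error.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .assembly import GuidanceParams
from .coloring import ColoringOptions
from .digestion import RestrictionEnzyme, XHOI
from .omalign import OMScoringParams
from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    enzyme: RestrictionEnzyme = field(default_factory=lambda: XHOI)
    om_scoring: OMScoringParams = field(default_factory=OMScoringParams)
    coloring: ColoringOptions = field(default_factory=ColoringOptions)
    guidance: GuidanceParams = field(default_factory=GuidanceParams)
    simulation: Optional[SimulationConfig] = None

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "log_level": self.log_level,
            "enzyme": {
                "name": self.enzyme.name,
                "motif": self.enzyme.motif,
                "cut_offset": self.enzyme.cut_offset,
            },
            "om_scoring": asdict(self.om_scoring),
            "coloring": asdict(self.coloring),
            "guidance": asdict(self.guidance),
        }
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    def to_yaml(self, dest) -> None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        known = {"seed", "log_level", "enzyme", "om_scoring", "coloring",
                 "guidance", "simulation"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        enzyme = XHOI
        if "enzyme" in d:
            enzyme = RestrictionEnzyme(**d["enzyme"])
        return cls(
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
            enzyme=enzyme,
            om_scoring=OMScoringParams(**d.get("om_scoring", {})),
            coloring=ColoringOptions(**d.get("coloring", {})),
            guidance=GuidanceParams(**d.get("guidance", {})),
            simulation=(
                SimulationConfig.from_dict(d["simulation"])
                if "simulation" in d and d["simulation"] is not None
                else None
            ),
        )

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)


def load_config(path: Optional[str]) -> PipelineConfig:
    """Load a config file, or the full defaults when ``path`` is None."""
    if path is None:
        return PipelineConfig()
    return PipelineConfig.from_yaml(path)
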