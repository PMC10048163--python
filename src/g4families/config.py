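"""Run configuration: every module's parameter block in one place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .cluster import ScoringParams, SphereParams
from .detect import DetectionParams
from .family import MergeConfig, RefinementConfig
from .msa import AlignScoring
from .simulate import SimConfig
from .thermo import EnergyModel

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run, serialisable and reloadable.

    The default thresholds are the refinement-loop operating points:
    distinctness alpha 0.05, membership probability 0.99, gap-score ceiling
    0.10, post-merge gap ceiling 0.6, at most 100 iterations, and for the
    cross-method merge log odds 5, Akaike weight 0.7, gap score 0.07.
    """

    detection: DetectionParams = field(default_factory=DetectionParams)
    sphere: SphereParams = field(default_factory=SphereParams)
    similarity: ScoringParams = field(default_factory=ScoringParams)
    msa: AlignScoring = field(default_factory=AlignScoring)
    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    merge: MergeConfig = field(default_factory=MergeConfig)
    thermo: EnergyModel = field(default_factory=EnergyModel)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    verbosity: int = 1

    def to_json(self) -> str:
        return json.dumps(
            {f.name: _encode(getattr(self, f.name)) for f in dataclasses.fields(self)},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            val = data[f.name]
            if f.name in _BLOCKS:
                kwargs[f.name] = _BLOCKS[f.name](**val)
            else:
                kwargs[f.name] = val
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())


_BLOCKS = {
    "detection": DetectionParams,
    "sphere": SphereParams,
    "similarity": ScoringParams,
    "msa": AlignScoring,
    "refinement": RefinementConfig,
    "merge": MergeConfig,
    "thermo": EnergyModel,
    "sim": SimConfig,
}


def _encode(value):
    if dataclasses.is_dataclass(value):
        return dataclasses.asdict(value)
    return value
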