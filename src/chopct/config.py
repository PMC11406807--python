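"""Run configuration: one JSON document covering every stage's parameters."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Optional

from .morphometry import MorphometryConfig
from .phantom import PhantomSpec
from .plexus import PlexusParams
from .ventricle import SegmentationParams

__all__ = ["RunConfig"]


def _from_dict(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class RunConfig:
    """All pipeline parameters, JSON-serializable; unknown keys are rejected."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    plexus: PlexusParams = field(default_factory=PlexusParams)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    gpa_remove_scale: bool = True
    gpa_tol: float = 1e-6
    gpa_max_iter: int = 100
    seed: int = 0
    verbosity: str = "info"
    output_root: str = "."

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        nested = {
            "segmentation": SegmentationParams,
            "plexus": PlexusParams,
            "morphometry": MorphometryConfig,
            "phantom": PhantomSpec,
        }
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key in nested:
                kwargs[key] = _from_dict(nested[key], value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
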