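"""The 37-variable feature registry.

The registry is a versioned YAML contract: it fixes the name, order, type and
unit of every predictor column. Feature assembly emits columns in registry
order and trained models store the registry hash; prediction refuses vectors
built against a different registry.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import SchemaError


@dataclass(frozen=True)
class FeatureRegistry:
    version: int
    features: tuple[dict, ...]
    names: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(f["name"] for f in self.features))
        if len(set(self.names)) != len(self.names):
            raise SchemaError("registry contains duplicate feature names")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def hash(self) -> str:
        payload = f"v{self.version}:" + ",".join(self.names)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_registry(path: str | None = None) -> FeatureRegistry:
    """Load the bundled registry, or one from an explicit YAML path."""
    if path is None:
        text = resources.files("glycotwin.data").joinpath("registry.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if "features" not in raw:
        raise SchemaError("registry YAML lacks a 'features' list")
    return FeatureRegistry(version=int(raw.get("version", 1)),
                           features=tuple(raw["features"]))
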