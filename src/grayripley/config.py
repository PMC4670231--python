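"""Run configuration: one serializable record of everything a run needs.

A ``RunConfig`` round-trips losslessly through JSON; every CLI run writes
its resolved config next to its outputs so any artifact can be reproduced
byte-for-byte from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    """Resolved parameters of one analysis run."""

    input_path: str | None = None
    simulation: dict | None = None
    radii: list[float] = field(default_factory=list)
    edge_method: str = "full_field"
    replicates: int = 1000
    seed: int = 0
    mask_policy: str = "full"
    mask_path: str | None = None
    output_dir: str = "."
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        return cls(**json.loads(source))


def write_sidecar(out_path: str | Path, params: dict) -> Path:
    """Write the resolved parameters of a run next to its main output."""
    side = Path(str(out_path) + ".config.json")
    side.write_text(json.dumps(params, indent=2, sort_keys=True, default=str))
    return side
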