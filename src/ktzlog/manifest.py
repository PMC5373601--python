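"""Run manifests: every CLI run records what produced its outputs.

A manifest is a JSON document with the subcommand, the full configuration
(every threshold and seed), the package version and the list of output
files, so any artifact can be regenerated by replaying the manifest.
Reruns are bit-identical except for the recorded wall time.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List

from . import __version__


@dataclass
class RunManifest:
    command: str
    config: Dict[str, Any]
    outputs: List[str] = field(default_factory=list)
    version: str = __version__
    wall_time_s: float = 0.0
    _t0: float = field(default_factory=time.perf_counter, repr=False)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        self.wall_time_s = time.perf_counter() - self._t0
        doc = {
            "command": self.command,
            "config": _jsonable(self.config),
            "outputs": self.outputs,
            "version": self.version,
            "wall_time_s": self.wall_time_s,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        import dataclasses

        return _jsonable(dataclasses.asdict(obj))
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def manifest_path_for(output_path) -> Path:
    p = Path(output_path)
    return p.with_suffix(p.suffix + ".manifest.json")
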