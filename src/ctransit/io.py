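"""Reading and writing system definitions and run configurations.

A system definition is a small YAML or JSON mapping::

    names: [leaf, wood, soil]
    u: [10.0, 0.0, 0.0]        # PgC yr^-1
    B:                          # yr^-1, column j = losses from pool j
      - [-1.0, 0.0, 0.0]
      - [0.5, -0.1, 0.0]
      - [0.2, 0.05, -0.01]

Format is chosen by file extension (.yaml/.yml/.json); the writer emits
the same structure so definitions round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .core import CompartmentalSystem

__all__ = ["system_to_dict", "system_from_dict", "read_system", "write_system"]


def system_to_dict(sys: CompartmentalSystem) -> dict:
    return {
        "names": list(sys.names),
        "u": [float(v) for v in sys.u],
        "B": [[float(v) for v in row] for row in sys.B],
    }


def system_from_dict(d: dict) -> CompartmentalSystem:
    missing = {"u", "B"} - set(d)
    if missing:
        raise ValueError(f"system definition missing key(s): {sorted(missing)}")
    return CompartmentalSystem(B=d["B"], u=d["u"], names=tuple(d.get("names", ())))


def _format_of(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in (".yaml", ".yml"):
        return "yaml"
    if ext == ".json":
        return "json"
    raise ValueError(f"unsupported system-definition extension {ext!r} (use .yaml/.yml/.json)")


def read_system(path) -> CompartmentalSystem:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if _format_of(path) == "yaml" else json.loads(text)
    return system_from_dict(data)


def write_system(sys: CompartmentalSystem, path) -> None:
    path = Path(path)
    d = system_to_dict(sys)
    if _format_of(path) == "yaml":
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2) + "\n")
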