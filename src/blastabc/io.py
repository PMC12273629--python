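"""Parameter-file round-tripping (YAML/JSON keyed by parameter field names)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .model import BaseParams, ChimeraParams

__all__ = ["params_to_dict", "params_from_dict", "load_params", "save_params"]


def params_to_dict(params: BaseParams | ChimeraParams) -> dict:
    if isinstance(params, ChimeraParams):
        d = dataclasses.asdict(params)
        d["base"] = dataclasses.asdict(params.base)
        return d
    return dataclasses.asdict(params)


def params_from_dict(d: dict) -> BaseParams | ChimeraParams:
    if "base" in d:
        base = BaseParams(**d["base"])
        rest = {k: v for k, v in d.items() if k != "base"}
        return ChimeraParams(base=base, **rest)
    return BaseParams(**d)


def load_params(path: str | Path) -> BaseParams | ChimeraParams:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return params_from_dict(d)


def save_params(params: BaseParams | ChimeraParams, path: str | Path) -> None:
    path = Path(path)
    d = params_to_dict(params)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
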