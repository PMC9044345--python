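"""Checkpoint I/O: weights in an .npz container, architecture config as JSON."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .modules import Module

__all__ = ["save_checkpoint", "load_weights", "load_config_dict"]


def _config_to_dict(config) -> dict:
    if dataclasses.is_dataclass(config):
        return dataclasses.asdict(config)
    return dict(config)


def save_checkpoint(path: str | Path, module: Module, config=None) -> Path:
    """Save module weights to ``<path>.npz`` and the config to ``<path>.json``."""
    path = Path(path)
    if path.suffix == ".npz":
        path = path.with_suffix("")
    np.savez(path.with_suffix(".npz"), **module.state_dict())
    if config is not None:
        path.with_suffix(".json").write_text(json.dumps(_config_to_dict(config), indent=2, default=list))
    return path.with_suffix(".npz")


def load_weights(path: str | Path, module: Module) -> Module:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        module.load_state_dict(dict(data))
    return module


def load_config_dict(path: str | Path) -> dict:
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    return json.loads(path.read_text())
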