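"""Pipeline configuration: packaged YAML defaults with user overrides."""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources

import yaml

__all__ = ["PipelineConfig", "load_config", "default_config"]


def _packaged_defaults() -> dict:
    with resources.files("microspeech.data").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def _deep_update(base: dict, other: dict) -> dict:
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


class PipelineConfig:
    """Stage parameters keyed by module name.

    All defaults are embedded in the package (``data/defaults.yaml``); a
    user YAML and keyword overrides are merged on top.  Access stages as
    attributes (``cfg.decode["outer_folds"]``).
    """

    def __init__(self, overrides: dict | None = None):
        self._data = _packaged_defaults()
        if overrides:
            _deep_update(self._data, copy.deepcopy(overrides))

    def __getattr__(self, stage: str) -> dict:
        data = object.__getattribute__(self, "_data")
        if stage in data:
            return data[stage]
        raise AttributeError(stage)

    def __getitem__(self, stage: str) -> dict:
        return self._data[stage]

    def as_dict(self) -> dict:
        return copy.deepcopy(self._data)

    def hash(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        blob = json.dumps(self._data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config() -> PipelineConfig:
    return PipelineConfig()


def load_config(path: str | None = None, **overrides) -> PipelineConfig:
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    _deep_update(user, overrides)
    return PipelineConfig(user)
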