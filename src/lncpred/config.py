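"""YAML hyperparameter configuration loading."""

from __future__ import annotations

from pathlib import Path

import yaml

from .fusion import EncoderConfig
from .nafs import NafsConfig
from .sdne import SdneConfig
from .training import TrainConfig

__all__ = ["config_from_dict", "load_config"]

_SECTIONS = {"nafs": NafsConfig, "sdne": SdneConfig, "enc": EncoderConfig}


def config_from_dict(raw: dict) -> TrainConfig:
    """Build a TrainConfig from a (possibly partial) nested mapping.

    Top-level keys map to TrainConfig fields; the ``nafs``, ``sdne`` and
    ``enc`` sections map to their sub-configs.  Dotted keys like
    ``nafs.k`` are accepted as a flat alternative.
    """
    raw = dict(raw or {})
    nested: dict[str, dict] = {name: {} for name in _SECTIONS}
    top: dict = {}
    for key, value in raw.items():
        if "." in key:
            section, sub = key.split(".", 1)
            if section not in _SECTIONS:
                raise KeyError(f"unknown config section {section!r}")
            nested[section][sub] = value
        elif key in _SECTIONS:
            nested[key].update(value or {})
        else:
            top[key] = value
    kwargs = dict(top)
    if "ablations" in kwargs:
        kwargs["ablations"] = tuple(kwargs["ablations"])
    for name, cls in _SECTIONS.items():
        section = nested[name]
        if name == "nafs" and "r_list" in section:
            section["r_list"] = tuple(section["r_list"])
        kwargs[name] = cls(**section)
    return TrainConfig(**kwargs)


def load_config(path: str | Path | None) -> TrainConfig:
    """Load a YAML config file; None or a missing body give defaults."""
    if path is None:
        return TrainConfig()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw or {})
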