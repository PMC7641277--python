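"""Shipped preset library (pacemaker phenotypes, channel conditions)."""

from __future__ import annotations

from importlib import resources

import yaml

from .synthio import ChannelPreset, PacemakerPreset


def _load() -> dict:
    text = resources.files("sanephys").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def pacemaker_preset(name: str) -> PacemakerPreset:
    cfg = _load()["pacemaker"]
    if name not in cfg:
        raise KeyError(f"unknown pacemaker preset {name!r}; have {sorted(cfg)}")
    return PacemakerPreset(name=name, **cfg[name])


def channel_preset(name: str) -> ChannelPreset:
    cfg = _load()["channel"]
    if name not in cfg:
        raise KeyError(f"unknown channel preset {name!r}; have {sorted(cfg)}")
    return ChannelPreset(name=name, **cfg[name])


def list_presets() -> dict:
    cfg = _load()
    return {kind: sorted(entries) for kind, entries in cfg.items()}
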