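"""YAML configuration loading for the command-line interface.

A config file may carry any of the sections ``sim``, ``model``, ``mcmc``
and ``study``; each maps 1:1 onto the corresponding dataclass fields.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .cnv_model import ModelConfig
from .evaluation import StudyDesign
from .inference import MCMCConfig
from .simulator import AssocParams, SimConfig


def _build(cls, data: dict, **extra):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    clean = dict(data)
    for key, value in clean.items():
        if isinstance(value, list):
            clean[key] = tuple(value)
    return cls(**{**clean, **extra})


def load_config(path: str | Path | None) -> dict:
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = dict(raw.get("sim", {}))
    assoc = sim_raw.pop("assoc", None)
    if assoc is not None:
        assoc = _build(AssocParams, assoc)
    out = {
        "sim": _build(SimConfig, sim_raw, assoc=assoc),
        "model": _build(ModelConfig, raw.get("model", {})),
        "mcmc": _build(MCMCConfig, raw.get("mcmc", {})),
    }
    study_raw = dict(raw.get("study", {}))
    out["study"] = _build(
        StudyDesign,
        study_raw,
        sim=out["sim"],
        model=out["model"],
    )
    return out
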