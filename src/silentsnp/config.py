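"""Configuration loading and run provenance.

Plain-YAML configs mirror the parameter dataclasses field for field; unknown
keys are rejected so a typo cannot silently fall back to a default.  Every
CLI run writes a JSON sidecar (config snapshot, seeds, package version) next
to its artifacts, from which the run can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import yaml

from .synthetic import PanelSpec
from .translation import TranslationParameters

__all__ = [
    "default_params_path",
    "load_params",
    "load_panel_spec",
    "write_sidecar",
]


def default_params_path() -> Path:
    """Path of the packaged default translation-parameter config."""
    return Path(
        resources.files("silentsnp").joinpath("data/translation_defaults.yaml")
    )


def _load_into(cls, path, overrides=None):
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter fields")
    if overrides:
        raw.update(overrides)
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(
            f"{path}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    # YAML gives lists; tuple-typed fields need converting
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
    }
    return cls(**kwargs)


def load_params(path=None, **overrides) -> TranslationParameters:
    """Load :class:`TranslationParameters` from YAML (packaged defaults if
    ``path`` is None), applying keyword overrides last."""
    return _load_into(
        TranslationParameters, path or default_params_path(), overrides
    )


def load_panel_spec(path, **overrides) -> PanelSpec:
    """Load a :class:`PanelSpec` from YAML."""
    return _load_into(PanelSpec, path, overrides)


def write_sidecar(path, mode: str, config: dict, seed) -> None:
    """Write the JSON provenance sidecar for one run."""
    from . import __version__

    payload = {
        "tool": "silentsnp",
        "version": __version__,
        "mode": mode,
        "seed": seed,
        "config": config,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
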