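"""Single-file key:value configuration with CLI overrides."""

from __future__ import annotations

from pathlib import Path

import yaml

from grffl.datatypes import PipelineConfig, ValidationError

_FIELDS = {"flank_bp", "k_range", "seed", "enrichment_alpha", "fit_window_hours"}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML key:value config file; keyword overrides win over the file.

    Unknown keys are rejected so typos do not silently fall back to defaults.
    """
    settings: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"{path}: config must be a key:value mapping")
        settings.update(loaded)
    settings.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(settings) - _FIELDS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "k_range" in settings:
        settings["k_range"] = tuple(settings["k_range"])
    return PipelineConfig(**settings)
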