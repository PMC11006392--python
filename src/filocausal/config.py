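"""YAML run-configuration mirroring the analysis parameters."""

from __future__ import annotations

from pathlib import Path

import yaml

from .io_tables import TrackFilterConfig
from .preprocess import PreprocessConfig

__all__ = ["load_config"]


def load_config(path: str | Path) -> dict:
    """Load a YAML config into a dict of parameter objects.

    Recognised top-level keys: ``track_filters`` (TrackFilterConfig fields),
    ``preprocess`` (PreprocessConfig fields, or ``preset: casin``), ``ccf``,
    ``granger``, ``puncta`` (passed through as dicts).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    tf = raw.get("track_filters", {})
    out["track_filters"] = TrackFilterConfig(**tf)
    pp = dict(raw.get("preprocess", {}))
    if pp.pop("preset", None) == "casin":
        base = PreprocessConfig.casin()
        out["preprocess"] = (
            PreprocessConfig(**{**base.__dict__, **pp}) if pp else base
        )
    else:
        out["preprocess"] = PreprocessConfig(**pp)
    for key in ("ccf", "granger", "puncta", "simulate"):
        out[key] = dict(raw.get(key, {}))
    return out
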