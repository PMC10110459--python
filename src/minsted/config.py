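"""YAML/JSON configuration loading.

A config file may contain any of the sections ``optics``, ``localizer``,
``precision``, ``render``, ``sample``; missing sections fall back to
defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .epsf_model import OpticsModel
from .localizer import LocalizerConfig
from .precision_stats import PrecisionConfig
from .render_io import RenderConfig
from .sample_models import KineticsModel, SiteSet, make_npc, make_origami

__all__ = ["load_config", "build_sample"]


def _read(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def load_config(path) -> dict:
    """Parse a config file into typed config objects.

    Returns a dict with keys ``optics``, ``localizer``, ``precision``,
    ``render`` (instances) and ``sample`` (raw dict, see
    :func:`build_sample`).
    """
    raw = _read(path)
    out = {
        "optics": OpticsModel(**raw.get("optics", {})),
        "localizer": LocalizerConfig(**raw.get("localizer", {})),
        "precision": PrecisionConfig(**raw.get("precision", {})),
        "render": RenderConfig(**raw.get("render", {})),
        "sample": raw.get("sample", {}),
    }
    return out


def build_sample(sample: dict) -> tuple[SiteSet, KineticsModel, float]:
    """Build (sites, kinetics, duration_s) from the ``sample`` config section."""
    kind = sample.get("kind", "origami")
    duration_s = float(sample.get("duration_s", 60.0))
    kin = KineticsModel(**sample.get("kinetics", {}))
    if kind == "origami":
        sites = make_origami(
            spacing=float(sample.get("spacing_nm", 12.0)),
            rows=int(sample.get("rows", 3)),
            cols=int(sample.get("cols", 3)),
            layout=sample.get("layout", "rect"),
        )
    elif kind == "npc":
        sites = make_npc(
            diameter=float(sample.get("diameter_nm", 112.0)),
            stagger_deg=float(sample.get("stagger_deg", 5.0)),
        )
    elif kind == "custom":
        import numpy as np

        pts = np.asarray(sample["positions"], dtype=float)
        sites = SiteSet(pts, list(range(len(pts))), structure_kind="custom")
    else:
        raise ValueError(f"unknown sample kind {kind!r}")
    return sites, kin, duration_s
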