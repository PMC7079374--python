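"""Flat YAML configuration for the pipeline.

Only a handful of knobs are exposed at the config level; everything else is
reachable through the library API.  Unknown keys raise, so typos fail fast.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .model import CariesModel
from .state import DemographyParams, ProgressionRates
from .synthetic import SugarAnchors, default_inputs

__all__ = ["default_config", "load_config", "model_from_config", "config_hash"]

_DEFAULTS = {
    "seed": 0,
    "start": 2010,
    "end": 2040,
    "dt": 0.25,
    "population_anchors": {2010: 50.40e6, 2020: 53.37e6, 2030: 54.10e6, 2040: 52.62e6},
    "mortality_35plus": 0.015,
    "band35_fraction": 0.6,
    "ssb_price_baht_per_litre": 20.0,
    "sugar_content_kg_per_litre": 0.15,
    "total_sugar_2000_g_day": 76.19,
    "total_sugar_2015_g_day": 104.46,
    "ssb_share_2000": 0.15,
    "ssb_share_2015": 0.21,
    "vl_to_l": 0.063,
    "l_to_m": 0.066,
    "m_to_h": 0.063,
    "access_multiplier": 1.0,
}


def default_config() -> dict:
    return dict(_DEFAULTS)


def load_config(path: str | Path | None) -> dict:
    cfg = default_config()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(cfg)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(raw)
    return cfg


def config_hash(cfg: dict) -> str:
    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def model_from_config(cfg: dict) -> CariesModel:
    anchors = SugarAnchors(
        total_sugar_2000=cfg["total_sugar_2000_g_day"],
        total_sugar_2015=cfg["total_sugar_2015_g_day"],
        ssb_share_2000=cfg["ssb_share_2000"],
        ssb_share_2015=cfg["ssb_share_2015"],
    )
    inputs = default_inputs(
        seed=cfg["seed"],
        price_baht_per_litre=cfg["ssb_price_baht_per_litre"],
        sugar_content=cfg["sugar_content_kg_per_litre"],
        anchors=anchors,
        population_anchors={int(k): float(v) for k, v in cfg["population_anchors"].items()},
        mortality_config={
            "mortality_35plus": cfg["mortality_35plus"],
            "band35_fraction": cfg["band35_fraction"],
        },
    )
    model = CariesModel(
        inputs=inputs,
        rates=ProgressionRates(cfg["vl_to_l"], cfg["l_to_m"], cfg["m_to_h"]),
        demography=DemographyParams(mortality_35plus=cfg["mortality_35plus"]),
        base_sugar_content=cfg["sugar_content_kg_per_litre"],
        start=int(cfg["start"]),
        end=int(cfg["end"]),
        dt=float(cfg["dt"]),
    )
    if cfg["access_multiplier"] != 1.0:
        from dataclasses import replace

        model.uptake = replace(model.uptake, access_multiplier=cfg["access_multiplier"])
    return model
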