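"""Pipeline configuration: every analysis threshold in one place.

Defaults are the values the analyses assume throughout: detection threshold
4 counts, FDR cutoff 0.1, RRHO step 10, bias-band multiplier 2, fidelity
cutoff 0.10, low-expression pre-filter 4 counts.  A YAML file with nested
sections may override any subset.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import yaml

log = logging.getLogger("dgecompare")

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # detection
    detection_threshold: int = 4
    fidelity_min_total: int = 4
    fidelity_cutoff: float = 0.10
    # downsampling
    downsample_variant: str = "hypergeometric"
    downsample_min_count: int = 4
    downsample_summed_filter: bool = False
    downsample_reps: int = 16
    # concordance
    band_k: float = 2.0
    # differential expression
    fdr_cutoff: float = 0.1
    de_min_total: int = 4
    dispersion_mode: str = "tagwise"
    # rrho
    rrho_step: int = 10
    # go power
    power_alpha: float = 0.05
    power_threshold: float = 0.8
    power_n_sim: int = 1000

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "detection": ("detection_threshold", "fidelity_min_total", "fidelity_cutoff"),
    "downsample": (
        "downsample_variant", "downsample_min_count",
        "downsample_summed_filter", "downsample_reps",
    ),
    "concordance": ("band_k",),
    "diffexp": ("fdr_cutoff", "de_min_total", "dispersion_mode"),
    "rrho": ("rrho_step",),
    "gopower": ("power_alpha", "power_threshold", "power_n_sim"),
}


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; flat keys and nested sections both accepted."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    updates: dict = {}
    for key, value in data.items():
        if isinstance(value, dict) and key in _SECTIONS:
            for k, v in value.items():
                name = k if k in known else f"{key}_{k}"
                if name not in known:
                    raise ValueError(f"unknown config key {key}.{k}")
                updates[name] = v
        elif key in known:
            updates[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    cfg = replace(cfg, **updates)
    log.info("config loaded from %s: %s", path, updates)
    return cfg
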