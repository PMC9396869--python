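"""Run configuration with YAML / flat key=value loading."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class MethConfig:
    """Methylation probe screening (regression of GE on probe values)."""

    p_threshold: float = 0.05   # the source literature prints 0.5; see docs
    r2_threshold: float = 0.3


@dataclass
class DmConfig:
    """Differential-methylation probe filter."""

    delta_quantile: float = 0.75
    p_threshold: float = 0.05


@dataclass
class BgeConfig:
    alpha_mu: float = 1.0
    alpha_w: float | None = None   # None -> N + 2
    t_scale: float | None = None   # None -> am (aw - N - 1) / (am + 1)


@dataclass
class McmcConfig:
    """Sampler settings; defaults are the study conditions.

    The sampling phase draws ``sampling_iterations`` structures per
    chain (two chains), discards the first ``burn_in`` and thins every
    ``thin``; the greedy horizon keeps the best of ``n_paths``
    independent 500-iteration segments.
    """

    sampling_iterations: int = 200_000
    burn_in: int = 100_000
    thin: int = 500
    p_mbr: float = 1.0 / 15.0
    horizon: int = 500
    n_paths: int = 3
    beta_min: float = 0.5
    beta_max: float = 10.0
    beta_init_upper: float = 10.0
    sigma_init: float = 5.0
    adapt1_iterations: int = 2_000
    adapt1_batch: int = 100
    adapt2_iterations: int = 10_000
    transient_window: int = 500
    transient_max_windows: int = 20
    accept_low: float = 0.28
    accept_high: float = 0.60
    sigma_step: float = 0.4
    sigma_step_fine: float = 0.1
    extension_block: int = 50_000
    max_extensions: int = 2
    seed: int = 0


@dataclass
class Config:
    meth: MethConfig = field(default_factory=MethConfig)
    dm: DmConfig = field(default_factory=DmConfig)
    bge: BgeConfig = field(default_factory=BgeConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)


_SECTIONS = {"meth": MethConfig, "dm": DmConfig, "bge": BgeConfig,
             "mcmc": McmcConfig}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> Config:
    """Build a Config from a YAML file and/or flat ``section.key`` overrides."""
    cfg = Config()
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    flat: dict[str, dict] = {}
    for key, val in raw.items():
        if isinstance(val, dict):
            flat.setdefault(key, {}).update(val)
        elif "." in key:
            sect, sub = key.split(".", 1)
            flat.setdefault(sect, {})[sub] = val
        else:
            raise ValueError(f"unrecognised config key {key!r}")
    for key, val in (overrides or {}).items():
        sect, sub = key.split(".", 1)
        flat.setdefault(sect, {})[sub] = val
    for sect, entries in flat.items():
        if sect not in _SECTIONS:
            raise ValueError(f"unknown config section {sect!r}")
        target = getattr(cfg, sect)
        valid = {f.name for f in fields(target)}
        for sub, val in entries.items():
            if sub not in valid:
                raise ValueError(f"unknown config key {sect}.{sub}")
            setattr(target, sub, val)
    return cfg
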