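"""Key-value configuration shared by the CLI subcommands."""

from __future__ import annotations

import logging

import yaml

DEFAULTS: dict = {
    "biomass_path": None,        # input biomass CSV; None -> simulate
    "design_path": None,         # input design CSV; None -> default design
    "preset": "jena_like",       # simulation preset when simulating
    "seed": 0,
    "delimiter": ",",
    "window_width": 5,
    "outlier_multiplier": 6.0,
    "time_transform": "linear",  # for slope/indirect trends
    "n_boot": 1000,
    "windows": "nonoverlap",     # 'nonoverlap' | 'rolling' for the paths command
    "sown_only": True,           # sown species contribute sigma_i = 0 series
}


def load_config(path: str | None) -> dict:
    """Load a YAML config, filling unspecified keys from DEFAULTS."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
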