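"""Synthetic grassland-experiment generator with known ground truth.

The generator produces species-level annual biomass for every plot in a
design under a multiplicative log-normal model:

    biomass_ijt = (m0_i / N) · exp(−max(d0 − d1·log2 N, 0)·t)
                  · exp(sel_link · z_i · 1[N>1])
                  · exp(u_t + v_it + ε_ijt)

for species *i* in plot *j* (sown richness *N*) in year *t* (t = 0 is the
first year), where m0_i is the species' lognormal monoculture baseline,
z_i its standardized log-baseline (so ``sel_link`` couples intrinsically
productive species to mixture dominance — a selection-effect control),
u_t a common year effect, v_it a species-specific year deviation shared
across plots (a species has one "good year" everywhere, which is what
makes monoculture-based relative yields meaningful), and ε independent
residual noise. With probability ``dropout_prob`` an observation is set
to zero, exercising the monoculture-failure exclusion path downstream.

The richness-dependent decline rate max(d0 − d1·log2 N, 0) makes
monocultures decline fastest and diverse mixtures least, the temporal
structure whose recovery the slope and path modules are tested on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd

from divstab.design import PlotDesign


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    All SDs are on the natural-log scale and must be non-negative;
    ``0 <= dropout_prob < 1``.
    """

    n_years: int = 17
    seed: int = 0
    m0_log_mean: float = 6.0  # exp(6) ≈ 400 g/m², a typical grassland ANPP
    m0_log_sd: float = 0.5
    d0: float = 0.06  # baseline proportional decline per year
    d1: float = 0.015  # decline reduction per log2(richness) unit
    sigma_year: float = 0.2
    sigma_species_year: float = 0.3
    sigma_resid: float = 0.2
    sel_link: float = 0.0
    dropout_prob: float = 0.0

    def validate(self) -> None:
        for name in ("m0_log_sd", "sigma_year", "sigma_species_year", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError(f"dropout_prob must be in [0, 1), got {self.dropout_prob}")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")


@dataclass
class GroundTruth:
    """Realized latent quantities, stored for recovery tests."""

    m0: pd.Series  # per-species baseline, indexed by species_id
    year_effects: np.ndarray  # u_t, length n_years
    species_year: pd.DataFrame  # v_it, species × years


def decline_rate(cfg: SimulationConfig, richness: int) -> float:
    """Effective proportional decline per year at a given sown richness."""
    return max(cfg.d0 - cfg.d1 * math.log2(richness), 0.0)


def simulate_experiment(
    design: list[PlotDesign], cfg: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a full experiment for a design under a configuration.

    Returns the long-format biomass table (plot_id, year, species_id,
    biomass) with years numbered 1…n_years, and the realized ground truth.
    Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    species = sorted({s for p in design for s in p.composition})
    n_sp, n_yr = len(species), cfg.n_years
    sp_index = {s: k for k, s in enumerate(species)}

    log_m0 = rng.normal(cfg.m0_log_mean, cfg.m0_log_sd, size=n_sp)
    m0 = np.exp(log_m0)
    sd = log_m0.std()
    z = (log_m0 - log_m0.mean()) / sd if sd > 0 else np.zeros(n_sp)

    u = rng.normal(0.0, cfg.sigma_year, size=n_yr) if cfg.sigma_year > 0 else np.zeros(n_yr)
    v = (
        rng.normal(0.0, cfg.sigma_species_year, size=(n_sp, n_yr))
        if cfg.sigma_species_year > 0
        else np.zeros((n_sp, n_yr))
    )

    t = np.arange(n_yr, dtype=float)
    plot_ids, years_col, species_col, biomass_col = [], [], [], []
    for plot in design:
        N = plot.sown_richness
        mixture = N > 1 and not plot.is_monoculture_reference
        rate = decline_rate(cfg, N)
        for s in sorted(plot.composition):
            k = sp_index[s]
            mean_log = (
                math.log(m0[k] / N)
                - rate * t
                + (cfg.sel_link * z[k] if mixture else 0.0)
                + u
                + v[k]
            )
            eps = rng.normal(0.0, cfg.sigma_resid, size=n_yr) if cfg.sigma_resid > 0 else 0.0
            biomass = np.exp(mean_log + eps)
            if cfg.dropout_prob > 0:
                biomass = np.where(rng.random(n_yr) < cfg.dropout_prob, 0.0, biomass)
            plot_ids.extend([plot.plot_id] * n_yr)
            years_col.extend(range(1, n_yr + 1))
            species_col.extend([s] * n_yr)
            biomass_col.extend(biomass.tolist())

    table = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "year": years_col,
            "species_id": species_col,
            "biomass": biomass_col,
        }
    )
    truth = GroundTruth(
        m0=pd.Series(m0, index=pd.Index(species, name="species_id"), name="m0"),
        year_effects=u,
        species_year=pd.DataFrame(v, index=species, columns=range(1, n_yr + 1)),
    )
    return table, truth


_PRESETS: dict[str, SimulationConfig] = {
    # no diversity effects at all: decline identical across richness,
    # no baseline-dominance coupling; noise only
    "null": SimulationConfig(
        d0=0.03, d1=0.0, sel_link=0.0,
        sigma_year=0.1, sigma_species_year=0.1, sigma_resid=0.2,
    ),
    # richness-dependent decline: complementarity strengthens over time
    "complementarity_growth": SimulationConfig(
        d0=0.08, d1=0.02, sel_link=0.0,
        sigma_year=0.1, sigma_species_year=0.15, sigma_resid=0.15,
    ),
    # species-specific year deviations dominate: asynchrony-driven stability
    "asynchrony": SimulationConfig(
        d0=0.0, d1=0.0, sel_link=0.0,
        sigma_year=0.05, sigma_species_year=0.4, sigma_resid=0.1,
    ),
    # productive species dominate mixtures: positive selection effect
    "selection": SimulationConfig(
        d0=0.0, d1=0.0, sel_link=0.5,
        sigma_year=0.1, sigma_species_year=0.1, sigma_resid=0.15,
    ),
    # everything nonzero at the 17-year scale of the emulated experiment
    "jena_like": SimulationConfig(
        n_years=17, d0=0.06, d1=0.015, sel_link=0.2,
        sigma_year=0.2, sigma_species_year=0.3, sigma_resid=0.2,
        dropout_prob=0.02,
    ),
}


def scenario_presets() -> dict[str, SimulationConfig]:
    """Return fresh copies of the named scenario configurations."""
    return {name: replace(cfg) for name, cfg in _PRESETS.items()}


def get_preset(name: str, **overrides) -> SimulationConfig:
    """Fetch one preset by name, optionally overriding fields."""
    presets = scenario_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return replace(presets[name], **overrides)


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
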