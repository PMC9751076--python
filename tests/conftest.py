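import numpy as np
import pandas as pd
import pytest

from divstab import (
    build_default_design,
    simulate_experiment,
    monoculture_index,
    partition_annual,
    flag_outliers,
)
from divstab.simulate import get_preset


@pytest.fixture(scope="session")
def design():
    return build_default_design(seed=1)


@pytest.fixture(scope="session")
def jena_sim(design):
    """One 17-year simulation with all effect channels active."""
    cfg = get_preset("jena_like", seed=3)
    table, truth = simulate_experiment(design, cfg)
    return table, truth


@pytest.fixture(scope="session")
def jena_table(jena_sim):
    return jena_sim[0]


@pytest.fixture(scope="session")
def jena_mono(jena_table, design):
    return monoculture_index(jena_table, design)


@pytest.fixture(scope="session")
def jena_effects(jena_table, jena_mono, design):
    return flag_outliers(partition_annual(jena_table, jena_mono, design))


def toy_design():
    """Two-species mixture plus its two monoculture references."""
    from divstab.design import PlotDesign

    return [
        PlotDesign("MIX", 1, 2, frozenset({"A", "B"}), 1),
        PlotDesign("MONO_A", 1, 1, frozenset({"A"}), 1, is_monoculture_reference=True),
        PlotDesign("MONO_B", 2, 1, frozenset({"B"}), 1, is_monoculture_reference=True),
    ]


def toy_table(mix_by_year: dict, mono_by_year: dict) -> pd.DataFrame:
    """Long table from {year: {species: O}} and {year: {species: M}}."""
    rows = []
    for year, sp in mix_by_year.items():
        for s, o in sp.items():
            rows.append(("MIX", year, s, o))
    for year, sp in mono_by_year.items():
        for s, m in sp.items():
            rows.append((f"MONO_{s}", year, s, m))
    return pd.DataFrame(rows, columns=["plot_id", "year", "species_id", "biomass"])


def partition_oracle(O: dict, M: dict) -> dict:
    """Brute-force evaluation of the partition formulas on one plot-year.

    Independent of the pipeline: direct translation of the definitions
    RY_i = O_i/M_i, RYT = ΣRY_i, NE = ΣO − ΣM/N, CE = (RYT−1)(ΣM/N),
    SE = (N−1)·cov(M, RY − 1/N), excluding species with M_i = 0.
    """
    used = [s for s in O if M.get(s, 0) > 0]
    n = len(used)
    ry = {s: O[s] / M[s] for s in used}
    ryt = sum(ry.values())
    mbar = sum(M[s] for s in used) / n
    ne = sum(O[s] for s in used) - mbar
    ce = (ryt - 1.0) * mbar
    m_arr = np.array([M[s] for s in used], dtype=float)
    ry_dev = np.array([ry[s] - 1.0 / n for s in used], dtype=float)
    se = (n - 1) * np.cov(m_arr, ry_dev, ddof=1)[0, 1] if n > 1 else 0.0
    return {"N_used": n, "RYT": ryt, "NE": ne, "CE": ce, "SE": se}


def synchrony_oracle(series: dict) -> dict:
    """Direct evaluation of θ, asynchrony, CVs from per-species series."""
    mat = np.array(list(series.values()), dtype=float)
    community = mat.sum(axis=0)
    mu, sd = community.mean(), community.std(ddof=1)
    sum_sd = mat.std(axis=1, ddof=1).sum()
    theta = np.sqrt(sd**2 / sum_sd**2) if sum_sd > 0 else np.nan
    return {
        "mu_net": mu,
        "sd_net": sd,
        "theta": theta,
        "asynchrony": 1 - theta,
        "cv_pop": sum_sd / mu,
        "cv_net": sd / mu,
        "stability": mu / sd if sd > 0 else np.nan,
    }
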