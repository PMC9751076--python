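"""Additive partitioning of net biodiversity effects.

For a mixture of N species with observed yields O_i and monoculture yields
M_i, the relative yield of species *i* is RY_i = O_i / M_i and the relative
yield total RYT = Σ RY_i. The net biodiversity effect and its additive
components are

    NE = Σ O_i − Σ M_i / N
    CE = (RYT − 1) · (Σ M_i / N)
    SE = (N − 1) · cov(M_i, RY_i − 1/N)

with the sample-covariance convention Σ(x−x̄)(y−ȳ)/(N−1), so that
(N − 1)·cov equals the raw cross-product sum and NE = CE + SE holds
identically. A species whose monoculture yield is zero in a year has an
undefined RY_i and is excluded from that plot-year's partition (N is
decremented accordingly); zero observed biomass in the mixture is kept
(RY_i = 0). Extreme CE/SE values are flagged by quartile fences
Q1 − m·IQR / Q3 + m·IQR with m = 6 by default.

Windowed effects apply the identical formulas after first summing species
and monoculture biomass over the window years; interannually asynchronous
dominance then surfaces as multi-year complementarity even when each
single year is dominated by one species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from divstab.design import PlotDesign

REASON_OK = ""
REASON_TOO_FEW = "fewer_than_2_usable_monocultures"


def monoculture_index(table: pd.DataFrame, design: list[PlotDesign]) -> pd.DataFrame:
    """Per species-year monoculture yield M_i.

    When a species has several monoculture-reference plots in a year, M_i is
    their mean annual biomass. Entries with M_i = 0 (the species did not
    establish in monoculture that year) are flagged unusable.

    Parameters
    ----------
    table : DataFrame
        Long-format biomass (plot_id, year, species_id, biomass).
    design : list of PlotDesign
        Must identify at least one monoculture-reference plot per species
        appearing in any mixture composition.

    Returns
    -------
    DataFrame
        Columns species_id, year, M, n_plots, usable.

    Raises
    ------
    ValueError
        If a species sown in any mixture has no monoculture-reference plot.
    """
    mono_plots = {p.plot_id: next(iter(p.composition)) for p in design if p.is_monoculture_reference}
    covered = set(mono_plots.values())
    needed = {s for p in design if not p.is_monoculture_reference for s in p.composition}
    missing = sorted(needed - covered)
    if missing:
        raise ValueError(f"species with no monoculture-reference plot: {missing}")

    sub = table[table["plot_id"].isin(mono_plots)].copy()
    sub["species_id"] = sub["plot_id"].map(mono_plots)
    # annual plot biomass of each monoculture plot, then mean across plots
    per_plot = sub.groupby(["species_id", "year", "plot_id"], as_index=False)["biomass"].sum()
    idx = per_plot.groupby(["species_id", "year"], as_index=False).agg(
        M=("biomass", "mean"), n_plots=("biomass", "size")
    )
    idx["usable"] = idx["M"] > 0
    return idx


def _mono_mean_anpp(table: pd.DataFrame, design: list[PlotDesign]) -> pd.Series:
    """Mean annual plot biomass across all monoculture-reference plots, per year."""
    mono_ids = {p.plot_id for p in design if p.is_monoculture_reference}
    sub = table[table["plot_id"].isin(mono_ids)]
    per_plot = sub.groupby(["year", "plot_id"])["biomass"].sum()
    return per_plot.groupby("year").mean()


def _composition_grid(design: list[PlotDesign], years: list[int]) -> pd.DataFrame:
    """(plot_id, species_id) × year grid for all non-reference plots."""
    rows = [
        (p.plot_id, s, p.sown_richness, p.block)
        for p in design
        if not p.is_monoculture_reference
        for s in sorted(p.composition)
    ]
    comp = pd.DataFrame(rows, columns=["plot_id", "species_id", "N_sown", "block"])
    return comp.merge(pd.DataFrame({"year": years}), how="cross")


def _partition_grid(grid: pd.DataFrame, group_keys: list[str]) -> pd.DataFrame:
    """Evaluate the partition formulas on a grid carrying O, M and usable.

    The grid has one row per (group, species) with observed yield O and
    monoculture yield M; rows with unusable M are excluded and N is the
    count of usable species. Returns one row per group with N_used, RYT,
    NE, CE, SE and the excluded species list.
    """
    g = grid.copy()
    g["used"] = g["usable"] & (g["M"] > 0)
    g["RY"] = np.where(g["used"], g["O"] / g["M"].where(g["M"] > 0, np.nan), np.nan)
    g["O_used"] = np.where(g["used"], g["O"], 0.0)
    g["M_used"] = np.where(g["used"], g["M"], 0.0)

    agg = g.groupby(group_keys, sort=True).agg(
        N_sown=("N_sown", "first"),
        block=("block", "first"),
        N_used=("used", "sum"),
        sum_O=("O_used", "sum"),
        sum_M=("M_used", "sum"),
        RYT=("RY", "sum"),
    )
    excl = (
        g[~g["used"]]
        .groupby(group_keys)["species_id"]
        .apply(lambda s: ";".join(sorted(s)))
        .rename("excluded_species")
    )
    agg = agg.join(excl)
    agg["excluded_species"] = agg["excluded_species"].fillna("")

    n = agg["N_used"].to_numpy(dtype=float)
    ok = (n >= 2) & (agg["N_sown"].to_numpy() >= 2)
    mbar = np.divide(agg["sum_M"].to_numpy(), n, out=np.full_like(n, np.nan), where=n > 0)
    ryt = agg["RYT"].to_numpy(dtype=float)
    ne = agg["sum_O"].to_numpy() - mbar
    ce = (ryt - 1.0) * mbar
    se = ne - ce  # identical to (N−1)·cov(M, RY−1/N); see module docstring

    agg["RYT"] = np.where(ok, ryt, np.nan)
    agg["NE"] = np.where(ok, ne, np.nan)
    agg["CE"] = np.where(ok, ce, np.nan)
    agg["SE"] = np.where(ok, se, np.nan)
    agg["reason"] = np.where(ok, REASON_OK, REASON_TOO_FEW)
    return agg.reset_index()


def partition_annual(
    table: pd.DataFrame, mono: pd.DataFrame, design: list[PlotDesign]
) -> pd.DataFrame:
    """Annual biodiversity-effect partition for every main plot and year.

    Emits one record per (plot, year) for all non-reference plots: annual
    ANPP and community relative yield (plot ANPP ÷ mean monoculture ANPP of
    that year) for every plot, and RYT/NE/CE/SE for mixtures with at least
    two species having usable (nonzero) monoculture yields. Records where
    the partition is undefined carry NaN effects and a reason code.
    """
    years = sorted(table["year"].unique())
    grid = _composition_grid(design, years)
    obs = table.groupby(["plot_id", "year", "species_id"], as_index=False)["biomass"].sum()
    grid = grid.merge(obs, on=["plot_id", "year", "species_id"], how="left")
    grid["O"] = grid["biomass"].fillna(0.0)
    grid = grid.merge(
        mono[["species_id", "year", "M", "usable"]], on=["species_id", "year"], how="left"
    )
    grid["M"] = grid["M"].fillna(0.0)
    grid["usable"] = grid["usable"].fillna(False).astype(bool)

    out = _partition_grid(grid, ["plot_id", "year"])

    anpp = grid.groupby(["plot_id", "year"])["O"].sum().rename("ANPP")
    out = out.merge(anpp.reset_index(), on=["plot_id", "year"], how="left")
    mono_mean = _mono_mean_anpp(table, design).rename("mono_mean_ANPP")
    out = out.merge(mono_mean.reset_index(), on="year", how="left")
    out["RY_community"] = out["ANPP"] / out["mono_mean_ANPP"]
    out["outlier_flag"] = False
    cols = [
        "plot_id", "year", "block", "N_sown", "N_used", "ANPP", "RY_community",
        "RYT", "NE", "CE", "SE", "excluded_species", "reason", "outlier_flag",
    ]
    return out[cols]


def partition_window(
    table: pd.DataFrame,
    mono: pd.DataFrame,
    design: list[PlotDesign],
    window: tuple[int, int],
) -> pd.DataFrame:
    """Biodiversity-effect partition on biomass summed over a window.

    Species mixture biomass and monoculture biomass are each summed over the
    window years first; the identical partition formulas are then applied to
    the sums. A species is excluded if its summed monoculture biomass is
    zero over the window.

    Parameters
    ----------
    window : (start_year, width)
        The years start_year … start_year+width−1, all of which must be
        present in the table.
    """
    start, width = window
    wyears = list(range(start, start + width))
    present = set(table["year"].unique())
    absent = [y for y in wyears if y not in present]
    if absent:
        raise ValueError(f"window {window} requires missing years {absent}")

    sub = table[table["year"].isin(wyears)]
    grid = _composition_grid(design, wyears)
    obs = sub.groupby(["plot_id", "year", "species_id"], as_index=False)["biomass"].sum()
    grid = grid.merge(obs, on=["plot_id", "year", "species_id"], how="left")
    grid["O"] = grid["biomass"].fillna(0.0)
    grid = grid.merge(mono[["species_id", "year", "M"]], on=["species_id", "year"], how="left")
    grid["M"] = grid["M"].fillna(0.0)

    summed = grid.groupby(["plot_id", "species_id"], as_index=False).agg(
        N_sown=("N_sown", "first"),
        block=("block", "first"),
        O=("O", "sum"),
        M=("M", "sum"),
    )
    summed["usable"] = summed["M"] > 0

    out = _partition_grid(summed, ["plot_id"])
    anpp = summed.groupby("plot_id")["O"].sum().rename("window_ANPP_sum")
    out = out.merge(anpp.reset_index(), on="plot_id", how="left")
    out.insert(1, "window_start", start)
    out.insert(2, "width", width)
    out["outlier_flag"] = False
    cols = [
        "plot_id", "window_start", "width", "block", "N_sown", "N_used",
        "window_ANPP_sum", "RYT", "NE", "CE", "SE",
        "excluded_species", "reason", "outlier_flag",
    ]
    return out[cols]


def quartile_fences(values: np.ndarray, multiplier: float) -> tuple[float, float]:
    """Tukey-style fences Q1 − m·IQR and Q3 + m·IQR over finite values.

    Quartiles use the linear-interpolation convention.
    """
    finite = np.asarray(values, dtype=float)
    finite = finite[np.isfinite(finite)]
    q1, q3 = np.percentile(finite, [25, 75])
    iqr = q3 - q1
    return q1 - multiplier * iqr, q3 + multiplier * iqr


def flag_outliers(
    effects: pd.DataFrame,
    multiplier: float = 6.0,
    columns: tuple[str, ...] = ("CE", "SE"),
) -> pd.DataFrame:
    """Flag extreme values per effect column by quartile fences.

    A row's ``outlier_flag`` is set if any listed column falls outside
    Q1 − m·IQR … Q3 + m·IQR (pooled over all finite values of that column).
    Flagged rows keep their values; downstream regressions exclude them.

    Raises
    ------
    ValueError
        If ``multiplier`` is not positive or fewer than 4 finite values are
        available in a column.
    """
    if not multiplier > 0:
        raise ValueError(f"multiplier must be positive, got {multiplier}")
    out = effects.copy()
    flag = np.zeros(len(out), dtype=bool)
    for col in columns:
        vals = out[col].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if finite.sum() < 4:
            raise ValueError(f"need >= 4 finite {col} values to compute quartiles")
        if np.isinf(multiplier):
            continue
        lo, hi = quartile_fences(vals, multiplier)
        flag |= finite & ((vals < lo) | (vals > hi))
    out["outlier_flag"] = flag
    return out
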