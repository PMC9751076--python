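"""Temporal stability, species synchrony, and population variability.

Over a window of years, a plot's annual community biomass series has mean
μ_net and (sample, n−1) standard deviation σ_net. Community stability is
the inverse coefficient of variation μ_net/σ_net. Species synchrony is

    θ = σ_net / Σ_i σ_i                     (0 ≤ θ ≤ 1)

where σ_i are the per-species temporal standard deviations (the printed
square-root-of-squares form is algebraically identical for non-negative
arguments); asynchrony is 1 − θ. Population-level variability is
CV_pop = (Σ_i σ_i)/μ_net, whose inverse is population stability, and the
exact identity CV_net = θ · CV_pop links the three.

Species that are sown in a plot but never recorded contribute a constant
zero series (σ_i = 0), which leaves θ unchanged; monocultures have θ ≡ 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from divstab.design import PlotDesign


def enumerate_windows(years: list[int], width: int) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """All rolling windows of a given width, plus a non-overlapping subset.

    Rolling windows start at every year for which the full width fits:
    count = n_years − width + 1. The non-overlapping subset has the maximal
    count k = n_years // width, spread evenly so the first window starts at
    the first year and the last ends at the final year (for 17 years and
    width 5 this gives starts at years 1, 7 and 13 — i.e. gaps of one year
    between consecutive windows).

    Parameters
    ----------
    years : list of int
        Consecutive study years (e.g. range(2003, 2020)).
    width : int
        Window width in years; must be >= 2 (temporal variance is
        undefined below that) and <= the number of years.

    Returns
    -------
    (rolling, nonoverlapping)
        Two lists of (start_year, width) tuples.
    """
    years = sorted(years)
    n = len(years)
    if width < 2:
        raise ValueError(f"window width must be >= 2 (variance undefined), got {width}")
    if width > n:
        raise ValueError(f"window width {width} exceeds the {n} available years")
    if years != list(range(years[0], years[0] + n)):
        raise ValueError("years must be consecutive")

    rolling = [(years[i], width) for i in range(n - width + 1)]

    k = n // width
    if k == 1:
        starts = [0]
    else:
        span = n - width  # last admissible start offset
        starts = [round(j * span / (k - 1)) for j in range(k)]
    nonoverlap = [(years[s], width) for s in starts]
    return rolling, nonoverlap


def _series_matrix(sub: pd.DataFrame, composition: frozenset, wyears: list[int]) -> np.ndarray:
    """Species × years biomass matrix with zeros for unrecorded entries."""
    mat = (
        sub.pivot_table(index="species_id", columns="year", values="biomass", aggfunc="sum")
        .reindex(index=sorted(composition), columns=wyears)
        .fillna(0.0)
    )
    return mat.to_numpy(dtype=float)


def window_metrics(
    table: pd.DataFrame,
    design: list[PlotDesign],
    window: tuple[int, int],
    sown_only: bool = True,
) -> pd.DataFrame:
    """Stability and synchrony metrics per plot over one window.

    For each non-reference plot with all window years present: the annual
    community series gives μ_net and σ_net; per sown species the annual
    series (zeros included for years the species was not recorded) gives
    σ_i; then θ = σ_net/Σσ_i, asynchrony = 1 − θ, CV_pop = Σσ_i/μ_net and
    stability = μ_net/σ_net. Records where Σσ_i = 0 or μ_net = 0 are
    emitted with NaN in the undefined fields and a reason code.

    Parameters
    ----------
    sown_only : bool
        If True (default), every sown species contributes a series even if
        never observed; if False, only observed species enter Σσ_i.
    """
    start, width = window
    wyears = list(range(start, start + width))
    sub = table[table["year"].isin(wyears)]
    by_plot = dict(tuple(sub.groupby("plot_id")))

    records = []
    for plot in design:
        if plot.is_monoculture_reference:
            continue
        psub = by_plot.get(plot.plot_id)
        rec = {
            "plot_id": plot.plot_id,
            "window_start": start,
            "width": width,
            "block": plot.block,
            "N_sown": plot.sown_richness,
            "reason": "",
        }
        if psub is None or set(psub["year"].unique()) != set(wyears):
            rec.update(
                mu_net=np.nan, sd_net=np.nan, cv_net=np.nan, stability=np.nan,
                theta=np.nan, asynchrony=np.nan, cv_pop=np.nan, pop_stability=np.nan,
                reason="missing_window_years",
            )
            records.append(rec)
            continue
        comp = plot.composition if sown_only else frozenset(psub["species_id"].unique())
        mat = _series_matrix(psub, comp, wyears)
        community = mat.sum(axis=0)
        mu = community.mean()
        sd = community.std(ddof=1)
        sum_sd_i = mat.std(axis=1, ddof=1).sum()

        theta = sd / sum_sd_i if sum_sd_i > 0 else np.nan
        cv_pop = sum_sd_i / mu if mu > 0 else np.nan
        cv_net = sd / mu if mu > 0 else np.nan
        rec.update(
            mu_net=mu,
            sd_net=sd,
            cv_net=cv_net,
            stability=mu / sd if sd > 0 else np.nan,
            theta=theta,
            asynchrony=1.0 - theta if np.isfinite(theta) else np.nan,
            cv_pop=cv_pop,
            pop_stability=mu / sum_sd_i if sum_sd_i > 0 else np.nan,
        )
        if sum_sd_i == 0:
            rec["reason"] = "all_species_constant"
        elif mu == 0:
            rec["reason"] = "zero_mean_biomass"
        records.append(rec)
    return pd.DataFrame.from_records(records)


def rolling_window_metrics(
    table: pd.DataFrame, design: list[PlotDesign], width: int, sown_only: bool = True
) -> pd.DataFrame:
    """Concatenated :func:`window_metrics` over all rolling windows."""
    years = sorted(table["year"].unique())
    rolling, _ = enumerate_windows(years, width)
    return pd.concat(
        [window_metrics(table, design, w, sown_only=sown_only) for w in rolling],
        ignore_index=True,
    )


def pooled_metrics(table: pd.DataFrame, design: list[PlotDesign], sown_only: bool = True) -> pd.DataFrame:
    """Per-plot metrics over the full span of years (one maximal window)."""
    years = sorted(table["year"].unique())
    return window_metrics(table, design, (years[0], len(years)), sown_only=sown_only)
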