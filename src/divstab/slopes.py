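"""Richness–response power-law slopes and their exact decompositions.

Cross-sectional fits of log(response) on log(sown richness) give the power
exponent *b* of the richness–response relationship for each year or
window. Because ordinary least squares is linear in the response, slopes
of log-products decompose exactly on a common plot set:

    b_CVnet⁻¹ = b_mean − b_SD            (CV_net⁻¹ = μ_net/σ_net)
    b_CVnet⁻¹ = b_θ⁻¹ + b_CVpop⁻¹        (CV_net⁻¹ = θ⁻¹ · CV_pop⁻¹)

The slope of log(asynchrony) = log(1 − θ) is also reported; it carries the
field's usual interpretation but does not satisfy a sum identity exactly,
since log(1 − θ) is not a linear combination of the other logs.

Trend tests regress per-year (or per-window) slopes on time to detect
strengthening or weakening richness effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: default transform per response for the yearly richness fits; None = identity
RESPONSE_TRANSFORMS: dict[str, str | None] = {
    "ANPP": "sqrt",
    "RY_community": "log",
    "NE": None,
    "CE": None,
    "SE": None,
    "RYT": "log",
}

_TRANSFORMS = {None: lambda x: x, "log": np.log, "sqrt": np.sqrt}

#: responses measured in g/m² whose slopes are rescaled by yearly mean ANPP
ABSOLUTE_EFFECTS = ("NE", "CE", "SE")


def _fit(x: np.ndarray, y: np.ndarray) -> dict:
    res = stats.linregress(x, y)
    return {
        "b": res.slope,
        "intercept": res.intercept,
        "stderr": res.stderr,
        "p": res.pvalue,
        "r2": res.rvalue**2,
        "n": len(x),
    }


def yearly_richness_fits(
    effects: pd.DataFrame,
    responses: dict[str, str | None] | None = None,
    exclude_outliers: bool = True,
) -> pd.DataFrame:
    """Per-year OLS fits of (transformed) responses on log(sown richness).

    Parameters
    ----------
    effects : DataFrame
        Annual partition output (plot_id, year, N_sown, ANPP, RY_community,
        RYT, NE, CE, SE, outlier_flag).
    responses : mapping response -> transform (None | "log" | "sqrt")
        Defaults to :data:`RESPONSE_TRANSFORMS`. Rows with non-positive
        values under a log transform are dropped from that fit.
    exclude_outliers : bool
        Drop rows with ``outlier_flag`` set (default True).

    Returns
    -------
    DataFrame
        One row per (response, year) with b, intercept, stderr, p, r2, n;
        years with fewer than 3 distinct richness values are skipped with
        a reason.
    """
    responses = RESPONSE_TRANSFORMS if responses is None else responses
    rows = []
    for (year,), sub in effects.groupby(["year"]):
        for resp, tname in responses.items():
            if resp not in sub.columns:
                continue
            data = sub
            if exclude_outliers and resp in ("NE", "CE", "SE", "RYT") and "outlier_flag" in sub:
                data = sub[~sub["outlier_flag"].astype(bool)]
            y_raw = data[resp].to_numpy(dtype=float)
            x_raw = data["N_sown"].to_numpy(dtype=float)
            mask = np.isfinite(y_raw)
            if tname == "log":
                mask &= y_raw > 0
            y = _TRANSFORMS[tname](y_raw[mask])
            x = np.log(x_raw[mask])
            rec = {"response": resp, "transform": tname or "identity", "year": year}
            if len(np.unique(x)) < 3:
                rec.update(b=np.nan, intercept=np.nan, stderr=np.nan, p=np.nan,
                           r2=np.nan, n=int(mask.sum()), reason="fewer_than_3_richness_levels")
            else:
                rec.update(_fit(x, y), reason="")
            rows.append(rec)
    return pd.DataFrame(rows)


def relative_effect_slopes(fits: pd.DataFrame, effects: pd.DataFrame) -> pd.DataFrame:
    """Express absolute-effect slopes relative to yearly field productivity.

    NE/CE/SE are measured in g/m², so their richness slopes are divided by
    the grand-mean ANPP of all plots in the same year, making slopes
    comparable across years of very different productivity.
    """
    grand = effects.groupby("year")["ANPP"].mean().rename("mean_ANPP")
    out = fits[fits["response"].isin(ABSOLUTE_EFFECTS)].merge(
        grand.reset_index(), on="year", how="left"
    )
    zero = ~(out["mean_ANPP"] > 0)
    out["b_relative"] = np.where(zero, np.nan, out["b"] / out["mean_ANPP"])
    out["reason"] = np.where(zero, "zero_grand_mean_ANPP", out["reason"])
    return out


def slope_trend(
    fits: pd.DataFrame,
    value: str = "b",
    time: str = "year",
    time_transform: str = "linear",
) -> pd.DataFrame:
    """Regress per-time slopes on time to test for a temporal trend.

    Parameters
    ----------
    fits : DataFrame
        Rows with a ``response`` column, a time column and a slope column.
    time_transform : "linear" | "log"
        Regress on time as-is or on log(time index).

    Returns
    -------
    DataFrame
        One row per response: trend (slope of b on time), intercept,
        stderr, p, r2, n.
    """
    if time_transform not in ("linear", "log"):
        raise ValueError(f"time_transform must be 'linear' or 'log', got {time_transform!r}")
    rows = []
    for resp, sub in fits.groupby("response"):
        sub = sub[np.isfinite(sub[value])]
        if len(sub) < 3:
            raise ValueError(f"need >= 3 time points for a trend fit of {resp!r}, got {len(sub)}")
        t = sub[time].to_numpy(dtype=float)
        if time_transform == "log":
            t = t - t.min() + 1.0
            t = np.log(t)
        res = _fit(t, sub[value].to_numpy(dtype=float))
        rows.append({"response": resp, "time_transform": time_transform,
                     "trend": res["b"], "intercept": res["intercept"],
                     "stderr": res["stderr"], "p": res["p"], "r2": res["r2"], "n": res["n"]})
    return pd.DataFrame(rows)


def relative_to_year1(effects: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Productivity of each plot relative to its first-year productivity.

    Divides each plot's annual ANPP by its ANPP in the first year present,
    log-transforms the ratio, and fits a per-richness-level linear year
    trend of the log ratio (the decline rate of that richness level).

    Returns
    -------
    (ratios, trends)
        ratios: plot_id, year, N_sown, ANPP, ratio, log_ratio.
        trends: per richness level decline slope of log-ratio on year,
        with stderr, p, r2, n.
    """
    year1 = effects["year"].min()
    base = (
        effects.loc[effects["year"] == year1, ["plot_id", "ANPP"]]
        .rename(columns={"ANPP": "ANPP_year1"})
    )
    ratios = effects[["plot_id", "year", "N_sown", "ANPP"]].merge(base, on="plot_id", how="left")
    excluded = ratios["ANPP_year1"] <= 0
    if excluded.any():
        import logging

        logging.getLogger("divstab").warning(
            "relative_to_year1: excluding %d plots with zero first-year ANPP",
            ratios.loc[excluded, "plot_id"].nunique(),
        )
    ratios = ratios[~excluded.fillna(True)].copy()
    ratios["ratio"] = ratios["ANPP"] / ratios["ANPP_year1"]
    ratios["log_ratio"] = np.log(ratios["ratio"].where(ratios["ratio"] > 0, np.nan))

    rows = []
    for level, sub in ratios.groupby("N_sown"):
        sub = sub[np.isfinite(sub["log_ratio"])]
        res = _fit(sub["year"].to_numpy(float), sub["log_ratio"].to_numpy(float))
        rows.append({"N_sown": level, "decline_slope": res["b"], "stderr": res["stderr"],
                     "p": res["p"], "r2": res["r2"], "n": res["n"]})
    return ratios, pd.DataFrame(rows)


#: metric -> (numerator log expression) used in the window-slope decomposition
_DECOMP_FIELDS = {
    "b_mean": "mu_net",
    "b_sd": "sd_net",
    "b_cvnet_inv": "stability",
    "b_async": "asynchrony",
    "b_cvpop_inv": "pop_stability",
    "b_invtheta": "inv_theta",
}


def decompose_window_slopes(metrics: pd.DataFrame) -> pd.DataFrame:
    """Power-law slope decomposition of stability per window.

    For each window, OLS slopes of log μ_net, log σ_net, log CV_net⁻¹,
    log asynchrony, log CV_pop⁻¹ and log θ⁻¹ on log richness are fitted on
    the common set of plots where all six quantities are positive and
    finite (monocultures drop out through asynchrony = 0). On that common
    set the identities b_CVnet⁻¹ = b_mean − b_SD and
    b_CVnet⁻¹ = b_θ⁻¹ + b_CVpop⁻¹ hold to machine precision; the gaps are
    reported as ``identity_gap_mean_sd`` and ``identity_gap_async``
    (the latter measured against b_async + b_CVpop⁻¹, which is *not* an
    exact identity).
    """
    m = metrics.copy()
    m["inv_theta"] = 1.0 / m["theta"]
    rows = []
    for start, sub in m.groupby("window_start"):
        common = np.ones(len(sub), dtype=bool)
        for field in _DECOMP_FIELDS.values():
            vals = sub[field].to_numpy(dtype=float)
            common &= np.isfinite(vals) & (vals > 0)
        sub = sub[common]
        rec: dict = {"window_start": start, "n": len(sub)}
        if len(sub) < 3 or sub["N_sown"].nunique() < 3:
            for name in _DECOMP_FIELDS:
                rec[name] = np.nan
            rec.update(identity_gap_mean_sd=np.nan, identity_gap_async=np.nan,
                       reason="fewer_than_3_richness_levels")
            rows.append(rec)
            continue
        x = np.log(sub["N_sown"].to_numpy(dtype=float))
        for name, field in _DECOMP_FIELDS.items():
            res = _fit(x, np.log(sub[field].to_numpy(dtype=float)))
            rec[name] = res["b"]
            rec[f"{name}_p"] = res["p"]
        rec["identity_gap_mean_sd"] = rec["b_cvnet_inv"] - (rec["b_mean"] - rec["b_sd"])
        rec["identity_gap_async"] = rec["b_cvnet_inv"] - (rec["b_async"] + rec["b_cvpop_inv"])
        rec["identity_gap_invtheta"] = rec["b_cvnet_inv"] - (rec["b_invtheta"] + rec["b_cvpop_inv"])
        rec["reason"] = ""
        rows.append(rec)
    return pd.DataFrame(rows)
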