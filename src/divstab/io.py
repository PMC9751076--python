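"""Reading and writing the pipeline's tables.

Biomass tables are long-format delimited text with one row per
(plot, year, species[, harvest]) observation in g/m²; spring and summer
harvest rows are summed into annual values on read.
"""

from __future__ import annotations

import logging
import os

import pandas as pd

logger = logging.getLogger("divstab")

REQUIRED_COLUMNS = ("plot_id", "year", "species_id", "biomass")


def read_biomass(path: str, sep: str = ",") -> pd.DataFrame:
    """Read and validate a long-format biomass table.

    An optional ``harvest`` column (e.g. spring/summer) is collapsed by
    summing biomass per (plot_id, year, species_id).

    Parameters
    ----------
    path : str
        Delimited text file with a header naming at least
        plot_id, year, species_id and biomass.
    sep : str
        Field delimiter (default comma).

    Returns
    -------
    pandas.DataFrame
        Columns plot_id, year, species_id, biomass; one row per
        plot-year-species; biomass non-negative.

    Raises
    ------
    ValueError
        If a required column is missing or any biomass is negative.
    """
    df = pd.read_csv(path, sep=sep)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"biomass table {path!r} is missing required column {col!r}")
    n_raw = len(df)
    df = df.dropna(subset=["plot_id", "year", "species_id", "biomass"])
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.warning("read_biomass: dropped %d malformed rows from %s", n_dropped, path)
    if len(df) == 0:
        logger.warning("read_biomass: %s contains no data rows", path)
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    df = df.astype({"year": int, "biomass": float})
    neg = df[df["biomass"] < 0]
    if len(neg):
        raise ValueError(f"negative biomass in {path!r}: first offending row {neg.iloc[0].to_dict()}")
    pooled = (
        df.groupby(["plot_id", "year", "species_id"], as_index=False, sort=True)["biomass"].sum()
    )
    logger.info("read_biomass: %d raw rows -> %d pooled rows from %s", n_raw, len(pooled), path)
    return pooled


def pool_harvests(df: pd.DataFrame) -> pd.DataFrame:
    """Sum harvests per (plot_id, year, species_id) on an in-memory table."""
    return df.groupby(["plot_id", "year", "species_id"], as_index=False, sort=True)["biomass"].sum()


def write_table(records: pd.DataFrame, path: str, sep: str = ",") -> None:
    """Write any tabular result as delimited text at full float precision.

    Column order is preserved; the written file round-trips through
    :func:`pandas.read_csv` to the values it was given (within 1e-12).
    """
    if records is None:
        raise ValueError("records must not be None")
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"directory does not exist: {parent}")
    records.to_csv(path, sep=sep, index=False, float_format="%.17g")
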