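"""Descriptive summaries of effort, landings ratio and species composition.

These mirror the nominal-trend tables a fisheries analyst produces before
modelling: total hooks set by year/month/fleet, the ratio of shark landings
to total landings by weight, and the percentage composition of shark
landings by numbers (%N) and weight (%W).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import SPECIES

__all__ = ["effort_summary", "shark_ratio", "composition"]


def effort_summary(records: pd.DataFrame, by) -> pd.DataFrame:
    """Total hooks set within groups; group totals conserve the grand total.

    ``by`` is a column name or list of column names (``year``, ``month``,
    ``fleet``, ``area`` ...).
    """
    by = [by] if isinstance(by, str) else list(by)
    out = (records.groupby(by, observed=True)["hooks"].sum()
           .reset_index(name="hooks_total"))
    return out


def shark_ratio(records: pd.DataFrame, by=("year", "fleet")) -> pd.DataFrame:
    """Shark weight over total landed weight per group; 0/0 is missing."""
    for col in ("weight_blue", "weight_mako", "weight_other"):
        if (pd.to_numeric(records[col], errors="coerce") < 0).any():
            raise ValueError(f"negative weights in {col}")
    by = [by] if isinstance(by, str) else list(by)
    g = records.groupby(by, observed=True)[
        ["weight_blue", "weight_mako", "weight_other"]].sum()
    shark = g["weight_blue"] + g["weight_mako"]
    total = shark + g["weight_other"]
    ratio = shark / total.replace(0.0, np.nan)   # 0/0 -> missing, not 0
    return ratio.rename("shark_ratio").reset_index()


def composition(records: pd.DataFrame, grouping=None) -> pd.DataFrame:
    """Species composition of shark landings by numbers (%N) and weight (%W).

    Returns one row per species within each group of ``grouping`` (or one
    overall group when ``grouping`` is None); within any group %N and %W each
    sum to 100 (when the group has any sharks at all).
    """
    grouping = ([] if grouping is None
                else [grouping] if isinstance(grouping, str)
                else list(grouping))
    long = []
    for sp in SPECIES:
        part = records[grouping].copy() if grouping else pd.DataFrame(
            index=records.index)
        part["species"] = sp
        part["n_sharks"] = pd.to_numeric(records[f"count_{sp}"],
                                         errors="coerce")
        part["weight_kg"] = pd.to_numeric(records[f"weight_{sp}"],
                                          errors="coerce")
        long.append(part)
    long = pd.concat(long, ignore_index=True)
    keys = grouping + ["species"]
    tbl = long.groupby(keys, observed=True)[
        ["n_sharks", "weight_kg"]].sum().reset_index()
    if grouping:
        tot = tbl.groupby(grouping, observed=True)[
            ["n_sharks", "weight_kg"]].transform("sum")
    else:
        tot = pd.DataFrame({
            "n_sharks": np.repeat(tbl["n_sharks"].sum(), len(tbl)),
            "weight_kg": np.repeat(tbl["weight_kg"].sum(), len(tbl)),
        })
    tbl["pct_N"] = 100.0 * tbl["n_sharks"] / tot["n_sharks"].replace(0, np.nan)
    tbl["pct_W"] = 100.0 * tbl["weight_kg"] / tot["weight_kg"].replace(0, np.nan)
    return tbl
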