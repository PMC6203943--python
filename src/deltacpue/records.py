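"""Logbook record schema and I/O.

A longline logbook is represented as a :class:`pandas.DataFrame` with one row
per set and a fixed column layout (:data:`LOGBOOK_COLUMNS`).  Each row records
when and where the set was made, by which vessel and fleet, the fishing effort
(hooks per line), whether a fisheries observer was aboard, and the retained
catch of blue sharks and shortfin makos by number and weight, plus the
combined weight of all other retained species (tunas, swordfish, other
sharks) used for composition reporting.
"""

from __future__ import annotations

import pandas as pd

#: Column order of a logbook table; one row per longline set.
LOGBOOK_COLUMNS = [
    "set_id",
    "year",
    "month",
    "day",
    "vessel_id",
    "fleet",
    "observer",
    "latitude",
    "longitude",
    "hooks",
    "count_blue",
    "count_mako",
    "weight_blue",
    "weight_mako",
    "weight_other",
    "target",
]

#: Fleet levels, reference level first.
FLEET_LEVELS = ("foreign", "local")
#: Observer levels, reference level first.
OBSERVER_LEVELS = ("no", "unknown", "yes")
#: Shark species modelled individually.
SPECIES = ("blue", "mako")
#: Declared target of a set.
TARGET_LEVELS = ("tuna", "swordfish", "shark")

#: Fields that must be non-missing for a record to be analysable.
REQUIRED_FIELDS = [
    "set_id", "year", "month", "day", "vessel_id", "fleet", "observer",
    "latitude", "longitude", "hooks",
    "count_blue", "count_mako", "weight_blue", "weight_mako", "weight_other",
]


class LogbookFormatError(ValueError):
    """Raised when a table cannot be interpreted as a logbook."""


def validate_logbook(df: pd.DataFrame) -> pd.DataFrame:
    """Check that ``df`` has the logbook column layout.

    Returns the frame unchanged on success; raises
    :class:`LogbookFormatError` naming the first offending column otherwise.
    Value-level problems (out-of-range hooks, impossible positions) are the
    cleaning module's job, not a format error.
    """
    missing = [c for c in LOGBOOK_COLUMNS if c not in df.columns]
    if missing:
        raise LogbookFormatError(f"missing logbook columns: {missing}")
    return df


def read_logbook(path) -> pd.DataFrame:
    """Read a logbook CSV (UTF-8, '.' decimal separator)."""
    df = pd.read_csv(path)
    return validate_logbook(df)


def write_logbook(df: pd.DataFrame, path) -> None:
    """Write a logbook CSV with the canonical column order first."""
    cols = [c for c in LOGBOOK_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, index=False)
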