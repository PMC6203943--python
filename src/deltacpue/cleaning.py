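"""Record-validity filters for logbook data, with an auditable report.

A set is retained only if it passes every rule: no required field missing,
fishing date within the study window, position inside the study region,
effort (hooks per line) within the plausible range, per-species retained
counts below a cap, and fewer sharks (both species combined) than hooks set
(strict inequality — a set cannot catch a shark on every hook).

A record failing several rules is tallied once, under the first failing rule
in a fixed order, so rejection tallies are deterministic and partition the
input together with the retained set.  Anomalies in fields not modelled
downstream (depth, set duration, catch/weight mismatches) are covered by the
generic missing-field rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import REQUIRED_FIELDS, validate_logbook

__all__ = ["CleaningRules", "CleaningReport", "LogbookCleaner",
           "clean_records", "RULE_ORDER"]

#: Fixed attribution order: the first failing rule owns the rejection.
RULE_ORDER = ("missing_field", "year", "position", "hooks", "count_cap",
              "sharks_vs_hooks")


@dataclass(frozen=True)
class CleaningRules:
    """Bounds of the validity filters (all bounds inclusive except the
    sharks-vs-hooks rule, which is strict)."""

    year_range: tuple = (2000, 2015)
    hooks_range: tuple = (310, 3800)
    count_cap: int = 801
    cap_mode: str = "per_species"           # or "combined"
    latitude_range: tuple = (-45.0, -26.85)
    longitude_range: tuple = (8.0, 36.9)

    def __post_init__(self):
        for name in ("year_range", "hooks_range", "latitude_range",
                     "longitude_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        if self.cap_mode not in ("per_species", "combined"):
            raise ValueError(f"unknown cap_mode {self.cap_mode!r}")


@dataclass
class CleaningReport:
    """What survived, what was removed, and why."""

    n_input: int
    n_retained: int
    retained_fraction: float
    rejections_by_rule: dict
    retained: pd.DataFrame
    rejected: pd.DataFrame = None

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "retained_fraction": self.retained_fraction,
            "rejections_by_rule": dict(self.rejections_by_rule),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _rule_masks(df: pd.DataFrame, rules: CleaningRules) -> dict:
    """Boolean failure mask per rule (True = record fails that rule)."""
    miss = df[REQUIRED_FIELDS].isna().any(axis=1).to_numpy()

    year = pd.to_numeric(df["year"], errors="coerce")
    y_bad = ~year.between(*rules.year_range)

    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    pos_bad = ~(lat.between(*rules.latitude_range)
                & lon.between(*rules.longitude_range))

    hooks = pd.to_numeric(df["hooks"], errors="coerce")
    h_bad = ~hooks.between(*rules.hooks_range)

    cb = pd.to_numeric(df["count_blue"], errors="coerce")
    cm = pd.to_numeric(df["count_mako"], errors="coerce")
    if rules.cap_mode == "per_species":
        cap_bad = (cb > rules.count_cap) | (cm > rules.count_cap)
    else:
        cap_bad = (cb + cm) > rules.count_cap

    svh_bad = ~((cb + cm) < hooks)

    # .between / comparisons with NaN are False, i.e. NaNs "fail" these
    # rules too — but the missing_field rule comes first in attribution.
    return {
        "missing_field": miss,
        "year": y_bad.to_numpy(),
        "position": pos_bad.to_numpy(),
        "hooks": h_bad.to_numpy(),
        "count_cap": cap_bad.to_numpy(),
        "sharks_vs_hooks": svh_bad.to_numpy(),
    }


def clean_records(records: pd.DataFrame,
                  rules: CleaningRules = CleaningRules(),
                  keep_rejected: bool = False) -> CleaningReport:
    """Apply all validity rules; return retained data and per-rule tallies."""
    validate_logbook(records)
    n = len(records)
    if n == 0:
        return CleaningReport(0, 0, 0.0, {r: 0 for r in RULE_ORDER},
                              records.copy(),
                              records.copy() if keep_rejected else None)
    masks = _rule_masks(records, rules)
    attributed = np.full(n, "", dtype=object)
    for rule in RULE_ORDER:
        fresh = masks[rule] & (attributed == "")
        attributed[fresh] = rule
    retained_mask = attributed == ""
    tallies = {rule: int(np.sum(attributed == rule)) for rule in RULE_ORDER}
    retained = records.loc[retained_mask].copy()
    rejected = records.loc[~retained_mask].copy() if keep_rejected else None
    if keep_rejected:
        rejected["rejection_rule"] = attributed[~retained_mask]
    return CleaningReport(
        n_input=n,
        n_retained=int(retained_mask.sum()),
        retained_fraction=float(retained_mask.sum() / n),
        rejections_by_rule=tallies,
        retained=retained,
        rejected=rejected,
    )


class LogbookCleaner:
    """Transformer wrapper around :func:`clean_records`.

    ``transform`` returns the retained frame; the full report of the last
    call is kept on ``report_``.
    """

    def __init__(self, rules: CleaningRules = CleaningRules()):
        self.rules = rules

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.report_ = clean_records(X, self.rules)
        return self.report_.retained

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def get_params(self, deep=True):
        return {"rules": self.rules}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
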