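"""Spatial stratification of longline sets off southern Africa.

The study region spans the SE Atlantic and SW Indian Oceans around South
Africa and is split into four analysis areas chosen to follow the tuna-RFMO
reporting boundary at 20°E and the major current systems:

* **West** — cool temperate Benguela-influenced waters, west of 20°E and
  north of 33°S (up to the Namibian-border latitude).
* **Southwest** — the dynamic Benguela/Agulhas boundary zone including the
  western Agulhas Bank, west of 20°E and south of 33°S.
* **South** — the lower Agulhas Current / eastern Agulhas Bank, 20°E–26°E.
* **East** — subtropical upper Agulhas Current waters, east of 26°E up to the
  Mozambique-border latitude.

Sets west of 20°E fall in the ICCAT reporting region, sets east of it in the
IOTC region.  All interval edges are half-open on the eastern/southern side,
so a point exactly on 20°E or 26°E falls in the area to the east.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AREAS = ("West", "Southwest", "South", "East")
RFMOS = ("ICCAT", "IOTC")


class PositionError(ValueError):
    """Raised for non-finite coordinates."""


@dataclass(frozen=True)
class AreaScheme:
    """Boundary longitudes/latitudes defining the four analysis areas.

    The Namibian- and Mozambique-border latitudes are not sharp analytic
    constants; the defaults below are configurable northern clips of the
    study region, and only region membership (not the exact border) affects
    the analysis.
    """

    rfmo_split_longitude: float = 20.0       # ICCAT west / IOTC east
    west_south_boundary_latitude: float = -33.0
    south_east_boundary_longitude: float = 26.0
    northern_bound_atlantic: float = -28.6   # ~ Namibian border
    northern_bound_indian: float = -26.85    # ~ Mozambique border
    southern_bound: float = -45.0
    western_bound: float = 8.0
    eastern_bound: float = 36.9

    def __post_init__(self):
        if not self.rfmo_split_longitude < self.south_east_boundary_longitude:
            raise ValueError("rfmo_split_longitude must lie west of "
                             "south_east_boundary_longitude")
        if not (self.western_bound < self.rfmo_split_longitude
                < self.eastern_bound):
            raise ValueError("RFMO split must fall inside the study region")
        if not self.southern_bound < min(self.northern_bound_atlantic,
                                         self.northern_bound_indian):
            raise ValueError("study region is empty (southern >= northern)")


def assign_area(latitude, longitude, scheme: AreaScheme = AreaScheme()):
    """Map positions to one of the four areas, or ``None`` outside the region.

    Accepts scalars or array-likes; returns a single label or an object array
    of labels/None.  Raises :class:`PositionError` on non-finite coordinates.
    """
    lat = np.asarray(latitude, dtype=float)
    lon = np.asarray(longitude, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise PositionError("non-finite coordinates")
    scalar = lat.ndim == 0 and lon.ndim == 0
    lat, lon = np.atleast_1d(lat), np.atleast_1d(lon)

    out = np.full(lat.shape, None, dtype=object)
    in_lon = (lon >= scheme.western_bound) & (lon < scheme.eastern_bound)
    atl = in_lon & (lon < scheme.rfmo_split_longitude)
    ind = in_lon & ~atl

    west = (atl & (lat >= scheme.west_south_boundary_latitude)
            & (lat < scheme.northern_bound_atlantic))
    southwest = (atl & (lat < scheme.west_south_boundary_latitude)
                 & (lat >= scheme.southern_bound))
    south = (ind & (lon < scheme.south_east_boundary_longitude)
             & (lat >= scheme.southern_bound)
             & (lat < scheme.northern_bound_indian))
    east = (ind & (lon >= scheme.south_east_boundary_longitude)
            & (lat >= scheme.southern_bound)
            & (lat < scheme.northern_bound_indian))
    out[west] = "West"
    out[southwest] = "Southwest"
    out[south] = "South"
    out[east] = "East"
    return out.item() if scalar else out


def assign_rfmo(longitude, scheme: AreaScheme = AreaScheme()):
    """ICCAT west of the 20°E split, IOTC at or east of it (half-open)."""
    lon = np.asarray(longitude, dtype=float)
    if not np.all(np.isfinite(lon)):
        raise PositionError("non-finite longitude")
    scalar = lon.ndim == 0
    lon = np.atleast_1d(lon)
    out = np.where(lon < scheme.rfmo_split_longitude, "ICCAT", "IOTC")
    return out.item() if scalar else out.astype(object)


def rfmo_of_area(area: str) -> str:
    """Reporting region implied by an analysis area."""
    return "ICCAT" if area in ("West", "Southwest") else "IOTC"


class AreaAssigner:
    """Transformer adding ``area`` and ``rfmo`` columns to a logbook frame.

    sklearn-style: stateless, ``fit`` is a no-op, ``transform`` returns a
    copy with the two new columns (``area`` is ``None`` outside the region).
    """

    def __init__(self, scheme: AreaScheme = AreaScheme()):
        self.scheme = scheme

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        out["area"] = assign_area(
            X["latitude"].to_numpy(), X["longitude"].to_numpy(), self.scheme)
        out["rfmo"] = assign_rfmo(X["longitude"].to_numpy(), self.scheme)
        return out

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def get_params(self, deep=True):
        return {"scheme": self.scheme}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
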