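"""Synthetic set-by-set longline logbooks with known ground truth.

The generator is the exact probabilistic inverse of the two-part model the
package fits: for each set an encounter indicator is drawn Bernoulli with
probability ``inverse-logit`` of a linear predictor (year, month, fleet,
observer fixed effects plus a per-vessel normal intercept on the logit
scale), and — on encounter — a positive catch rate in sharks per 1,000 hooks
is drawn from a gamma distribution whose log-mean carries its own linear
predictor and vessel intercept, with constant shape.  Retained counts are
back-derived from the catch rate and the effort of the set, coerced to at
least one animal on encounter (an encounter must be visible in a
retained-count logbook).

Structural realism follows the fishery being emulated: two fleets with
distinct truncated-normal hooks-per-line distributions, separate local and
foreign vessel pools, positions drawn uniformly within per-area bounding
boxes (so spatial stratification has known truth), observer coverage that is
near-complete for the foreign fleet from 2002 onwards, and two shark species
(blue, shortfin mako) with independent parameter sets.

A companion contamination step (:func:`inject_anomalies`) corrupts chosen
fractions of records in each anomaly class that the cleaning rules must
reject, returning the corrupted ids for oracle tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special, stats

from .records import LOGBOOK_COLUMNS, FLEET_LEVELS, OBSERVER_LEVELS

__all__ = [
    "SpeciesEffects", "SyntheticTruth", "ConfigurationError",
    "default_truth", "generate_logbook", "inject_anomalies",
    "ANOMALY_CLASSES", "save_truth", "load_truth",
]

#: Hooks-per-line range that cleaned records must satisfy; the generator
#: truncates to this range so uncorrupted synthetic data pass the effort
#: filter by construction.
HOOKS_RANGE = (310, 3800)

ANOMALY_CLASSES = (
    "position_out_of_region", "year_out_of_range", "hooks_out_of_range",
    "count_over_cap", "sharks_ge_hooks", "missing_field",
)


class ConfigurationError(ValueError):
    """An invalid generator configuration, naming the offending field."""


@dataclass
class SpeciesEffects:
    """Ground-truth parameters of one species' two-part model.

    Coefficient maps are keyed by reference-coded term levels
    (``"Intercept"``, ``"year[2004]"``, ``"fleet[local]"`` ...); missing keys
    are zero.  Scales: logit for the binomial part, log for the gamma part.
    """

    beta_binomial: dict = field(default_factory=lambda: {"Intercept": 0.5})
    beta_gamma: dict = field(default_factory=lambda: {"Intercept": 2.0})
    sigma_vessel_binomial: float = 0.5
    sigma_vessel_gamma: float = 0.4
    gamma_shape: float = 1.0
    mean_individual_weight: float = 30.0   # kg, for logbook weight fields


@dataclass
class SyntheticTruth:
    """Full parameterization of a synthetic logbook, kept for recovery tests.

    The flat single-species accessors (``beta_binomial`` & co.) refer to the
    blue-shark block; the shortfin-mako block has an independent parameter
    set, as in the fishery emulated.
    """

    blue: SpeciesEffects = field(default_factory=SpeciesEffects)
    mako: SpeciesEffects = field(default_factory=lambda: SpeciesEffects(
        beta_binomial={"Intercept": 0.6},
        beta_gamma={"Intercept": 1.2},
        sigma_vessel_binomial=0.4,
        sigma_vessel_gamma=0.35,
        gamma_shape=1.5,
        mean_individual_weight=55.0,
    ))
    hooks_mean_sd_by_fleet: dict = field(default_factory=lambda: {
        "foreign": (2493.0, 597.0), "local": (1282.0, 250.0)})
    n_vessels_by_fleet: dict = field(default_factory=lambda: {
        "foreign": 49, "local": 61})
    n_sets: int = 29018
    seed: int = 0
    years: tuple = tuple(range(2000, 2016))
    months: tuple = tuple(range(1, 13))
    local_fleet_share: float = 0.58           # 16,810 of 29,018 sets
    area_weights: dict = field(default_factory=lambda: {
        "West": 0.15, "Southwest": 0.25, "South": 0.38, "East": 0.22})
    area_boxes: dict = field(default_factory=lambda: {
        "West": (-33.0, -28.7, 9.0, 19.9),
        "Southwest": (-40.0, -33.1, 9.0, 19.9),
        "South": (-40.0, -30.0, 20.1, 25.9),
        "East": (-35.0, -27.0, 26.1, 36.5),
    })
    # Observer assignment: P(no, unknown, yes) per condition.
    observer_probs_local: tuple = (0.60, 0.10, 0.30)
    observer_probs_foreign_early: tuple = (0.80, 0.10, 0.10)
    observer_probs_foreign_late: tuple = (0.05, 0.05, 0.90)
    foreign_full_coverage_year: int = 2002
    local_target_probs: tuple = (0.25, 0.50, 0.25)   # tuna, swordfish, shark
    weight_other_mean_by_fleet: dict = field(default_factory=lambda: {
        "foreign": 3000.0, "local": 600.0})

    # -- spec-level flat accessors (blue shark block) -------------------
    @property
    def beta_binomial(self):
        return self.blue.beta_binomial

    @property
    def beta_gamma(self):
        return self.blue.beta_gamma

    @property
    def sigma_vessel_binomial(self):
        return self.blue.sigma_vessel_binomial

    @property
    def sigma_vessel_gamma(self):
        return self.blue.sigma_vessel_gamma

    @property
    def gamma_shape(self):
        return self.blue.gamma_shape

    def species_effects(self, species: str) -> SpeciesEffects:
        return {"blue": self.blue, "mako": self.mako}[species]


def default_truth(seed: int = 0, n_sets: int = 29018, years=None,
                  months=None, n_vessels_by_fleet=None) -> SyntheticTruth:
    """Study-condition defaults with a full 16-year, 12-month design.

    Effect magnitudes are plausible for the fishery emulated: encounter odds
    and positive catch rates rise from 2004 onwards, blue sharks are
    encountered more often by the foreign fleet but retained in far greater
    numbers by local vessels, makos show the opposite fleet pattern, and
    reported presence/magnitude drop when an observer is aboard.

    ``years``/``months`` restrict the categorical design (coefficients for
    excluded levels are dropped) and ``n_vessels_by_fleet`` overrides the
    fleet sizes — used for reduced simulation experiments.
    """
    full_years = tuple(range(2000, 2016))
    full_months = tuple(range(1, 13))
    years = full_years if years is None else tuple(years)
    months = full_months if months is None else tuple(months)

    def year_map(step, jump_year=None, jump=0.0):
        out = {}
        for y in years[1:]:
            val = step * (y - years[0]) + (0.45 if y >= 2004 else 0.0)
            if jump_year is not None and y == jump_year:
                val += jump
            out[f"year[{y}]"] = round(val, 4)
        return out

    def month_map(amp):
        return {f"month[{m}]": round(amp * np.sin(2 * np.pi * (m - 1) / 12), 4)
                for m in months[1:]}

    blue_bin = {"Intercept": 0.40, "fleet[local]": -0.40,
                "observer[yes]": -0.50, "observer[unknown]": -0.10}
    blue_bin.update(year_map(0.02, jump_year=2011, jump=0.6))
    blue_bin.update(month_map(0.15))
    blue_gam = {"Intercept": 2.10, "fleet[local]": 0.80,
                "observer[yes]": -0.40, "observer[unknown]": -0.10}
    blue_gam.update(year_map(0.04, jump_year=2011, jump=1.0))
    blue_gam.update(month_map(0.10))

    mako_bin = {"Intercept": 0.55, "fleet[local]": 0.30,
                "observer[yes]": -0.60, "observer[unknown]": -0.15}
    mako_bin.update(year_map(0.02))
    mako_bin.update(month_map(0.20))
    mako_gam = {"Intercept": 1.10, "fleet[local]": 0.40,
                "observer[yes]": -0.30, "observer[unknown]": -0.10}
    mako_gam.update(year_map(0.03))
    mako_gam.update(month_map(0.15))

    truth = SyntheticTruth(
        blue=SpeciesEffects(beta_binomial=blue_bin, beta_gamma=blue_gam,
                            sigma_vessel_binomial=0.5, sigma_vessel_gamma=0.4,
                            gamma_shape=1.0, mean_individual_weight=30.0),
        mako=SpeciesEffects(beta_binomial=mako_bin, beta_gamma=mako_gam,
                            sigma_vessel_binomial=0.4, sigma_vessel_gamma=0.35,
                            gamma_shape=1.5, mean_individual_weight=55.0),
        n_sets=n_sets, seed=seed, years=years, months=months,
    )
    if n_vessels_by_fleet is not None:
        truth.n_vessels_by_fleet = dict(n_vessels_by_fleet)
    return truth


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check_probs(name, probs):
    p = np.asarray(probs, float)
    if p.size != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must be 3 probabilities summing to 1")


def validate_truth(truth: SyntheticTruth) -> None:
    if truth.n_sets < 0:
        raise ConfigurationError("n_sets must be >= 0")
    if not truth.years:
        raise ConfigurationError("years must be non-empty")
    if not truth.months or any(m < 1 or m > 12 for m in truth.months):
        raise ConfigurationError("months must be within 1..12")
    if not 0.0 <= truth.local_fleet_share <= 1.0:
        raise ConfigurationError("local_fleet_share must be in [0, 1]")
    for fleet in FLEET_LEVELS:
        if truth.n_vessels_by_fleet.get(fleet, 0) < 1:
            raise ConfigurationError(
                f"n_vessels_by_fleet[{fleet}] must be >= 1")
        mean, sd = truth.hooks_mean_sd_by_fleet[fleet]
        if not (HOOKS_RANGE[0] <= mean <= HOOKS_RANGE[1]):
            raise ConfigurationError(
                f"hooks_mean_sd_by_fleet[{fleet}] mean outside "
                f"{HOOKS_RANGE}")
        if sd <= 0:
            raise ConfigurationError(
                f"hooks_mean_sd_by_fleet[{fleet}] sd must be > 0")
    for species in ("blue", "mako"):
        eff = truth.species_effects(species)
        if eff.sigma_vessel_binomial < 0 or eff.sigma_vessel_gamma < 0:
            raise ConfigurationError(f"{species}: sigma_vessel_* must be >= 0")
        if eff.gamma_shape <= 0:
            raise ConfigurationError(f"{species}: gamma_shape must be > 0")
    w = np.array([truth.area_weights[a] for a in truth.area_boxes], float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ConfigurationError("area_weights must be non-negative, sum > 0")
    for area, (lat0, lat1, lon0, lon1) in truth.area_boxes.items():
        if not (lat0 < lat1 and lon0 < lon1):
            raise ConfigurationError(f"area_boxes[{area}] is empty")
    _check_probs("observer_probs_local", truth.observer_probs_local)
    _check_probs("observer_probs_foreign_early",
                 truth.observer_probs_foreign_early)
    _check_probs("observer_probs_foreign_late",
                 truth.observer_probs_foreign_late)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _linear_predictor(beta: dict, year, month, fleet, observer) -> np.ndarray:
    eta = np.full(year.shape, beta.get("Intercept", 0.0), dtype=float)
    for key, val in beta.items():
        if key == "Intercept" or val == 0.0:
            continue
        term, lev = key[:-1].split("[", 1)
        if term == "year":
            eta += val * (year == int(lev))
        elif term == "month":
            eta += val * (month == int(lev))
        elif term == "fleet":
            eta += val * (fleet == lev)
        elif term == "observer":
            eta += val * (observer == lev)
        else:
            raise ConfigurationError(f"unknown coefficient key {key!r}")
    return eta


def generate_logbook(truth: SyntheticTruth):
    """Simulate a logbook under ``truth``; returns ``(records, truth)``.

    Deterministic given ``truth.seed``; the truth object is returned
    unchanged alongside the table, mirroring how it is stored as a sidecar.
    """
    validate_truth(truth)
    rng = np.random.default_rng(truth.seed)
    n = truth.n_sets
    if n == 0:
        return pd.DataFrame(columns=LOGBOOK_COLUMNS), truth

    fleet = np.where(rng.random(n) < truth.local_fleet_share,
                     "local", "foreign").astype(object)

    vessel_pools = {
        "local": np.array([f"L{i:03d}" for i in
                           range(truth.n_vessels_by_fleet["local"])]),
        "foreign": np.array([f"F{i:03d}" for i in
                             range(truth.n_vessels_by_fleet["foreign"])]),
    }
    vessel = np.empty(n, dtype=object)
    for fl in FLEET_LEVELS:
        idx = np.flatnonzero(fleet == fl)
        vessel[idx] = rng.choice(vessel_pools[fl], size=idx.size)

    year = rng.choice(np.asarray(truth.years), size=n)
    month = rng.choice(np.asarray(truth.months), size=n)
    day = rng.integers(1, 29, size=n)

    areas = list(truth.area_boxes)
    w = np.array([truth.area_weights[a] for a in areas], float)
    area = rng.choice(np.array(areas, dtype=object), size=n, p=w / w.sum())
    lat = np.empty(n)
    lon = np.empty(n)
    for a in areas:
        idx = np.flatnonzero(area == a)
        lat0, lat1, lon0, lon1 = truth.area_boxes[a]
        lat[idx] = rng.uniform(lat0, lat1, idx.size)
        lon[idx] = rng.uniform(lon0, lon1, idx.size)

    hooks = np.empty(n)
    lo, hi = HOOKS_RANGE
    for fl in FLEET_LEVELS:
        idx = np.flatnonzero(fleet == fl)
        mean, sd = truth.hooks_mean_sd_by_fleet[fl]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        hooks[idx] = stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                         size=idx.size, random_state=rng)
    hooks = np.rint(hooks).astype(int)

    observer = np.empty(n, dtype=object)
    u = rng.random(n)
    conds = [
        (fleet == "local", truth.observer_probs_local),
        ((fleet == "foreign") & (year < truth.foreign_full_coverage_year),
         truth.observer_probs_foreign_early),
        ((fleet == "foreign") & (year >= truth.foreign_full_coverage_year),
         truth.observer_probs_foreign_late),
    ]
    for mask, probs in conds:
        cum = np.cumsum(probs)
        lab = np.array(OBSERVER_LEVELS, dtype=object)
        observer[mask] = lab[np.searchsorted(cum, u[mask], side="right")
                             .clip(max=2)]

    target = np.where(fleet == "foreign", "tuna", "").astype(object)
    idx_local = np.flatnonzero(fleet == "local")
    target[idx_local] = rng.choice(
        np.array(["tuna", "swordfish", "shark"], dtype=object),
        size=idx_local.size, p=np.asarray(truth.local_target_probs, float))

    df = pd.DataFrame({
        "set_id": [f"S{i:06d}" for i in range(n)],
        "year": year.astype(int), "month": month.astype(int),
        "day": day.astype(int),
        "vessel_id": vessel, "fleet": fleet, "observer": observer,
        "latitude": lat, "longitude": lon, "hooks": hooks,
        "target": target,
    })

    all_vessels = np.concatenate([vessel_pools["local"],
                                  vessel_pools["foreign"]])
    for species in ("blue", "mako"):
        eff = truth.species_effects(species)
        u_bin = dict(zip(all_vessels, rng.normal(
            0.0, eff.sigma_vessel_binomial, all_vessels.size)))
        u_gam = dict(zip(all_vessels, rng.normal(
            0.0, eff.sigma_vessel_gamma, all_vessels.size)))
        ub = np.array([u_bin[v] for v in vessel])
        ug = np.array([u_gam[v] for v in vessel])

        eta_b = _linear_predictor(eff.beta_binomial, year, month, fleet,
                                  observer) + ub
        eta_g = _linear_predictor(eff.beta_gamma, year, month, fleet,
                                  observer) + ug
        encounter = rng.random(n) < special.expit(eta_b)
        k = eff.gamma_shape
        cpue = rng.gamma(k, np.exp(eta_g) / k, size=n)
        count = np.rint(cpue * hooks / 1000.0).astype(int)
        count = np.where(encounter, np.maximum(count, 1), 0)
        wt_mult = rng.lognormal(-0.045, 0.3, size=n)    # mean ~ 1
        weight = np.where(count > 0,
                          count * eff.mean_individual_weight * wt_mult, 0.0)
        df[f"count_{species}"] = count
        df[f"weight_{species}"] = np.round(weight, 1)

    mean_other = np.array([truth.weight_other_mean_by_fleet[f]
                           for f in fleet])
    sigma_o = 0.6
    df["weight_other"] = np.round(rng.lognormal(
        np.log(mean_other) - 0.5 * sigma_o ** 2, sigma_o, size=n), 1)

    return df[LOGBOOK_COLUMNS], truth


# ---------------------------------------------------------------------------
# contamination
# ---------------------------------------------------------------------------

def inject_anomalies(records: pd.DataFrame, rates: dict, seed: int = 0):
    """Corrupt disjoint record fractions, one anomaly class at a time.

    ``rates`` maps anomaly class to the fraction of records to corrupt;
    classes are drawn without replacement and disjointly in the fixed order
    of :data:`ANOMALY_CLASSES`.  Returns ``(corrupted, ids_by_class)`` where
    ``ids_by_class`` maps each class to the sorted list of corrupted
    ``set_id`` values (the oracle for cleaning tests).
    """
    unknown = set(rates) - set(ANOMALY_CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown anomaly classes: {sorted(unknown)}")
    for cls, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError(f"rate for {cls} outside [0, 1]")
    n = len(records)
    counts = {cls: int(round(rates.get(cls, 0.0) * n))
              for cls in ANOMALY_CLASSES}
    if sum(counts.values()) > n:
        raise ConfigurationError("total corruption fraction exceeds 1")

    rng = np.random.default_rng(seed)
    out = records.copy()
    perm = rng.permutation(n)
    pos = 0
    ids_by_class: dict = {}
    for cls in ANOMALY_CLASSES:
        c = counts[cls]
        if c == 0:
            continue
        idx = out.index[perm[pos:pos + c]]
        pos += c
        ids_by_class[cls] = sorted(out.loc[idx, "set_id"].tolist())
        if cls == "position_out_of_region":
            out.loc[idx, "latitude"] = rng.uniform(-75.0, -60.0, c)
        elif cls == "year_out_of_range":
            side = rng.random(c) < 0.5
            out.loc[idx, "year"] = np.where(
                side, rng.integers(1985, 2000, c), rng.integers(2016, 2030, c))
        elif cls == "hooks_out_of_range":
            side = rng.random(c) < 0.5
            out.loc[idx, "hooks"] = np.where(
                side, rng.integers(1, 310, c), rng.integers(3801, 9000, c))
        elif cls == "count_over_cap":
            cnt = rng.integers(802, 1000, c)
            out.loc[idx, "count_blue"] = cnt
            out.loc[idx, "weight_blue"] = cnt * 30.0
        elif cls == "sharks_ge_hooks":
            hooks = rng.integers(310, 1601, c)
            blue = (hooks + 1) // 2
            mako = hooks - blue + rng.integers(0, 4, c)
            out.loc[idx, "hooks"] = hooks
            out.loc[idx, "count_blue"] = blue
            out.loc[idx, "count_mako"] = mako
            out.loc[idx, "weight_blue"] = blue * 30.0
            out.loc[idx, "weight_mako"] = mako * 55.0
        elif cls == "missing_field":
            numeric = ["hooks", "latitude", "longitude", "month"]
            for j, i in enumerate(idx):
                fld = numeric[j % len(numeric)]
                out.loc[i, fld] = np.nan
    return out, ids_by_class


# ---------------------------------------------------------------------------
# truth sidecar serialization
# ---------------------------------------------------------------------------

def save_truth(truth: SyntheticTruth, path) -> None:
    """Write the ground-truth parameter set as a JSON sidecar."""
    d = asdict(truth)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2, default=list)


def load_truth(path) -> SyntheticTruth:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    for sp in ("blue", "mako"):
        d[sp] = SpeciesEffects(**d[sp])
    for key in ("years", "months", "observer_probs_local",
                "observer_probs_foreign_early", "observer_probs_foreign_late",
                "local_target_probs"):
        d[key] = tuple(d[key])
    d["hooks_mean_sd_by_fleet"] = {k: tuple(v) for k, v
                                   in d["hooks_mean_sd_by_fleet"].items()}
    d["area_boxes"] = {k: tuple(v) for k, v in d["area_boxes"].items()}
    return SyntheticTruth(**d)
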