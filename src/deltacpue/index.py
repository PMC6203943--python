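"""Standardized annual CPUE indices with propagated uncertainty.

The standardized index for a year is the product of the back-transformed
year-effect predictions of the two submodels:

    index(year) = p_hat(year) * mu_hat(year)      [sharks / 1,000 hooks]

where ``p_hat`` is the predicted probability of a non-zero catch (binomial
submodel, logit link) and ``mu_hat`` the predicted positive catch rate
(gamma submodel, log link).  Standard errors come from first-order delta
method transforms: the link-scale SE of the year prediction is mapped
through the inverse link derivative, and the SE of the product assumes the
two submodels are independent (their likelihoods share no response
information — zeros vs positive magnitudes).

Two prediction policies are exposed: hold all non-year factors at their
reference levels (default), or average predictions over the observed
distribution of the other factors ("population-average").  Sudden
year-on-year jumps beyond a ratio threshold are flagged post hoc as
anomalies to be interpreted against fishery history rather than abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = ["IndexSeries", "backtransform", "propagate_product_error",
           "predict_year_effects", "flag_anomalies"]


def backtransform(coefficient: float, se: float, link: str,
                  bias_correct: bool = False):
    """Map a link-scale estimate and SE to the observation scale.

    First-order delta method: for the logit link the derivative is
    ``p(1-p)``; for the log link it is the estimate itself.  The lognormal
    bias-corrected point estimate ``exp(c + se^2/2)`` is available for the
    log link behind ``bias_correct``.
    """
    if se < 0:
        raise ValueError("se must be >= 0")
    if link == "logit":
        est = float(special.expit(coefficient))
        return est, float(se * est * (1.0 - est))
    if link == "log":
        est = float(np.exp(coefficient + (0.5 * se ** 2 if bias_correct
                                          else 0.0)))
        return est, float(se * est)
    raise ValueError(f"unknown link {link!r}")


def propagate_product_error(p: float, se_p: float, mu: float,
                            se_mu: float) -> float:
    """Delta-method SE of the product of two independent estimates."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if se_p < 0 or se_mu < 0:
        raise ValueError("standard errors must be >= 0")
    return float(np.hypot(mu * se_p, p * se_mu))


def flag_anomalies(index_values, years=None, ratio_threshold: float = 3.0,
                   floor: float = 1e-9) -> pd.DataFrame:
    """Flag years whose index jumps by more than ``ratio_threshold`` in
    either direction relative to the previous year.

    ``index_values`` may be a sequence or a DataFrame with ``year`` and
    ``index`` columns (sorted by year).  Returns a frame of flagged years
    with the offending ratio; empty for fewer than two years.
    """
    if ratio_threshold <= 1.0:
        raise ValueError("ratio_threshold must be > 1")
    if isinstance(index_values, pd.DataFrame):
        frame = index_values.sort_values("year")
        vals = frame["index"].to_numpy(float)
        yrs = frame["year"].to_numpy()
    else:
        vals = np.asarray(index_values, float)
        yrs = np.asarray(years if years is not None
                         else np.arange(len(vals)))
    rows = []
    for t in range(1, len(vals)):
        prev, cur = vals[t - 1] + floor, vals[t] + floor
        ratio = max(cur / prev, prev / cur)
        if ratio > ratio_threshold:
            rows.append({"year": yrs[t], "ratio": float(ratio)})
    return pd.DataFrame(rows, columns=["year", "ratio"])


@dataclass
class IndexSeries:
    """Per-year standardized index for one species in one area."""

    species: str
    area: str | None
    frame: pd.DataFrame   # year, p_hat, se_p, mu_hat, se_mu, index,
    #                       se_index, anomaly_flag

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "area", self.area)
        out.insert(0, "species", self.species)
        out.to_csv(path, index=False)


def _year_predictions(fit, policy: str):
    """Link-scale year-effect predictions (estimate, se) for one submodel."""
    est = fit._estimator
    if est is None:
        raise ValueError("fitted submodel lacks its estimator")
    if "year" not in est.levels_:
        raise ValueError("year is not a fixed term of this fit")
    if not fit.converged:
        raise ValueError("cannot build an index from a non-converged fit")
    beta = fit.coef_vector
    cov = np.asarray(fit.covariance)
    names = fit.coef_names
    col = {nm: j for j, nm in enumerate(names)}
    years = list(est.levels_["year"])
    p = len(names)

    if policy == "reference":
        rows = np.zeros((len(years), p))
        rows[:, col["Intercept"]] = 1.0
        for i, yr in enumerate(years[1:], start=1):
            rows[i, col[f"year[{yr}]"]] = 1.0
        eta = rows @ beta
        var = np.einsum("ij,jk,ik->i", rows, cov, rows)
        return years, eta, np.sqrt(np.clip(var, 0.0, None)), None
    if policy == "population":
        X = est.X_
        year_cols = [col[f"year[{yr}]"] for yr in years[1:]]
        Xz = X.copy()
        Xz[:, year_cols] = 0.0
        etas, grads = [], []
        for i, yr in enumerate(years):
            Xy = Xz.copy()
            if i > 0:
                Xy[:, col[f"year[{yr}]"]] = 1.0
            eta_i = Xy @ beta
            if fit.spec.link == "logit":
                mu_i = special.expit(eta_i)
                dmu = mu_i * (1.0 - mu_i)
            else:
                mu_i = np.exp(np.clip(eta_i, -500, 500))
                dmu = mu_i
            grad = (dmu[:, None] * Xy).mean(axis=0)
            etas.append(float(np.mean(mu_i)))
            grads.append(grad)
        grads = np.array(grads)
        var = np.einsum("ij,jk,ik->i", grads, cov, grads)
        return years, np.array(etas), np.sqrt(np.clip(var, 0.0, None)), "resp"
    raise ValueError(f"unknown prediction policy {policy!r}")


def predict_year_effects(fit_binomial, fit_gamma, policy: str = "reference",
                         bias_correct: bool = False,
                         ratio_threshold: float = 3.0) -> IndexSeries:
    """Standardized index series from the two fitted submodels.

    Under the default reference policy all non-year categorical effects sit
    at their reference level and the vessel intercept at zero; year
    predictions and their link-scale SEs are back-transformed and multiplied.
    Under the population-average policy predictions are averaged over the
    observed covariate distribution on the response scale.
    """
    years_b, est_b, se_b, kind_b = _year_predictions(fit_binomial, policy)
    years_g, est_g, se_g, kind_g = _year_predictions(fit_gamma, policy)
    common = [y for y in years_b if y in set(years_g)]
    if not common:
        raise ValueError("submodels share no year levels")

    rows = []
    for yr in common:
        ib, ig = years_b.index(yr), years_g.index(yr)
        if kind_b == "resp":            # already on the observation scale
            p_hat, se_p = float(est_b[ib]), float(se_b[ib])
            mu_hat, se_mu = float(est_g[ig]), float(se_g[ig])
        else:
            p_hat, se_p = backtransform(est_b[ib], se_b[ib], "logit")
            mu_hat, se_mu = backtransform(est_g[ig], se_g[ig], "log",
                                          bias_correct=bias_correct)
        rows.append({
            "year": yr, "p_hat": p_hat, "se_p": se_p,
            "mu_hat": mu_hat, "se_mu": se_mu,
            "index": p_hat * mu_hat,
            "se_index": propagate_product_error(p_hat, se_p, mu_hat, se_mu),
        })
    frame = pd.DataFrame(rows).sort_values("year").reset_index(drop=True)
    flags = flag_anomalies(frame, ratio_threshold=ratio_threshold)
    frame["anomaly_flag"] = frame["year"].isin(set(flags["year"])).to_numpy()
    return IndexSeries(species=fit_binomial.spec.species,
                       area=fit_binomial.spec.area, frame=frame)


def plot_index(series: IndexSeries, ax=None):
    """Index ± SE per year for one species/area (matplotlib, optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    f = series.frame
    ax.errorbar(f["year"], f["index"], yerr=f["se_index"], fmt="o-",
                capsize=2)
    flagged = f[f["anomaly_flag"]]
    if len(flagged):
        ax.plot(flagged["year"], flagged["index"], "r*", markersize=12)
    ax.set_xlabel("year")
    ax.set_ylabel("sharks / 1,000 hooks")
    title = series.species if series.area is None \
        else f"{series.species} — {series.area}"
    ax.set_title(title)
    return ax
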