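"""Two-part (delta/hurdle) mixed models for zero-inflated CPUE.

Catch rates from longline logbooks are zero-inflated: many sets retain no
sharks at all, while positive catches are continuous-ish and highly dispersed.
The classical fisheries "delta method" therefore splits the analysis into

* a **binomial** submodel (logit link) for the probability that a set has a
  non-zero catch, fitted to presence/absence over all sets, and
* a **gamma** submodel (log link) for the magnitude of the positive catch
  rate (sharks per 1,000 hooks), fitted to the positive sets only.

Both submodels carry the same fixed categorical effects (year, month, fleet,
observer) and a normally distributed per-vessel random intercept on the link
scale.  The random intercept is integrated out of the likelihood with a
Laplace approximation (one inner Newton mode search per vessel); an adaptive
Gauss–Hermite quadrature oracle is provided for auditing that approximation
on small instances.  Fixed-effect sets are chosen by forward BIC selection.

Estimators follow scikit-learn conventions (``fit``, fitted attributes with a
trailing underscore, ``get_params``/``set_params``) and accept the logbook
DataFrame directly; thin functional wrappers mirror the pipeline vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special
from sklearn.base import BaseEstimator

from .records import FLEET_LEVELS, OBSERVER_LEVELS

__all__ = [
    "ModelSpec", "FittedSubmodel", "BinomialGLMM", "GammaGLMM",
    "compute_cpue", "positive_subset", "fit_binomial_glmm", "fit_gamma_glmm",
    "dispersion_diagnostic", "DispersionDiagnostic", "stepwise_select",
    "marginal_loglik_oracle", "build_design", "HurdleContractError",
]

#: Canonical level order for the categorical terms whose levels are not
#: self-ordering (years and months sort numerically; Table-1 style orderings
#: put the reference level first).
CATEGORY_ORDERS = {"fleet": list(FLEET_LEVELS), "observer": list(OBSERVER_LEVELS)}

_ETA_CLIP = 500.0  # guards exp() overflow far from any optimum


class HurdleContractError(ValueError):
    """Gamma submodel offered a non-positive response (a zero set)."""


# ---------------------------------------------------------------------------
# responses and design matrices
# ---------------------------------------------------------------------------

def compute_cpue(records: pd.DataFrame, species: str) -> np.ndarray:
    """Catch rate in sharks per 1,000 hooks for each set.

    ``count_<species> * 1000 / hooks``; raises on non-positive effort.
    """
    hooks = np.asarray(records["hooks"], dtype=float)
    if np.any(~(hooks > 0)):
        raise ValueError("hooks must be positive to compute CPUE")
    counts = np.asarray(records[f"count_{species}"], dtype=float)
    return counts * 1000.0 / hooks


def positive_subset(records: pd.DataFrame, species: str) -> pd.DataFrame:
    """Sets with at least one retained individual of ``species``."""
    return records.loc[records[f"count_{species}"] > 0]


def build_design(data: pd.DataFrame, fixed_terms) -> tuple[np.ndarray, list, dict]:
    """Reference-coded design matrix with an explicit intercept.

    The first level of each categorical term (chronological for year/month,
    Table-1 order for fleet and observer) is the baseline; only levels
    observed in ``data`` enter the design.  Returns ``(X, names, levels)``.
    """
    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]
    levels_by_term: dict = {}
    for term in fixed_terms:
        vals = data[term]
        if term in CATEGORY_ORDERS:
            observed = set(vals.unique())
            levels = [l for l in CATEGORY_ORDERS[term] if l in observed]
            extra = sorted(observed - set(levels))
            levels += extra
        else:
            levels = sorted(vals.unique())
        levels_by_term[term] = levels
        arr = vals.to_numpy()
        for lev in levels[1:]:
            cols.append((arr == lev).astype(float))
            names.append(f"{term}[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient after reference coding; "
            f"terms {tuple(fixed_terms)} are confounded in these data")
    return X, names, levels_by_term


# ---------------------------------------------------------------------------
# model specification / fitted summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One submodel of the hurdle: which part, which terms, which stratum."""

    part: str                                   # "binomial" | "gamma"
    fixed_terms: tuple = ("year", "month", "fleet", "observer")
    random_term: str | None = "vessel_intercept"
    species: str = "blue"
    area: str | None = None

    def __post_init__(self):
        if self.part not in ("binomial", "gamma"):
            raise ValueError(f"unknown part {self.part!r}")
        if self.random_term not in (None, "vessel_intercept"):
            raise ValueError(f"unknown random term {self.random_term!r}")

    @property
    def link(self) -> str:
        return "logit" if self.part == "binomial" else "log"


@dataclass
class FittedSubmodel:
    """Estimates and bookkeeping for one fitted submodel."""

    spec: ModelSpec
    coefficients: dict
    coef_names: list
    covariance: np.ndarray          # fixed-effect block of inverse information
    sigma_vessel: float
    shape: float | None
    loglik: float
    n_obs: int
    bic: float
    converged: bool
    vessel_modes: dict
    warnings: list = field(default_factory=list)
    _estimator: object = None

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[n] for n in self.coef_names])

    def to_dict(self) -> dict:
        se = np.sqrt(np.clip(np.diag(self.covariance), 0, None))
        return {
            "part": self.spec.part,
            "link": self.spec.link,
            "species": self.spec.species,
            "area": self.spec.area,
            "fixed_terms": list(self.spec.fixed_terms),
            "random_term": self.spec.random_term,
            "coefficients": self.coefficients,
            "se": dict(zip(self.coef_names, se.tolist())),
            "covariance": np.asarray(self.covariance).tolist(),
            "sigma_vessel": self.sigma_vessel,
            "shape": self.shape,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "bic": self.bic,
            "converged": self.converged,
            "vessel_modes": self.vessel_modes,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# likelihood families (contributions per observation, derivatives in eta)
# ---------------------------------------------------------------------------

class _Binomial:
    name = "binomial"
    has_shape = False

    @staticmethod
    def ll(y, eta, shape=None):
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        return y * eta - np.logaddexp(0.0, eta)

    @staticmethod
    def d1(y, eta, shape=None):
        return y - special.expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))

    @staticmethod
    def d2(y, eta, shape=None):
        p = special.expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return p * (1.0 - p)


class _Gamma:
    name = "gamma"
    has_shape = True

    @staticmethod
    def ll(y, eta, shape):
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        k = shape
        return (k * np.log(k) - special.gammaln(k) + (k - 1.0) * np.log(y)
                - k * eta - k * y * np.exp(-eta))

    @staticmethod
    def d1(y, eta, shape):
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        return shape * (y * np.exp(-eta) - 1.0)

    @staticmethod
    def d2(y, eta, shape):
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        return shape * y * np.exp(-eta)

    @staticmethod
    def dll_dk(y, eta, shape):
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        k = shape
        return (np.log(k) + 1.0 - special.digamma(k) + np.log(y)
                - eta - y * np.exp(-eta))


_FAMILIES = {"binomial": _Binomial, "gamma": _Gamma}


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------

def _inner_modes(xb, y, codes, m, tau, family, shape, u0,
                 tol=1e-11, max_iter=200):
    """Per-group Newton search for the random-intercept modes.

    The per-group log integrand is strictly concave in ``u`` for both
    families, so undamped Newton with a step clip converges globally.
    Returns ``(u, eta, h)`` with ``h`` the negative curvature at the mode
    (the Laplace Hessian), per group.
    """
    u = u0.copy()
    eta = xb + u[codes]
    for _ in range(max_iter):
        g = np.bincount(codes, weights=family.d1(y, eta, shape),
                        minlength=m) - tau * u
        h = np.bincount(codes, weights=family.d2(y, eta, shape),
                        minlength=m) + tau
        step = np.clip(g / h, -5.0, 5.0)
        u += step
        eta = xb + u[codes]
        if np.max(np.abs(step)) < tol:
            break
    h = np.bincount(codes, weights=family.d2(y, eta, shape), minlength=m) + tau
    return u, eta, h


def _laplace_loglik(theta, X, y, codes, m, family, has_random, u_state):
    """Laplace-approximated marginal log-likelihood at parameter ``theta``.

    ``theta`` stacks the fixed coefficients, then ``log sigma_vessel`` if a
    random intercept is present, then ``log shape`` for the gamma family.
    ``u_state`` is a persistent mode vector used for warm starts.
    """
    p = X.shape[1]
    beta = theta[:p]
    pos = p
    if has_random:
        log_sigma = theta[pos]
        pos += 1
    shape = np.exp(theta[pos]) if family.has_shape else None
    xb = X @ beta
    if not has_random:
        return float(np.sum(family.ll(y, xb, shape)))
    sigma = np.exp(log_sigma)
    tau = sigma ** -2
    u, eta, h = _inner_modes(xb, y, codes, m, tau, family, shape, u_state)
    u_state[:] = u
    ll = (np.sum(family.ll(y, eta, shape))
          - 0.5 * tau * np.sum(u * u)
          - m * log_sigma
          - 0.5 * np.sum(np.log(h)))
    return float(ll)


def _numeric_hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian of scalar ``f`` at ``x``."""
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _glm_score_hessian(theta, X, y, family):
    """Analytic score and Hessian of the *negative* log-likelihood for the
    fixed-effects-only model (used for Newton polish and exact covariance)."""
    p = X.shape[1]
    beta = theta[:p]
    shape = np.exp(theta[p]) if family.has_shape else None
    eta = X @ beta
    d1 = family.d1(y, eta, shape)
    d2 = family.d2(y, eta, shape)
    grad = np.empty(theta.size)
    grad[:p] = -(X.T @ d1)
    H = np.empty((theta.size, theta.size))
    H[:p, :p] = X.T @ (d2[:, None] * X)
    if family.has_shape:
        k = shape
        dll_dk = family.dll_dk(y, eta, shape)
        grad[p] = -k * np.sum(dll_dk)
        d2ll_dk2 = y.size * (1.0 / k - special.polygamma(1, k))
        H[p, p] = -(k * np.sum(dll_dk) + k * k * d2ll_dk2)
        cross = -(X.T @ d1)          # d2(nll)/dbeta dlog k = -X' d1
        H[:p, p] = cross
        H[p, :p] = cross
    return grad, H


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _BaseGLMM(BaseEstimator):
    """Shared fitting engine for the two hurdle submodels."""

    _part: str = ""

    def __init__(self, species="blue", fixed_terms=("year", "month", "fleet",
                                                    "observer"),
                 random_effect="vessel_id", tol=1e-8, max_iter=1000,
                 compute_covariance=True, separation_bound=15.0):
        self.species = species
        self.fixed_terms = fixed_terms
        self.random_effect = random_effect
        self.tol = tol
        self.max_iter = max_iter
        self.compute_covariance = compute_covariance
        self.separation_bound = separation_bound

    # -- responses -----------------------------------------------------
    def _response(self, data):
        raise NotImplementedError

    @property
    def family_(self):
        return _FAMILIES[self._part]

    # -- fitting ---------------------------------------------------------
    def fit(self, data: pd.DataFrame, y=None):
        family = self.family_
        y = self._response(data) if y is None else np.asarray(y, float)
        X, names, levels = build_design(data, self.fixed_terms)
        n, p = X.shape

        has_random = self.random_effect is not None
        if has_random:
            vessels, codes = np.unique(
                data[self.random_effect].to_numpy(), return_inverse=True)
            m = vessels.size
            if m < 2:
                raise ValueError(
                    "random vessel intercept needs at least 2 vessels")
        else:
            vessels, codes, m = np.array([]), np.zeros(n, int), 0

        n_extra = int(has_random) + int(family.has_shape)
        x0 = np.zeros(p + n_extra)
        bounds = [(None, None)] * p
        if has_random:
            x0[p] = np.log(0.5)
            bounds.append((np.log(1e-3), np.log(50.0)))
        if family.has_shape:
            x0[-1] = 0.0
            bounds.append((np.log(1e-3), np.log(1e4)))

        u_state = np.zeros(max(m, 1))

        def nll(theta):
            return -_laplace_loglik(theta, X, y, codes, m, family,
                                    has_random, u_state)

        if has_random:
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=bounds,
                options=dict(maxiter=self.max_iter, ftol=1e-13, gtol=1e-9))
            theta, fun, success = res.x, res.fun, bool(res.success)
        else:
            def jac(theta):
                return _glm_score_hessian(theta, X, y, family)[0]

            res = optimize.minimize(
                nll, x0, jac=jac, method="L-BFGS-B", bounds=bounds,
                options=dict(maxiter=self.max_iter, ftol=1e-13, gtol=1e-10))
            theta, fun = res.x, res.fun
            # Newton polish to closed-form accuracy
            for _ in range(25):
                g, H = _glm_score_hessian(theta, X, y, family)
                try:
                    step = np.linalg.solve(H, g)
                except np.linalg.LinAlgError:
                    break
                theta = theta - step
                if np.max(np.abs(step)) < 1e-12:
                    break
            fun = nll(theta)
            success = bool(res.success) and np.isfinite(fun)

        self.converged_ = success and np.all(np.isfinite(theta))
        self.coef_ = theta[:p].copy()
        self.coef_names_ = names
        self.levels_ = levels
        pos = p
        if has_random:
            self.sigma_vessel_ = float(np.exp(theta[pos]))
            pos += 1
        else:
            self.sigma_vessel_ = 0.0
        self.shape_ = float(np.exp(theta[-1])) if family.has_shape else None
        self.loglik_ = float(-fun)
        self.n_obs_ = n
        n_params = theta.size
        self.n_params_ = n_params
        self.bic_ = float(2.0 * fun + n_params * np.log(n))
        self.theta_ = theta

        self.warnings_ = []
        if self._part == "binomial" and np.any(
                np.abs(self.coef_) > self.separation_bound):
            self.warnings_.append(
                "possible separation: |coefficient| exceeds "
                f"{self.separation_bound}")
        if not self.converged_:
            self.warnings_.append("optimizer did not report convergence")

        # random-intercept predictions at the optimum
        if has_random:
            tau = self.sigma_vessel_ ** -2
            u, _, _ = _inner_modes(X @ self.coef_, y, codes, m, tau, family,
                                   self.shape_, np.zeros(m))
            self.vessel_modes_ = dict(zip(vessels.tolist(),
                                          np.round(u, 12).tolist()))
        else:
            self.vessel_modes_ = {}

        # observed-information covariance
        if self.compute_covariance:
            if has_random:
                H = _numeric_hessian(nll, theta)
            else:
                _, H = _glm_score_hessian(theta, X, y, family)
            try:
                cov_full = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov_full = np.linalg.pinv(H)
            self.cov_full_ = cov_full
            self.cov_ = cov_full[:p, :p]
        else:
            self.cov_full_ = None
            self.cov_ = np.full((p, p), np.nan)

        self.X_ = X
        self._has_random = has_random
        return self

    # -- prediction -------------------------------------------------------
    def _design_for(self, data: pd.DataFrame) -> np.ndarray:
        """Design rows for new data on the fitted coding (unseen levels map
        to the reference level)."""
        n = len(data)
        X = np.zeros((n, len(self.coef_names_)))
        X[:, 0] = 1.0
        col = {name: j for j, name in enumerate(self.coef_names_)}
        for term, levels in self.levels_.items():
            arr = data[term].to_numpy()
            for lev in levels[1:]:
                X[:, col[f"{term}[{lev}]"]] = (arr == lev).astype(float)
        return X

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        return self._design_for(data) @ self.coef_

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Response-scale mean with the random intercept at zero."""
        eta = self.linear_predictor(data)
        if self._part == "binomial":
            return special.expit(eta)
        return np.exp(eta)


class BinomialGLMM(_BaseGLMM):
    """Mixed logistic regression for the probability of a non-zero catch."""

    _part = "binomial"

    def _response(self, data):
        return (data[f"count_{self.species}"].to_numpy() > 0).astype(float)


class GammaGLMM(_BaseGLMM):
    """Mixed gamma (log link) regression for positive CPUE magnitude.

    Must be fitted on the positive subset; a zero response violates the
    hurdle contract and raises.
    """

    _part = "gamma"

    def _response(self, data):
        cpue = compute_cpue(data, self.species)
        if np.any(cpue <= 0):
            raise HurdleContractError(
                "gamma submodel requires strictly positive CPUE; "
                "subset the data to sets with a non-zero catch first")
        return cpue


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def _wrap(est: _BaseGLMM, spec: ModelSpec) -> FittedSubmodel:
    return FittedSubmodel(
        spec=spec,
        coefficients=dict(zip(est.coef_names_, est.coef_.tolist())),
        coef_names=list(est.coef_names_),
        covariance=est.cov_,
        sigma_vessel=est.sigma_vessel_,
        shape=est.shape_,
        loglik=est.loglik_,
        n_obs=est.n_obs_,
        bic=est.bic_,
        converged=bool(est.converged_),
        vessel_modes=est.vessel_modes_,
        warnings=list(est.warnings_),
        _estimator=est,
    )


def _estimator_for(spec: ModelSpec, **kw) -> _BaseGLMM:
    cls = BinomialGLMM if spec.part == "binomial" else GammaGLMM
    random = "vessel_id" if spec.random_term else None
    return cls(species=spec.species, fixed_terms=tuple(spec.fixed_terms),
               random_effect=random, **kw)


def fit_binomial_glmm(data: pd.DataFrame, spec: ModelSpec,
                      **kw) -> FittedSubmodel:
    """Fit the presence/absence submodel on all (cleaned) sets."""
    if spec.part != "binomial":
        raise ValueError("spec.part must be 'binomial'")
    est = _estimator_for(spec, **kw).fit(data)
    return _wrap(est, spec)


def fit_gamma_glmm(data: pd.DataFrame, spec: ModelSpec,
                   **kw) -> FittedSubmodel:
    """Fit the positive-catch submodel on the positive subset."""
    if spec.part != "gamma":
        raise ValueError("spec.part must be 'gamma'")
    est = _estimator_for(spec, **kw).fit(data)
    return _wrap(est, spec)


# ---------------------------------------------------------------------------
# dispersion diagnostic (Taylor power law)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionDiagnostic:
    """Slope of log variance on log mean over covariate cells.

    A slope near 2 (variance proportional to the squared mean) is the
    signature of a constant-shape gamma error and motivates the gamma choice
    for the positive part.
    """

    available: bool
    slope: float | None
    intercept: float | None
    n_cells: int
    message: str = ""


def dispersion_diagnostic(data: pd.DataFrame, species: str = "blue",
                          cell_terms=("year", "area"), min_cells: int = 3,
                          min_per_cell: int = 5) -> DispersionDiagnostic:
    """Regress log per-cell variance of positive CPUE on log per-cell mean."""
    pos = positive_subset(data, species)
    if len(pos) == 0:
        return DispersionDiagnostic(False, None, None, 0, "no positive sets")
    cpue = pd.Series(compute_cpue(pos, species), index=pos.index, name="cpue")
    grouped = cpue.groupby([pos[t] for t in cell_terms], observed=True)
    stats = grouped.agg(["mean", "var", "count"]).dropna()
    ok = (stats["count"] >= min_per_cell) & (stats["mean"] > 0) \
        & (stats["var"] > 0)
    stats = stats.loc[ok]
    if len(stats) < min_cells:
        return DispersionDiagnostic(
            False, None, None, int(len(stats)),
            f"only {len(stats)} qualifying cells (need {min_cells})")
    x = np.log(stats["mean"].to_numpy())
    v = np.log(stats["var"].to_numpy())
    slope, intercept = np.polyfit(x, v, 1)
    return DispersionDiagnostic(True, float(slope), float(intercept),
                                int(len(stats)))


# ---------------------------------------------------------------------------
# BIC forward selection
# ---------------------------------------------------------------------------

def stepwise_select(data: pd.DataFrame, part: str,
                    candidate_terms=("month", "fleet", "observer"),
                    species: str = "blue", area: str | None = None,
                    base_terms=("year",), random_term="vessel_intercept",
                    **fit_kw):
    """Forward BIC selection over candidate fixed terms.

    Year and the vessel random intercept are always retained.  At each step
    the candidate lowering BIC the most is added; selection stops when no
    addition lowers BIC.  Returns ``(best_spec, table)`` where ``table`` lists
    every evaluated specification with its BIC and convergence status.
    """
    fit_kw.setdefault("compute_covariance", False)
    fitter = fit_binomial_glmm if part == "binomial" else fit_gamma_glmm

    def evaluate(terms):
        spec = ModelSpec(part=part, fixed_terms=tuple(terms),
                         random_term=random_term, species=species, area=area)
        fit = fitter(data, spec, **fit_kw)
        return spec, fit

    rows = []
    current = list(base_terms)
    spec, fit = evaluate(current)
    best_bic = fit.bic if fit.converged else np.inf
    rows.append({"step": 0, "terms": "+".join(current), "bic": fit.bic,
                 "converged": fit.converged, "selected": True})
    remaining = list(candidate_terms)
    step = 0
    while remaining:
        step += 1
        trial = []
        for term in remaining:
            t_spec, t_fit = evaluate(current + [term])
            bic = t_fit.bic if t_fit.converged else np.inf
            rows.append({"step": step, "terms": "+".join(current + [term]),
                         "bic": t_fit.bic, "converged": t_fit.converged,
                         "selected": False})
            trial.append((bic, term, t_spec))
        bic_best, term_best, spec_best = min(trial, key=lambda t: t[0])
        if bic_best < best_bic:
            best_bic = bic_best
            current.append(term_best)
            remaining.remove(term_best)
            spec = spec_best
            for r in rows:
                if r["step"] == step and r["terms"] == "+".join(current):
                    r["selected"] = True
        else:
            break
    table = pd.DataFrame(rows)
    return spec, table


# ---------------------------------------------------------------------------
# quadrature oracle
# ---------------------------------------------------------------------------

def marginal_loglik_oracle(data: pd.DataFrame, spec: ModelSpec,
                           parameters: dict, n_nodes: int = 50,
                           max_vessels: int = 20) -> float:
    """Marginal log-likelihood by adaptive Gauss–Hermite quadrature.

    Integrates the vessel random intercept exactly (to quadrature accuracy)
    for small instances; intended as an independent audit of the Laplace
    approximation, not as a fitting engine.  ``parameters`` holds
    ``coefficients`` (term name → value, missing names are zero),
    ``sigma_vessel`` and, for the gamma part, ``shape``.
    """
    if n_nodes < 20:
        raise ValueError("use at least 20 quadrature nodes")
    family = _FAMILIES[spec.part]
    est = _estimator_for(spec)
    y = est._response(data)
    X, names, _ = build_design(data, spec.fixed_terms)
    coeffs = parameters["coefficients"]
    unknown = set(coeffs) - set(names)
    if unknown:
        raise ValueError(f"coefficients not in design: {sorted(unknown)}")
    beta = np.array([coeffs.get(nm, 0.0) for nm in names])
    sigma = float(parameters.get("sigma_vessel", 0.0))
    shape = parameters.get("shape")
    if family.has_shape and shape is None:
        raise ValueError("gamma part needs a 'shape' parameter")

    xb = X @ beta
    if spec.random_term is None or sigma == 0.0:
        return float(np.sum(family.ll(y, xb, shape)))

    vessels, codes = np.unique(data["vessel_id"].to_numpy(),
                               return_inverse=True)
    m = vessels.size
    if m > max_vessels:
        raise ValueError(
            f"oracle is for small instances (<= {max_vessels} vessels), "
            f"got {m}")
    tau = sigma ** -2
    u, _, h = _inner_modes(xb, y, codes, m, tau, family, shape, np.zeros(m))
    z, w = hermgauss(n_nodes)
    scale = 1.0 / np.sqrt(h)                       # per-vessel adaptive scale
    total = 0.0
    log_norm = -0.5 * np.log(2.0 * np.pi) - np.log(sigma)
    for j in range(m):
        idx = codes == j
        uj = u[j] + np.sqrt(2.0) * scale[j] * z    # (n_nodes,)
        eta = xb[idx][None, :] + uj[:, None]
        g = (family.ll(y[idx][None, :], eta, shape).sum(axis=1)
             - 0.5 * tau * uj ** 2 + log_norm)
        total += special.logsumexp(np.log(w) + z ** 2 + g) \
            + 0.5 * np.log(2.0) + np.log(scale[j])
    return float(total)
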