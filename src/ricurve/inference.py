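"""Multimodel inference on RIC timescale and amplitude.

Two model families are fitted to the per-individual RIC summaries:

* **timescale** — a logistic mixed model on the binary dominant timescale
  (0 = short-term, 1 = long-term), and
* **amplitude** — Gaussian mixed models on the transformed peak-to-trough
  amplitude of the short- and long-term RICs (log for the absolute-clutch
  measure, square root for the mean-centred measure).

Every model carries a birth-year random intercept (cohort effect).  All
2^3 = 8 subsets of the fixed-effect pool {mean individual clutch size,
population, sex} are fitted by maximum likelihood, ranked by AICc
(``-2*loglik + 2k + 2k(k+1)/(n-k-1)``), weighted with Akaike weights
``exp(-delta/2)`` renormalised over the candidate set, and the models within
two AICc units of the best are averaged (conditional averaging by default).
Estimated marginal means are computed from the single best-fitting model and
back-transformed to the response scale with delta-method standard errors.

The Gaussian mixed models are fitted with statsmodels ``MixedLM`` (ML, not
REML, so fixed-effect structures are AICc-comparable).  The logistic
random-intercept model is fitted here by direct maximisation of the marginal
likelihood with Gauss–Hermite quadrature over the random effect.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "FIXED_POOL",
    "DEFAULT_REFERENCE_LEVELS",
    "CandidateModel",
    "ModelFit",
    "ModelSelectionTable",
    "ZeroAmplitudeError",
    "enumerate_candidates",
    "build_analysis_table",
    "fit_model",
    "aicc",
    "delta_and_weights",
    "select_models",
    "average_within_delta",
    "marginal_means",
]

FIXED_POOL = ("mean_individual_clutch", "population", "sex")
DEFAULT_REFERENCE_LEVELS = {"population": "D-Muro", "sex": "female"}

_RESPONSE_COLUMNS = {
    "timescale_binary": "dominant_scale_binary",
    "amplitude_short": "amplitude_short",
    "amplitude_long": "amplitude_long",
}


class ZeroAmplitudeError(ValueError):
    """A log transform was requested on data containing zero amplitudes.

    Drop the zero-amplitude rows (and count them) before fitting.
    """


@dataclass(frozen=True)
class CandidateModel:
    response: str
    fixed_terms: tuple[str, ...]
    transform: str  # none | log | sqrt
    family: str  # bernoulli_logit | gaussian

    @staticmethod
    def make(response: str, measure: str, fixed_terms: Sequence[str]) -> "CandidateModel":
        if response == "timescale_binary":
            transform, family = "none", "bernoulli_logit"
        elif response in ("amplitude_short", "amplitude_long"):
            transform = "log" if measure == "absolute" else "sqrt"
            family = "gaussian"
        else:
            raise ValueError(f"unknown response {response!r}")
        return CandidateModel(response, tuple(fixed_terms), transform, family)


@dataclass
class ModelFit:
    model: CandidateModel
    coef_names: list[str]
    coefficients: dict[str, float]
    cov: np.ndarray | None
    loglik: float
    k_params: int
    n_obs: int
    random_intercept_variance: float
    residual_variance: float | None
    converged: bool
    reference_levels: dict[str, str] = field(default_factory=dict)
    factor_levels: dict[str, list[str]] = field(default_factory=dict)


def enumerate_candidates(
    response: str,
    measure: str = "absolute",
    fixed_pool: Sequence[str] = FIXED_POOL,
) -> list[CandidateModel]:
    """All fixed-effect subsets (including intercept-only), smallest first."""
    pool = tuple(fixed_pool)
    out = []
    for r in range(len(pool) + 1):
        for combo in itertools.combinations(pool, r):
            out.append(CandidateModel.make(response, measure, combo))
    return out


# ---------------------------------------------------------------------------
# Analysis table
# ---------------------------------------------------------------------------

def build_analysis_table(series_list, classifications) -> pd.DataFrame:
    """Join per-individual metadata with RIC classifications.

    ``amplitude_short`` / ``amplitude_long`` are the peak-to-trough amplitudes
    of the short- and long-scale members among the two leading RICs (NaN when
    the individual has no RIC of that scale among them).
    """
    meta = {
        s.individual_id: {
            "population": s.population,
            "sex": s.sex,
            "birth_year": s.birth_year,
            "mean_individual_clutch": s.mean_individual_clutch,
        }
        for s in series_list
    }
    rows = []
    for c in classifications:
        m = meta[c.individual_id]
        amp_short = np.nan
        amp_long = np.nan
        leading = [(c.dominant_scale, c.dominant_amplitude)]
        if c.secondary_scale is not None:
            leading.append((c.secondary_scale, c.secondary_amplitude))
        for scale, amp in leading:
            if scale == "short":
                amp_short = amp if np.isnan(amp_short) else max(amp_short, amp)
            else:
                amp_long = amp if np.isnan(amp_long) else max(amp_long, amp)
        rows.append(
            {
                "individual_id": c.individual_id,
                "measure": c.measure,
                **m,
                "dominant_scale_binary": 0 if c.dominant_scale == "short" else 1,
                "amplitude_short": amp_short,
                "amplitude_long": amp_long,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _design(
    data: pd.DataFrame,
    fixed_terms: Sequence[str],
    reference_levels: Mapping[str, str],
) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Treatment-coded design matrix with an explicit intercept."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    factor_levels: dict[str, list[str]] = {}
    for term in fixed_terms:
        if term == "mean_individual_clutch":
            cols.append(data[term].to_numpy(dtype=float))
            names.append(term)
        else:
            levels = sorted(data[term].astype(str).unique())
            ref = reference_levels.get(term, levels[0])
            if ref not in levels:
                ref = levels[0]
            ordered = [ref] + [lv for lv in levels if lv != ref]
            factor_levels[term] = ordered
            vals = data[term].astype(str).to_numpy()
            for lv in ordered[1:]:
                cols.append((vals == lv).astype(float))
                names.append(f"{term}[{lv}]")
    return np.column_stack(cols), names, factor_levels


# ---------------------------------------------------------------------------
# Logistic random-intercept model (Gauss–Hermite ML)
# ---------------------------------------------------------------------------

def _fit_logit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_nodes: int = 25,
) -> tuple[np.ndarray, float, float, np.ndarray, bool]:
    """ML fit of logit(P(y=1)) = X beta + b_g, b_g ~ N(0, sigma^2).

    Returns (beta, sigma2, loglik, cov_beta, converged).  The marginal
    likelihood integrates the random intercept out with Gauss–Hermite
    quadrature; sigma is constrained to [0, inf) so the fit degenerates
    cleanly to plain logistic regression when the between-group variance
    vanishes.
    """
    _, codes = np.unique(groups, return_inverse=True)
    n_groups = codes.max() + 1
    nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
    log_w = np.log(wts) - 0.5 * np.log(np.pi)
    p = X.shape[1]

    def negll(theta: np.ndarray) -> float:
        beta, sigma = theta[:p], theta[p]
        eta = X @ beta
        b = np.sqrt(2.0) * sigma * nodes  # (Q,)
        lp = eta[:, None] + b[None, :]  # (n, Q)
        ll_obs = y[:, None] * lp - np.logaddexp(0.0, lp)
        group_ll = np.zeros((n_groups, n_nodes))
        np.add.at(group_ll, codes, ll_obs)
        return -float(np.sum(logsumexp(group_ll + log_w[None, :], axis=1)))

    # warm start from a fixed-effects-only logistic fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            beta0 = sm.Logit(y, X).fit(disp=False, maxiter=200).params
        except Exception:
            beta0 = np.zeros(p)
    theta0 = np.concatenate([np.asarray(beta0, dtype=float), [0.3]])
    bounds = [(None, None)] * p + [(0.0, None)]
    res = minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12})
    beta_hat, sigma_hat = res.x[:p], float(res.x[p])
    loglik = -float(res.fun)

    # delta-method covariance of the fixed effects; when sigma sits on the
    # boundary the full Hessian is singular in sigma, so hold sigma fixed.
    if sigma_hat > 1e-4:
        H = approx_hess(res.x, negll)
        try:
            cov_beta = np.linalg.inv(H)[:p, :p]
        except np.linalg.LinAlgError:
            cov_beta = np.linalg.pinv(H)[:p, :p]
    else:
        H = approx_hess(beta_hat, lambda b: negll(np.concatenate([b, [sigma_hat]])))
        try:
            cov_beta = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_beta = np.linalg.pinv(H)
    return beta_hat, sigma_hat**2, loglik, cov_beta, bool(res.success)


# ---------------------------------------------------------------------------
# Gaussian random-intercept model (statsmodels MixedLM, ML)
# ---------------------------------------------------------------------------

def _ols_ml(y: np.ndarray, X: np.ndarray):
    """Zero-variance limit of the mixed model: plain OLS, ML log-likelihood."""
    fit = sm.OLS(y, X).fit()
    beta = np.asarray(fit.params, dtype=float)
    resid = y - X @ beta
    n = y.size
    scale_ml = float(resid @ resid) / n
    llf = -0.5 * n * (np.log(2.0 * np.pi * scale_ml) + 1.0)
    cov = np.asarray(fit.cov_params()) * scale_ml / float(fit.scale)
    return beta, 0.0, float(llf), cov, scale_ml, True


def _fit_gaussian_random_intercept(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """ML MixedLM fit with a cascade of optimizers.

    When the between-group variance degenerates to the boundary the MixedLM
    Hessian is singular; in that case the exact zero-variance profile (OLS
    with ML scale) is used, provided it does not lose likelihood.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(y, X, groups=groups)
        best = None
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            try:
                fit = md.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if not np.isfinite(fit.llf):  # optimizer can report a bogus boundary llf
                continue
            if best is None or fit.llf > best.llf:
                best = fit
            if fit.converged:
                break
    ols = _ols_ml(y, X)
    if best is None or ols[2] >= float(best.llf) - 1e-8:
        return ols
    cov = np.asarray(best.cov_params())[: X.shape[1], : X.shape[1]]
    return (
        np.asarray(best.fe_params, dtype=float),
        float(np.asarray(best.cov_re)[0, 0]),
        float(best.llf),
        cov,
        float(best.scale),
        bool(best.converged),
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _transform_response(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return values
    if transform == "log":
        if np.any(values <= 0):
            raise ZeroAmplitudeError(
                "log transform requires strictly positive amplitudes; "
                "drop zero-amplitude rows (and count them) before fitting"
            )
        return np.log(values)
    if transform == "sqrt":
        if np.any(values < 0):
            raise ValueError("sqrt transform requires non-negative amplitudes")
        return np.sqrt(values)
    raise ValueError(f"unknown transform {transform!r}")


def fit_model(
    model: CandidateModel,
    data: pd.DataFrame,
    reference_levels: Mapping[str, str] | None = None,
) -> ModelFit:
    """Maximum-likelihood fit of one candidate model with a birth-year
    random intercept.

    ``k_params`` counts fixed effects + the random-intercept variance
    (+ the residual variance for Gaussian models), matching standard
    information-criterion bookkeeping for these model families.
    """
    refs = dict(DEFAULT_REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)
    if data.empty:
        raise ValueError("cannot fit a model to an empty table")

    col = _RESPONSE_COLUMNS[model.response]
    resp = data[col].to_numpy(dtype=float)
    if np.isnan(resp).any():
        raise ValueError(f"response column {col!r} contains missing values; drop them first")

    X, names, factor_levels = _design(data, model.fixed_terms, refs)
    groups = data["birth_year"].to_numpy()

    if model.family == "bernoulli_logit":
        y = resp.astype(int)
        beta, sigma2, loglik, cov, converged = _fit_logit_random_intercept(
            y.astype(float), X, groups
        )
        k = X.shape[1] + 1
        resid_var = None
    else:
        y = _transform_response(resp, model.transform)
        beta, sigma2, loglik, cov, resid_var, converged = _fit_gaussian_random_intercept(y, X, groups)
        k = X.shape[1] + 2

    return ModelFit(
        model=model,
        coef_names=names,
        coefficients=dict(zip(names, (float(b) for b in beta))),
        cov=cov,
        loglik=loglik,
        k_params=k,
        n_obs=len(data),
        random_intercept_variance=float(sigma2),
        residual_variance=resid_var,
        converged=converged,
        reference_levels=refs,
        factor_levels=factor_levels,
    )


# ---------------------------------------------------------------------------
# AICc, weights, averaging
# ---------------------------------------------------------------------------

def aicc(loglik, k_params: int | None = None, n_obs: int | None = None) -> float:
    """Small-sample Akaike criterion; accepts a :class:`ModelFit` or raw values."""
    if isinstance(loglik, ModelFit):
        fit = loglik
        loglik, k_params, n_obs = fit.loglik, fit.k_params, fit.n_obs
    if n_obs <= k_params + 1:
        raise ValueError(f"AICc undefined: n = {n_obs} <= k + 1 = {k_params + 1}")
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n_obs - k_params - 1)


def delta_and_weights(aicc_values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """AICc differences from the best model and normalised Akaike weights."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("empty AICc list")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


@dataclass
class ModelSelectionTable:
    fits: list[ModelFit]
    aicc: np.ndarray
    delta: np.ndarray
    weight: np.ndarray
    retain_threshold: float

    @property
    def order(self) -> np.ndarray:
        return np.argsort(self.aicc, kind="stable")

    @property
    def retained_indices(self) -> list[int]:
        return [i for i in self.order if self.delta[i] < self.retain_threshold]

    @property
    def best_fit(self) -> ModelFit:
        return self.fits[int(self.order[0])]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in self.order:
            f = self.fits[i]
            rows.append(
                {
                    "terms": "+".join(f.model.fixed_terms) or "(intercept)",
                    "df": f.k_params,
                    "loglik": f.loglik,
                    "aicc": self.aicc[i],
                    "delta": self.delta[i],
                    "weight": self.weight[i],
                    "retained": bool(self.delta[i] < self.retain_threshold),
                    "converged": f.converged,
                }
            )
        return pd.DataFrame(rows)


def select_models(fits: Sequence[ModelFit], retain_threshold: float = 2.0) -> ModelSelectionTable:
    """Rank candidate fits by AICc.  Non-converged fits are excluded with a warning."""
    usable = [f for f in fits if f.converged]
    dropped = len(fits) - len(usable)
    if dropped:
        warnings.warn(f"excluded {dropped} non-converged fit(s) from model selection")
    if not usable:
        raise ValueError("no converged fits to select among")
    a = np.array([aicc(f) for f in usable])
    delta, weight = delta_and_weights(a)
    return ModelSelectionTable(list(usable), a, delta, weight, retain_threshold)


def average_within_delta(
    table: ModelSelectionTable,
    threshold: float | None = None,
    method: str = "conditional",
) -> tuple[dict[str, float], list[ModelFit]]:
    """Weighted-average coefficients over the retained (delta < threshold) set.

    ``conditional`` averages each term only over retained models containing
    it; ``full`` substitutes zero where a term is absent.  Weights are
    renormalised over the retained set in both cases.
    """
    thr = table.retain_threshold if threshold is None else threshold
    idx = [i for i in table.order if table.delta[i] < thr]
    retained = [table.fits[i] for i in idx]
    w = np.array([table.weight[i] for i in idx])
    w = w / w.sum()

    all_names: list[str] = []
    for f in retained:
        for name in f.coef_names:
            if name not in all_names:
                all_names.append(name)

    averaged: dict[str, float] = {}
    for name in all_names:
        if method == "conditional":
            num = sum(wi * f.coefficients[name] for wi, f in zip(w, retained) if name in f.coefficients)
            den = sum(wi for wi, f in zip(w, retained) if name in f.coefficients)
            averaged[name] = num / den
        elif method == "full":
            averaged[name] = float(
                sum(wi * f.coefficients.get(name, 0.0) for wi, f in zip(w, retained))
            )
        else:
            raise ValueError(f"unknown averaging method {method!r}")
    return averaged, retained


# ---------------------------------------------------------------------------
# Estimated marginal means
# ---------------------------------------------------------------------------

def _inverse_link(eta: float, se_eta: float, fit: ModelFit) -> tuple[float, float, str]:
    if fit.model.family == "bernoulli_logit":
        p = float(expit(eta))
        return p, p * (1.0 - p) * se_eta, "inverse-logit"
    if fit.model.transform == "log":
        return float(np.exp(eta)), float(np.exp(eta)) * se_eta, "exp"
    if fit.model.transform == "sqrt":
        return float(eta * eta), 2.0 * abs(float(eta)) * se_eta, "square"
    return float(eta), se_eta, "identity"


def marginal_means(
    fit: ModelFit,
    data: pd.DataFrame,
    factor: str,
) -> pd.DataFrame:
    """Estimated marginal means per level of ``factor``, on the response scale.

    Other factors in the model are averaged with equal level weights on the
    linear-predictor scale, the continuous covariate is held at its grand
    mean, and the random intercept at zero; estimates and delta-method
    standard errors are back-transformed through the inverse link.  If the
    factor is absent from the model a single grand-mean row is returned.
    """
    names = fit.coef_names
    beta = np.array([fit.coefficients[n] for n in names])
    cov = fit.cov if fit.cov is not None else np.zeros((len(names), len(names)))

    def averaged_row(fixed_level: tuple[str, str] | None) -> np.ndarray:
        row = np.zeros(len(names))
        row[names.index("intercept")] = 1.0
        if "mean_individual_clutch" in names:
            row[names.index("mean_individual_clutch")] = float(
                data["mean_individual_clutch"].mean()
            )
        for term, levels in fit.factor_levels.items():
            if fixed_level is not None and term == fixed_level[0]:
                lv = fixed_level[1]
                if lv != levels[0]:
                    row[names.index(f"{term}[{lv}]")] = 1.0
            else:
                # equal weight over levels: each non-reference dummy gets 1/L
                for lv in levels[1:]:
                    row[names.index(f"{term}[{lv}]")] = 1.0 / len(levels)
        return row

    rows = []
    if factor in fit.factor_levels:
        for lv in fit.factor_levels[factor]:
            L = averaged_row((factor, lv))
            eta = float(L @ beta)
            se_eta = float(np.sqrt(max(L @ cov @ L, 0.0)))
            est, se, note = _inverse_link(eta, se_eta, fit)
            rows.append({"factor": factor, "factor_level": lv, "estimate": est,
                         "se": se, "scale_note": note})
    else:
        L = averaged_row(None)
        eta = float(L @ beta)
        se_eta = float(np.sqrt(max(L @ cov @ L, 0.0)))
        est, se, note = _inverse_link(eta, se_eta, fit)
        rows.append({"factor": factor, "factor_level": "(grand mean: factor not in model)",
                     "estimate": est, "se": se, "scale_note": note})
    return pd.DataFrame(rows)
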