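"""Censored-regression adjustment of BP for antihypertensive treatment.

Observed BP under treatment is a lower bound on the untreated BP, so a
treated measurement is right-censored at its observed value.  Untreated
observations contribute the normal density, treated ones the survival
term 1 - Phi((y - Xb)/s).  After the ML fit, a treated observation is
replaced by the mean of the normal truncated below at the observed value
(fitted + sigma*lambda(z), inverse Mills ratio lambda), and the working
trait is the residual: observed - fitted for untreated, adjusted -
fitted for treated.  These residuals (rSBP, rDBP) are what the SEMs
consume; no further covariate adjustment happens downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm


class TobitError(ValueError):
    pass


@dataclass
class TobitFit:
    beta: np.ndarray        # mmHg per covariate unit, intercept first
    sigma: float            # residual SD, mmHg
    loglik: float
    converged: bool
    n_treated: int
    n_untreated: int


@dataclass
class AdjustedTrait:
    observed: np.ndarray
    fitted: np.ndarray
    adjusted: np.ndarray   # == observed for untreated, >= observed treated
    residual: np.ndarray   # the working rBP values


def inverse_mills(z: np.ndarray) -> np.ndarray:
    """lambda(z) = phi(z)/(1 - Phi(z)), overflow-safe.

    Evaluated in log space; beyond z = 30 the asymptotic expansion
    z + 1/z is used so the result is always finite.
    """
    z = np.asarray(z, float)
    out = np.empty_like(z)
    big = z > 30.0
    safe = ~big
    out[safe] = np.exp(norm.logpdf(z[safe]) - norm.logsf(z[safe]))
    out[big] = z[big] + 1.0 / z[big]
    return out


def _negll_and_grad(theta, y, X, treated):
    beta, logs = theta[:-1], theta[-1]
    s = np.exp(logs)
    z = (y - X @ beta) / s
    unc = ~treated
    nll = (0.5 * np.sum(z[unc] ** 2) + unc.sum() * (logs + 0.5 * np.log(2 * np.pi))
           - np.sum(norm.logsf(z[treated])))
    lam = inverse_mills(z[treated])
    w = np.zeros_like(z)
    w[unc] = z[unc]
    w[treated] = lam
    g_beta = -(X.T @ w) / s
    g_logs = unc.sum() - np.sum(z[unc] ** 2) - np.sum(z[treated] * lam)
    return nll, np.append(g_beta, g_logs)


def fit_censored_regression(y: np.ndarray, X: np.ndarray,
                            treated: np.ndarray) -> TobitFit:
    """ML fit of the right-censored normal regression.

    With no treated observations the likelihood reduces to OLS (the ML
    sigma uses the 1/n variance).  All-treated input is unidentified and
    raises :class:`TobitError`.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    treated = np.asarray(treated, bool)
    if X.shape[0] != len(y) or len(treated) != len(y):
        raise ValueError("y, X, treated must have matching lengths")
    if treated.all():
        raise TobitError("all observations treated: model unidentified")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise TobitError("covariate matrix is rank deficient")

    unc = ~treated
    b0, *_ = np.linalg.lstsq(X[unc], y[unc], rcond=None)
    resid = y[unc] - X[unc] @ b0
    s0 = max(np.sqrt(np.mean(resid ** 2)), 1e-6)
    x0 = np.append(b0, np.log(s0))

    res = minimize(_negll_and_grad, x0, args=(y, X, treated),
                   jac=True, method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 500})
    if not res.success:
        # BFGS can stall on precision loss near the optimum; polish
        res2 = minimize(_negll_and_grad, res.x, args=(y, X, treated),
                        jac=True, method="L-BFGS-B",
                        options={"ftol": 1e-12, "gtol": 1e-9})
        if res2.fun <= res.fun:
            res = res2
    converged = bool(res.success) or np.linalg.norm(res.jac) < 1e-3
    if not converged:
        warnings.warn("censored regression did not converge")
    return TobitFit(beta=res.x[:-1], sigma=float(np.exp(res.x[-1])),
                    loglik=-float(res.fun), converged=converged,
                    n_treated=int(treated.sum()), n_untreated=int(unc.sum()))


def tobit_loglik(beta, sigma, y, X, treated) -> float:
    """Log-likelihood at arbitrary parameters (for ML-property checks)."""
    theta = np.append(np.asarray(beta, float), np.log(sigma))
    nll, _ = _negll_and_grad(theta, np.asarray(y, float),
                             np.atleast_2d(np.asarray(X, float)),
                             np.asarray(treated, bool))
    return -nll


def adjust_and_residualize(y, X, treated, fit: TobitFit) -> AdjustedTrait:
    """Impute treated observations to their truncated-normal mean and
    residualize against the fitted covariate effects."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    treated = np.asarray(treated, bool)
    fitted = X @ fit.beta
    adjusted = y.copy()
    z = (y[treated] - fitted[treated]) / fit.sigma
    adjusted[treated] = fitted[treated] + fit.sigma * inverse_mills(z)
    residual = adjusted - fitted  # == y - fitted for untreated
    return AdjustedTrait(observed=y, fitted=fitted, adjusted=adjusted,
                         residual=residual)


DEFAULT_COVARIATES = ("age", "sex", "smoke")


def run_adjustment(phenotypes: pd.DataFrame, trait: str,
                   covariates=DEFAULT_COVARIATES
                   ) -> tuple[pd.DataFrame, dict[int, TobitFit]]:
    """Per-visit censored-regression adjustment of one trait.

    ``phenotypes`` is the long table (FID, IID, visit, SBP, DBP, age,
    sex, smoke, treated).  Returns a wide table indexed by (FID, IID)
    with columns ``r{trait}_v{t}`` plus the per-visit fits.  Rows with
    missing trait or covariates get missing residuals.
    """
    if trait not in ("SBP", "DBP"):
        raise ValueError("trait must be 'SBP' or 'DBP'")
    missing_cov = [c for c in covariates if c not in phenotypes.columns]
    if missing_cov:
        raise ValueError(f"covariates not in table: {missing_cov}")

    visits = sorted(phenotypes["visit"].unique())
    pieces, fits = [], {}
    for t in visits:
        sub = phenotypes[phenotypes["visit"] == t]
        ok = sub[trait].notna()
        for c in covariates:
            ok &= sub[c].notna()
        sub = sub[ok]
        col = f"r{trait}_v{t}"
        if len(sub) == 0:
            warnings.warn(f"visit {t}: no usable observations for {trait}")
            continue
        X = np.column_stack([np.ones(len(sub))]
                            + [sub[c].to_numpy(float) for c in covariates])
        y = sub[trait].to_numpy(float)
        treated = sub["treated"].to_numpy() > 0
        fit = fit_censored_regression(y, X, treated)
        fits[int(t)] = fit
        adj = adjust_and_residualize(y, X, treated, fit)
        pieces.append(pd.DataFrame(
            {col: adj.residual},
            index=pd.MultiIndex.from_frame(sub[["FID", "IID"]])))
    wide = pd.concat(pieces, axis=1) if pieces else pd.DataFrame()
    return wide, fits


def residualize_dataset(phenotypes: pd.DataFrame,
                        covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Adjust both traits; returns the wide residual table with columns
    interleaved per visit (rSBP_v1, rDBP_v1, rSBP_v2, ...)."""
    sbp, _ = run_adjustment(phenotypes, "SBP", covariates)
    dbp, _ = run_adjustment(phenotypes, "DBP", covariates)
    wide = pd.concat([sbp, dbp], axis=1)
    visits = sorted(int(c.split("_v")[1]) for c in sbp.columns)
    order = []
    for t in visits:
        order += [f"rSBP_v{t}", f"rDBP_v{t}"]
    return wide.reindex(columns=order)
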