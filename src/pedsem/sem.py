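"""Latent-variable SEMs for longitudinal bivariate traits in pedigrees.

Two models of the latent blood-pressure process eta_t underlying the
medication-adjusted traits (rSBP_t, rDBP_t):

* ``ar`` — first-order autoregressive latent process with measurement
  error: eta_1 = mu_1 + gamma*g + zeta_1, eta_t = beta*eta_{t-1} + zeta_t,
  where each structural disturbance zeta_t = a_t + e_t splits into an
  additive-genetic part (variance sigma2_a, correlated 2*phi_ij between
  relatives) and an environmental part (variance sigma2_z).  The SNP acts
  on the first latent and propagates forward through beta.

* ``lg`` — latent growth curve: eta_t = I + lambda_t*S + v_t with fixed
  loadings lambda_t = (0, 1, 2, ...); intercept I = mu_I + gamma*g +
  a_I + e_I and slope S = mu_S + a_S + e_S carry a 2x2 additive-genetic
  covariance Sigma_a and environmental covariance Sigma_e; v_t is a
  visit-level environmental disturbance.  The SNP acts on the intercept,
  hence on every visit equally.

Measurement model (both): rSBP_t = eta_t + eps_S, rDBP_t =
lambda_dbp*eta_t + eps_D, with the SBP loading fixed at 1 for
identification so paths are in trait units.

The model-implied observed moments follow the standard reduced form
Sigma = Lam (I-B)^{-1} Psi (I-B)^{-T} Lam^T + Theta, with Psi split into
additive (Psi_A) and environmental (Psi_E) parts.  For a family with
kinship matrix Phi the stacked phenotype vector is multivariate normal
with covariance V = 2Phi (x) Sigma_A + I (x) Sigma_E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize

from .pedigree import KinshipMatrix

_LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# parameters and model structure
# --------------------------------------------------------------------------

@dataclass
class SemParams:
    """Free parameters of either SEM.

    AR uses ``beta_ar``, scalar pairs ``sigma2_a``/``sigma2_z`` =
    (first-visit, later-visit) disturbance variances and ``mu = (mu_1,)``.
    LG uses 2x2 ``sigma2_a``/``sigma2_z`` for (I, S), the visit-level
    environmental variance ``sigma2_v`` and ``mu = (mu_I, mu_S)``.
    ``theta`` holds the (rSBP, rDBP) measurement-error variances, shared
    across visits.  ``gamma_snp`` is the SNP path in trait units per
    minor allele (0 under the null).
    """

    kind: str
    lambda_dbp: float
    mu: tuple
    theta: tuple
    gamma_snp: float = 0.0
    beta_ar: float | None = None
    sigma2_a: object = None
    sigma2_z: object = None
    sigma2_v: float | None = None
    growth_loadings: np.ndarray | None = None

    def validate(self) -> None:
        if self.kind == "ar":
            if not (abs(self.beta_ar) < 1):
                raise ValueError("|beta_ar| must be < 1")
            for v in (*self.sigma2_a, *self.sigma2_z):
                if v < 0:
                    raise ValueError("variances must be >= 0")
        elif self.kind == "lg":
            for m in (self.sigma2_a, self.sigma2_z):
                if np.min(np.linalg.eigvalsh(np.asarray(m))) < -1e-10:
                    raise ValueError("LG 2x2 variance matrices must be PSD")
            if self.sigma2_v < 0:
                raise ValueError("sigma2_v must be >= 0")
        else:
            raise ValueError(f"unknown model kind '{self.kind}'")
        if min(self.theta) <= 0:
            raise ValueError("measurement-error variances must be > 0")


def ar_params(mu1=0.0, lambda_dbp=0.7, beta_ar=0.6,
              sigma2_a=(31.25, 20.0), sigma2_z=(46.875, 30.0),
              theta=(40.0, 20.0), gamma_snp=0.0) -> SemParams:
    """AR parameters; defaults give a stationary latent process with
    disturbance heritability 0.4 and BP-like residual variances (mmHg^2)."""
    return SemParams(kind="ar", lambda_dbp=lambda_dbp, mu=(mu1,),
                     beta_ar=beta_ar, sigma2_a=tuple(sigma2_a),
                     sigma2_z=tuple(sigma2_z), theta=tuple(theta),
                     gamma_snp=gamma_snp)


def lg_params(mu_i=0.0, mu_s=1.0, lambda_dbp=0.7,
              sigma2_a=((30.0, 2.0), (2.0, 2.0)),
              sigma2_z=((40.0, 3.0), (3.0, 3.0)),
              sigma2_v=10.0, theta=(40.0, 20.0), gamma_snp=0.0) -> SemParams:
    return SemParams(kind="lg", lambda_dbp=lambda_dbp, mu=(mu_i, mu_s),
                     sigma2_a=np.asarray(sigma2_a, float),
                     sigma2_z=np.asarray(sigma2_z, float),
                     sigma2_v=sigma2_v, theta=tuple(theta),
                     gamma_snp=gamma_snp)


@dataclass
class SemModel:
    """Structure of one SEM: maps :class:`SemParams` to the matrices
    (Lam, B, Gamma, Psi_A, Psi_E, Theta) of the reduced form."""

    kind: str
    n_visits: int

    def __post_init__(self) -> None:
        if self.kind not in {"ar", "lg"}:
            raise ValueError(f"unsupported model kind '{self.kind}'")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")

    @property
    def n_observed(self) -> int:
        return 2 * self.n_visits

    @property
    def n_latent(self) -> int:
        # LG carries (I, S) plus one latent per visit
        return self.n_visits if self.kind == "ar" else self.n_visits + 2

    @property
    def trait_names(self) -> tuple[str, str]:
        return ("rSBP", "rDBP")

    def default_growth_loadings(self) -> np.ndarray:
        return np.arange(self.n_visits, dtype=float)

    def matrices(self, params: SemParams):
        """Return (Lam, B, Gamma_unit, Psi_A, Psi_E, theta_diag).

        Gamma_unit is the unit SNP path (the actual path is
        ``params.gamma_snp * Gamma_unit``); theta_diag the length-2T
        diagonal of the measurement-error covariance.
        """
        T, L = self.n_visits, self.n_latent
        lam_d = params.lambda_dbp
        Lam = np.zeros((2 * T, L))
        B = np.zeros((L, L))
        Gamma = np.zeros(L)
        Psi_A = np.zeros((L, L))
        Psi_E = np.zeros((L, L))

        if self.kind == "ar":
            for t in range(T):
                Lam[2 * t, t] = 1.0
                Lam[2 * t + 1, t] = lam_d
            for t in range(1, T):
                B[t, t - 1] = params.beta_ar
            Gamma[0] = 1.0
            a1, ar = params.sigma2_a
            z1, zr = params.sigma2_z
            Psi_A[0, 0], Psi_E[0, 0] = a1, z1
            for t in range(1, T):
                Psi_A[t, t], Psi_E[t, t] = ar, zr
        else:  # lg: latent order (I, S, eta_1..eta_T)
            loads = (params.growth_loadings if params.growth_loadings is not None
                     else self.default_growth_loadings())
            for t in range(T):
                Lam[2 * t, 2 + t] = 1.0
                Lam[2 * t + 1, 2 + t] = lam_d
                B[2 + t, 0] = 1.0
                B[2 + t, 1] = loads[t]
            Gamma[0] = 1.0
            Psi_A[:2, :2] = np.asarray(params.sigma2_a, float)
            Psi_E[:2, :2] = np.asarray(params.sigma2_z, float)
            for t in range(T):
                Psi_E[2 + t, 2 + t] = params.sigma2_v

        theta_diag = np.tile(np.asarray(params.theta, float), T)
        return Lam, B, Gamma, Psi_A, Psi_E, theta_diag

    def latent_mean(self, params: SemParams) -> np.ndarray:
        L = self.n_latent
        nu = np.zeros(L)
        if self.kind == "ar":
            nu[0] = params.mu[0]
        else:
            nu[0], nu[1] = params.mu
        return nu


@dataclass
class ModelMoments:
    """Model-implied observed-trait moments (length 2T / 2T x 2T)."""

    mean: np.ndarray            # observed mean for g = 0
    snp_direction: np.ndarray   # d mean / d(gamma*g): Lam (I-B)^-1 Gamma_unit
    mean_per_allele: np.ndarray  # gamma_snp * snp_direction
    sigma_A: np.ndarray         # additive-genetic observed covariance
    sigma_E: np.ndarray         # environmental + measurement covariance


def model_moments(model: SemModel, params: SemParams) -> ModelMoments:
    """Propagate structural parameters through the reduced form."""
    Lam, B, Gamma, Psi_A, Psi_E, theta_diag = model.matrices(params)
    I = np.eye(model.n_latent)
    try:
        red = np.linalg.solve(I - B, np.eye(model.n_latent))
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError("(I - B) is singular") from exc
    G = Lam @ red  # observed = G @ (nu + Gamma*gamma*g + disturbances) + eps
    mean = G @ model.latent_mean(params)
    direction = G @ Gamma
    sigma_A = G @ Psi_A @ G.T
    sigma_E = G @ Psi_E @ G.T + np.diag(theta_diag)
    return ModelMoments(mean=mean, snp_direction=direction,
                        mean_per_allele=params.gamma_snp * direction,
                        sigma_A=sigma_A, sigma_E=sigma_E)


# --------------------------------------------------------------------------
# family data and likelihood
# --------------------------------------------------------------------------

@dataclass
class FamilyData:
    """Phenotypes and relationship structure for one analyzed family.

    ``y`` is (n_members, 2*n_visits) with NaN for missing observations,
    columns ordered (rSBP_1, rDBP_1, rSBP_2, ...).  ``kin2`` is 2*Phi
    restricted to the analyzed members.  ``g`` optionally holds the
    genotype of a single SNP (used when the SNP path is free).
    """

    family_id: str
    ids: list[str]
    kin2: np.ndarray
    y: np.ndarray
    g: np.ndarray | None = None
    _eig: tuple | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def complete(self) -> bool:
        return not np.isnan(self.y).any()

    def eig(self):
        """Cached eigendecomposition of 2*Phi (d, U)."""
        if self._eig is None:
            d, U = np.linalg.eigh(self.kin2)
            self._eig = (np.clip(d, 0.0, None), U)
        return self._eig


def assemble_families(kinships: dict[str, KinshipMatrix],
                      residuals: pd.DataFrame, n_visits: int) -> list[FamilyData]:
    """Build :class:`FamilyData` from kinships and a wide residual table.

    ``residuals`` is indexed by (FID, IID) with columns rSBP_v{t} and
    rDBP_v{t}.  Individuals missing every observation are dropped (their
    kinship rows are removed); others keep NaNs for per-visit deletion.
    """
    cols = []
    for t in range(1, n_visits + 1):
        cols += [f"rSBP_v{t}", f"rDBP_v{t}"]
    out: list[FamilyData] = []
    for fid, kin in kinships.items():
        rows, keep_idx = [], []
        for k, iid in enumerate(kin.ids):
            try:
                row = residuals.loc[(fid, iid), cols].to_numpy(dtype=float)
            except KeyError:
                continue
            if np.isnan(row).all():
                continue
            rows.append(row)
            keep_idx.append(k)
        if not rows:
            continue
        idx = np.asarray(keep_idx)
        out.append(FamilyData(
            family_id=fid,
            ids=[kin.ids[k] for k in keep_idx],
            kin2=kin.additive[np.ix_(idx, idx)],
            y=np.vstack(rows)))
    return out


def _family_mean(moments: ModelMoments, n: int, g: np.ndarray | None) -> np.ndarray:
    mean = np.tile(moments.mean, (n, 1))
    if g is not None:
        mean += np.outer(np.asarray(g, float), moments.mean_per_allele)
    return mean


def family_loglik(moments: ModelMoments, kin, y: np.ndarray,
                  g: np.ndarray | None = None) -> float:
    """Log density of one family's stacked phenotypes.

    Builds the dense covariance V = 2Phi (x) Sigma_A + I (x) Sigma_E,
    deletes rows/columns for missing observations, and evaluates the
    multivariate-normal log density of the remaining entries.

    ``kin`` is a :class:`KinshipMatrix` or the 2*Phi array directly.
    """
    kin2 = kin.additive if isinstance(kin, KinshipMatrix) else np.asarray(kin, float)
    fid = kin.family_id if isinstance(kin, KinshipMatrix) else "?"
    y = np.atleast_2d(np.asarray(y, float))
    n = y.shape[0]
    mean = _family_mean(moments, n, g)
    resid = (y - mean).ravel()
    mask = ~np.isnan(y.ravel())
    V = np.kron(kin2, moments.sigma_A) + np.kron(np.eye(n), moments.sigma_E)
    V = V[np.ix_(mask, mask)]
    r = resid[mask]
    try:
        c, low = scipy.linalg.cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"family '{fid}': covariance not positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = r @ scipy.linalg.cho_solve((c, low), r)
    return -0.5 * (len(r) * _LOG2PI + logdet + quad)


def _loglik_complete(moments: ModelMoments, fam: FamilyData) -> float:
    """Fast path for complete families using the eigen structure of
    2Phi (x) Sigma_A + I (x) Sigma_E (no dense Kronecker build)."""
    d, U = fam.eig()
    mean = _family_mean(moments, fam.n, fam.g)
    R = U.T @ (fam.y - mean)
    # simultaneous diagonalization of (Sigma_A, Sigma_E)
    w, Q = scipy.linalg.eigh(moments.sigma_A, moments.sigma_E)
    w = np.clip(w, 0.0, None)
    Z = R @ Q
    denom = 1.0 + np.outer(d, w)  # (n, 2T)
    sign, logdet_E = np.linalg.slogdet(moments.sigma_E)
    if sign <= 0:
        raise np.linalg.LinAlgError("Sigma_E not positive definite")
    m = fam.y.size
    return -0.5 * (m * _LOG2PI + fam.n * logdet_E
                   + np.sum(np.log(denom)) + np.sum(Z * Z / denom))


class _CompleteStack:
    """All complete families rotated into the kinship eigenbasis once.

    After rotating each family's (n, 2T) phenotype block by U^T (U from
    2Phi = U diag(d) U^T), the rows become independent with covariance
    d_i*Sigma_A + Sigma_E, so the whole dataset's likelihood is a single
    batched computation per parameter value.
    """

    def __init__(self, families: list[FamilyData]):
        R, u1, d, ug = [], [], [], []
        self.has_g = any(f.g is not None for f in families)
        for fam in families:
            dd, U = fam.eig()
            R.append(U.T @ fam.y)
            u1.append(U.T @ np.ones(fam.n))
            d.append(dd)
            if self.has_g:
                if fam.g is None:
                    raise ValueError("genotype missing for some families")
                ug.append(U.T @ np.asarray(fam.g, float))
        self.R = np.vstack(R)
        self.u1 = np.concatenate(u1)
        self.d = np.concatenate(d)
        self.ug = np.concatenate(ug) if self.has_g else None
        self.n_rows = self.R.shape[0]

    def loglik(self, moments: ModelMoments) -> float:
        resid = self.R - np.outer(self.u1, moments.mean)
        if self.has_g:
            resid -= np.outer(self.ug, moments.mean_per_allele)
        w, Q = scipy.linalg.eigh(moments.sigma_A, moments.sigma_E)
        w = np.clip(w, 0.0, None)
        Z = resid @ Q
        denom = 1.0 + np.outer(self.d, w)
        sign, logdet_E = np.linalg.slogdet(moments.sigma_E)
        if sign <= 0:
            raise np.linalg.LinAlgError("Sigma_E not positive definite")
        return -0.5 * (self.R.size * _LOG2PI + self.n_rows * logdet_E
                       + np.sum(np.log(denom)) + np.sum(Z * Z / denom))


def total_loglik(model: SemModel, params: SemParams,
                 families: list[FamilyData]) -> float:
    """Sum of family log-likelihoods; fast path for complete families."""
    moments = model_moments(model, params)
    total = 0.0
    for fam in families:
        if fam.complete:
            total += _loglik_complete(moments, fam)
        else:
            total += family_loglik(moments, fam.kin2, fam.y, fam.g)
    return total


# --------------------------------------------------------------------------
# parameter transformation (unconstrained optimization scale)
# --------------------------------------------------------------------------

def _chol_to_vec(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, float)
    # nudge to PD for the Cholesky of a boundary start
    L = np.linalg.cholesky(S + 1e-8 * np.eye(2))
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])


def _vec_to_chol(v: np.ndarray) -> np.ndarray:
    L = np.array([[np.exp(v[0]), 0.0], [v[1], np.exp(v[2])]])
    return L @ L.T


class ParamTransform:
    """Bijection between :class:`SemParams` and an unconstrained vector.

    Log scale for variances, atanh for beta_ar, log-diagonal Cholesky for
    the LG 2x2 components; gamma (if free) enters untransformed as the
    last element.
    """

    def __init__(self, model: SemModel, free_gamma: bool = False):
        self.model = model
        self.free_gamma = free_gamma
        if model.kind == "ar":
            names = ["mu1", "lambda_dbp", "beta_ar",
                     "sigma2_a1", "sigma2_a", "sigma2_z1", "sigma2_z",
                     "theta_sbp", "theta_dbp"]
        else:
            names = ["mu_I", "mu_S", "lambda_dbp",
                     "sa_11", "sa_21", "sa_22", "se_11", "se_21", "se_22",
                     "sigma2_v", "theta_sbp", "theta_dbp"]
        if free_gamma:
            names.append("gamma_snp")
        self.names = names

    @property
    def n_params(self) -> int:
        return len(self.names)

    def pack(self, p: SemParams) -> np.ndarray:
        if self.model.kind == "ar":
            x = [p.mu[0], p.lambda_dbp, np.arctanh(p.beta_ar),
                 *np.log(np.maximum([p.sigma2_a[0], p.sigma2_a[1],
                                     p.sigma2_z[0], p.sigma2_z[1]], 1e-12)),
                 np.log(p.theta[0]), np.log(p.theta[1])]
        else:
            x = [p.mu[0], p.mu[1], p.lambda_dbp,
                 *_chol_to_vec(p.sigma2_a), *_chol_to_vec(p.sigma2_z),
                 np.log(max(p.sigma2_v, 1e-12)),
                 np.log(p.theta[0]), np.log(p.theta[1])]
        if self.free_gamma:
            x.append(p.gamma_snp)
        return np.asarray(x, float)

    def unpack(self, x: np.ndarray) -> SemParams:
        x = np.asarray(x, float)
        gamma = x[-1] if self.free_gamma else 0.0
        if self.model.kind == "ar":
            return SemParams(
                kind="ar", mu=(x[0],), lambda_dbp=x[1],
                beta_ar=np.tanh(x[2]),
                sigma2_a=(np.exp(x[3]), np.exp(x[4])),
                sigma2_z=(np.exp(x[5]), np.exp(x[6])),
                theta=(np.exp(x[7]), np.exp(x[8])), gamma_snp=gamma)
        return SemParams(
            kind="lg", mu=(x[0], x[1]), lambda_dbp=x[2],
            sigma2_a=_vec_to_chol(x[3:6]), sigma2_z=_vec_to_chol(x[6:9]),
            sigma2_v=np.exp(x[9]),
            theta=(np.exp(x[10]), np.exp(x[11])), gamma_snp=gamma)

    def natural_vector(self, p: SemParams) -> np.ndarray:
        """Natural-scale parameter vector in ``self.names`` order
        (Cholesky entries reported as the covariance entries)."""
        if self.model.kind == "ar":
            v = [p.mu[0], p.lambda_dbp, p.beta_ar, *p.sigma2_a, *p.sigma2_z,
                 *p.theta]
        else:
            Sa, Se = np.asarray(p.sigma2_a), np.asarray(p.sigma2_z)
            v = [p.mu[0], p.mu[1], p.lambda_dbp,
                 Sa[0, 0], Sa[1, 0], Sa[1, 1], Se[0, 0], Se[1, 0], Se[1, 1],
                 p.sigma2_v, *p.theta]
        if self.free_gamma:
            v.append(p.gamma_snp)
        return np.asarray(v, float)


# --------------------------------------------------------------------------
# maximum-likelihood fitting
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    params: SemParams
    loglik: float
    n_params: int
    converged: bool
    se: np.ndarray | None
    n_obs_used: int
    model: SemModel
    transform: ParamTransform
    x: np.ndarray  # estimate on the transformed scale
    param_names: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        nat = self.transform.natural_vector(self.params)
        out = {"kind": self.model.kind, "loglik": float(self.loglik),
               "converged": bool(self.converged),
               "n_obs_used": int(self.n_obs_used),
               "estimates": {n: float(v) for n, v in zip(self.param_names, nat)}}
        if self.se is not None:
            out["se"] = {n: float(s) for n, s in zip(self.param_names, self.se)}
        return out


def moment_start(model: SemModel, families: list[FamilyData]) -> SemParams:
    """Crude method-of-moments starting values from pooled empirical
    moments (relatedness ignored; only needs to land in the basin)."""
    Y = np.vstack([f.y for f in families])
    mean = np.nanmean(Y, axis=0)
    Yc = Y - mean
    dfY = pd.DataFrame(Yc)
    C = dfY.cov().to_numpy()
    T = model.n_visits
    sbp = [2 * t for t in range(T)]
    dbp = [2 * t + 1 for t in range(T)]
    var_s = np.mean(C[sbp, sbp])
    var_d = np.mean(C[dbp, dbp])
    cov_sd = np.mean([C[2 * t, 2 * t + 1] for t in range(T)])
    # lam from cross-visit ratio cov(D_t, S_t') / cov(S_t, S_t')
    num = den = 0.0
    for t in range(T):
        for u in range(T):
            if t != u:
                num += C[dbp[t], sbp[u]]
                den += C[sbp[t], sbp[u]]
    lam = num / den if abs(den) > 1e-8 and num / den > 0.05 else \
        max(cov_sd, 0.05 * var_s) / var_s
    lam = float(np.clip(lam, 0.1, 3.0))
    var_eta = float(np.clip(cov_sd / lam, 0.1 * var_s, 0.95 * var_s))
    th_s = max(var_s - var_eta, 0.05 * var_s)
    th_d = max(var_d - lam ** 2 * var_eta, 0.05 * var_d)

    if model.kind == "ar":
        if T >= 2:
            lag = np.mean([C[sbp[t], sbp[t + 1]] for t in range(T - 1)])
            beta = float(np.clip(lag / var_eta, -0.9, 0.9))
        else:
            beta = 0.3
        s_rest = max(var_eta * (1 - beta ** 2), 0.05 * var_eta)
        return SemParams(kind="ar", mu=(float(mean[0]),), lambda_dbp=lam,
                         beta_ar=beta,
                         sigma2_a=(0.4 * var_eta, 0.4 * s_rest),
                         sigma2_z=(0.6 * var_eta, 0.6 * s_rest),
                         theta=(th_s, th_d))

    mu_i = float(mean[0])
    mu_s = float(np.mean(np.diff(mean[sbp]))) if T >= 2 else 0.0
    v_i = max(0.5 * var_eta, 0.05 * var_s)
    v_s = max(0.1 * var_eta, 0.01 * var_s)
    Sa = np.array([[0.4 * v_i, 0.0], [0.0, 0.4 * v_s]])
    Se = np.array([[0.6 * v_i, 0.0], [0.0, 0.6 * v_s]])
    return SemParams(kind="lg", mu=(mu_i, mu_s), lambda_dbp=lam,
                     sigma2_a=Sa, sigma2_z=Se, sigma2_v=0.25 * var_eta,
                     theta=(th_s, th_d))


def _neg_loglik_factory(model, families, transform):
    complete = [f for f in families if f.complete]
    partial = [f for f in families if not f.complete]
    stack = _CompleteStack(complete) if complete else None

    def f(x):
        try:
            p = transform.unpack(x)
            moments = model_moments(model, p)
            ll = stack.loglik(moments) if stack is not None else 0.0
            for fam in partial:
                ll += family_loglik(moments, fam.kin2, fam.y, fam.g)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll
    return f


def numerical_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    x = np.asarray(x, float)
    q = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((q, q))
    f0 = f(x)
    for i in range(q):
        for j in range(i, q):
            ei = np.zeros(q); ei[i] = h[i]
            ej = np.zeros(q); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)) / (4 * h[i] * h[j])
    return H


def _jitter(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return x + rng.normal(0.0, 0.3, size=len(x))


def fit_ml(model: SemModel, families: list[FamilyData],
           fix_gamma_zero: bool = True, n_starts: int = 3,
           start: SemParams | None = None, seed: int = 0,
           compute_se: bool = True, maxiter: int = 500) -> FitResult:
    """Fit a SEM by maximum likelihood over all families.

    Quasi-Newton (L-BFGS-B) on the transformed parameter scale from
    ``n_starts`` starting points (a moment-based start, then jittered
    copies); the best optimum is returned.  With ``fix_gamma_zero`` the
    SNP path is fixed at 0 and no genotypes are consumed (the null fit);
    otherwise each family's ``g`` attribute supplies the tested SNP.
    """
    if len(families) < 1:
        raise ValueError("no families to fit")
    transform = ParamTransform(model, free_gamma=not fix_gamma_zero)
    rng = np.random.default_rng(seed)
    nll = _neg_loglik_factory(model, families, transform)

    if start is None:
        start = moment_start(model, families)
    x0 = transform.pack(start)
    if not fix_gamma_zero and len(x0) < transform.n_params:
        x0 = np.append(x0, start.gamma_snp)

    best = None
    any_converged = False
    for s in range(max(1, n_starts)):
        xs = x0 if s == 0 else _jitter(x0, rng)
        res = minimize(nll, xs, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-11,
                                "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError("all optimization starts failed")
    if not any_converged:
        warnings.warn("SEM fit did not formally converge; returning best point")

    params = transform.unpack(best.x)
    n_obs = int(sum(np.sum(~np.isnan(f.y)) for f in families))
    se = None
    if compute_se:
        se = _standard_errors(nll, best.x, transform)
    return FitResult(params=params, loglik=-best.fun,
                     n_params=transform.n_params,
                     converged=any_converged, se=se, n_obs_used=n_obs,
                     model=model, transform=transform, x=best.x,
                     param_names=list(transform.names))


def _standard_errors(nll, x, transform) -> np.ndarray | None:
    """Delta-method SEs of the natural parameters from the observed
    information on the transformed scale."""
    try:
        H = numerical_hessian(nll, x)
        cov_t = np.linalg.pinv(H)
        # Jacobian of natural params wrt transformed params
        q = len(x)
        h = 1e-5 * np.maximum(1.0, np.abs(x))
        J = np.empty((transform.n_params, q))
        for j in range(q):
            e = np.zeros(q); e[j] = h[j]
            hi = transform.natural_vector(transform.unpack(x + e))
            lo = transform.natural_vector(transform.unpack(x - e))
            J[:, j] = (hi - lo) / (2 * h[j])
        var = np.clip(np.diag(J @ cov_t @ J.T), 0.0, None)
        return np.sqrt(var)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
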