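"""Rapid score test for SNP association against a fitted null SEM.

The SNP path gamma enters the model mean only (through the latent
reduced form), so its score at the null ML fit is

    U(g) = sum_f (g_f (x) c)^T V_f^{-1} r_f,

with c the per-allele mean direction, r_f the null residuals and V_f the
null family covariance.  The variance of the efficient score
orthogonalizes against the nuisance parameters nu:

    Var = I_gg - I_gn I_nn^{-1} I_ng,

all blocks evaluated at the null with the expected information (the
nuisance block assembled numerically from moment derivatives).  The
statistic T = U^2 / Var is chi-square with 1 df.  Everything that does
not involve the genotype is precomputed once, so a genome scan touches
only cached per-family factors per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import chi2, spearmanr

from .sem import (FamilyData, FitResult, ModelMoments, ParamTransform,
                  SemModel, fit_ml, model_moments, total_loglik)

CHI2_1_MEDIAN = 0.45494
_LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# null cache
# --------------------------------------------------------------------------

@dataclass
class _FamilyCache:
    family_id: str
    ids: list[str]
    n: int
    obs_dim: int
    logdet: float
    quad: float
    w: np.ndarray   # (n,)   per-member score weights  C^T V^-1 r
    M: np.ndarray   # (n,n)  C^T V^-1 C
    K: np.ndarray   # (n,q)  C^T V^-1 D


@dataclass
class NullFitCache:
    """SNP-independent precomputation for the score scan."""

    model: SemModel
    fit: FitResult
    moments: ModelMoments
    families: list[_FamilyCache]
    I_nn: np.ndarray
    ids: list[tuple[str, str]]  # flat (FID, IID) order genotypes must follow
    slices: list[slice]

    def null_loglik(self) -> float:
        """Recompute the null log-likelihood from cached factors."""
        total = 0.0
        for fc in self.families:
            total += -0.5 * (fc.obs_dim * _LOG2PI + fc.logdet + fc.quad)
        return total

    @property
    def sample_names(self) -> list[str]:
        return [f"{fid}:{iid}" for fid, iid in self.ids]


def _moment_derivatives(model: SemModel, transform: ParamTransform,
                        x0: np.ndarray, step: float = 1e-4):
    """Central-difference derivatives of (mean, Sigma_A, Sigma_E) with
    respect to the transformed nuisance parameters at the null."""
    q = len(x0)
    h = step * np.maximum(1.0, np.abs(x0))
    d_mean, d_A, d_E = [], [], []
    for j in range(q):
        e = np.zeros(q); e[j] = h[j]
        hi = model_moments(model, transform.unpack(x0 + e))
        lo = model_moments(model, transform.unpack(x0 - e))
        d_mean.append((hi.mean - lo.mean) / (2 * h[j]))
        d_A.append((hi.sigma_A - lo.sigma_A) / (2 * h[j]))
        d_E.append((hi.sigma_E - lo.sigma_E) / (2 * h[j]))
    return d_mean, d_A, d_E


def build_null_cache(fit: FitResult, model: SemModel,
                     families: list[FamilyData]) -> NullFitCache:
    """Precompute per-family factors and the nuisance information.

    ``fit`` must be a null fit (gamma fixed at 0).  The expected
    information is used throughout; because the latent intercept's mean
    derivative is exactly the per-allele direction, the efficient score
    is invariant to allele-label flips and exactly zero for constant
    genotypes.
    """
    if fit.transform.free_gamma:
        raise ValueError("cache requires a null fit with gamma fixed at 0")
    moments = model_moments(model, fit.params)
    c = moments.snp_direction  # length 2T
    d_mean, d_A, d_E = _moment_derivatives(model, fit.transform, fit.x)
    q = len(d_mean)

    caches: list[_FamilyCache] = []
    ids: list[tuple[str, str]] = []
    slices: list[slice] = []
    I_nn = np.zeros((q, q))
    pos = 0
    for fam in families:
        n = fam.n
        y = fam.y
        mask2d = ~np.isnan(y)
        mask = mask2d.ravel()
        obs_dim = int(mask.sum())
        V = (np.kron(fam.kin2, moments.sigma_A)
             + np.kron(np.eye(n), moments.sigma_E))[np.ix_(mask, mask)]
        try:
            cfac = scipy.linalg.cho_factor(V, lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"family '{fam.family_id}': null covariance not positive "
                f"definite") from exc
        logdet = 2.0 * np.sum(np.log(np.diag(cfac[0])))
        resid = (y - np.tile(moments.mean, (n, 1))).ravel()[mask]
        vr = scipy.linalg.cho_solve(cfac, resid)

        # C: column per member, the per-allele direction on observed rows
        C = np.zeros((obs_dim, n))
        row_of = np.cumsum(mask) - 1
        for i in range(n):
            for t in range(y.shape[1]):
                if mask2d[i, t]:
                    C[row_of[i * y.shape[1] + t], i] = c[t]
        ViC = scipy.linalg.cho_solve(cfac, C)

        # D: mean derivatives per nuisance parameter on observed rows
        D = np.zeros((obs_dim, q))
        for j in range(q):
            D[:, j] = np.tile(d_mean[j], (n, 1)).ravel()[mask]
        ViD = scipy.linalg.cho_solve(cfac, D)

        # expected nuisance information: mean part + trace part
        I_nn += D.T @ ViD
        W = []
        for j in range(q):
            dV = (np.kron(fam.kin2, d_A[j])
                  + np.kron(np.eye(n), d_E[j]))[np.ix_(mask, mask)]
            W.append(scipy.linalg.cho_solve(cfac, dV))
        for j in range(q):
            for k in range(j, q):
                tr = 0.5 * np.sum(W[j] * W[k].T)
                I_nn[j, k] += tr
                if k != j:
                    I_nn[k, j] += tr

        caches.append(_FamilyCache(
            family_id=fam.family_id, ids=list(fam.ids), n=n,
            obs_dim=obs_dim, logdet=float(logdet),
            quad=float(resid @ vr),
            w=C.T @ vr, M=C.T @ ViC, K=C.T @ ViD))
        ids += [(fam.family_id, iid) for iid in fam.ids]
        slices.append(slice(pos, pos + n))
        pos += n

    return NullFitCache(model=model, fit=fit, moments=moments,
                        families=caches, I_nn=I_nn, ids=ids, slices=slices)


# --------------------------------------------------------------------------
# per-SNP test
# --------------------------------------------------------------------------

STATUS_OK = "ok"
STATUS_MONOMORPHIC = "skipped_monomorphic"
STATUS_MISSING = "skipped_missing"
STATUS_FAILED = "failed"


@dataclass
class SnpResult:
    snp_id: str
    chrom: str = "."
    pos: int = 0
    maf: float = float("nan")
    n_used: int = 0
    score_stat: float = float("nan")
    p_value: float = float("nan")
    status: str = STATUS_OK


def score_test(cache: NullFitCache, g: np.ndarray,
               snp_id: str = "", chrom: str = ".", pos: int = 0,
               max_missing: float = 0.5) -> SnpResult:
    """Score test of one SNP; ``g`` is the 0/1/2 dosage vector aligned
    to ``cache.ids`` (NaN or negative = missing, mean-imputed)."""
    g = np.asarray(g, float).copy()
    g[g < 0] = np.nan
    obs = ~np.isnan(g)
    n_obs = int(obs.sum())
    res = SnpResult(snp_id=snp_id, chrom=chrom, pos=pos, n_used=n_obs)
    if n_obs == 0 or (len(g) - n_obs) / len(g) > max_missing:
        res.status = STATUS_MISSING
        return res
    freq = float(np.mean(g[obs])) / 2.0
    res.maf = min(freq, 1.0 - freq)
    if np.nanvar(g) == 0.0:
        res.status = STATUS_MONOMORPHIC
        return res
    g[~obs] = 2.0 * freq  # mean imputation keeps cached factors valid
    # center: the constant direction coincides with the latent-intercept
    # mean derivative, so it carries zero efficient information; removing
    # it makes allele-label flips (g -> 2-g) exact sign flips of U
    g -= 2.0 * freq

    U = 0.0
    I_gg = 0.0
    I_gn = np.zeros(cache.I_nn.shape[0])
    for fc, sl in zip(cache.families, cache.slices):
        gf = g[sl]
        U += gf @ fc.w
        I_gg += gf @ fc.M @ gf
        I_gn += gf @ fc.K
    try:
        var = I_gg - I_gn @ np.linalg.solve(cache.I_nn, I_gn)
    except np.linalg.LinAlgError:
        var = I_gg - I_gn @ np.linalg.pinv(cache.I_nn) @ I_gn
    if not np.isfinite(var) or var <= 1e-10 * max(I_gg, 1.0):
        res.status = STATUS_FAILED
        return res
    stat = U * U / var
    if not np.isfinite(stat):
        res.status = STATUS_FAILED
        return res
    res.score_stat = float(stat)
    res.p_value = float(chi2.sf(stat, 1))
    return res


# --------------------------------------------------------------------------
# genome scan
# --------------------------------------------------------------------------

@dataclass
class ScanSummary:
    model_label: str
    n_tested: int
    lambda_gc: float
    qq_expected: np.ndarray
    qq_observed: np.ndarray
    suggestive_hits: list[SnpResult] = field(default_factory=list)
    n_dropped_individuals: int = 0


def genomic_inflation(stats: np.ndarray) -> float:
    """Median association chi-square over the null chi2_1 median."""
    stats = np.asarray(stats, float)
    stats = stats[np.isfinite(stats)]
    if len(stats) == 0:
        raise ValueError("no statistics to summarize")
    return float(np.median(stats) / CHI2_1_MEDIAN)


def qq_coordinates(p_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 P, both sorted ascending."""
    p = np.sort(np.asarray(p_values, float))
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)[::-1]
    observed = -np.log10(np.clip(p, 1e-300, 1.0))[::-1]
    return expected, observed


def gwas_scan(cache: NullFitCache, genotypes: pd.DataFrame,
              threshold: float = 1e-5, model_label: str = "",
              snp_meta: pd.DataFrame | None = None
              ) -> tuple[ScanSummary, pd.DataFrame]:
    """Stream SNP columns through :func:`score_test`.

    ``genotypes``: rows indexed "FID:IID", one column per SNP.  Rows are
    aligned to the cache's analyzed individuals; genotyped individuals
    without phenotypes are dropped, phenotyped ones without genotypes
    become missing (imputed per SNP).  ``snp_meta`` may carry ``chrom``
    and ``pos`` indexed by SNP id.
    """
    names = cache.sample_names
    aligned = genotypes.reindex(names)
    n_dropped = len(genotypes.index.difference(names))
    G = aligned.to_numpy(dtype=float)

    results = []
    for j, snp in enumerate(aligned.columns):
        chrom_, pos_ = ".", 0
        if snp_meta is not None and snp in snp_meta.index:
            chrom_ = str(snp_meta.loc[snp, "chrom"])
            pos_ = int(snp_meta.loc[snp, "pos"])
        results.append(score_test(cache, G[:, j], snp_id=str(snp),
                                  chrom=chrom_, pos=pos_))
    table = pd.DataFrame([vars(r) for r in results])
    ok = table[table["status"] == STATUS_OK]
    if len(ok) == 0:
        raise ValueError("no SNP produced a valid score test")
    lam = genomic_inflation(ok["score_stat"].to_numpy())
    exp_q, obs_q = qq_coordinates(ok["p_value"].to_numpy())
    hits = [r for r in results
            if r.status == STATUS_OK and r.p_value < threshold]
    hits.sort(key=lambda r: r.p_value)
    summary = ScanSummary(model_label=model_label, n_tested=len(ok),
                          lambda_gc=lam, qq_expected=exp_q,
                          qq_observed=obs_q, suggestive_hits=hits,
                          n_dropped_individuals=int(n_dropped))
    return summary, table


def qq_plot(summary: ScanSummary, path) -> None:
    """Write a Q-Q plot of observed vs expected -log10 P."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(summary.qq_expected, summary.qq_observed, s=6, alpha=0.6)
    lim = max(summary.qq_expected.max(), summary.qq_observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    ax.set_xlabel("expected $-\\log_{10} P$")
    ax.set_ylabel("observed $-\\log_{10} P$")
    ax.set_title(f"{summary.model_label} "
                 f"($\\lambda_{{GC}}$ = {summary.lambda_gc:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# oracles and model comparison
# --------------------------------------------------------------------------

def refit_chisq(model: SemModel, families: list[FamilyData],
                null_fit: FitResult, g: np.ndarray,
                slices: list[slice] | None = None) -> float:
    """Likelihood-ratio chi-square from refitting with the SNP path free
    (the slow per-SNP oracle the score test approximates)."""
    if slices is None:
        pos, slices = 0, []
        for fam in families:
            slices.append(slice(pos, pos + fam.n))
            pos += fam.n
    for fam, sl in zip(families, slices):
        fam.g = np.asarray(g, float)[sl]
    try:
        start = null_fit.params
        fit1 = fit_ml(model, families, fix_gamma_zero=False, n_starts=1,
                      start=start, compute_se=False)
        ll0 = null_fit.loglik
        return max(0.0, 2.0 * (fit1.loglik - ll0))
    finally:
        for fam in families:
            fam.g = None


@dataclass
class ModelComparison:
    rank_correlation: float
    n_common: int
    overlap_hits: int
    hits_a: int
    hits_b: int
    shared_hit_ids: list[str]
    merged: pd.DataFrame


def compare_models(results_a: pd.DataFrame, results_b: pd.DataFrame,
                   threshold: float = 1e-5,
                   labels: tuple[str, str] = ("ar", "lg")) -> ModelComparison:
    """Spearman correlation of P values and overlap of suggestive hits
    between two scans of the same SNP universe."""
    a, b = labels
    m = results_a.merge(results_b, on="snp_id", suffixes=(f"_{a}", f"_{b}"))
    if len(m) == 0:
        raise ValueError("the two result tables share no SNPs")
    ok = m[(m[f"status_{a}"] == STATUS_OK) & (m[f"status_{b}"] == STATUS_OK)]
    rho = float(spearmanr(ok[f"p_value_{a}"], ok[f"p_value_{b}"]).statistic)
    hits_a = set(ok.loc[ok[f"p_value_{a}"] < threshold, "snp_id"])
    hits_b = set(ok.loc[ok[f"p_value_{b}"] < threshold, "snp_id"])
    shared = sorted(hits_a & hits_b)
    return ModelComparison(rank_correlation=rho, n_common=len(ok),
                           overlap_hits=len(shared), hits_a=len(hits_a),
                           hits_b=len(hits_b), shared_hit_ids=shared,
                           merged=m)
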