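"""Synthetic pedigrees, gene-dropped genotypes and longitudinal BP traits.

Emulates the structure of a multi-generation family blood-pressure study:
~20 pedigrees of a few dozen members, three visits of correlated SBP/DBP,
polygenic familial resemblance, age/sex/smoking covariate effects, and
antihypertensive treatment that lowers the observed BP of a subset.  The
latent trajectories are generated exactly under the AR or latent-growth
SEM of :mod:`pedsem.sem`, so downstream fits are parameter-recovery
exercises with known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import (FEMALE, MALE, Individual, KinshipMatrix, Pedigree,
                       kinship_matrix, parse_pedigree, write_linkage)
from .sem import SemModel, SemParams, ar_params, lg_params

DEFAULT_COVARIATE_EFFECTS = {
    "SBP": {"intercept": 120.0, "age": 0.5, "sex": 3.0, "smoke": 4.0},
    "DBP": {"intercept": 75.0, "age": 0.25, "sex": 1.5, "smoke": 2.0},
}


@dataclass
class SimulationConfig:
    """Study-design knobs for one simulated cohort.

    Defaults describe a modest test cohort; :func:`full_scale_config`
    returns the configuration matching a 20-family study with families
    of 27-107 members.  ``sex`` enters covariates as 1=male, 0=female;
    age increases by ``visit_gap_years`` between visits.
    """

    n_families: int = 20
    family_template: str = "three_generation"  # or a pedigree file path
    n_snps: int = 1000
    maf_range: tuple = (0.05, 0.5)
    n_visits: int = 3
    model: str = "ar"
    true_params: SemParams | None = None
    covariate_effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_COVARIATE_EFFECTS.items()})
    treatment_rule: dict = field(
        default_factory=lambda: {"threshold": 140.0, "probability": 0.7})
    treatment_effect_mean: float = 12.0
    treatment_effect_sd: float = 4.0
    treatment_effect_dbp_scale: float = 0.5
    missing_visit_rate: object = 0.0  # scalar or per-visit sequence
    smoking_rate: float = 0.3
    visit_gap_years: float = 5.0
    n_children_range: tuple = (2, 5)
    n_grandchildren_range: tuple = (1, 4)
    family_size_range: tuple | None = None
    causal_snps: dict = field(default_factory=dict)  # snp index -> gamma
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        if not (0 <= self.treatment_rule["probability"] <= 1):
            raise ValueError("treatment probability must be in [0, 1]")
        if self.true_params is None:
            self.true_params = ar_params() if self.model == "ar" else lg_params()
        if self.true_params.kind != self.model:
            raise ValueError(
                f"true_params kind '{self.true_params.kind}' does not match "
                f"model '{self.model}'")

    def visit_missing_rates(self) -> np.ndarray:
        r = np.asarray(self.missing_visit_rate, dtype=float)
        if r.ndim == 0:
            r = np.full(self.n_visits, float(r))
        if len(r) != self.n_visits or (r < 0).any() or (r > 1).any():
            raise ValueError("missing_visit_rate must be in [0,1] per visit")
        return r


def full_scale_config(**overrides) -> SimulationConfig:
    """20 three-generation families of 27-107 members, 3 visits."""
    kw = dict(n_families=20, n_children_range=(4, 10),
              n_grandchildren_range=(2, 8), family_size_range=(27, 107))
    kw.update(overrides)
    return SimulationConfig(**kw)


# --------------------------------------------------------------------------
# pedigrees
# --------------------------------------------------------------------------

def _one_three_generation(fid: str, rng: np.random.Generator,
                          config: SimulationConfig) -> Pedigree:
    inds: list[Individual] = []
    gen: dict[str, int] = {}

    def add(iid, pat, mat, sex, g):
        inds.append(Individual(fid, iid, pat, mat, sex))
        gen[iid] = g

    add("1", None, None, MALE, 0)
    add("2", None, None, FEMALE, 0)
    nxt = 3
    c_lo, c_hi = config.n_children_range
    g_lo, g_hi = config.n_grandchildren_range
    for _ in range(int(rng.integers(c_lo, c_hi + 1))):
        child = str(nxt); nxt += 1
        child_sex = MALE if rng.random() < 0.5 else FEMALE
        add(child, "1", "2", child_sex, 1)
        spouse = str(nxt); nxt += 1
        spouse_sex = FEMALE if child_sex == MALE else MALE
        add(spouse, None, None, spouse_sex, 1)
        pat, mat = (child, spouse) if child_sex == MALE else (spouse, child)
        for _ in range(int(rng.integers(g_lo, g_hi + 1))):
            add(str(nxt), pat, mat, MALE if rng.random() < 0.5 else FEMALE, 2)
            nxt += 1
    ped = Pedigree(fid, inds)
    ped.generation = {iid: gen[iid] for iid in ped.ids}  # type: ignore[attr-defined]
    return ped


def simulate_pedigrees(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> list[Pedigree]:
    """Generate family structures; deterministic given the config seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.family_template != "three_generation":
        return parse_pedigree(config.family_template)
    peds = []
    for f in range(config.n_families):
        fid = f"fam{f + 1}"
        for _ in range(200):
            ped = _one_three_generation(fid, rng, config)
            if config.family_size_range is None:
                break
            lo, hi = config.family_size_range
            if lo <= len(ped) <= hi:
                break
        peds.append(ped)
    return peds


def _generations(ped: Pedigree) -> dict[str, int]:
    """Generation index per member (spouses aligned with their partner)."""
    if hasattr(ped, "generation"):
        return ped.generation  # type: ignore[attr-defined]
    depth = {}
    for ind in ped.individuals:
        if ind.is_founder:
            depth[ind.individual_id] = 0
        else:
            depth[ind.individual_id] = max(depth[ind.father_id],
                                           depth[ind.mother_id]) + 1
    # align married-in founders with their partner's generation
    for ind in ped.individuals:
        if not ind.is_founder:
            d = depth[ind.individual_id] - 1
            depth[ind.father_id] = max(depth[ind.father_id], d)
            depth[ind.mother_id] = max(depth[ind.mother_id], d)
    return depth


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def gene_drop(peds: list[Pedigree], n_snps: int, mafs: np.ndarray,
              rng: np.random.Generator) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Drop unlinked SNP alleles through the pedigrees.

    Founders draw each allele Bernoulli(maf); a child inherits one
    uniformly chosen allele from each parent, which for unlinked loci is
    a Bernoulli(g_parent/2) minor-allele transmission.  Returns the
    (individuals x SNPs) minor-allele-count matrix and the (FID, IID)
    row order.
    """
    mafs = np.asarray(mafs, float)
    if len(mafs) != n_snps or (mafs < 0).any() or (mafs > 0.5).any():
        raise ValueError("mafs must have length n_snps and lie in [0, 0.5]")
    ids: list[tuple[str, str]] = []
    rows: dict[tuple[str, str], np.ndarray] = {}
    for ped in peds:
        for ind in ped.individuals:
            key = (ped.family_id, ind.individual_id)
            if ind.is_founder:
                g = rng.binomial(1, mafs) + rng.binomial(1, mafs)
            else:
                gf = rows[(ped.family_id, ind.father_id)]
                gm = rows[(ped.family_id, ind.mother_id)]
                g = rng.binomial(1, gf / 2.0) + rng.binomial(1, gm / 2.0)
            rows[key] = g.astype(np.int8)
            ids.append(key)
    geno = np.vstack([rows[k] for k in ids])
    return geno, ids


def simulate_polygenic(kin: KinshipMatrix, sigma2_a,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw additive-genetic values with covariance 2Phi * sigma2_a.

    ``sigma2_a`` may be a scalar (returns shape (n,)) or a k x k matrix
    (returns shape (n, k) with covariance 2Phi (x) sigma2_a).
    """
    kin2 = kin.additive
    d, U = np.linalg.eigh(kin2)
    if d.min() < -1e-8:
        raise ValueError(f"2*Phi for family '{kin.family_id}' is not PSD")
    L = U * np.sqrt(np.clip(d, 0.0, None))
    n = kin2.shape[0]
    S = np.atleast_2d(np.asarray(sigma2_a, float))
    if S.shape == (1, 1):
        return np.sqrt(S[0, 0]) * (L @ rng.standard_normal(n))
    w, V = np.linalg.eigh(S)
    Ls = V * np.sqrt(np.clip(w, 0.0, None))
    return L @ rng.standard_normal((n, S.shape[0])) @ Ls.T


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Everything the generator knows that an analyst would not."""

    model: str
    params: SemParams
    ids: list[tuple[str, str]]
    latents: np.ndarray        # (N, T) latent BP trajectories
    polygenic: np.ndarray      # (N, T) for AR; (N, 2) (I,S) parts for LG
    true_sbp: np.ndarray       # (N, T) untreated BP
    true_dbp: np.ndarray
    treated: np.ndarray        # (N, T) 0/1
    treatment_effect: np.ndarray  # (N,)
    mafs: np.ndarray
    causal_snps: dict

    def to_json(self, path) -> None:
        p = asdict(self)
        p["params"] = _params_to_jsonable(self.params)
        for k in ("latents", "polygenic", "true_sbp", "true_dbp",
                  "treated", "treatment_effect", "mafs"):
            p[k] = np.asarray(p[k]).tolist()
        p["ids"] = [list(t) for t in self.ids]
        p["causal_snps"] = {str(k): v for k, v in self.causal_snps.items()}
        Path(path).write_text(json.dumps(p))

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        p = json.loads(Path(path).read_text())
        p["params"] = _params_from_jsonable(p["params"])
        for k in ("latents", "polygenic", "true_sbp", "true_dbp",
                  "treated", "treatment_effect", "mafs"):
            p[k] = np.asarray(p[k])
        p["ids"] = [tuple(t) for t in p["ids"]]
        p["causal_snps"] = {int(k): v for k, v in p["causal_snps"].items()}
        return cls(**p)


def _params_to_jsonable(p: SemParams) -> dict:
    d = asdict(p)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
        elif isinstance(v, tuple):
            d[k] = list(v)
    return d


def _params_from_jsonable(d: dict) -> SemParams:
    d = dict(d)
    if d["kind"] == "lg":
        d["sigma2_a"] = np.asarray(d["sigma2_a"])
        d["sigma2_z"] = np.asarray(d["sigma2_z"])
    else:
        d["sigma2_a"] = tuple(d["sigma2_a"])
        d["sigma2_z"] = tuple(d["sigma2_z"])
    d["mu"] = tuple(d["mu"])
    d["theta"] = tuple(d["theta"])
    if d.get("growth_loadings") is not None:
        d["growth_loadings"] = np.asarray(d["growth_loadings"])
    return SemParams(**d)


def _latent_trajectories(ped: Pedigree, kin: KinshipMatrix, params: SemParams,
                         snp_term: np.ndarray, n_visits: int,
                         rng: np.random.Generator):
    """Latents and their polygenic parts for one family, generated from
    the structural equations themselves."""
    n = len(ped)
    T = n_visits
    eta = np.zeros((n, T))
    if params.kind == "ar":
        poly = np.zeros((n, T))
        for t in range(T):
            s2a = params.sigma2_a[0] if t == 0 else params.sigma2_a[1]
            s2z = params.sigma2_z[0] if t == 0 else params.sigma2_z[1]
            a = simulate_polygenic(kin, s2a, rng) if s2a > 0 else np.zeros(n)
            e = rng.normal(0.0, np.sqrt(s2z), n) if s2z > 0 else np.zeros(n)
            poly[:, t] = a
            zeta = a + e
            if t == 0:
                eta[:, 0] = params.mu[0] + snp_term + zeta
            else:
                eta[:, t] = params.beta_ar * eta[:, t - 1] + zeta
        return eta, poly
    # lg
    A = simulate_polygenic(kin, params.sigma2_a, rng)
    w, V = np.linalg.eigh(np.asarray(params.sigma2_z, float))
    E = rng.standard_normal((n, 2)) @ (V * np.sqrt(np.clip(w, 0, None))).T
    I_lat = params.mu[0] + snp_term + A[:, 0] + E[:, 0]
    S_lat = params.mu[1] + A[:, 1] + E[:, 1]
    loads = (params.growth_loadings if params.growth_loadings is not None
             else np.arange(T, dtype=float))
    for t in range(T):
        v = rng.normal(0.0, np.sqrt(params.sigma2_v), n) \
            if params.sigma2_v > 0 else np.zeros(n)
        eta[:, t] = I_lat + loads[t] * S_lat + v
    return eta, A


def simulate_phenotypes(peds: list[Pedigree], genotypes: np.ndarray,
                        geno_ids: list[tuple[str, str]],
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, SimTruth]:
    """Generate the longitudinal phenotype table and the ground truth.

    Observed BP at each visit = latent measurement model + covariate
    effects + measurement error; treated visits are lowered by a
    per-individual treatment effect; visits are then deleted at the
    configured missingness rates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    params = config.true_params
    T = config.n_visits
    row_of = {k: i for i, k in enumerate(geno_ids)}

    ids: list[tuple[str, str]] = []
    lat_all, poly_all = [], []
    sbp_all, dbp_all = [], []
    age_all, sex_all, smoke_all = [], [], []
    for ped in peds:
        kin = kinship_matrix(ped)
        n = len(ped)
        snp_term = np.zeros(n)
        for j, gamma in config.causal_snps.items():
            gcol = np.array([genotypes[row_of[(ped.family_id, iid)], j]
                             for iid in ped.ids], float)
            snp_term += gamma * gcol
        eta, poly = _latent_trajectories(ped, kin, params, snp_term, T, rng)
        th_s, th_d = params.theta
        sbp = eta + rng.normal(0, np.sqrt(th_s), (n, T))
        dbp = params.lambda_dbp * eta + rng.normal(0, np.sqrt(th_d), (n, T))

        gens = _generations(ped)
        base_age = {0: 62.0, 1: 38.0, 2: 16.0}
        age0 = np.array([base_age.get(gens[iid], 16.0) + rng.uniform(-4, 4)
                         for iid in ped.ids])
        sex = np.array([1.0 if ind.sex == MALE else 0.0
                        for ind in ped.individuals])
        smoke = (rng.random(n) < config.smoking_rate).astype(float)
        ages = age0[:, None] + config.visit_gap_years * np.arange(T)[None, :]

        ce = config.covariate_effects
        cov_s = (ce["SBP"]["intercept"] + ce["SBP"]["age"] * ages
                 + ce["SBP"]["sex"] * sex[:, None]
                 + ce["SBP"]["smoke"] * smoke[:, None])
        cov_d = (ce["DBP"]["intercept"] + ce["DBP"]["age"] * ages
                 + ce["DBP"]["sex"] * sex[:, None]
                 + ce["DBP"]["smoke"] * smoke[:, None])
        sbp += cov_s
        dbp += cov_d

        ids += [(ped.family_id, iid) for iid in ped.ids]
        lat_all.append(eta); poly_all.append(poly)
        sbp_all.append(sbp); dbp_all.append(dbp)
        age_all.append(ages); sex_all.append(sex); smoke_all.append(smoke)

    lat = np.vstack(lat_all)
    poly = np.vstack(poly_all)
    true_sbp = np.vstack(sbp_all)
    true_dbp = np.vstack(dbp_all)
    ages = np.vstack(age_all)
    sex = np.concatenate(sex_all)
    smoke = np.concatenate(smoke_all)
    N = len(ids)

    # treatment: individuals inclined to treat (Bernoulli) are treated at
    # visits where their true untreated SBP exceeds the threshold
    rule = config.treatment_rule
    inclined = rng.random(N) < rule["probability"]
    treated = (true_sbp > rule["threshold"]) & inclined[:, None]
    effect = np.clip(rng.normal(config.treatment_effect_mean,
                                config.treatment_effect_sd, N), 0.0, None)
    obs_sbp = true_sbp - treated * effect[:, None]
    obs_dbp = true_dbp - treated * (config.treatment_effect_dbp_scale
                                    * effect[:, None])

    miss = config.visit_missing_rates()
    keep = rng.random((N, T)) >= miss[None, :]

    rows = []
    for i, (fid, iid) in enumerate(ids):
        for t in range(T):
            if not keep[i, t]:
                continue
            rows.append({
                "FID": fid, "IID": iid, "visit": t + 1,
                "SBP": obs_sbp[i, t], "DBP": obs_dbp[i, t],
                "age": ages[i, t], "sex": sex[i], "smoke": smoke[i],
                "treated": int(treated[i, t])})
    phenos = pd.DataFrame(rows)

    truth = SimTruth(model=config.model, params=params, ids=ids,
                     latents=lat, polygenic=poly, true_sbp=true_sbp,
                     true_dbp=true_dbp, treated=treated.astype(np.int8),
                     treatment_effect=effect,
                     mafs=np.array([]), causal_snps=dict(config.causal_snps))
    return phenos, truth


def simulate_dataset(config: SimulationConfig):
    """Full cohort: pedigrees, genotypes, phenotypes, truth.

    Returns (peds, genotypes, geno_ids, mafs, phenotypes, truth); all
    randomness derives from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    r_ped, r_geno, r_pheno = [np.random.default_rng(s) for s in ss.spawn(3)]
    peds = simulate_pedigrees(config, r_ped)
    mafs = r_geno.uniform(*config.maf_range, config.n_snps)
    geno, geno_ids = gene_drop(peds, config.n_snps, mafs, r_geno)
    phenos, truth = simulate_phenotypes(peds, geno, geno_ids, config, r_pheno)
    truth.mafs = mafs
    return peds, geno, geno_ids, mafs, phenos, truth


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

def write_dataset(outdir, peds, genotypes, geno_ids, phenotypes,
                  mafs=None, truth: SimTruth | None = None,
                  snp_ids: list[str] | None = None) -> dict:
    """Emit pedigree (LINKAGE), phenotype CSV, dosage TSV, minimal VCF
    and (optionally) the truth JSON; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_snps = genotypes.shape[1]
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(n_snps)]

    paths = {"pedigree": outdir / "pedigree.ped",
             "phenotypes": outdir / "phenotypes.csv",
             "dosage": outdir / "genotypes.tsv",
             "vcf": outdir / "genotypes.vcf"}
    write_linkage(paths["pedigree"], peds)
    phenotypes.to_csv(paths["phenotypes"], index=False)

    sample_names = [f"{fid}:{iid}" for fid, iid in geno_ids]
    dose = pd.DataFrame(genotypes, index=sample_names, columns=snp_ids)
    dose.index.name = "individual"
    dose.to_csv(paths["dosage"], sep="\t")

    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for j in range(n_snps):
            gts = "\t".join(gt_code[int(g)] for g in genotypes[:, j])
            fh.write(f"1\t{j + 1}\t{snp_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")

    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def read_dosage(path) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Read a dosage TSV (rows FID:IID, columns SNP ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [tuple(s.split(":", 1)) for s in df.index]
    return df, ids


def read_vcf(path) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Read GT dosages (0/1/2, -1 missing) from a VCF via cyvcf2."""
    from cyvcf2 import VCF
    vcf = VCF(str(path), gts012=True)
    samples = vcf.samples
    cols, names = [], []
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=np.int16)
        gt[gt == 3] = -1  # UNKNOWN under gts012
        cols.append(gt)
        names.append(var.ID or f"{var.CHROM}:{var.POS}")
    geno = np.column_stack(cols) if cols else np.empty((len(samples), 0), int)
    df = pd.DataFrame(geno, index=samples, columns=names)
    ids = [tuple(s.split(":", 1)) for s in samples]
    return df, ids


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"FID": str, "IID": str})


def pivot_wide(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long phenotype table to the wide residual-column layout
    (rSBP_v{t}, rDBP_v{t}) without any adjustment — for cohorts simulated
    directly on the residual scale (no covariates, no treatment)."""
    wide = phenotypes.pivot_table(index=["FID", "IID"], columns="visit",
                                  values=["SBP", "DBP"])
    out = pd.DataFrame(index=wide.index)
    for t in sorted(phenotypes["visit"].unique()):
        out[f"rSBP_v{t}"] = wide[("SBP", t)]
        out[f"rDBP_v{t}"] = wide[("DBP", t)]
    return out
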