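import numpy as np
import pandas as pd
import pytest

from pedsem.pedigree import Individual, Pedigree, kinship_matrix
from pedsem.sem import assemble_families
from pedsem.simulate import SimulationConfig, pivot_wide, simulate_dataset

NO_COVARIATES = {"SBP": {"intercept": 0, "age": 0, "sex": 0, "smoke": 0},
                 "DBP": {"intercept": 0, "age": 0, "sex": 0, "smoke": 0}}
NO_TREATMENT = {"threshold": 1e9, "probability": 0.0}


def residual_scale_config(**kw) -> SimulationConfig:
    """Cohort simulated directly on the residual scale (no covariate
    effects, no treatment), so SBP/DBP columns are already the SEM input."""
    kw.setdefault("covariate_effects",
                  {k: dict(v) for k, v in NO_COVARIATES.items()})
    kw.setdefault("treatment_rule", dict(NO_TREATMENT))
    return SimulationConfig(**kw)


def families_from(phenos, peds, n_visits=3):
    kins = {p.family_id: kinship_matrix(p) for p in peds}
    return assemble_families(kins, pivot_wide(phenos), n_visits)


@pytest.fixture
def trio_pedigree():
    inds = [Individual("f1", "F", None, None, "male"),
            Individual("f1", "M", None, None, "female"),
            Individual("f1", "C", "F", "M", "female")]
    return Pedigree("f1", inds)


@pytest.fixture
def trio_file(tmp_path):
    p = tmp_path / "trio.ped"
    p.write_text("f1 F 0 0 1\nf1 M 0 0 2\nf1 C F M 2\n")
    return p


@pytest.fixture(scope="session")
def small_ar_dataset():
    """Residual-scale AR cohort shared across tests (read-only)."""
    cfg = residual_scale_config(seed=101, n_families=12, n_snps=100,
                                model="ar", n_children_range=(2, 4),
                                n_grandchildren_range=(1, 3))
    peds, geno, gids, mafs, phenos, truth = simulate_dataset(cfg)
    fams = families_from(phenos, peds)
    return dict(cfg=cfg, peds=peds, geno=geno, gids=gids, mafs=mafs,
                phenos=phenos, truth=truth, families=fams)
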