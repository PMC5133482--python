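"""Pedigree parsing, validation and additive-relationship (kinship) matrices.

A pedigree is a directed acyclic graph of parent-offspring links within one
family.  The kinship coefficient phi_ij is the probability that one allele
drawn at random from individual i and one from j are identical by descent;
the polygenic covariance between relatives is 2*phi_ij*sigma2_a, which is
why every likelihood downstream consumes 2*Phi.

Founders are assumed non-inbred and mutually unrelated (phi_ii = 0.5,
phi_ij = 0 between founders), the standard assumption for family studies
where founder genealogy is unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN,
              "m": MALE, "f": FEMALE, "male": MALE, "female": FEMALE,
              "unknown": UNKNOWN, "": UNKNOWN, "na": UNKNOWN}

#: parent codes that mean "unknown"
_NULL_PARENT = {"0", "", "na", "nan", "none", "."}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigree input."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are either both ``None`` (founder) or both
    set and resolvable within the same family.
    """

    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str = UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """One family, individuals stored ancestors-before-descendants."""

    family_id: str
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.individuals = _toposort(self.family_id, self.individuals)
        self._index = {ind.individual_id: k for k, ind in enumerate(self.individuals)}

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    def index_of(self, individual_id: str) -> int:
        return self._index[individual_id]

    def parents_of(self, individual_id: str) -> tuple[str | None, str | None]:
        ind = self.individuals[self._index[individual_id]]
        return ind.father_id, ind.mother_id

    @property
    def founders(self) -> list[str]:
        return [i.individual_id for i in self.individuals if i.is_founder]


@dataclass
class KinshipMatrix:
    """Kinship coefficients phi_ij for one family, in pedigree order."""

    family_id: str
    ids: list[str]
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (len(self.ids), len(self.ids)):
            raise ValueError("phi shape does not match ids")

    @property
    def additive(self) -> np.ndarray:
        """The numerator relationship matrix 2*Phi (PSD)."""
        return 2.0 * self.phi


def _toposort(family_id: str, individuals: list[Individual]) -> list[Individual]:
    """Order ancestors before descendants; raise on cycles / duplicates."""
    by_id: dict[str, Individual] = {}
    for ind in individuals:
        if ind.individual_id in by_id:
            raise PedigreeError(
                f"duplicate individual '{ind.individual_id}' in family '{family_id}'")
        by_id[ind.individual_id] = ind

    order: list[Individual] = []
    state: dict[str, int] = {}  # 0=visiting, 1=done

    for start in by_id:
        if start in state:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        while stack:
            iid, phase = stack.pop()
            if phase == 0:
                if state.get(iid) == 1:
                    continue
                if state.get(iid) == 0:
                    raise PedigreeError(
                        f"pedigree cycle involving '{iid}' in family '{family_id}'")
                state[iid] = 0
                stack.append((iid, 1))
                ind = by_id[iid]
                for pid in (ind.father_id, ind.mother_id):
                    if pid is not None:
                        if pid not in by_id:
                            raise PedigreeError(
                                f"parent '{pid}' of '{iid}' not found in family "
                                f"'{family_id}'")
                        if state.get(pid) == 0:
                            raise PedigreeError(
                                f"pedigree cycle involving '{pid}' in family "
                                f"'{family_id}'")
                        if state.get(pid) != 1:
                            stack.append((pid, 0))
            else:
                if state.get(iid) != 1:
                    state[iid] = 1
                    order.append(by_id[iid])
    return order


def _normalize_parent(code: str) -> str | None:
    return None if code.strip().lower() in _NULL_PARENT else code.strip()


def _normalize_sex(code: str) -> str:
    return _SEX_CODES.get(code.strip().lower(), UNKNOWN)


def parse_pedigree(path, format: str = "linkage", strict: bool = False) -> list[Pedigree]:
    """Parse a pedigree file into one :class:`Pedigree` per family.

    Parameters
    ----------
    path:
        LINKAGE/PLINK-fam style file: columns FID IID PAT MAT SEX,
        whitespace-delimited (``format="linkage"``) or comma-delimited
        with a header (``format="csv"``).  ``"0"``/empty marks an
        unknown parent; sex codes 1=male, 2=female, 0=unknown.
    strict:
        If True, a parent id without its own record is an error.  By
        default such parents are auto-inserted as founders with a
        warning, which is common in real-world pedigree files.

    Returns
    -------
    list of Pedigree, one per family id, individuals in topological
    (ancestors-first) order.
    """
    if format not in {"linkage", "csv"}:
        raise ValueError(f"unknown pedigree format '{format}'")

    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(",") if format == "csv" else line.split()
            if format == "csv" and lineno == 1 and fields[0].strip().lower() in {"fid", "family", "family_id"}:
                continue
            if len(fields) < 5:
                raise PedigreeError(
                    f"{path}: line {lineno}: expected >=5 columns, got {len(fields)}")
            rows.append([f.strip() for f in fields[:5]])

    families: dict[str, list[Individual]] = {}
    seen: set[tuple[str, str]] = set()
    for fid, iid, pat, mat, sex in rows:
        if (fid, iid) in seen:
            raise PedigreeError(f"duplicate individual '{iid}' in family '{fid}'")
        seen.add((fid, iid))
        father, mother = _normalize_parent(pat), _normalize_parent(mat)
        # half-founders get a placeholder for the missing parent so the
        # both-or-none parent invariant (and the kinship recursion) holds
        if (father is None) != (mother is None):
            missing = "father" if father is None else "mother"
            placeholder = f"_{missing}_of_{iid}"
            warnings.warn(
                f"individual '{iid}' in family '{fid}' is a half-founder; "
                f"inserting placeholder {missing} '{placeholder}'")
            if father is None:
                father = placeholder
            else:
                mother = placeholder
        families.setdefault(fid, []).append(
            Individual(fid, iid, father, mother, _normalize_sex(sex)))

    # auto-insert parents that appear only as references
    for fid, inds in families.items():
        known = {i.individual_id for i in inds}
        referenced: dict[str, str] = {}
        for ind in inds:
            if ind.father_id is not None:
                referenced.setdefault(ind.father_id, MALE)
            if ind.mother_id is not None:
                referenced.setdefault(ind.mother_id, FEMALE)
        for pid, sex in referenced.items():
            if pid not in known:
                if strict:
                    raise PedigreeError(
                        f"parent '{pid}' referenced in family '{fid}' has no record")
                warnings.warn(
                    f"parent '{pid}' in family '{fid}' has no record; "
                    f"inserted as founder")
                inds.append(Individual(fid, pid, None, None, sex))

    return [Pedigree(fid, inds) for fid, inds in families.items()]


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Compute the kinship matrix by the standard tabular recursion.

    In topological order: phi_ii = 0.5*(1 + phi_fm) with f, m the parents
    of i (0.5 for founders), and phi_ij = 0.5*(phi_jf + phi_jm) for every
    previously processed j (which cannot be a descendant of i).
    """
    n = len(ped)
    phi = np.zeros((n, n))
    for k, ind in enumerate(ped.individuals):
        if ind.is_founder:
            phi[k, k] = 0.5
        else:
            f = ped.index_of(ind.father_id)
            m = ped.index_of(ind.mother_id)
            phi[k, k] = 0.5 * (1.0 + phi[f, m])
            phi[k, :k] = 0.5 * (phi[f, :k] + phi[m, :k])
            phi[:k, k] = phi[k, :k]
    return KinshipMatrix(ped.family_id, ped.ids, phi)


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``code`` is machine-readable."""

    code: str
    message: str


def validate_pedigree(ped: Pedigree) -> list[Finding]:
    """Report (never raise) structural oddities in a parsed pedigree.

    Checks: parents with inconsistent recorded sex, half-founders
    (placeholder parents inserted at parse time), and families whose
    members fall into more than one connected component.
    """
    findings: list[Finding] = []
    for ind in ped.individuals:
        for pid, expected in ((ind.father_id, MALE), (ind.mother_id, FEMALE)):
            if pid is None:
                continue
            parent = ped.individuals[ped.index_of(pid)]
            if parent.sex not in (expected, UNKNOWN):
                role = "father" if expected == MALE else "mother"
                findings.append(Finding(
                    "sex_inconsistency",
                    f"{role} '{pid}' of '{ind.individual_id}' is recorded as "
                    f"{parent.sex}"))
        if ind.individual_id.startswith("_father_of_") or \
                ind.individual_id.startswith("_mother_of_"):
            findings.append(Finding(
                "half_founder",
                f"placeholder parent '{ind.individual_id}' marks a half-founder"))

    g = nx.Graph()
    g.add_nodes_from(ped.ids)
    for ind in ped.individuals:
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None:
                g.add_edge(ind.individual_id, pid)
    n_comp = nx.number_connected_components(g)
    if n_comp > 1:
        findings.append(Finding(
            "disconnected",
            f"family '{ped.family_id}' has {n_comp} disconnected components"))
    return findings


def write_linkage(path, peds: list[Pedigree]) -> None:
    """Write pedigrees in the whitespace LINKAGE dialect (FID IID PAT MAT SEX)."""
    sex_code = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
    with open(path, "w") as fh:
        for ped in peds:
            for ind in ped.individuals:
                fh.write(f"{ind.family_id} {ind.individual_id} "
                         f"{ind.father_id or '0'} {ind.mother_id or '0'} "
                         f"{sex_code[ind.sex]}\n")
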