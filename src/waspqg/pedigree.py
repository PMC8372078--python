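"""Haplodiploid pedigrees and additive relatedness matrices.

In haplodiploid insects females develop from fertilized (diploid) eggs and
males from unfertilized (haploid) eggs, so a male has a dam but never a
sire, and he transmits his entire single genome to every daughter.  The
additive relationship between two individuals is ``a = 2 * coancestry``,
where coancestry (kinship) is the probability that one allele drawn at
random from each individual is identical by descent; a haploid male holds a
single allele, so his self-coancestry is 1.

The tabular recursion below is validated against an independent
gene-dropping Monte-Carlo oracle (:func:`gene_drop_coancestry`).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from waspqg.tables import PEDIGREE_SCHEMA, read_table

FEMALE = "F"
MALE = "M"

_SEX_ALIASES = {
    "f": FEMALE, "female": FEMALE, "diploid": FEMALE,
    "m": MALE, "male": MALE, "haploid": MALE,
}


class PedigreeError(ValueError):
    """Invalid pedigree structure (cycle, duplicate id, male with a sire...)."""


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    sex: str  # FEMALE (diploid) or MALE (haploid)
    dam: str | None = None
    sire: str | None = None


@dataclass(frozen=True)
class Pedigree:
    """Validated pedigree in topological (parents-first) order.

    ``dam_idx``/``sire_idx`` hold the parent's position in ``ids`` or -1 for
    an unknown parent (treated as a unique unrelated founder).
    """

    ids: tuple[str, ...]
    sexes: tuple[str, ...]
    dam_idx: np.ndarray
    sire_idx: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, label: str) -> int:
        try:
            return self.ids.index(label)
        except ValueError:
            raise KeyError(f"id {label!r} not in pedigree") from None

    def is_female(self, i: int) -> bool:
        return self.sexes[i] == FEMALE


@dataclass(frozen=True)
class RelatednessMatrix:
    """Additive relationship matrix (a = 2 x coancestry) over ordered ids."""

    ids: tuple[str, ...]
    entries: np.ndarray

    def loc(self, i: str, j: str) -> float:
        ids = list(self.ids)
        return float(self.entries[ids.index(i), ids.index(j)])


def _normalize_sex(sex: str) -> str:
    key = sex.strip().lower()
    if key not in _SEX_ALIASES:
        raise PedigreeError(f"unknown sex code {sex!r}")
    return _SEX_ALIASES[key]


def build_pedigree(records: list[PedigreeRecord]) -> Pedigree:
    """Validate records and return a topologically ordered pedigree.

    Rejects duplicate ids, males carrying a sire (an unfertilized egg has no
    father), parents of the wrong sex, and any ancestry cycle (including
    self-parenting).
    """
    seen: dict[str, PedigreeRecord] = {}
    for rec in records:
        if rec.id in seen:
            raise PedigreeError(f"duplicate id {rec.id!r}")
        seen[rec.id] = rec

    sexes = {rec.id: _normalize_sex(rec.sex) for rec in records}
    graph = nx.DiGraph()
    graph.add_nodes_from(seen)
    for rec in records:
        sex = sexes[rec.id]
        if sex == MALE and rec.sire is not None:
            raise PedigreeError(
                f"male {rec.id!r} has a sire; haploid males develop from "
                f"unfertilized eggs"
            )
        for parent, want in ((rec.dam, FEMALE), (rec.sire, MALE)):
            if parent is None:
                continue
            if parent == rec.id:
                raise PedigreeError(f"{rec.id!r} is its own parent")
            if parent in sexes and sexes[parent] != want:
                role = "dam" if want == FEMALE else "sire"
                raise PedigreeError(
                    f"{role} {parent!r} of {rec.id!r} is not {want}"
                )
            if parent not in seen:
                # unknown parent: implicit unrelated founder, not a graph node
                continue
            graph.add_edge(parent, rec.id)

    if not nx.is_directed_acyclic_graph(graph):
        cyc = nx.find_cycle(graph)
        raise PedigreeError(f"pedigree contains a cycle: {cyc}")

    order = list(nx.lexicographical_topological_sort(graph))
    pos = {label: k for k, label in enumerate(order)}
    dam_idx = np.full(len(order), -1, dtype=np.int64)
    sire_idx = np.full(len(order), -1, dtype=np.int64)
    for label in order:
        rec = seen[label]
        if rec.dam is not None and rec.dam in pos:
            dam_idx[pos[label]] = pos[rec.dam]
        if rec.sire is not None and rec.sire in pos:
            sire_idx[pos[label]] = pos[rec.sire]
    return Pedigree(
        ids=tuple(order),
        sexes=tuple(sexes[label] for label in order),
        dam_idx=dam_idx,
        sire_idx=sire_idx,
    )


def _coancestry_matrix(ped: Pedigree) -> np.ndarray:
    """Tabular coancestry recursion under haplodiploid transmission.

    Processing parents-first, for individual i with dam d and sire s:

    - female i:  f(i,j) = (f(d,j) + f(s,j)) / 2 for earlier j;
                 f(i,i) = 1/2 + f(d,s)/2  (inbreeding enters naturally)
    - male i:    f(i,j) = f(d,j);  f(i,i) = 1 (single allele)

    Unknown parents contribute coancestry 0 (unique unrelated founders).
    """
    n = len(ped)
    K = np.zeros((n, n))
    for i in range(n):
        d, s = int(ped.dam_idx[i]), int(ped.sire_idx[i])
        if ped.is_female(i):
            for j in range(i):
                fd = K[d, j] if d >= 0 else 0.0
                fs = K[s, j] if s >= 0 else 0.0
                K[i, j] = K[j, i] = 0.5 * (fd + fs)
            fds = K[d, s] if (d >= 0 and s >= 0) else 0.0
            K[i, i] = 0.5 + 0.5 * fds
        else:
            for j in range(i):
                K[i, j] = K[j, i] = K[d, j] if d >= 0 else 0.0
            K[i, i] = 1.0
    return K


def haplodiploid_amatrix(ped: Pedigree) -> RelatednessMatrix:
    """Additive relationship matrix a = 2 x coancestry for the pedigree."""
    return RelatednessMatrix(ids=ped.ids, entries=2.0 * _coancestry_matrix(ped))


def gene_drop_coancestry(
    ped: Pedigree,
    i: str,
    j: str,
    n_reps: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo coancestry estimate by dropping alleles down the pedigree.

    Founders receive unique allele labels (two per female, one per male).
    A daughter gets her sire's single allele plus one maternal allele drawn
    at random; a son gets one maternal allele.  Coancestry is the frequency
    with which one random allele of *i* and one of *j* are identical by
    descent.  Returns ``(estimate, mc_standard_error)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ii, jj = ped.index(i), ped.index(j)
    rng = np.random.default_rng(seed)
    n = len(ped)

    # allele state per individual: two columns (males duplicate their allele)
    a1 = np.empty((n_reps, n), dtype=np.int64)
    a2 = np.empty((n_reps, n), dtype=np.int64)
    next_founder = 0
    for k in range(n):
        d, s = int(ped.dam_idx[k]), int(ped.sire_idx[k])
        if d >= 0:
            pick = rng.integers(0, 2, size=n_reps, dtype=np.int64)
            maternal = np.where(pick == 0, a1[:, d], a2[:, d])
        else:
            maternal = np.full(n_reps, next_founder, dtype=np.int64)
            next_founder += 1
        if ped.is_female(k):
            if s >= 0:
                paternal = a1[:, s]  # sire transmits his single allele
            else:
                paternal = np.full(n_reps, next_founder, dtype=np.int64)
                next_founder += 1
            a1[:, k], a2[:, k] = maternal, paternal
        else:
            a1[:, k] = a2[:, k] = maternal

    pick_i = rng.integers(0, 2, size=n_reps)
    pick_j = rng.integers(0, 2, size=n_reps)
    allele_i = np.where(pick_i == 0, a1[:, ii], a2[:, ii])
    allele_j = np.where(pick_j == 0, a1[:, jj], a2[:, jj])
    hits = allele_i == allele_j
    est = float(hits.mean())
    se = float(np.sqrt(max(est * (1 - est), 1e-12) / n_reps))
    return est, se


def phenotyped_submatrix(A: RelatednessMatrix, ids: list[str]) -> RelatednessMatrix:
    """Principal submatrix over the phenotyped individuals, in given order."""
    pos = {label: k for k, label in enumerate(A.ids)}
    try:
        idx = np.array([pos[label] for label in ids], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"id {exc.args[0]!r} not in relatedness matrix") from None
    return RelatednessMatrix(
        ids=tuple(ids), entries=A.entries[np.ix_(idx, idx)]
    )


# ---------------------------------------------------------------------------
# Table-level interface


def pedigree_from_table(df: pd.DataFrame) -> Pedigree:
    """Build a pedigree from a validated table (empty parent = unknown)."""
    records = []
    for r in df.itertuples(index=False):
        dam = None if str(r.dam).strip() in ("", "nan", "0") else str(r.dam)
        sire = None if str(r.sire).strip() in ("", "nan", "0") else str(r.sire)
        records.append(PedigreeRecord(id=str(r.id), sex=str(r.sex), dam=dam, sire=sire))
    return build_pedigree(records)


def load_pedigree(path) -> Pedigree:
    return pedigree_from_table(read_table(path, PEDIGREE_SCHEMA))


def amatrix_to_frame(A: RelatednessMatrix) -> pd.DataFrame:
    return pd.DataFrame(A.entries, index=list(A.ids), columns=list(A.ids))
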