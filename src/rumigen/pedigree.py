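"""Pedigree handling and numerator relationship matrix machinery.

The additive (numerator) relationship matrix ``A`` collects the expected
additive-genetic relationships a_ij between every pair of animals in a
pedigree; its diagonal is 1 + F_i, where F_i is the inbreeding coefficient.
``A`` (through its sparse inverse) structures the random animal effect of
the mixed "animal model" used for variance-component estimation.

Unknown parents are treated as unrelated, non-inbred founders; no genetic
groups are fitted.
"""

from __future__ import annotations

import dataclasses
import graphlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

#: strings accepted as "parent unknown" in pedigree files
UNKNOWN_SENTINELS = {"", "0", "na", "nan", "none", ".", "?"}


class PedigreeError(ValueError):
    """Structurally invalid pedigree (cycle, duplicate animal id, bad order)."""


@dataclasses.dataclass(frozen=True)
class PedigreeRecord:
    """One animal with its parent links and management descriptors."""

    animal_id: str
    sire_id: str | None
    dam_id: str | None
    birth_year: int | None = None
    flock: str | None = None
    cohort: str | None = None


def _normalise_id(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    text = str(value).strip()
    if text.lower() in UNKNOWN_SENTINELS:
        return None
    return text


def read_pedigree(source) -> list[PedigreeRecord]:
    """Read pedigree rows and return records topologically sorted.

    Parameters
    ----------
    source
        CSV path or DataFrame-like with columns ``animal, sire, dam`` and
        optionally ``birth_year, flock, cohort``. Unknown parents may be
        encoded as ``0``, empty, or NA.

    Returns
    -------
    list of PedigreeRecord with every parent preceding its offspring.
    Parents that appear only as parents are added as founder records.

    Raises
    ------
    PedigreeError
        On duplicate animal ids or ancestry cycles (the cycle is named).
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, dtype=str)
    else:
        df = pd.DataFrame(source).copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    for required in ("animal", "sire", "dam"):
        if required not in df.columns:
            raise PedigreeError(f"pedigree input lacks required column {required!r}")

    records: dict[str, PedigreeRecord] = {}
    for row in df.itertuples(index=False):
        animal = _normalise_id(getattr(row, "animal"))
        if animal is None:
            raise PedigreeError("pedigree row with missing animal id")
        if animal in records:
            raise PedigreeError(f"duplicate animal_id {animal!r} in pedigree")
        birth_year = getattr(row, "birth_year", None)
        if birth_year is not None and _normalise_id(birth_year) is not None:
            birth_year = int(float(birth_year))
        else:
            birth_year = None
        records[animal] = PedigreeRecord(
            animal_id=animal,
            sire_id=_normalise_id(getattr(row, "sire")),
            dam_id=_normalise_id(getattr(row, "dam")),
            birth_year=birth_year,
            flock=_normalise_id(getattr(row, "flock", None)),
            cohort=_normalise_id(getattr(row, "cohort", None)),
        )

    # implicit founders: ids that only ever appear as parents
    for rec in list(records.values()):
        for parent in (rec.sire_id, rec.dam_id):
            if parent is not None and parent not in records:
                records[parent] = PedigreeRecord(parent, None, None)

    sorter: graphlib.TopologicalSorter = graphlib.TopologicalSorter()
    for rec in records.values():
        parents = [p for p in (rec.sire_id, rec.dam_id) if p is not None]
        sorter.add(rec.animal_id, *parents)
    try:
        order = list(sorter.static_order())
    except graphlib.CycleError as err:
        cycle = " -> ".join(err.args[1])
        raise PedigreeError(f"cycle in pedigree: {cycle}") from err
    return [records[a] for a in order]


def _parent_indices(pedigree: list[PedigreeRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Map sire/dam ids to positional indices (-1 = unknown); checks ordering."""
    pos = {rec.animal_id: i for i, rec in enumerate(pedigree)}
    if len(pos) != len(pedigree):
        raise PedigreeError("duplicate animal_id in pedigree list")
    sire = np.full(len(pedigree), -1, dtype=np.int64)
    dam = np.full(len(pedigree), -1, dtype=np.int64)
    for i, rec in enumerate(pedigree):
        for arr, pid in ((sire, rec.sire_id), (dam, rec.dam_id)):
            if pid is None:
                continue
            j = pos.get(pid)
            if j is None:
                raise PedigreeError(f"parent {pid!r} of {rec.animal_id!r} not in pedigree")
            if j >= i:
                raise PedigreeError(
                    f"pedigree not topologically sorted: parent {pid!r} does not "
                    f"precede {rec.animal_id!r}"
                )
            arr[i] = j
    return sire, dam


@dataclasses.dataclass
class RelationshipMatrix:
    """Dense additive relationship matrix with its animal ordering."""

    ids: list[str]
    values: np.ndarray

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficient F_i = a_ii - 1."""
        return np.diag(self.values) - 1.0

    def loc(self, animal_i: str, animal_j: str) -> float:
        i = self.ids.index(animal_i)
        j = self.ids.index(animal_j)
        return float(self.values[i, j])


@dataclasses.dataclass
class RelationshipMatrixInverse:
    """Sparse inverse of the additive relationship matrix."""

    ids: list[str]
    matrix: sparse.csr_matrix


def build_A(pedigree: list[PedigreeRecord]) -> RelationshipMatrix:
    """Build the dense numerator relationship matrix by the tabular method.

    a_ii = 1 + 0.5 * a_(sire, dam); a_ij (j older) = 0.5 * (a_j,sire +
    a_j,dam); unknown parents contribute zero.
    """
    sire, dam = _parent_indices(pedigree)
    n = len(pedigree)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
            row = 0.5 * (A[:i, s] + A[:i, d])
        elif s >= 0:
            A[i, i] = 1.0
            row = 0.5 * A[:i, s]
        elif d >= 0:
            A[i, i] = 1.0
            row = 0.5 * A[:i, d]
        else:
            A[i, i] = 1.0
            row = np.zeros(i)
        A[:i, i] = row
        A[i, :i] = row
    return RelationshipMatrix(ids=[r.animal_id for r in pedigree], values=A)


def inbreeding_coefficients(pedigree: list[PedigreeRecord]) -> np.ndarray:
    """Inbreeding coefficients without forming the full dense A.

    F_i = 0.5 * a(sire_i, dam_i), computed by running the tabular method on
    the ancestor closure of each animal's parents. Exact for arbitrary
    (acyclic) pedigrees; cost grows with pedigree depth, which is shallow
    for the cohort-style pedigrees this package targets.
    """
    sire, dam = _parent_indices(pedigree)
    n = len(pedigree)
    F = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 or d < 0:
            continue
        # ancestor closure of {s, d}
        closure: set[int] = set()
        stack = [s, d]
        while stack:
            k = stack.pop()
            if k in closure:
                continue
            closure.add(k)
            for p in (sire[k], dam[k]):
                if p >= 0:
                    stack.append(p)
        subset = sorted(closure)
        local = {k: idx for idx, k in enumerate(subset)}
        m = len(subset)
        a = np.zeros((m, m))
        for idx, k in enumerate(subset):
            ps = local.get(sire[k], -1) if sire[k] >= 0 else -1
            pd_ = local.get(dam[k], -1) if dam[k] >= 0 else -1
            if ps >= 0 and pd_ >= 0:
                a[idx, idx] = 1.0 + 0.5 * a[ps, pd_]
                row = 0.5 * (a[:idx, ps] + a[:idx, pd_])
            elif ps >= 0:
                a[idx, idx] = 1.0
                row = 0.5 * a[:idx, ps]
            elif pd_ >= 0:
                a[idx, idx] = 1.0
                row = 0.5 * a[:idx, pd_]
            else:
                a[idx, idx] = 1.0
                row = np.zeros(idx)
            a[:idx, idx] = row
            a[idx, :idx] = row
        F[i] = 0.5 * a[local[s], local[d]]
    return F


def build_A_inverse(pedigree: list[PedigreeRecord]) -> RelationshipMatrixInverse:
    """Sparse A-inverse by Henderson's rules with inbreeding correction.

    For animal i with Mendelian-sampling variance
    ``d_i = 1 - 0.25*(1 + F_sire) - 0.25*(1 + F_dam)`` (terms only for known
    parents), alpha_i = 1/d_i contributes alpha at (i,i), -alpha/2 at the
    animal-parent cells and alpha/4 at the parent-parent cells.
    """
    sire, dam = _parent_indices(pedigree)
    F = inbreeding_coefficients(pedigree)
    n = len(pedigree)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        dvar = 1.0
        if s >= 0:
            dvar -= 0.25 * (1.0 + F[s])
        if d >= 0:
            dvar -= 0.25 * (1.0 + F[d])
        alpha = 1.0 / dvar
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
        known = [p for p in (s, d) if p >= 0]
        for p in known:
            for q in known:
                add(p, q, alpha / 4.0)
    mat = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrixInverse(ids=[r.animal_id for r in pedigree], matrix=mat)


def pedigree_to_frame(pedigree: list[PedigreeRecord]) -> pd.DataFrame:
    """Tabular view of a pedigree, in the CSV dialect read_pedigree accepts."""
    return pd.DataFrame(
        {
            "animal": [r.animal_id for r in pedigree],
            "sire": [r.sire_id or "0" for r in pedigree],
            "dam": [r.dam_id or "0" for r in pedigree],
            "birth_year": [r.birth_year for r in pedigree],
            "flock": [r.flock for r in pedigree],
            "cohort": [r.cohort for r in pedigree],
        }
    )
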