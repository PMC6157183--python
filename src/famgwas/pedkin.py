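"""Pedigrees and expected kinship matrices.

The kinship coefficient ``phi(i, j)`` is the probability that an allele
sampled at random from individual *i* and one sampled from *j* are
identical by descent.  For a non-inbred individual ``phi(i, i) = 0.5``;
more generally ``phi(i, i) = 0.5 * (1 + f_i)`` with *f_i* the inbreeding
coefficient (the kinship of the parents).  The matrix of kinship
coefficients is the ``K`` that enters every mixed model in this package:
model code uses ``K`` exactly as stored, never ``2K``.

Kinship is computed by the standard recursion over a topological ordering
of the parent graph:

* founders are mutually unrelated, ``phi = 0.5`` with themselves;
* ``phi(i, i) = 0.5 * (1 + phi(father_i, mother_i))``;
* ``phi(i, j) = 0.5 * (phi(father_i, j) + phi(mother_i, j))`` whenever
  *j* is not a descendant of *i* (guaranteed by processing order).

Inbred pedigrees (diagonal above 0.5) are supported; individuals from
different families always have kinship 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Sex",
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "compute_kinship",
    "write_kinship",
]

MISSING_PARENT = ""


class PedigreeError(ValueError):
    """Structural or parse error in a pedigree."""


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"

    @classmethod
    def from_code(cls, code: str) -> "Sex":
        code = str(code).strip().lower()
        if code in {"1", "m", "male"}:
            return cls.male
        if code in {"2", "f", "female"}:
            return cls.female
        return cls.unknown


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str  # "" when missing
    mother: str
    sex: Sex
    family: str

    @property
    def is_founder(self) -> bool:
        return self.father == MISSING_PARENT and self.mother == MISSING_PARENT


@dataclass
class Pedigree:
    """A validated collection of individuals with parent links.

    Invariants enforced at construction: ids unique, every named parent
    present, the parent graph acyclic, founders have both parents missing
    (a single known parent is allowed and treated as half-founder).
    """

    records: list[Individual]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for k, rec in enumerate(self.records):
            if rec.iid in self._index:
                raise PedigreeError(f"duplicate individual id {rec.iid!r}")
            if rec.iid == MISSING_PARENT:
                raise PedigreeError("empty individual id")
            self._index[rec.iid] = k
        orphans = sorted(
            {
                p
                for rec in self.records
                for p in (rec.father, rec.mother)
                if p != MISSING_PARENT and p not in self._index
            }
        )
        if orphans:
            raise PedigreeError(f"parents absent from pedigree: {orphans}")
        self._toposort()  # raises on cycles

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    @property
    def ids(self) -> list[str]:
        return [r.iid for r in self.records]

    def record(self, iid: str) -> Individual:
        return self.records[self._index[iid]]

    def founders(self) -> list[str]:
        return [r.iid for r in self.records if r.is_founder]

    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for r in self.records:
            fams.setdefault(r.family, []).append(r.iid)
        return fams

    def _toposort(self) -> list[str]:
        """Order ids so that parents precede children; raise on cycles."""
        indeg = {r.iid: 0 for r in self.records}
        children: dict[str, list[str]] = {r.iid: [] for r in self.records}
        for r in self.records:
            for p in (r.father, r.mother):
                if p != MISSING_PARENT:
                    indeg[r.iid] += 1
                    children[p].append(r.iid)
        order = [i for i in indeg if indeg[i] == 0]
        head = 0
        while head < len(order):
            cur = order[head]
            head += 1
            for ch in children[cur]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    order.append(ch)
        if len(order) != len(self.records):
            cyclic = sorted(i for i, d in indeg.items() if d > 0)
            raise PedigreeError(
                f"cycle in parent graph involving individual(s) {cyclic}"
            )
        return order


@dataclass
class KinshipMatrix:
    """Symmetric PSD matrix of kinship coefficients with row/column ids."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("kinship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids not in kinship matrix: {missing}")
        idx = np.array([pos[i] for i in ids])
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(ids))


# ---------------------------------------------------------------------------
# reading / writing


def _normalize_parent(tok: str) -> str:
    tok = tok.strip()
    return MISSING_PARENT if tok in {"0", "", ".", "NA"} else tok


def read_pedigree(
    path,
    dialect: str = "fam_like",
    promote_missing_parents: bool = False,
) -> Pedigree:
    """Read a pedigree file.

    ``fam_like``: whitespace-delimited, no header, columns
    ``family iid father mother sex`` (extra columns ignored); ``0`` or
    empty codes a missing parent.

    ``three_generation_tsv``: tab-separated with a header naming at least
    ``iid``, ``father``, ``mother``, ``sex``, ``family`` in any order.

    With ``promote_missing_parents=True``, parents referenced but not
    listed as records are added as founders (with a warning) instead of
    raising.
    """
    rows: list[tuple[str, str, str, str, str]] = []  # fam, iid, fa, mo, sex
    with open(path) as fh:
        if dialect == "fam_like":
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                tok = line.split()
                if len(tok) < 5:
                    raise PedigreeError(f"line {ln}: expected >=5 columns")
                rows.append((tok[0], tok[1], tok[2], tok[3], tok[4]))
        elif dialect == "three_generation_tsv":
            header = fh.readline().rstrip("\n").split("\t")
            col = {name.strip().lower(): k for k, name in enumerate(header)}
            need = ["iid", "father", "mother", "sex", "family"]
            absent = [c for c in need if c not in col]
            if absent:
                raise PedigreeError(f"header missing columns: {absent}")
            for line in fh:
                if not line.strip():
                    continue
                tok = line.rstrip("\n").split("\t")
                rows.append(
                    (
                        tok[col["family"]],
                        tok[col["iid"]],
                        tok[col["father"]],
                        tok[col["mother"]],
                        tok[col["sex"]],
                    )
                )
        else:
            raise ValueError(f"unknown pedigree dialect {dialect!r}")

    records = [
        Individual(
            iid=iid.strip(),
            father=_normalize_parent(fa),
            mother=_normalize_parent(mo),
            sex=Sex.from_code(sx),
            family=fam.strip(),
        )
        for fam, iid, fa, mo, sx in rows
    ]
    if promote_missing_parents:
        known = {r.iid for r in records}
        fam_of: dict[str, str] = {}
        sex_of: dict[str, Sex] = {}
        for r in records:
            if r.father and r.father not in known:
                fam_of[r.father] = r.family
                sex_of[r.father] = Sex.male
            if r.mother and r.mother not in known:
                fam_of[r.mother] = r.family
                sex_of[r.mother] = Sex.female
        if fam_of:
            warnings.warn(
                f"promoted {len(fam_of)} referenced-but-unlisted parents "
                f"to founders: {sorted(fam_of)}",
                stacklevel=2,
            )
            records = [
                Individual(p, MISSING_PARENT, MISSING_PARENT, sex_of[p], fam_of[p])
                for p in fam_of
            ] + records
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write in the fam_like dialect (``0`` for missing parents)."""
    sex_code = {Sex.male: "1", Sex.female: "2", Sex.unknown: "0"}
    with open(path, "w") as fh:
        for r in ped.records:
            fh.write(
                f"{r.family} {r.iid} {r.father or '0'} {r.mother or '0'} "
                f"{sex_code[r.sex]}\n"
            )


# ---------------------------------------------------------------------------
# kinship


def compute_kinship(
    ped: Pedigree, subset: Sequence[str] | None = None
) -> KinshipMatrix:
    """Expected kinship matrix by the standard recursion.

    The full matrix is computed over the whole pedigree first and then
    restricted to ``subset`` (compute-then-subset; the two orders agree
    for expected kinship, but ancestors always contribute).
    """
    order = ped._toposort()
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    parents = {
        r.iid: (
            pos[r.father] if r.father else -1,
            pos[r.mother] if r.mother else -1,
        )
        for r in ped.records
    }
    for k, iid in enumerate(order):
        fa, mo = parents[iid]
        # self kinship: 0.5 * (1 + kinship(father, mother))
        f_i = phi[fa, mo] if fa >= 0 and mo >= 0 else 0.0
        phi[k, k] = 0.5 * (1.0 + f_i)
        for j in range(k):  # earlier in order => j not a descendant of k
            val = 0.0
            if fa >= 0:
                val += 0.5 * phi[fa, j]
            if mo >= 0:
                val += 0.5 * phi[mo, j]
            phi[k, j] = phi[j, k] = val

    ids = list(ped.ids) if subset is None else list(subset)
    bad = [i for i in ids if i not in pos]
    if bad:
        raise KeyError(f"subset ids not in pedigree: {bad}")
    if not ids:
        raise ValueError("empty subset")
    idx = np.array([pos[i] for i in ids])
    return KinshipMatrix(phi[np.ix_(idx, idx)], ids)


def write_kinship(K: KinshipMatrix, path) -> None:
    """TSV matrix with a header row and leading id column."""
    with open(path, "w") as fh:
        fh.write("iid\t" + "\t".join(K.ids) + "\n")
        for iid, row in zip(K.ids, K.values):
            fh.write(iid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_kinship(path) -> KinshipMatrix:
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")[1:]
        vals = np.loadtxt(fh, usecols=range(1, len(ids) + 1), ndmin=2)
    return KinshipMatrix(vals, ids)
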