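"""Pedigree validation, inbreeding and the numerator relationship matrix.

The additive (numerator) relationship matrix A collects the expected
proportions of alleles shared identical-by-descent between every pair of
pedigree members; its diagonal is 1 + F, with F the inbreeding coefficient.
A parameterises the covariance of polygenic effects, MVN(0, A sigma2_a),
in the segregation, variance-component and association models.

Unknown parents are treated as unrelated, non-inbred founders.  Matrices
are dense: the target scale (a closed nucleus herd, tens of thousands of
records at most) is comfortably within dense-arithmetic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = 0  # pedigree code for an unknown parent

__all__ = [
    "PedigreeError",
    "Pedigree",
    "load_pedigree",
    "validate_pedigree",
    "inbreeding",
    "a_matrix",
]


class PedigreeError(ValueError):
    """Structural defect in a pedigree (cycle, duplicate id, sex conflict)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    ``table`` has columns id, sire, dam, sex, litter, generation with parents
    always preceding offspring; ``index`` maps id -> row position.
    """

    table: pd.DataFrame
    index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {i: k for k, i in enumerate(self.table["id"])}

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def parent_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Row positions of sire and dam per individual; -1 for unknown."""
        pos = lambda col: np.array(
            [self.index.get(p, -1) if p != UNKNOWN else -1 for p in self.table[col]],
            dtype=np.int64,
        )
        return pos("sire"), pos("dam")

    def category_counts(self) -> dict[str, int]:
        """Pedigree-structure summary: distinct parents and grandparents.

        Mirrors the bookkeeping customary for nucleus-herd reports (number of
        sires, dams, sires of sires, ...).
        """
        t = self.table
        sire_of = dict(zip(t["id"], t["sire"]))
        dam_of = dict(zip(t["id"], t["dam"]))
        sires = {s for s in t["sire"] if s != UNKNOWN}
        dams = {d for d in t["dam"] if d != UNKNOWN}
        known = lambda xs: {x for x in xs if x != UNKNOWN and x is not None}
        return {
            "n_records": len(t),
            "n_litters": t["litter"].nunique(),
            "n_sires": len(sires),
            "n_dams": len(dams),
            "n_sires_of_sire": len(known(sire_of.get(s, UNKNOWN) for s in sires)),
            "n_dams_of_sire": len(known(dam_of.get(s, UNKNOWN) for s in sires)),
            "n_sires_of_dam": len(known(sire_of.get(d, UNKNOWN) for d in dams)),
            "n_dams_of_dam": len(known(dam_of.get(d, UNKNOWN) for d in dams)),
        }


def load_pedigree(path) -> Pedigree:
    """Read a pedigree CSV (columns id,sire,dam,sex,litter,generation; 0 =
    unknown parent) and validate it."""
    df = pd.read_csv(path)
    return validate_pedigree(df)


def validate_pedigree(records: pd.DataFrame) -> Pedigree:
    """Check structure and return a topologically sorted :class:`Pedigree`.

    Raises
    ------
    PedigreeError
        on duplicated ids, an individual among its own ancestors, or a parent
        used both as sire and dam / with conflicting recorded sex.
    """
    df = records.copy()
    required = ["id", "sire", "dam"]
    for col in required:
        if col not in df.columns:
            raise PedigreeError(f"pedigree is missing required column {col!r}")
    for col, default in (("sex", "U"), ("litter", 0), ("generation", -1)):
        if col not in df.columns:
            df[col] = default

    ids = df["id"]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise PedigreeError(f"duplicated individual ids: {sorted(set(dup))[:10]}")
    idset = set(ids)

    # parent sex consistency
    sires = {s for s in df["sire"] if s != UNKNOWN}
    dams = {d for d in df["dam"] if d != UNKNOWN}
    both = sires & dams
    if both:
        raise PedigreeError(f"ids used as both sire and dam: {sorted(both)[:10]}")
    sex_of = dict(zip(df["id"], df["sex"]))
    bad_sex = [s for s in sires if sex_of.get(s, "M") == "F"] + [
        d for d in dams if sex_of.get(d, "F") == "M"
    ]
    if bad_sex:
        raise PedigreeError(f"parent sex conflicts for ids: {sorted(bad_sex)[:10]}")

    # Kahn topological sort over the parent->offspring DAG
    children: dict = {i: [] for i in ids}
    indeg = {i: 0 for i in ids}
    for i, s, d in zip(df["id"], df["sire"], df["dam"]):
        for p in (s, d):
            if p != UNKNOWN and p in idset:
                children[p].append(i)
                indeg[i] += 1
    order, queue = [], [i for i in ids if indeg[i] == 0]
    while queue:
        nxt = []
        for i in queue:
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        queue = nxt
    if len(order) != len(df):
        cyclic = sorted(i for i in ids if indeg[i] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving ids {cyclic[:10]}")

    df = df.set_index("id").loc[order].reset_index()
    return Pedigree(df)


def _a_full(ped: Pedigree) -> np.ndarray:
    """Dense A over the whole pedigree by the tabular (recursive) method:
    a_ij = (a_{j,s(i)} + a_{j,d(i)})/2 for j < i, a_ii = 1 + a_{s(i),d(i)}/2.
    """
    n = len(ped)
    sire, dam = ped.parent_arrays()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def inbreeding(ped: Pedigree) -> pd.Series:
    """Inbreeding coefficient F per individual (F = a(sire, dam)/2).

    Founders, and any individual with an unknown parent, have F = 0.
    """
    A = _a_full(ped)
    return pd.Series(np.diag(A) - 1.0, index=ped.ids, name="F")


def a_matrix(ped: Pedigree, subset_ids=None) -> pd.DataFrame:
    """Numerator relationship matrix, optionally restricted to ``subset_ids``.

    The recursion always runs over the full ancestry; the subset only selects
    rows/columns of the result, so relationships through unlisted ancestors
    are preserved.
    """
    A = _a_full(ped)
    ids = list(ped.ids)
    out = pd.DataFrame(A, index=ids, columns=ids)
    if subset_ids is not None:
        subset_ids = list(subset_ids)
        missing = [i for i in subset_ids if i not in ped.index]
        if missing:
            raise PedigreeError(f"ids not in pedigree: {missing[:10]}")
        out = out.loc[subset_ids, subset_ids]
    return out
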