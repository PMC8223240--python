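"""Extended twin-family pedigrees and their covariance structures.

A pedigree is a forest of family graphs read from a FAM-style text file
(family id, individual id, father, mother, sex) extended with a twin-group
column and a zygosity code.  From it we build, family by family, the two
matrices that parameterise the ACE variance decomposition:

* the additive genetic relationship matrix ``A`` (expected proportion of
  alleles shared identically by descent, times one): 1 on the diagonal and
  for MZ co-twins, 1/2 for parent-offspring and full siblings (DZ twins
  included), 0 for unrelated founders such as spouses;
* the twin shared-environment indicator ``C``: 1 on the diagonal and for
  co-twins of the same twin group (MZ and DZ alike), 0 elsewhere.  Ordinary
  siblings do not share this component — it captures the environment twins
  share while growing up together, not the household in general.

``A`` is computed by the tabular method: individuals are sorted so parents
precede offspring and a(i,j) = (a(father_i,j) + a(mother_i,j)) / 2, with
founder terms zero; afterwards every MZ pair is collapsed to genetic
identity (co-twin entry 1, equal rows/columns against all third parties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FOUNDER = "0"

PED_COLUMNS = [
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "twin_group",
    "zygosity",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, bad twin groups...)."""


@dataclass
class Pedigree:
    """Validated family forest with zygosity annotations.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per individual with columns ``family_id, individual_id,
        father_id, mother_id, sex, twin_group, zygosity``.  Parent ids are
        either the id of another individual in the same family or the
        founder marker ``"0"``.  ``twin_group`` is ``"0"`` for non-twins;
        ``zygosity`` is ``MZ``, ``DZ`` or ``NA``.
    """

    table: pd.DataFrame
    _families: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        t = self.table.copy()
        for c in PED_COLUMNS:
            if c not in t.columns:
                raise PedigreeError(f"pedigree table missing column {c!r}")
        for c in ("family_id", "individual_id", "father_id", "mother_id",
                  "sex", "twin_group", "zygosity"):
            t[c] = t[c].astype(str)
        self.table = t.reset_index(drop=True)
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_fam(cls, path) -> "Pedigree":
        """Read a whitespace/tab-delimited FAM-style file with twin columns.

        Columns: family_id individual_id father_id mother_id sex(1/2)
        twin_group zygosity(MZ/DZ/NA).  A header line is optional and
        detected by the literal column name in the first field.
        """
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                         comment="#", keep_default_na=False)
        if df.iloc[0, 0] == "family_id":
            df = df.iloc[1:].reset_index(drop=True)
        if df.shape[1] != len(PED_COLUMNS):
            raise PedigreeError(
                f"expected {len(PED_COLUMNS)} columns, got {df.shape[1]}")
        df.columns = PED_COLUMNS
        return cls(df)

    def to_fam(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        t = self.table
        if t["individual_id"].duplicated().any():
            dup = t.loc[t["individual_id"].duplicated(), "individual_id"].iloc[0]
            raise PedigreeError(f"duplicate individual id {dup!r}")
        fam_of = pd.Series(t["family_id"].to_numpy(),
                           index=t["individual_id"].to_numpy())
        for col in ("father_id", "mother_id"):
            parent = t[col]
            nonf = parent != FOUNDER
            if (nonf & (parent == t["individual_id"])).any():
                line = int(np.argmax((nonf & (parent == t["individual_id"]))
                                     .to_numpy())) + 1
                raise PedigreeError(
                    f"line {line}: individual "
                    f"{t['individual_id'].iloc[line - 1]!r} is its own parent")
            pf = parent.map(fam_of)
            bad = nonf & (pf.isna() | (pf != t["family_id"]))
            if bad.any():
                line = int(np.argmax(bad.to_numpy())) + 1
                raise PedigreeError(
                    f"line {line}: parent {parent.iloc[line - 1]!r} of "
                    f"{t['individual_id'].iloc[line - 1]!r} not in family "
                    f"{t['family_id'].iloc[line - 1]!r}")
        self._check_acyclic(t)
        self._check_twins(t)

    @staticmethod
    def _check_acyclic(t: pd.DataFrame) -> None:
        # vectorized Kahn peeling: repeatedly place individuals whose
        # parents are already placed; leftover rows imply a cycle
        pos = {i: k for k, i in enumerate(t["individual_id"])}
        fa = np.array([pos.get(p, -1) if p != FOUNDER else -1
                       for p in t["father_id"]])
        mo = np.array([pos.get(p, -1) if p != FOUNDER else -1
                       for p in t["mother_id"]])
        placed = np.zeros(len(t), dtype=bool)
        while True:
            ready = ~placed & \
                ((fa < 0) | placed[np.clip(fa, 0, None)]) & \
                ((mo < 0) | placed[np.clip(mo, 0, None)])
            if not ready.any():
                break
            placed |= ready
        if not placed.all():
            i = t["individual_id"].iloc[int(np.argmax(~placed))]
            raise PedigreeError(f"cyclic parentage involving {i!r}")

    @staticmethod
    def _check_twins(t: pd.DataFrame) -> None:
        twins = t[t["twin_group"] != "0"]
        if twins.empty:
            return
        bad = set(twins["zygosity"]) - {"MZ", "DZ"}
        if bad:
            raise PedigreeError(f"unknown zygosity code(s) {sorted(bad)}")
        agg = twins.groupby(["family_id", "twin_group"]).agg(
            n=("individual_id", "size"),
            n_zyg=("zygosity", "nunique"),
            n_fa=("father_id", "nunique"),
            n_mo=("mother_id", "nunique"))
        if (agg["n"] < 2).any():
            fam, tg = agg.index[int(np.argmax((agg["n"] < 2).to_numpy()))]
            raise PedigreeError(
                f"family {fam!r}: twin group {tg!r} has a single member")
        if (agg["n_zyg"] > 1).any():
            fam, tg = agg.index[int(np.argmax((agg["n_zyg"] > 1).to_numpy()))]
            raise PedigreeError(
                f"family {fam!r}: twin group {tg!r} mixes zygosities")
        if ((agg["n_fa"] > 1) | (agg["n_mo"] > 1)).any():
            sel = ((agg["n_fa"] > 1) | (agg["n_mo"] > 1)).to_numpy()
            fam, tg = agg.index[int(np.argmax(sel))]
            raise PedigreeError(
                f"family {fam!r}: twin group {tg!r} mixes parents")

    # -- accessors ----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    @property
    def family_ids(self) -> list:
        return list(dict.fromkeys(self.table["family_id"]))

    def founders(self) -> pd.Series:
        t = self.table
        return (t["father_id"] == FOUNDER) & (t["mother_id"] == FOUNDER)

    def families(self) -> dict:
        """Map family_id -> sub-table, cached."""
        if self._families is None:
            self._families = {f: g.reset_index(drop=True)
                              for f, g in self.table.groupby("family_id", sort=False)}
        return self._families


@dataclass
class RelationshipStructure:
    """Per-family additive (A) and twin shared-environment (C) matrices.

    ``index`` maps individual_id -> (family_id, position within family);
    ``A`` and ``C`` map family_id -> dense (n_f, n_f) arrays ordered as
    ``members[family_id]``.
    """

    members: dict
    A: dict
    C: dict
    index: dict

    @classmethod
    def from_pedigree(cls, ped: Pedigree) -> "RelationshipStructure":
        members, A, C, index = {}, {}, {}, {}
        cache: dict = {}
        for fam, g in ped.families().items():
            ids = list(g["individual_id"])
            members[fam] = ids
            sig = _structure_signature(g)
            if sig not in cache:
                cache[sig] = (_family_a_matrix(g), _family_c_matrix(g))
            A[fam], C[fam] = cache[sig]
            for pos, i in enumerate(ids):
                index[i] = (fam, pos)
        return cls(members=members, A=A, C=C, index=index)


def _structure_signature(g: pd.DataFrame) -> tuple:
    """Hashable key identifying a family's relationship pattern.

    Two families with identical member ordering of parent links, twin
    grouping and zygosity share the same A and C matrices, so those are
    computed once per signature (twin-register pedigrees repeat a handful
    of configurations thousands of times).
    """
    pos = {i: k for k, i in enumerate(g["individual_id"])}
    fa = tuple(pos.get(p, -1) for p in g["father_id"])
    mo = tuple(pos.get(p, -1) for p in g["mother_id"])
    tg_codes = pd.factorize(g["twin_group"])[0]
    tg = tuple(-1 if v == "0" else int(c)
               for v, c in zip(g["twin_group"], tg_codes))
    return (fa, mo, tg, tuple(g["zygosity"]))


def _topological_order(g: pd.DataFrame) -> list:
    """Indices of g sorted so that parents precede offspring."""
    ids = list(g["individual_id"])
    pos = {i: k for k, i in enumerate(ids)}
    parents = {r.individual_id: [p for p in (r.father_id, r.mother_id)
                                 if p != FOUNDER]
               for r in g.itertuples(index=False)}
    order, placed = [], set()
    pending = list(ids)
    while pending:
        progressed = False
        rest = []
        for i in pending:
            if all(p in placed for p in parents[i]):
                order.append(pos[i])
                placed.add(i)
                progressed = True
            else:
                rest.append(i)
        if not progressed:  # pragma: no cover - caught by validation
            raise PedigreeError("unresolvable parentage ordering")
        pending = rest
    return order


def _family_a_matrix(g: pd.DataFrame) -> np.ndarray:
    """Tabular-method additive relationship matrix for one family."""
    n = len(g)
    ids = list(g["individual_id"])
    pos = {i: k for k, i in enumerate(ids)}
    father = [pos.get(f, -1) if f != FOUNDER else -1 for f in g["father_id"]]
    mother = [pos.get(m, -1) if m != FOUNDER else -1 for m in g["mother_id"]]
    A = np.zeros((n, n))
    for i in _topological_order(g):
        fa, mo = father[i], mother[i]
        # relationship to previously processed individuals
        row = np.zeros(n)
        if fa >= 0:
            row += 0.5 * A[fa]
        if mo >= 0:
            row += 0.5 * A[mo]
        A[i] = row
        A[:, i] = row
        self_a = 1.0
        if fa >= 0 and mo >= 0:
            self_a += 0.5 * A[fa, mo]  # inbreeding term; zero in our families
        A[i, i] = self_a
    # collapse MZ groups to genetic identity
    twins = g[g["zygosity"] == "MZ"]
    for _, grp in twins.groupby("twin_group"):
        rows = [pos[i] for i in grp["individual_id"]]
        ref = A[rows[0]].copy()
        for r in rows:
            A[r] = ref
            A[:, r] = ref
        for r in rows:
            for s in rows:
                A[r, s] = A[rows[0], rows[0]]
    return A


def _family_c_matrix(g: pd.DataFrame) -> np.ndarray:
    """Twin shared-environment indicator: co-twins (MZ and DZ) only."""
    n = len(g)
    C = np.eye(n)
    pos = {i: k for k, i in enumerate(g["individual_id"])}
    twins = g[g["twin_group"] != "0"]
    for _, grp in twins.groupby("twin_group"):
        rows = [pos[i] for i in grp["individual_id"]]
        for r in rows:
            for s in rows:
                C[r, s] = 1.0
    return C


def read_pedigree(path) -> Pedigree:
    """Read and validate a FAM-style pedigree file with twin annotations."""
    return Pedigree.from_fam(path)


def additive_relationship_matrix(ped: Pedigree) -> RelationshipStructure:
    """Relationship structure (A and C per family) for a pedigree."""
    return RelationshipStructure.from_pedigree(ped)


def twin_shared_env_matrix(ped: Pedigree) -> dict:
    """Per-family twin shared-environment indicator matrices."""
    return {fam: _family_c_matrix(g) for fam, g in ped.families().items()}
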