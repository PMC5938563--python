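"""Pedigree container, validation, file IO and link statistics.

A pedigree is a directed acyclic parent->offspring structure over uniquely
identified individuals, each optionally carrying sex, birth year, nest
identity and a plumage-colour score on the seven-point dark-to-light scale
(1 = very dark ... 7 = very light).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "PedigreeError",
    "Individual",
    "Pedigree",
    "LinkCounts",
    "read_pedigree",
    "read_fam",
    "write_pedigree",
    "link_counts",
]

#: tokens normalised to "parent unknown" on input; "0" is emitted on output
MISSING_PARENT_CODES = frozenset({"0", "", "NA", "na", "NaN", "nan", "<NA>", "None"})

STANDARD_COLUMNS = ["id", "sire", "dam", "sex", "birth_year", "nest", "morph7"]

VALID_SEX = frozenset({"M", "F", "U"})


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, ...)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``sire``/``dam`` are ``None`` for unknown parents, ``sex`` is one of
    ``'M'``, ``'F'``, ``'U'`` and ``morph7``, when scored, lies in 1..7.
    """

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "U"
    birth_year: int | None = None
    nest: str | None = None
    morph7: int | None = None


def _norm_token(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    token = str(value).strip()
    return None if token in MISSING_PARENT_CODES else token


class Pedigree:
    """Validated pedigree with individuals stored in topological order.

    Parameters
    ----------
    table
        Frame with at least ``id``, ``sire``, ``dam`` columns. ``sex``
        (M/F/U), ``birth_year``, ``nest`` and ``morph7`` are optional;
        unknown-parent codes ("0", "", "NA") are normalised to missing.
        Extra columns are preserved untouched.

    Input row order never matters: rows are re-sorted so every parent
    precedes its offspring.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = _validate(table)
        self.ids: list[str] = self.table["id"].tolist()
        self.index: dict[str, int] = {v: i for i, v in enumerate(self.ids)}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_individuals(cls, individuals: Iterable[Individual]) -> "Pedigree":
        rows = [vars(ind) for ind in individuals]
        return cls(pd.DataFrame(rows))

    # -- basic structure ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, iid: str) -> bool:
        return iid in self.index

    @property
    def founders(self) -> list[str]:
        """Individuals with both parents unknown."""
        t = self.table
        return t.loc[t["sire"].isna() & t["dam"].isna(), "id"].tolist()

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    def parent_indices(self) -> tuple[list[int], list[int]]:
        """(sire_idx, dam_idx) per individual in topological order, -1 if unknown."""
        sidx = [self.index[s] if isinstance(s, str) else -1 for s in self.table["sire"]]
        didx = [self.index[d] if isinstance(d, str) else -1 for d in self.table["dam"]]
        return sidx, didx

    def phenotyped(self) -> pd.DataFrame:
        """Rows whose morph7 score is recorded."""
        return self.table[self.table["morph7"].notna()]

    def individual(self, iid: str) -> Individual:
        row = self.table.iloc[self.index[iid]]
        return Individual(
            id=row["id"],
            sire=row["sire"] if isinstance(row["sire"], str) else None,
            dam=row["dam"] if isinstance(row["dam"], str) else None,
            sex=row["sex"],
            birth_year=None if pd.isna(row["birth_year"]) else int(row["birth_year"]),
            nest=row["nest"] if isinstance(row["nest"], str) else None,
            morph7=None if pd.isna(row["morph7"]) else int(row["morph7"]),
        )


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    for col in ("id", "sire", "dam"):
        if col not in t.columns:
            raise PedigreeError(f"required column {col!r} missing")
    t["id"] = t["id"].map(_norm_token)
    if t["id"].isna().any():
        raise PedigreeError("empty individual id")
    dup = t["id"][t["id"].duplicated()]
    if len(dup):
        raise PedigreeError(f"duplicate individual id: {dup.iloc[0]!r}")
    for col in ("sire", "dam"):
        t[col] = t[col].map(_norm_token)

    # optional columns, normalised types
    if "sex" in t.columns:
        t["sex"] = t["sex"].map(lambda v: (_norm_token(v) or "U").upper())
        bad = set(t["sex"]) - VALID_SEX
        if bad:
            raise PedigreeError(f"invalid sex code(s): {sorted(bad)} (use M/F/U)")
    else:
        t["sex"] = "U"
    if "birth_year" in t.columns:
        t["birth_year"] = pd.to_numeric(t["birth_year"], errors="coerce").astype("Int64")
    else:
        t["birth_year"] = pd.array([pd.NA] * len(t), dtype="Int64")
    if "nest" in t.columns:
        t["nest"] = t["nest"].map(_norm_token)
    else:
        t["nest"] = None
    if "morph7" in t.columns:
        t["morph7"] = pd.to_numeric(t["morph7"], errors="coerce").astype("Int64")
        scored = t["morph7"].dropna()
        if len(scored) and not scored.between(1, 7).all():
            bad = scored[~scored.between(1, 7)].iloc[0]
            raise PedigreeError(f"morph7 score out of range 1..7: {bad}")
    else:
        t["morph7"] = pd.array([pd.NA] * len(t), dtype="Int64")

    known = set(t["id"])
    for col in ("sire", "dam"):
        refs = t[col].dropna()
        missing = set(refs) - known
        if missing:
            raise PedigreeError(
                f"{col} reference(s) do not resolve: {sorted(missing)[:5]}"
            )

    # sex consistency of parental roles
    sires, dams = set(t["sire"].dropna()), set(t["dam"].dropna())
    both = sires & dams
    if both:
        raise PedigreeError(f"individual(s) used as both sire and dam: {sorted(both)[:5]}")
    sex_of = dict(zip(t["id"], t["sex"]))
    for s in sires:
        if sex_of[s] == "F":
            raise PedigreeError(f"female individual used as sire: {s!r}")
    for d in dams:
        if sex_of[d] == "M":
            raise PedigreeError(f"male individual used as dam: {d!r}")

    # acyclicity + topological order (parents before offspring)
    g = nx.DiGraph()
    g.add_nodes_from(t["id"])
    for _, row in t.iterrows():
        for p in (row["sire"], row["dam"]):
            if isinstance(p, str):
                g.add_edge(p, row["id"])
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise PedigreeError(f"pedigree contains an ancestry cycle: {path}")
    order = list(nx.lexicographical_topological_sort(g))
    rank = {v: i for i, v in enumerate(order)}
    t = t.sort_values("id", key=lambda s: s.map(rank), kind="stable").reset_index(drop=True)

    # put standard columns first, keep extras in original order
    extras = [c for c in t.columns if c not in STANDARD_COLUMNS]
    return t[STANDARD_COLUMNS + extras]


# -- file IO -------------------------------------------------------------------


def read_pedigree(path: str | Path, dialect: Mapping[str, str] | None = None) -> Pedigree:
    """Read a pedigree CSV/TSV (delimiter sniffed from the header line).

    ``dialect`` maps standard column names (``id``, ``sire``, ...) to the
    file's column names when they differ.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if dialect:
        frame = frame.rename(columns={v: k for k, v in dialect.items()})
    return Pedigree(frame)


def read_fam(path: str | Path) -> Pedigree:
    """Read a PLINK ``.fam``-style file (FID and phenotype columns ignored)."""
    frame = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "id", "sire", "dam", "sex_code", "pheno"],
        dtype=str,
    )
    sex = frame["sex_code"].map({"1": "M", "2": "F"}).fillna("U")
    return Pedigree(
        pd.DataFrame({"id": frame["id"], "sire": frame["sire"], "dam": frame["dam"], "sex": sex})
    )


def write_pedigree(ped: Pedigree, path: str | Path, sep: str = ",") -> None:
    """Write the standard pedigree table; missing parents encoded as "0"."""
    t = ped.table.copy()
    for col in ("sire", "dam"):
        t[col] = t[col].fillna("0")
    t.to_csv(path, sep=sep, index=False)


# -- link statistics -----------------------------------------------------------


@dataclass(frozen=True)
class LinkCounts:
    """Pedigree link tallies used to gauge informativeness for quantitative
    genetic analysis. Sibling pairs are unordered and counted once; a pair
    sharing both parents is a full-sib pair only (never also half-sib)."""

    mother_offspring: int
    father_offspring: int
    full_sib: int
    half_sib: int


def _pairs(k: int) -> int:
    return k * (k - 1) // 2


def link_counts(ped: Pedigree) -> LinkCounts:
    """Count parent-offspring links and full-/half-sibling pairs."""
    t = ped.table
    mo = int(t["dam"].notna().sum())
    fo = int(t["sire"].notna().sum())

    both = t[t["sire"].notna() & t["dam"].notna()]
    full = int(sum(_pairs(k) for k in both.groupby(["sire", "dam"]).size()))
    share_sire = int(sum(_pairs(k) for k in t.groupby("sire", dropna=True).size()))
    share_dam = int(sum(_pairs(k) for k in t.groupby("dam", dropna=True).size()))
    half = share_sire + share_dam - 2 * full
    return LinkCounts(mother_offspring=mo, father_offspring=fo, full_sib=full, half_sib=half)
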