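"""Pedigree handling and the additive genetic relationship matrix.

The additive relationship matrix A (twice the kinship matrix) is the
covariance structure of the animal model's breeding values: under purely
additive inheritance, cov(a_i, a_j) = σ²_A · A_ij. It is built with the
tabular method over a pedigree sorted so parents precede offspring:

    A_jj = 1 + 0.5 · A_dam(j),sire(j)
    A_ij = 0.5 · (A_i,dam(j) + A_i,sire(j))    for i processed before j

with an unknown parent contributing 0 (treated as an unrelated,
non-inbred founder).

``permute_parentage`` implements the null-hypothesis pedigree shuffle used
for the heritability permutation test: the multiset of dam–sire pairs (the
pedigree "architecture") is preserved, but pairs are randomly reassigned
to sibships, so sibship sizes are kept while the genetic links between
phenotype and pedigree are broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "read_pedigree",
    "additive_relationship_matrix",
    "permute_parentage",
]

UNKNOWN = ""


def _norm(parent) -> str:
    if parent is None:
        return UNKNOWN
    if isinstance(parent, float) and np.isnan(parent):
        return UNKNOWN
    s = str(parent).strip()
    return UNKNOWN if s.lower() in ("", "na", "nan", "none", "unknown") else s


@dataclass
class Pedigree:
    """A validated, topologically sorted pedigree.

    ``records`` is a list of (id, dam, sire) with ``""`` for unknown
    parents; after ``validate_and_sort`` every named parent has a record
    (auto-added founders) and parents precede their offspring.
    """

    records: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def parents(self) -> dict[str, tuple[str, str]]:
        return {i: (d, s) for i, d, s in self.records}

    def validate_and_sort(self) -> "Pedigree":
        """Return a sorted copy: founders added, cycles rejected.

        Sorting is stable: among individuals with no ordering constraint the
        input order is preserved.
        """
        seen: set[str] = set()
        for i, d, s in self.records:
            if i in seen:
                raise ValueError(f"duplicate id {i!r} in pedigree")
            seen.add(i)
        recs = [(i, _norm(d), _norm(s)) for i, d, s in self.records]
        known = {r[0] for r in recs}
        founders = []
        for _, d, s in recs:
            for p in (d, s):
                if p != UNKNOWN and p not in known:
                    known.add(p)
                    founders.append((p, UNKNOWN, UNKNOWN))
        recs = founders + recs
        graph = nx.DiGraph()
        graph.add_nodes_from(i for i, _, _ in recs)
        for i, d, s in recs:
            for p in (d, s):
                if p != UNKNOWN:
                    graph.add_edge(p, i)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            loop = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise ValueError(f"pedigree contains an ancestry cycle: {loop}")
        order = {i: k for k, i in enumerate(i for i, _, _ in recs)}
        sorted_ids = list(
            nx.lexicographical_topological_sort(graph, key=lambda i: order[i])
        )
        by_id = {i: (d, s) for i, d, s in recs}
        return Pedigree([(i, *by_id[i]) for i in sorted_ids])

    def is_sorted(self) -> bool:
        pos = {i: k for k, (i, _, _) in enumerate(self.records)}
        return all(
            pos.get(p, -1) < pos[i]
            for i, d, s in self.records
            for p in (d, s)
            if p != UNKNOWN and p in pos
        )

    def prune(self, keep_ids) -> "Pedigree":
        """Restrict to ``keep_ids`` plus all of their ancestors."""
        parents = self.parents
        stack = [str(i) for i in keep_ids]
        kept: set[str] = set()
        while stack:
            i = stack.pop()
            if i in kept or i not in parents:
                continue
            kept.add(i)
            stack.extend(p for p in parents[i] if p != UNKNOWN)
        return Pedigree([r for r in self.records if r[0] in kept])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["id", "dam", "sire"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV (columns id, dam, sire; empty cell = unknown)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("id", "dam", "sire"):
        if col not in df.columns:
            raise ValueError(f"pedigree CSV missing column {col!r}")
    ped = Pedigree(list(df[["id", "dam", "sire"]].itertuples(index=False, name=None)))
    return ped.validate_and_sort()


@dataclass
class RelationshipMatrix:
    """Additive relatedness among an ordered set of individuals."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")

    def subset(self, ids) -> "RelationshipMatrix":
        idx = [self.ids.index(str(i)) for i in ids]
        return RelationshipMatrix([str(i) for i in ids], self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def additive_relationship_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Tabular-method A matrix of a sorted pedigree (dense).

    Unknown parents contribute zero relatedness; the diagonal is 1 + F with
    F the individual's inbreeding coefficient.
    """
    if not pedigree.is_sorted():
        raise ValueError("pedigree must be sorted (parents before offspring); "
                         "call validate_and_sort() first")
    ids = pedigree.ids
    index = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    for j, (_, dam, sire) in enumerate(pedigree.records):
        d = index.get(dam, -1)
        s = index.get(sire, -1)
        row = np.zeros(n)
        if d >= 0:
            row += 0.5 * a[d]
        if s >= 0:
            row += 0.5 * a[s]
        a[j, :j] = row[:j]
        a[:j, j] = row[:j]
        a[j, j] = 1.0 + (0.5 * a[d, s] if d >= 0 and s >= 0 else 0.0)
    return RelationshipMatrix(ids, a)


def permute_parentage(
    pedigree: Pedigree,
    offspring_ids,
    seed: int | np.random.Generator,
    max_retries: int = 100,
) -> Pedigree:
    """Randomly reassign dam–sire pairs to sibships, keeping the pair multiset.

    Offspring sharing a dam–sire pair stay together (sibship sizes are
    preserved); the pairs themselves are shuffled across sibships. Results
    violating acyclicity are resampled up to ``max_retries`` times.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offspring = [str(i) for i in offspring_ids]
    parents = pedigree.parents
    unknown = [i for i in offspring if i not in parents]
    if unknown:
        raise ValueError(f"offspring not in pedigree: {unknown}")
    # sibships: offspring grouped by their (dam, sire) pair, in pedigree order
    sibships: dict[tuple[str, str], list[str]] = {}
    for i in offspring:
        sibships.setdefault(parents[i], []).append(i)
    pairs = list(sibships.keys())
    groups = list(sibships.values())
    for _ in range(max_retries):
        perm = rng.permutation(len(pairs))
        new_parent = {
            child: pairs[perm[g]] for g, members in enumerate(groups) for child in members
        }
        records = [
            (i, *(new_parent[i] if i in new_parent else (d, s)))
            for i, d, s in pedigree.records
        ]
        try:
            return Pedigree(records).validate_and_sort()
        except ValueError:
            continue
    raise ValueError("could not find an acyclic parentage permutation")
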