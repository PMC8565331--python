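"""Secondary structures of a bistable RNA and their base-pair conflicts.

A bistable RNA populates two mutually exclusive hairpin folds. This
module represents each fold as a set of base pairs (1-based nucleotide
indices), finds the pairs that cannot coexist because they share a
nucleotide, and enumerates the maximum set of pairs from both folds
that can coexist — the pseudoknotted hybrid candidate for the
refolding transition state.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

__all__ = [
    "BasePair",
    "SecondaryStructure",
    "parse_dotbracket",
    "conflict_graph",
    "mutually_exclusive_pairs",
    "max_compatible_hybrid",
]


@dataclass(frozen=True, order=True)
class BasePair:
    """One base pair, 1-based indices with i < j."""

    i: int
    j: int

    def __post_init__(self):
        if self.i < 1:
            raise ValueError("i must be >= 1")
        if not self.i < self.j:
            raise ValueError("require i < j")

    def shares_nucleotide(self, other: "BasePair") -> bool:
        return bool({self.i, self.j} & {other.i, other.j})


@dataclass
class SecondaryStructure:
    """One fold of the RNA: length, base-pair set, and a fold label."""

    length: int
    pairs: frozenset[BasePair]
    label: str = ""

    def __post_init__(self):
        self.pairs = frozenset(self.pairs)
        seen: set[int] = set()
        for bp in self.pairs:
            if bp.j > self.length:
                raise ValueError(f"pair {bp} exceeds length {self.length}")
            for idx in (bp.i, bp.j):
                if idx in seen:
                    raise ValueError(f"nucleotide {idx} in more than one pair")
                seen.add(idx)

    @classmethod
    def from_pairs(cls, length: int, pairs, label: str = "") -> "SecondaryStructure":
        return cls(length, frozenset(BasePair(i, j) for i, j in pairs), label)

    def sorted_pairs(self) -> list[BasePair]:
        return sorted(self.pairs)


def parse_dotbracket(structure_string: str, label: str = "") -> SecondaryStructure:
    """Parse dot-bracket notation into a :class:`SecondaryStructure`.

    Only ``.``, ``(`` and ``)`` are allowed; brackets must balance.
    Positions are 1-based.
    """
    stack: list[int] = []
    pairs: set[BasePair] = set()
    for pos, ch in enumerate(structure_string, start=1):
        if ch == ".":
            continue
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.add(BasePair(stack.pop(), pos))
        else:
            raise ValueError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(len(structure_string), frozenset(pairs), label)


def conflict_graph(a: SecondaryStructure, b: SecondaryStructure) -> nx.Graph:
    """Graph over the pairs of both folds; edges join pairs sharing a nucleotide.

    Nodes are ``(origin, BasePair)`` tuples with origin "a" or "b", so a
    pair present in both folds appears twice. Conflicts within one fold
    cannot occur (a fold never reuses a nucleotide).
    """
    if a.length != b.length:
        raise ValueError("structures must have equal length")
    g = nx.Graph()
    nodes = [("a", bp) for bp in a.sorted_pairs()] + [("b", bp) for bp in b.sorted_pairs()]
    g.add_nodes_from(nodes)
    for (oa, pa), (ob, pb) in combinations(nodes, 2):
        if oa != ob and pa.shares_nucleotide(pb) and pa != pb:
            g.add_edge((oa, pa), (ob, pb))
    return g


def mutually_exclusive_pairs(a: SecondaryStructure, b: SecondaryStructure):
    """Every (pair_of_a, pair_of_b) that shares at least one nucleotide.

    These are the base pairs that must be broken and re-formed upon
    refolding between the two folds. A pair conflicts with itself, so for
    identical folds every pair appears as (p, p).
    """
    if a.length != b.length:
        raise ValueError("structures must have equal length")
    return {(pa, pb) for pa in a.pairs for pb in b.pairs
            if pa.shares_nucleotide(pb)}


def max_compatible_hybrid(a: SecondaryStructure, b: SecondaryStructure):
    """Maximum set of pairs from both folds with no shared nucleotide.

    This is a maximum independent set in the conflict graph over the
    union of pair sets — the largest pseudoknotted hybrid in which pairs
    of both folds coexist. Pair sets here are small (<= ~24 pairs), so an
    exact branch-and-bound search is used. Among equal-cardinality
    optima the lexicographically smallest sorted pair set is returned.

    Returns ``(pairs, count)`` with ``pairs`` a frozenset of BasePair.
    """
    if a.length != b.length:
        raise ValueError("structures must have equal length")
    universe = sorted(a.pairs | b.pairs)
    n = len(universe)
    conflict = [[universe[i].shares_nucleotide(universe[j]) and i != j
                 for j in range(n)] for i in range(n)]

    best: list[int] = []

    def extend(chosen: list[int], start: int):
        nonlocal best
        if len(chosen) + (n - start) < len(best):
            return  # cannot beat the incumbent
        if start == n:
            if len(chosen) > len(best):
                best = list(chosen)
            return
        # include universe[start] if compatible; trying inclusion first
        # makes the first maximum found the lexicographically smallest.
        if all(not conflict[start][c] for c in chosen):
            chosen.append(start)
            extend(chosen, start + 1)
            chosen.pop()
        extend(chosen, start + 1)

    extend([], 0)
    pairs = frozenset(universe[i] for i in best)
    return pairs, len(pairs)
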