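"""Quartet topologies and the strong/weak support classification.

The distance between the two blocks of a pair, measured separately in each
of the four sequences, is treated as a parsimony character with the four
distances as character states.  A distance multiset {a,a,b,b} (a != b)
*strongly* supports the topology pairing the equal-distance taxa: that
topology explains the states with a single indel event while both
alternatives need two.  A multiset {a,a,b,c} (a,b,c distinct) *weakly*
supports the topology pairing the equal pair: all three topologies cost
two events, but under a simple model where an indel occurs on each branch
with probability p < 0.5 the equal-pair topology is the most likely one.
Everything else is uninformative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Mapping

STRONG = "strong"
WEAK = "weak"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class QuartetTopology:
    """An unrooted resolved tree on four taxa: two cherries {a,b} | {c,d}.

    Stored canonically: taxa sorted within each cherry, cherries sorted.
    Ordering compares the string forms, so taxa of mixed types sort
    deterministically.
    """

    cherry1: tuple
    cherry2: tuple

    def _key(self):
        return (
            tuple(str(t) for t in self.cherry1),
            tuple(str(t) for t in self.cherry2),
        )

    def __lt__(self, other: "QuartetTopology") -> bool:
        return self._key() < other._key()

    @staticmethod
    def of(a, b, c, d) -> "QuartetTopology":
        if len({a, b, c, d}) != 4:
            raise ValueError("quartet taxa must be pairwise distinct")
        c1 = tuple(sorted((a, b), key=str))
        c2 = tuple(sorted((c, d), key=str))
        if tuple(map(str, c2)) < tuple(map(str, c1)):
            c1, c2 = c2, c1
        return QuartetTopology(c1, c2)

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.cherry1) | frozenset(self.cherry2)

    def __str__(self) -> str:
        a, b = self.cherry1
        c, d = self.cherry2
        return f"{a},{b}|{c},{d}"


def enumerate_topologies(taxa) -> list[QuartetTopology]:
    """The three resolved quartet topologies on four distinct taxa."""
    t = list(taxa)
    if len(t) != 4 or len(set(t)) != 4:
        raise ValueError("exactly four distinct taxa required")
    a, b, c, d = t
    return sorted(
        [
            QuartetTopology.of(a, b, c, d),
            QuartetTopology.of(a, c, b, d),
            QuartetTopology.of(a, d, b, c),
        ]
    )


@dataclass(frozen=True)
class SupportCall:
    """Outcome of classifying a 4-distance vector.

    ``kind`` is one of 'strong', 'weak', 'uninformative'; ``topology`` is
    present iff the call is informative.
    """

    kind: str
    topology: QuartetTopology | None = None

    @property
    def informative(self) -> bool:
        return self.kind != UNINFORMATIVE


def classify_support(distances: Mapping[Hashable, int]) -> SupportCall:
    """Classify a taxon -> inter-block-distance map.

    strong  <=> distances form {a,a,b,b} with a != b;
    weak    <=> distances form {a,a,b,c} with a, b, c pairwise distinct;
    uninformative otherwise ({a,a,a,a}, {a,a,a,b}, {a,b,c,d}).
    """
    if len(distances) != 4:
        raise ValueError("exactly four taxa required")
    counts = Counter(distances.values())
    multiplicities = sorted(counts.values(), reverse=True)
    if multiplicities == [2, 2]:
        (v1, _), (v2, _) = counts.most_common()
        g1 = [t for t, d in distances.items() if d == v1]
        g2 = [t for t, d in distances.items() if d == v2]
        return SupportCall(STRONG, QuartetTopology.of(*g1, *g2))
    if multiplicities == [2, 1, 1]:
        pair_val = next(v for v, n in counts.items() if n == 2)
        g1 = [t for t, d in distances.items() if d == pair_val]
        g2 = [t for t, d in distances.items() if d != pair_val]
        return SupportCall(WEAK, QuartetTopology.of(*g1, *g2))
    return SupportCall(UNINFORMATIVE)


def min_indel_events(
    distances: Mapping[Hashable, int], topology: QuartetTopology
) -> int:
    """Minimal number of state changes on the quartet tree with leaf
    states ``distances`` (small parsimony, unbounded integer alphabet).

    Fitch on the two internal nodes of the quartet: each cherry costs one
    change if its two leaf states differ; the internal edge costs one more
    if the cherries' state sets are disjoint.
    """
    if set(distances) != set(topology.taxa):
        raise ValueError("distance taxa do not match topology taxa")
    a, b = topology.cherry1
    c, d = topology.cherry2
    cost = 0
    s1 = {distances[a]} & {distances[b]}
    if not s1:
        cost += 1
        s1 = {distances[a], distances[b]}
    s2 = {distances[c]} & {distances[d]}
    if not s2:
        cost += 1
        s2 = {distances[c], distances[d]}
    if not s1 & s2:
        cost += 1
    return cost


def write_quartet_calls(calls, path, header: str = "") -> None:
    """One line per informative call: 'a,b|c,d<TAB>strong|weak'."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for call in calls:
            if call.informative:
                fh.write(f"{call.topology}\t{call.kind}\n")
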