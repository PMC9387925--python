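"""Evaluation against a reference tree.

Quartet *correctness* is the percentage of informative topology calls that
agree with the quartet induced by the reference tree on the same four
taxa; quartet *coverage* is the percentage of all C(N,4) four-taxon sets
with at least one informative call.  Whole trees are compared with the
Robinson-Foulds distance (symmetric difference of the non-trivial
bipartition sets), normalised by its maximum 2N - 6 for binary trees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import dendropy
from dendropy.calculate import treecompare

from .topology import QuartetTopology, SupportCall
from .trees import _component, _edges, adj_from_tree


def read_newick(source: str | Path, taxon_namespace=None) -> dendropy.Tree:
    """Read an unrooted Newick tree from a file path or a literal string."""
    text = str(source)
    looks_like_newick = "(" in text and ";" in text
    if not looks_like_newick:
        text = Path(source).read_text()
    tree = dendropy.Tree.get(
        data=text, schema="newick", taxon_namespace=taxon_namespace
    )
    tree.is_rooted = False
    return tree


def induced_quartet(tree: dendropy.Tree, taxa) -> QuartetTopology | None:
    """Restriction of a tree to four taxa; ``None`` if it is a star.

    The quartet ab|cd is induced iff some edge of the tree separates
    {a,b} from {c,d}.
    """
    quartet = set(taxa)
    if len(quartet) != 4:
        raise ValueError("exactly four distinct taxa required")
    adj = tree if isinstance(tree, dict) else adj_from_tree(tree)
    leaves = {n for n in adj if not isinstance(n, int)}
    unknown = quartet - leaves
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown, key=str)}")
    for u, v in _edges(adj):
        side = _component(adj, u, banned_edge=(u, v))
        inside = quartet & side
        if len(inside) == 2:
            a, b = sorted(inside, key=str)
            c, d = sorted(quartet - inside, key=str)
            return QuartetTopology.of(a, b, c, d)
    return None


@dataclass
class EvalReport:
    """Summary of an evaluation run against a reference tree."""

    n_informative_pairs: int = 0
    pct_correct_quartets: float = math.nan
    pct_coverage: float = math.nan
    n_unresolved_reference: int = 0
    rf: int | None = None
    nrf: float | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d.update(d.pop("extra"))
        return json.dumps(d, indent=2, default=str)

    def to_tsv(self) -> str:
        d = dict(self.__dict__)
        d.update(d.pop("extra"))
        keys = list(d)
        return (
            "\t".join(keys) + "\n" + "\t".join(str(d[k]) for k in keys) + "\n"
        )


def quartet_accuracy(
    calls, reference: dendropy.Tree, n_taxa: int | None = None
) -> EvalReport:
    """Correctness and coverage of informative quartet calls.

    Each call is counted once (per-pair weighting).  Calls whose induced
    reference quartet is unresolved count as incorrect but are also
    reported separately.  ``n_taxa`` defaults to the reference leaf count.
    """
    adj = adj_from_tree(reference)
    leaves = [n for n in adj if not isinstance(n, int)]
    n = n_taxa if n_taxa is not None else len(leaves)
    topologies = []
    for item in calls:
        if isinstance(item, SupportCall):
            if item.topology is None:
                continue
            topologies.append(item.topology)
        else:
            topologies.append(item)
    covered = {frozenset(t.taxa) for t in topologies}
    total_sets = math.comb(n, 4)
    coverage = 100.0 * len(covered) / total_sets if total_sets else math.nan
    if not topologies:
        return EvalReport(
            n_informative_pairs=0,
            pct_correct_quartets=math.nan,
            pct_coverage=coverage if topologies or total_sets else math.nan,
        )
    correct = 0
    unresolved = 0
    for top in topologies:
        ref = induced_quartet(adj, top.taxa)
        if ref is None:
            unresolved += 1
        elif ref == top:
            correct += 1
    return EvalReport(
        n_informative_pairs=len(topologies),
        pct_correct_quartets=100.0 * correct / len(topologies),
        pct_coverage=coverage,
        n_unresolved_reference=unresolved,
    )


def _common_namespace(
    t1: dendropy.Tree, t2: dendropy.Tree
) -> tuple[dendropy.Tree, dendropy.Tree]:
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=ns
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=ns
    )
    a.is_rooted = False
    b.is_rooted = False
    return a, b


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two trees' non-trivial bipartition sets.  Leaf sets must match."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    a, b = _common_namespace(t1, t2)
    return int(treecompare.symmetric_difference(a, b))


def normalized_rf(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """RF distance divided by its maximum 2N - 6 for binary trees."""
    n = sum(1 for _ in t1.leaf_node_iter())
    if n < 4:
        raise ValueError("at least 4 leaves required")
    return rf_distance(t1, t2) / (2 * n - 6)


def evaluate_tree(
    inferred: dendropy.Tree, reference: dendropy.Tree, calls=None
) -> EvalReport:
    """Full evaluation: RF / normalised RF, plus quartet accuracy when the
    informative calls are provided."""
    if calls is not None:
        report = quartet_accuracy(calls, reference)
    else:
        report = EvalReport()
    report.rf = rf_distance(inferred, reference)
    report.nrf = normalized_rf(inferred, reference)
    return report
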