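"""Tree building from informative block pairs.

Two routes are implemented.  (A) *Quartet amalgamation*: the topology
calls of the informative pairs are combined into a supertree with a
recursive weighted max-cut heuristic (quartets vote for or against each
candidate bipartition of the taxon set); the quartet list can also be
exported for external amalgamation tools.  (B) *Maximum parsimony*: each
informative pair becomes one column of a character matrix over the symbols
'0', '1', '2' (equal inter-block distances get equal symbols; taxa outside
the pair are missing, '-'), and the tree minimising the number of state
changes — i.e. of assumed indel events — is searched either exhaustively
(small taxon sets) or by stepwise addition plus tree-bisection-reconnection
rearrangements.

Unrooted trees are handled internally as adjacency maps whose leaves are
taxon-label strings and whose internal nodes are ints; public functions
accept and return :class:`dendropy.Tree`.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .pairs import BlockPair
from .topology import QuartetTopology, SupportCall, enumerate_topologies

SYMBOLS = "012"
MISSING = "-"
_BITS = {"0": 1, "1": 2, "2": 4, MISSING: 7}


# ---------------------------------------------------------------------------
# character matrix


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x informative-block-pairs matrix over {'0','1','2','-'}.

    ``rows[i]`` is the character string of ``taxa[i]``; all rows have the
    same length (one column per informative block pair).
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        if len(set(len(r) for r in self.rows)) > 1:
            raise ValueError("rows must have equal length")
        for r in self.rows:
            if set(r) - set(SYMBOLS + MISSING):
                raise ValueError(f"invalid symbols in row {r!r}")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> dict[str, str]:
        return {t: r[j] for t, r in zip(self.taxa, self.rows)}


def build_character_matrix(
    pairs: Iterable[BlockPair], taxa: Sequence[str]
) -> CharacterMatrix:
    """Encode informative block pairs as matrix columns.

    Within a column, distances are mapped to symbols in first-seen order
    over the ascending taxon order: first distance -> '0', next new
    distance -> '1', next -> '2'; taxa not involved in the pair get '-'.
    """
    taxa = tuple(taxa)
    cols: list[dict[str, str]] = []
    for pair in pairs:
        if not pair.support.informative:
            raise ValueError("cannot encode an uninformative block pair")
        symbol_of: dict[int, str] = {}
        col: dict[str, str] = {}
        for t in taxa:
            if t not in pair.distances:
                continue
            d = pair.distances[t]
            if d not in symbol_of:
                symbol_of[d] = SYMBOLS[len(symbol_of)]
            col[t] = symbol_of[d]
        if len(col) != 4:
            raise ValueError("block pair involves taxa outside the matrix")
        cols.append(col)
    rows = tuple(
        "".join(col.get(t, MISSING) for col in cols) for t in taxa
    )
    return CharacterMatrix(taxa=taxa, rows=rows)


# ---------------------------------------------------------------------------
# adjacency-map tree utilities

Adj = dict


def _nkey(n):
    return (0, n, "") if isinstance(n, int) else (1, -1, str(n))


def _edges(adj: Adj) -> list[tuple]:
    out = []
    for u in adj:
        for v in adj[u]:
            if _nkey(u) < _nkey(v):
                out.append((u, v))
    return out


def _copy(adj: Adj) -> Adj:
    return {k: list(v) for k, v in adj.items()}


def enumerate_unrooted_trees(taxa: Sequence[str]):
    """Yield every unrooted binary tree topology on the given leaf labels
    (3, 15, 105, 945, 10395, ... trees for 4, 5, 6, 7, 8 leaves)."""
    t = list(taxa)
    if len(t) < 3:
        raise ValueError("need at least 3 leaves")
    base: Adj = {0: [t[0], t[1], t[2]], t[0]: [0], t[1]: [0], t[2]: [0]}

    def extend(adj: Adj, i: int, next_id: int):
        if i == len(t):
            yield adj
            return
        leaf = t[i]
        for u, v in _edges(adj):
            new = _copy(adj)
            m = next_id
            new[u].remove(v)
            new[v].remove(u)
            new[u].append(m)
            new[v].append(m)
            new[m] = [u, v, leaf]
            new[leaf] = [m]
            yield from extend(new, i + 1, next_id + 1)

    yield from extend(base, 3, 1)


def _splits(adj: Adj) -> list[frozenset]:
    """Non-trivial bipartitions, each as the frozenset of the smaller side
    (lexicographic tie-break)."""
    leaves = sorted((n for n in adj if not isinstance(n, int)), key=str)
    out = []
    for u, v in _edges(adj):
        if not (isinstance(u, int) and isinstance(v, int)):
            continue
        side = _component(adj, u, banned_edge=(u, v))
        side_leaves = frozenset(n for n in side if not isinstance(n, int))
        other = frozenset(leaves) - side_leaves
        a, b = sorted([side_leaves, other], key=lambda s: (len(s), sorted(s, key=str)))
        out.append(a)
    return out


def _component(adj: Adj, start, banned_edge=None) -> set:
    seen = {start}
    stack = [start]
    while stack:
        n = stack.pop()
        for nb in adj[n]:
            if banned_edge and {n, nb} == set(banned_edge):
                continue
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def canonical_key(adj: Adj) -> tuple:
    """Deterministic total order on unrooted tree topologies, used to pick
    'the first' among equally parsimonious trees."""
    return tuple(sorted(tuple(sorted(s, key=str)) for s in _splits(adj)))


def adj_to_newick(adj: Adj) -> str:
    internal = [n for n in adj if isinstance(n, int)]
    if not internal:
        # two leaves joined by an edge
        leaves = sorted(adj, key=str)
        return f"({leaves[0]},{leaves[1]});"
    root = min(internal)

    def sub(node, parent) -> str:
        if not isinstance(node, int):
            return str(node)
        parts = [sub(nb, node) for nb in adj[node] if nb != parent]
        return "(" + ",".join(parts) + ")"

    parts = [sub(nb, root) for nb in adj[root]]
    return "(" + ",".join(parts) + ");"


def tree_from_adj(adj: Adj, taxon_namespace=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=adj_to_newick(adj),
        schema="newick",
        taxon_namespace=taxon_namespace,
    )


def adj_from_tree(tree: dendropy.Tree) -> Adj:
    """Adjacency map of a dendropy tree; a bifurcating root is suppressed
    so the result is the underlying unrooted tree."""
    adj: Adj = {}
    key_of = {}
    next_id = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            key_of[node] = node.taxon.label if node.taxon else str(node)
        else:
            key_of[node] = next_id
            next_id += 1
        adj[key_of[node]] = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            adj[key_of[node]].append(key_of[child])
            adj[key_of[child]].append(key_of[node])
    # suppress degree-2 nodes (e.g. a rooted tree's root)
    for n in [k for k in adj if isinstance(k, int)]:
        if len(adj[n]) == 2:
            a, b = adj[n]
            adj[a].remove(n)
            adj[b].remove(n)
            adj[a].append(b)
            adj[b].append(a)
            del adj[n]
    return adj


# ---------------------------------------------------------------------------
# Fitch small parsimony


def _leaf_bits(matrix: CharacterMatrix) -> dict[str, np.ndarray]:
    return {
        t: np.array([_BITS[c] for c in row], dtype=np.uint8)
        for t, row in zip(matrix.taxa, matrix.rows)
    }


def _fitch_changes(adj: Adj, leaf_bits: dict, ncols: int) -> np.ndarray:
    """Per-column minimal state changes by Fitch, rooting the unrooted tree
    along an arbitrary leaf edge.  Exact for fully resolved (binary) trees;
    missing leaves carry the full state set."""
    full = np.full(ncols, 7, dtype=np.uint8)
    leaves = sorted((n for n in adj if not isinstance(n, int)), key=str)
    l0 = leaves[0]
    if len(adj) == 2:  # single edge between two leaves
        a = leaf_bits.get(leaves[0], full)
        b = leaf_bits.get(leaves[1], full)
        return ((a & b) == 0).astype(np.int64)
    root = adj[l0][0]
    order = []
    stack = [(root, l0)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        if isinstance(node, int):
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node))
    changes = np.zeros(ncols, dtype=np.int64)
    state: dict = {}
    for node, parent in reversed(order):
        if not isinstance(node, int):
            state[node] = leaf_bits.get(node, full)
            continue
        st = None
        for nb in adj[node]:
            if nb == parent:
                continue
            cs = state[nb]
            if st is None:
                st = cs
            else:
                inter = st & cs
                empty = inter == 0
                changes += empty
                st = np.where(empty, st | cs, inter)
        state[node] = st
    inter = state[root] & leaf_bits.get(l0, full)
    changes += inter == 0
    return changes


def parsimony_score(tree, matrix: CharacterMatrix) -> int:
    """Total Fitch parsimony score of a tree for a character matrix.

    '-' cells impose no constraint (missing information).  The tree's leaf
    set must contain every matrix taxon; extra leaves count as missing.
    Accepts a dendropy.Tree or an internal adjacency map.
    """
    adj = tree if isinstance(tree, dict) else adj_from_tree(tree)
    leaves = {n for n in adj if not isinstance(n, int)}
    missing = set(matrix.taxa) - leaves
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")
    if matrix.ncols == 0:
        return 0
    return int(_fitch_changes(adj, _leaf_bits(matrix), matrix.ncols).sum())


# ---------------------------------------------------------------------------
# parsimony tree search


def _tbr_neighbours(adj: Adj):
    """Trees one tree-bisection-reconnection move away (includes leaf SPR
    as the degenerate case of a single-node component)."""
    next_id = max((n for n in adj if isinstance(n, int)), default=-1) + 1
    for u, v in _edges(adj):
        comp_u = _component(adj, u, banned_edge=(u, v))
        comp_v = set(adj) - comp_u
        pruned = _copy(adj)
        pruned[u].remove(v)
        pruned[v].remove(u)
        for endpoint in (u, v):
            if isinstance(endpoint, int) and len(pruned[endpoint]) == 2:
                a, b = pruned[endpoint]
                pruned[a].remove(endpoint)
                pruned[b].remove(endpoint)
                pruned[a].append(b)
                pruned[b].append(a)
                del pruned[endpoint]

        def attach_points(comp):
            nodes = [n for n in comp if n in pruned]
            if len(nodes) == 1:
                return [nodes[0]]
            return [
                (a, b)
                for a, b in _edges(pruned)
                if a in comp and b in comp
            ]

        for p1 in attach_points(comp_u):
            for p2 in attach_points(comp_v):
                new = _copy(pruned)
                nid = next_id
                ends = []
                for p in (p1, p2):
                    if isinstance(p, tuple):
                        a, b = p
                        m = nid
                        nid += 1
                        new[a].remove(b)
                        new[b].remove(a)
                        new[a].append(m)
                        new[b].append(m)
                        new[m] = [a, b]
                        ends.append(m)
                    else:
                        ends.append(p)
                e1, e2 = ends
                new[e1].append(e2)
                new[e2].append(e1)
                yield new


def _stepwise_addition(taxa: Sequence[str], score_fn) -> Adj:
    t = list(taxa)
    adj: Adj = {0: [t[0], t[1], t[2]], t[0]: [0], t[1]: [0], t[2]: [0]}
    next_id = 1
    for leaf in t[3:]:
        best = None
        for u, v in _edges(adj):
            new = _copy(adj)
            m = next_id
            new[u].remove(v)
            new[v].remove(u)
            new[u].append(m)
            new[v].append(m)
            new[m] = [u, v, leaf]
            new[leaf] = [m]
            cand = (score_fn(new), canonical_key(new), new)
            if best is None or cand[:2] < best[:2]:
                best = cand
        adj = best[2]
        next_id += 1
    return adj


def search_parsimony_tree(
    matrix: CharacterMatrix,
    mode: str = "auto",
    rng_seed: int = 0,
    n_starts: int = 4,
) -> dendropy.Tree:
    """Most-parsimonious unrooted tree for a character matrix.

    ``mode='exhaustive'`` scores every unrooted topology (feasible up to 8
    taxa); ``mode='heuristic'`` uses stepwise addition followed by
    tree-bisection-reconnection hill climbing from ``n_starts`` seeded
    addition orders.  ``mode='auto'`` picks exhaustive for <= 8 taxa.
    Among equally parsimonious trees the one with the smallest canonical
    split representation is returned.
    """
    taxa = matrix.taxa
    if len(taxa) < 4:
        raise ValueError("at least 4 taxa required")
    bits = _leaf_bits(matrix)
    ncols = matrix.ncols

    def score(adj: Adj) -> int:
        if ncols == 0:
            return 0
        return int(_fitch_changes(adj, bits, ncols).sum())

    if mode == "auto":
        mode = "exhaustive" if len(taxa) <= 8 else "heuristic"
    if mode == "exhaustive":
        best = None
        for adj in enumerate_unrooted_trees(taxa):
            s = score(adj)
            if best is None or s < best[0]:
                best = (s, canonical_key(adj), adj)
            elif s == best[0]:
                key = canonical_key(adj)
                if key < best[1]:
                    best = (s, key, adj)
        return tree_from_adj(best[2])
    if mode != "heuristic":
        raise ValueError(f"unknown mode: {mode}")

    rng = np.random.default_rng(rng_seed)
    best = None
    for start in range(max(1, n_starts)):
        order = list(taxa)
        if start > 0:
            rng.shuffle(order)
        adj = _stepwise_addition(order, score)
        current = (score(adj), canonical_key(adj), adj)
        improved = True
        while improved:
            improved = False
            for nb in _tbr_neighbours(current[2]):
                s = score(nb)
                if s < current[0]:
                    current = (s, canonical_key(nb), nb)
                    improved = True
                    break
                if s == current[0]:
                    key = canonical_key(nb)
                    if key < current[1]:
                        current = (s, key, nb)
        if best is None or current[:2] < best[:2]:
            best = current
    return tree_from_adj(best[2])


# ---------------------------------------------------------------------------
# quartet amalgamation (weighted max-cut supertree)


def _normalise_calls(calls) -> Counter:
    weights: Counter = Counter()
    for item in calls:
        if isinstance(item, QuartetTopology):
            weights[item] += 1
        elif isinstance(item, SupportCall):
            if item.topology is None:
                raise ValueError("uninformative call has no topology")
            weights[item.topology] += 1
        else:
            top, w = item
            weights[top] += w
    return weights


def _cut_score(weights: Counter, side: dict) -> int:
    """Quartets vote on a bipartition: +w when both cherries are intact and
    separated by the cut, -w for every cherry the cut splits."""
    score = 0
    for top, w in weights.items():
        a, b = top.cherry1
        c, d = top.cherry2
        split1 = side[a] != side[b]
        split2 = side[c] != side[d]
        if split1:
            score -= w
        if split2:
            score -= w
        if not split1 and not split2 and side[a] != side[c]:
            score += w
    return score


def _best_cut(taxa: list, weights: Counter, rng) -> tuple[set, set]:
    """Best bipartition with both sides of size >= 2 (so the recursion on
    each side, which carries one placeholder leaf, strictly shrinks)."""
    n = len(taxa)
    if n <= 16:
        best = None
        for bits in range(1, 2 ** (n - 1)):
            size_b = bits.bit_count()
            if size_b < 2 or n - size_b < 2:
                continue
            side = {taxa[0]: 0}
            for i, t in enumerate(taxa[1:]):
                side[t] = (bits >> i) & 1
            s = _cut_score(weights, side)
            if best is None or s > best[0]:
                best = (s, side)
        side = best[1]
    else:
        best = None
        for _ in range(8):
            assign = rng.integers(0, 2, size=n)
            assign[:2] = [0, 1]  # both sides non-empty
            assign[2:4] = [0, 1]
            side = {t: int(a) for t, a in zip(taxa, assign)}
            s = _cut_score(weights, side)
            improved = True
            while improved:
                improved = False
                for t in taxa:
                    counts = Counter(side.values())
                    if counts[side[t]] <= 2:
                        continue  # keep both sides >= 2
                    side[t] = 1 - side[t]
                    s2 = _cut_score(weights, side)
                    if s2 > s:
                        s = s2
                        improved = True
                    else:
                        side[t] = 1 - side[t]
            if best is None or s > best[0]:
                best = (s, dict(side))
        side = best[1]
    A = {t for t, v in side.items() if v == 0}
    B = {t for t, v in side.items() if v == 1}
    return A, B


class _Rep:
    """Placeholder leaf standing in for everything on the other side of a
    cut while a side is resolved recursively."""

    _count = itertools.count()

    def __init__(self):
        self.n = next(self._count)

    def __repr__(self):
        return f"<rep{self.n}>"

    def __lt__(self, other):
        return str(self) < str(other)


def _restrict_calls(weights: Counter, side: set, rep) -> Counter:
    out: Counter = Counter()
    for top, w in weights.items():
        inside = [t for t in top.taxa if t in side]
        if len(inside) == 4:
            out[top] += w
        elif len(inside) == 3:
            outside = next(t for t in top.taxa if t not in side)
            a, b = top.cherry1
            c, d = top.cherry2
            sub = {outside: rep}
            mapped = QuartetTopology.of(
                sub.get(a, a), sub.get(b, b), sub.get(c, c), sub.get(d, d)
            )
            out[mapped] += w
    return out


def _build_supertree(taxa: list, weights: Counter, rng, next_id: list) -> Adj:
    n = len(taxa)
    if n == 2:
        a, b = taxa
        return {a: [b], b: [a]}
    if n == 3:
        m = next_id[0]
        next_id[0] += 1
        return {m: list(taxa), taxa[0]: [m], taxa[1]: [m], taxa[2]: [m]}
    if n == 4:
        local = Counter(
            {t: w for t, w in weights.items() if t.taxa == frozenset(taxa)}
        )
        if local:
            top_w = max(local.values())
            top = min(t for t, w in local.items() if w == top_w)
        else:
            top = enumerate_topologies(taxa)[0]
        m1, m2 = next_id[0], next_id[0] + 1
        next_id[0] += 2
        a, b = top.cherry1
        c, d = top.cherry2
        return {
            m1: [a, b, m2],
            m2: [c, d, m1],
            a: [m1],
            b: [m1],
            c: [m2],
            d: [m2],
        }
    A, B = _best_cut(taxa, weights, rng)
    rep_b, rep_a = _Rep(), _Rep()
    adj_a = _build_supertree(
        sorted(A, key=str) + [rep_b], _restrict_calls(weights, A, rep_b), rng, next_id
    )
    adj_b = _build_supertree(
        sorted(B, key=str) + [rep_a], _restrict_calls(weights, B, rep_a), rng, next_id
    )
    pa = adj_a[rep_b][0]
    pb = adj_b[rep_a][0]
    adj_a[pa].remove(rep_b)
    del adj_a[rep_b]
    adj_b[pb].remove(rep_a)
    del adj_b[rep_a]
    adj_a.update(adj_b)
    adj_a[pa].append(pb)
    adj_a[pb].append(pa)
    return adj_a


def quartet_supertree(calls, rng_seed: int = 0) -> dendropy.Tree:
    """Amalgamate weighted quartet topology calls into one unrooted tree.

    Recursive weighted max-cut: the taxon set is bipartitioned by the cut
    that best agrees with the quartets (exhaustively for small taxon sets,
    by seeded local search otherwise), each side is resolved recursively
    with a placeholder leaf representing the other side, and the two parts
    are joined.  On a conflict-free, fully covering quartet set the result
    displays every input quartet.
    """
    weights = _normalise_calls(calls)
    taxa = sorted({t for top in weights for t in top.taxa}, key=str)
    if len(taxa) < 4:
        raise ValueError("at least 4 taxa required")
    rng = np.random.default_rng(rng_seed)
    adj = _build_supertree(taxa, weights, rng, next_id=[0])
    return tree_from_adj(adj)


# ---------------------------------------------------------------------------
# exporters / parsers


def export_quartets(calls) -> str:
    """Quartet-list text: one 'a,b|c,d' record per call, repeated by
    multiplicity (the input format of external quartet amalgamation
    tools)."""
    weights = _normalise_calls(calls)
    lines = []
    for top in sorted(weights):
        lines.extend([str(top)] * weights[top])
    return "\n".join(lines) + ("\n" if lines else "")


def parse_quartets(text: str) -> list[tuple[QuartetTopology, int]]:
    weights: Counter = Counter()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        line = line.split()[0]  # tolerate a trailing support-class column
        left, right = line.split("|")
        a, b = left.split(",")
        c, d = right.split(",")
        weights[QuartetTopology.of(a, b, c, d)] += 1
    return sorted(weights.items())


def export_matrix_phylip(matrix: CharacterMatrix) -> str:
    """Relaxed PHYLIP: header 'N ncols', then 'name<space>row' lines."""
    lines = [f"{len(matrix.taxa)} {matrix.ncols}"]
    width = max((len(t) for t in matrix.taxa), default=0) + 2
    for t, r in zip(matrix.taxa, matrix.rows):
        lines.append(f"{t:<{width}}{r}")
    return "\n".join(lines) + "\n"


def parse_matrix_phylip(text: str) -> CharacterMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n, ncols = (int(x) for x in lines[0].split())
    taxa, rows = [], []
    for ln in lines[1 : n + 1]:
        name, row = ln.split(None, 1)
        row = row.strip()
        if len(row) != ncols:
            raise ValueError("row length does not match header")
        taxa.append(name)
        rows.append(row)
    return CharacterMatrix(taxa=tuple(taxa), rows=tuple(rows))


def export_matrix_nexus(matrix: CharacterMatrix) -> str:
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.ncols};",
        f'  FORMAT SYMBOLS="{SYMBOLS}" MISSING={MISSING};',
        "  MATRIX",
    ]
    width = max((len(t) for t in matrix.taxa), default=0) + 2
    for t, r in zip(matrix.taxa, matrix.rows):
        lines.append(f"    {t:<{width}}{r}")
    lines += ["  ;", "END;"]
    return "\n".join(lines) + "\n"


def parse_matrix_nexus(text: str) -> CharacterMatrix:
    taxa, rows = [], []
    in_matrix = False
    for line in text.splitlines():
        s = line.strip()
        if s.upper() == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if s == ";" or s.upper().startswith("END"):
                break
            if s:
                name, row = s.split(None, 1)
                taxa.append(name)
                rows.append(row.strip())
    return CharacterMatrix(taxa=tuple(taxa), rows=tuple(rows))
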