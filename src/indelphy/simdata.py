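"""Synthetic sequence evolution with substitutions and indels.

Sequences are evolved along a known tree so that pairs of quartet blocks
with differing inter-block distances arise, and every pipeline stage can
be tested against a known truth.  Substitutions follow the Jukes-Cantor
model (branch lengths are expected substitutions per site); insertions and
deletions occur as a Poisson process along each branch with geometrically
distributed lengths, equiprobable direction, and uniform positions.  Every
indel is recorded in an event log so tests can trace informative block
pairs back to planted events.

The generator emulates neutrally evolving homologous sequences of
desk-scale size; it does not model rearrangements, duplications,
rate heterogeneity or base-composition bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .blocks import SequenceSet
from .patterns import ALPHABET
from .trees import CharacterMatrix
from .topology import QuartetTopology


def balanced_tree_newick(n_leaves: int = 8, branch_length: float = 0.01) -> str:
    """Newick for a balanced binary tree on A, B, C, ... with uniform
    branch lengths (expected substitutions per site)."""
    if n_leaves < 4 or n_leaves & (n_leaves - 1):
        raise ValueError("n_leaves must be a power of two >= 4")
    labels = [chr(ord("A") + i) for i in range(n_leaves)]

    def join(group):
        if len(group) == 1:
            return f"{group[0]}:{branch_length}"
        half = len(group) // 2
        return (
            f"({join(group[:half])},{join(group[half:])}):{branch_length}"
        )

    half = n_leaves // 2
    return f"({join(labels[:half])},{join(labels[half:])});"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation run.

    ``tree`` is a Newick string with branch lengths in expected
    substitutions per site; ``indel_rate`` is the expected number of indel
    events per site per unit branch length; indel lengths are geometric
    with mean ``indel_mean_length`` (so q = 1/mean); insertions and
    deletions are equiprobable.
    """

    tree: str = balanced_tree_newick()
    root_length: int = 50_000
    indel_rate: float = 0.05
    indel_mean_length: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if not 0 < 1.0 / self.indel_mean_length <= 1:
            raise ValueError("indel_mean_length must be >= 1")


@dataclass(frozen=True)
class IndelEvent:
    """One planted insertion or deletion."""

    branch: str  # label of the child node of the branch
    kind: str  # 'ins' or 'del'
    pos: int  # 0-based position in the child's coordinates at event time
    length: int


@dataclass
class SimResult:
    sequences: SequenceSet
    events: list[IndelEvent]
    tree: dendropy.Tree
    config: SimConfig = field(repr=False, default=None)


def _evolve_branch(
    seq: np.ndarray, t: float, cfg: SimConfig, rng: np.random.Generator, label: str
) -> tuple[np.ndarray, list[IndelEvent]]:
    events: list[IndelEvent] = []
    # Jukes-Cantor: per-site substitution probability for branch length t
    p_sub = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    if p_sub > 0 and len(seq):
        mask = rng.random(len(seq)) < p_sub
        n_hit = int(mask.sum())
        if n_hit:
            seq = seq.copy()
            seq[mask] = (seq[mask] + rng.integers(1, 4, size=n_hit)) % 4
    n_indels = rng.poisson(cfg.indel_rate * t * len(seq)) if len(seq) else 0
    for _ in range(n_indels):
        length = int(rng.geometric(1.0 / cfg.indel_mean_length))
        if rng.random() < 0.5 and len(seq) > length:
            pos = int(rng.integers(0, len(seq) - length + 1))
            seq = np.concatenate([seq[:pos], seq[pos + length :]])
            events.append(IndelEvent(label, "del", pos, length))
        else:
            pos = int(rng.integers(0, len(seq) + 1))
            insert = rng.integers(0, 4, size=length).astype(seq.dtype)
            seq = np.concatenate([seq[:pos], insert, seq[pos:]])
            events.append(IndelEvent(label, "ins", pos, length))
    return seq, events


def simulate(config: SimConfig) -> SimResult:
    """Evolve sequences along ``config.tree`` from a random root sequence.

    Reproducible for a fixed seed: same config -> byte-identical output.
    With zero branch lengths and zero indel rate all leaves equal the
    root.
    """
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    root_seq = rng.integers(0, 4, size=config.root_length).astype(np.uint8)
    seqs: dict[str, np.ndarray] = {}
    events: list[IndelEvent] = []
    n_internal = 0
    state = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.is_leaf():
            label = node.taxon.label
        else:
            label = f"node{n_internal}"
            n_internal += 1
        t = node.edge.length or 0.0
        child_seq, ev = _evolve_branch(
            state[id(node.parent_node)], t, config, rng, label
        )
        state[id(node)] = child_seq
        events.extend(ev)
        if node.is_leaf():
            seqs[label] = child_seq
    ids = sorted(seqs)
    strings = ["".join(ALPHABET[c] for c in seqs[i]) for i in ids]
    return SimResult(
        sequences=SequenceSet(ids=ids, seqs=strings),
        events=events,
        tree=tree,
        config=config,
    )


def write_events_tsv(events: list[IndelEvent], path: str | Path, header="") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("branch\tkind\tpos\tlength\n")
        for e in events:
            fh.write(f"{e.branch}\t{e.kind}\t{e.pos}\t{e.length}\n")


# ---------------------------------------------------------------------------
# toy worked-example fixtures


def _toy_sequences(
    taxa: list[str], gaps: dict[str, int], prefixes: dict[str, str]
) -> SequenceSet:
    """Four sequences sharing a 4-nt first block (pattern 1101, spaced word
    A G * C) and a unique downstream 7-mer, separated by per-taxon filler
    segments whose lengths are the wanted inter-block distances.  Fillers
    use taxon-specific content so that no word crossing a filler boundary
    is shared by all four sequences: the first common unique word is the
    second block itself."""
    block1 = "AGTC"  # matches pattern 1101 as spaced word AG*C
    block2 = "CAGTACG"
    filler_units = ["AC", "GA", "CT", "TG"]
    seqs = []
    for i, t in enumerate(taxa):
        g = gaps[t]
        filler = (filler_units[i] * (g // 2 + 1))[:g]
        seqs.append(prefixes[t] + block1 + filler + block2 + "GA")
    return SequenceSet(ids=list(taxa), seqs=seqs)


def paper_fixtures() -> dict:
    """Programmatic reconstructions of the worked toy examples.

    - ``fig3``: a strongly supporting block-pair geometry (pattern 1101,
      distances 2, 3, 2, 3 in S2, S4, S5, S8 -> topology S2,S5|S4,S8).
    - ``fig4``: a weakly supporting geometry (distances 2, 2, 3, 4 in
      S1, S4, S5, S6 -> topology S1,S4|S5,S6).
    - ``fig5``: the 6-taxon, 4-column character matrix built from four
      strongly supported quartets (S1,S2|S3,S6; S3,S6|S4,S5;
      S1,S6|S4,S5; S1,S4|S2,S5), two missing cells per column.
    """
    fig3_taxa = ["S2", "S4", "S5", "S8"]
    fig3_gaps = {"S2": 2, "S4": 3, "S5": 2, "S8": 3}
    fig3_prefixes = {"S2": "GG", "S4": "G", "S5": "GGG", "S8": ""}
    fig4_taxa = ["S1", "S4", "S5", "S6"]
    fig4_gaps = {"S1": 2, "S4": 2, "S5": 3, "S6": 4}
    fig4_prefixes = {"S1": "G", "S4": "GG", "S5": "G", "S6": "GG"}

    fig5_quartets = [
        (QuartetTopology.of("S1", "S2", "S3", "S6"), (2, 5)),
        (QuartetTopology.of("S3", "S6", "S4", "S5"), (4, 7)),
        (QuartetTopology.of("S1", "S6", "S4", "S5"), (3, 8)),
        (QuartetTopology.of("S1", "S4", "S2", "S5"), (6, 9)),
    ]
    taxa6 = tuple(f"S{i}" for i in range(1, 7))
    cols = []
    for top, (d_pair, d_other) in fig5_quartets:
        dist = {t: d_pair for t in top.cherry1}
        dist.update({t: d_other for t in top.cherry2})
        symbol_of: dict[int, str] = {}
        col = {}
        for t in taxa6:
            if t in dist:
                if dist[t] not in symbol_of:
                    symbol_of[dist[t]] = "012"[len(symbol_of)]
                col[t] = symbol_of[dist[t]]
        cols.append(col)
    rows = tuple("".join(c.get(t, "-") for c in cols) for t in taxa6)
    fig5_matrix = CharacterMatrix(taxa=taxa6, rows=rows)

    return {
        "fig3": {
            "sequences": _toy_sequences(fig3_taxa, fig3_gaps, fig3_prefixes),
            "pattern1": "1101",
            "distances": fig3_gaps,
            "topology": QuartetTopology.of("S2", "S5", "S4", "S8"),
        },
        "fig4": {
            "sequences": _toy_sequences(fig4_taxa, fig4_gaps, fig4_prefixes),
            "pattern1": "1101",
            "distances": fig4_gaps,
            "topology": QuartetTopology.of("S1", "S4", "S5", "S6"),
        },
        "fig5": {
            "matrix": fig5_matrix,
            "quartets": [t for t, _ in fig5_quartets],
        },
    }
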