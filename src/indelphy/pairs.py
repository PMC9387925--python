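"""Block pairs: a reference block plus a downstream second block.

For each reference quartet block B1, a second block B2 involving the same
four sequences is searched in a window of L nucleotides to the right of B1
in each sequence.  The second block is the leftmost spaced word (w.r.t. a
second pattern, by default seven contiguous match positions) that occurs
exactly once in each of the four windows; no similarity score is applied
to it, since a chance quartet block inside such small windows is unlikely.

The phylogenetic signal is the vector of inter-block distances
``D = start(B2) - start(B1) - len(P1)`` per sequence: the length of the
segment between the two blocks.  Differing distances hint at indels since
the four sequences diverged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import QuartetBlock, SequenceSet, _code_to_word, _window_codes
from .patterns import Pattern, SpacedWordOccurrence, second_block_pattern
from .topology import SupportCall, classify_support


@dataclass(frozen=True)
class BlockPair:
    """A reference block, its second block and the four distances D."""

    b1: QuartetBlock
    b2: QuartetBlock
    distances: dict  # taxon id -> D (non-negative int), ascending taxon index
    support: SupportCall

    def distance_vector(self) -> tuple[int, ...]:
        return tuple(self.distances.values())


class _SecondBlockIndex:
    """Per-sequence packed word codes for the second-block pattern."""

    def __init__(self, seqs: SequenceSet, pattern2: Pattern):
        self.pattern2 = pattern2
        self.codes = []
        self.valid = []
        for enc in seqs.encoded:
            codes, valid = _window_codes(enc, pattern2)
            self.codes.append(codes)
            self.valid.append(valid)


def find_second_block(
    b1: QuartetBlock,
    seqs: SequenceSet,
    pattern2: Pattern | None = None,
    L: int = 500,
    _index: _SecondBlockIndex | None = None,
) -> QuartetBlock | None:
    """Find the second block for a reference block, or ``None``.

    The search window in each sequence starts at the first position after
    the last pattern position of B1 and spans ``L`` nucleotides (clipped
    at the sequence end).  Candidate words must occur exactly once in each
    of the four windows; among candidates, the one with the smallest start
    position in B1's anchor sequence wins, ties broken by lexicographic
    word order.
    """
    pattern2 = pattern2 or second_block_pattern()
    idx = _index or _SecondBlockIndex(seqs, pattern2)
    uniq_codes: list[np.ndarray] = []
    uniq_pos: list[np.ndarray] = []
    for occ in b1.occs:
        start = occ.pos + b1.pattern_length
        codes_all = idx.codes[occ.seq_id]
        end = min(start + L, len(codes_all))
        if start >= end:
            return None
        valid = idx.valid[occ.seq_id][start:end]
        codes = codes_all[start:end][valid]
        if codes.size == 0:
            return None
        uniq, first, counts = np.unique(codes, return_index=True, return_counts=True)
        once = counts == 1
        offsets = np.flatnonzero(valid)
        uniq_codes.append(uniq[once])
        uniq_pos.append(start + offsets[first[once]])
    common = uniq_codes[0]
    for u in uniq_codes[1:]:
        common = np.intersect1d(common, u, assume_unique=True)
        if common.size == 0:
            return None
    anchor_pos = uniq_pos[b1.anchor_index][
        np.searchsorted(uniq_codes[b1.anchor_index], common)
    ]
    pick = np.lexsort((common, anchor_pos))[0]
    best = int(common[pick])
    word = _code_to_word(best, pattern2.weight)
    occs = tuple(
        SpacedWordOccurrence(
            seq_id=o.seq_id,
            pos=int(uniq_pos[i][np.searchsorted(uniq_codes[i], best)]),
            word=word,
        )
        for i, o in enumerate(b1.occs)
    )
    return QuartetBlock(
        word=word,
        occs=occs,
        anchor_index=b1.anchor_index,
        scores=None,
        pattern_length=pattern2.length,
    )


def block_distances(
    b1: QuartetBlock, b2: QuartetBlock, seqs: SequenceSet
) -> dict[str, int]:
    """Inter-block distances D per taxon, in ascending sequence order.

    ``D = start(B2) - start(B1) - len(P1)``: the length of the segment
    between the blocks.  Negative distances (overlap) are rejected.
    """
    if tuple(o.seq_id for o in b1.occs) != tuple(o.seq_id for o in b2.occs):
        raise ValueError("block pair must involve the same four sequences")
    out = {}
    for o1, o2 in zip(b1.occs, b2.occs):
        d = o2.pos - o1.pos - b1.pattern_length
        if d < 0:
            raise ValueError("second block overlaps the reference block")
        out[seqs.ids[o1.seq_id]] = d
    return out


@dataclass
class PairStats:
    """Counts of reference blocks by pairing outcome."""

    n_reference: int = 0
    n_no_second_block: int = 0
    n_uninformative: int = 0
    n_strong: int = 0
    n_weak: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def collect_block_pairs(
    blocks: list[QuartetBlock],
    seqs: SequenceSet,
    pattern2: Pattern | None = None,
    L: int = 500,
    stats: PairStats | None = None,
) -> list[BlockPair]:
    """Pair every reference block with its second block and keep the
    informative pairs (strong or weak support); the rest are discarded."""
    pattern2 = pattern2 or second_block_pattern()
    idx = _SecondBlockIndex(seqs, pattern2)
    stats = stats if stats is not None else PairStats()
    pairs: list[BlockPair] = []
    for b1 in blocks:
        stats.n_reference += 1
        b2 = find_second_block(b1, seqs, pattern2, L, _index=idx)
        if b2 is None:
            stats.n_no_second_block += 1
            continue
        dist = block_distances(b1, b2, seqs)
        call = classify_support(dist)
        if not call.informative:
            stats.n_uninformative += 1
            continue
        if call.kind == "strong":
            stats.n_strong += 1
        else:
            stats.n_weak += 1
        pairs.append(BlockPair(b1=b1, b2=b2, distances=dist, support=call))
    return pairs


def write_pairs_tsv(pairs: list[BlockPair], seqs: SequenceSet, path, header="") -> None:
    """TSV listing: taxa, 1-based positions of both blocks, D vector,
    support class and topology."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("taxa\tpos_b1\tpos_b2\tdistances\tsupport\ttopology\n")
        for p in pairs:
            taxa = ",".join(seqs.ids[o.seq_id] for o in p.b1.occs)
            pos1 = ",".join(str(o.pos + 1) for o in p.b1.occs)
            pos2 = ",".join(str(o.pos + 1) for o in p.b2.occs)
            dvec = ",".join(str(d) for d in p.distances.values())
            fh.write(
                f"{taxa}\t{pos1}\t{pos2}\t{dvec}\t{p.support.kind}\t{p.support.topology}\n"
            )
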