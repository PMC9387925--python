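"""Quartet-block discovery: one spaced word occurring in four sequences.

A *quartet block* is a set of four occurrences of the same spaced word in
four pairwise-distinct sequences — a local, gap-free four-way alignment.
To exclude random matches, one occurrence acts as the *anchor*: the other
three must have strictly positive don't-care similarity scores against it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .patterns import (
    ALPHABET,
    Pattern,
    SpacedWordOccurrence,
    SubstitutionMatrix,
    encode_sequence,
)


@dataclass
class SequenceSet:
    """N >= 4 named nucleotide sequences (one record per taxon)."""

    ids: list[str]
    seqs: list[str]
    encoded: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(self.ids) < 4:
            raise ValueError("at least 4 sequences are required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxon ids in input")
        if not self.encoded:
            self.encoded = [encode_sequence(s) for s in self.seqs]

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.encoded[i]

    @classmethod
    def from_fasta(cls, path: str | Path | io.TextIOBase) -> "SequenceSet":
        """Read a multi-FASTA; the first whitespace-delimited header token
        is the taxon id."""
        records = list(SeqIO.parse(path, "fasta"))
        ids = [r.id for r in records]
        seqs = [str(r.seq).upper() for r in records]
        return cls(ids=ids, seqs=seqs)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for tid, seq in zip(self.ids, self.seqs):
                fh.write(f">{tid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _window_codes(enc: np.ndarray, pattern: Pattern) -> tuple[np.ndarray, np.ndarray]:
    """Per-position packed spaced-word codes and validity mask.

    A window is valid if it fits and contains no ambiguous symbol anywhere
    (match or don't-care position).  Codes pack the match-position symbols
    big-endian base 4, so numeric order equals lexicographic word order.
    """
    ell, w = pattern.length, pattern.weight
    npos = len(enc) - ell + 1
    if npos <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    bad = np.concatenate(([0], np.cumsum(enc >= 4)))
    valid = (bad[ell:] - bad[:-ell]) == 0
    offs = pattern.match_offsets
    safe = np.where(enc >= 4, 0, enc).astype(np.int64)
    codes = np.zeros(npos, dtype=np.int64)
    mult = np.int64(1)
    for off in offs[::-1]:
        codes += safe[off : off + npos] * mult
        mult *= 4
    return codes, valid


def _code_to_word(code: int, weight: int) -> str:
    chars = []
    for _ in range(weight):
        chars.append(ALPHABET[code & 3])
        code >>= 2
    return "".join(reversed(chars))


def index_spaced_words(
    seqs: SequenceSet, pattern: Pattern
) -> dict[str, list[tuple[int, int]]]:
    """All valid spaced-word occurrences, grouped by word.

    Returns ``{word: [(seq_index, pos), ...]}`` with occurrences sorted by
    (seq_index, pos).
    """
    index: dict[int, list[tuple[int, int]]] = {}
    for sid, enc in enumerate(seqs.encoded):
        codes, valid = _window_codes(enc, pattern)
        for pos in np.flatnonzero(valid):
            index.setdefault(int(codes[pos]), []).append((sid, int(pos)))
    w = pattern.weight
    return {_code_to_word(code, w): occs for code, occs in index.items()}


@dataclass(frozen=True)
class QuartetBlock:
    """Four occurrences of one spaced word in four distinct sequences.

    ``occs`` is sorted by sequence index; ``anchor_index`` points at the
    anchor occurrence within ``occs``; ``scores`` holds the don't-care
    similarity score of each occurrence against the anchor (``None`` for
    the anchor itself, and for unscored second blocks).
    """

    word: str
    occs: tuple[SpacedWordOccurrence, ...]
    anchor_index: int = 0
    scores: tuple[int | None, ...] | None = None
    pattern_length: int = 0

    @property
    def seq_ids(self) -> tuple[int, ...]:
        return tuple(o.seq_id for o in self.occs)

    @property
    def anchor(self) -> SpacedWordOccurrence:
        return self.occs[self.anchor_index]

    def end(self, i: int) -> int:
        """One past the last pattern position of this block in occs[i]."""
        return self.occs[i].pos + self.pattern_length


def _score_against_anchor(
    seqs: SequenceSet,
    pattern: Pattern,
    matrix: SubstitutionMatrix,
    anchor: tuple[int, int],
    other: tuple[int, int],
) -> int:
    dc = pattern.dont_care_offsets
    if dc.size == 0:
        return 0
    a = seqs.encoded[anchor[0]][anchor[1] + dc].astype(np.intp)
    b = seqs.encoded[other[0]][other[1] + dc].astype(np.intp)
    return int(matrix.scores[a, b].sum())


def sample_quartet_blocks(
    index: dict[str, list[tuple[int, int]]],
    seqs: SequenceSet,
    pattern: Pattern,
    matrix: SubstitutionMatrix,
    max_blocks: int = 1_000_000,
    rng_seed: int = 0,
    quartets_per_word: int = 1,
    max_retries: int = 5,
    min_score: int = 0,
) -> list[QuartetBlock]:
    """Sample up to ``max_blocks`` quartet blocks from a spaced-word index.

    Words are visited in a seeded random order.  For each word occurring in
    at least four distinct sequences, up to ``quartets_per_word`` quartets
    are drawn: a random anchor occurrence plus one random occurrence from
    each of three other randomly chosen sequences.  A draw is kept only if
    all three non-anchor occurrences score strictly above ``min_score``
    against the anchor; failed draws are retried up to ``max_retries``
    times.  Output is reproducible for a fixed ``rng_seed`` and never
    contains two blocks with the same (word, occurrence positions).
    """
    rng = np.random.default_rng(rng_seed)
    words = sorted(w for w, occs in index.items() if len({s for s, _ in occs}) >= 4)
    rng.shuffle(words)
    blocks: list[QuartetBlock] = []
    seen: set[tuple] = set()
    for word in words:
        if len(blocks) >= max_blocks:
            break
        occs = index[word]
        by_seq: dict[int, list[tuple[int, int]]] = {}
        for o in occs:
            by_seq.setdefault(o[0], []).append(o)
        seq_ids = sorted(by_seq)
        for _ in range(quartets_per_word):
            if len(blocks) >= max_blocks:
                break
            for _try in range(max_retries + 1):
                anchor = occs[rng.integers(len(occs))]
                others = [s for s in seq_ids if s != anchor[0]]
                chosen = rng.choice(len(others), size=3, replace=False)
                picked = []
                ok = True
                scores = {}
                for ci in chosen:
                    sid = others[ci]
                    cand = by_seq[sid][rng.integers(len(by_seq[sid]))]
                    sc = _score_against_anchor(seqs, pattern, matrix, anchor, cand)
                    if sc <= min_score:
                        ok = False
                        break
                    picked.append(cand)
                    scores[cand] = sc
                if not ok:
                    continue
                quartet = sorted([anchor] + picked)
                key = (word, tuple(quartet))
                if key in seen:
                    break
                seen.add(key)
                occ_objs = tuple(
                    SpacedWordOccurrence(seq_id=s, pos=p, word=word)
                    for s, p in quartet
                )
                score_tuple = tuple(
                    None if (s, p) == anchor else scores[(s, p)] for s, p in quartet
                )
                blocks.append(
                    QuartetBlock(
                        word=word,
                        occs=occ_objs,
                        anchor_index=quartet.index(anchor),
                        scores=score_tuple,
                        pattern_length=pattern.length,
                    )
                )
                break
    return blocks


def write_blocks_tsv(blocks: list[QuartetBlock], seqs: SequenceSet, path, header="") -> None:
    """TSV block listing: word, taxon ids, 1-based positions, anchor, scores."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("word\ttaxa\tpositions\tanchor\tscores\n")
        for b in blocks:
            taxa = ",".join(seqs.ids[o.seq_id] for o in b.occs)
            poss = ",".join(str(o.pos + 1) for o in b.occs)
            scores = ",".join(
                "." if s is None else str(s) for s in (b.scores or ["."] * 4)
            )
            fh.write(f"{b.word}\t{taxa}\t{poss}\t{b.anchor_index}\t{scores}\n")
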