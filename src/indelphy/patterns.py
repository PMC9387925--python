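"""Binary patterns, spaced words and spaced-word-match (SpaM) scoring.

A *binary pattern* is a string over {0,1} whose ``1`` entries are *match
positions* and whose ``0`` entries are *don't-care positions*.  A *spaced
word* with respect to a pattern is the projection of a sequence window of
the pattern's length onto the match positions; two occurrences of the same
spaced word in two sequences form a spaced-word match — a local, gap-free
mini-alignment in which mismatches are only possible at the don't-care
positions.  The similarity score of such a match is the sum of nucleotide
substitution scores at the don't-care positions; it is what separates
homologous matches from background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

ALPHABET = "ACGT"

#: nucleotide -> small integer code; anything non-ACGT maps to 255
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

#: default don't-care substitution scores (Chiaromonte-style nucleotide
#: matrix as used by the FSWM family); rows/cols ordered A, C, G, T
DEFAULT_SCORES = np.array(
    [
        [91, -114, -31, -123],
        [-114, 100, -125, -31],
        [-31, -125, 100, -114],
        [-123, -31, -114, 91],
    ],
    dtype=np.int64,
)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, else 255)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_codes(codes: Iterable[int]) -> str:
    return "".join(ALPHABET[c] for c in codes)


@dataclass(frozen=True)
class Pattern:
    """A binary match / don't-care mask.

    ``mask`` is a tuple of 0/1 ints; the first entry is always 1 (a spaced
    word must start on a defined residue).
    """

    mask: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.mask:
            raise ValueError("pattern must be non-empty")
        if any(b not in (0, 1) for b in self.mask):
            raise ValueError("pattern mask may contain only 0 and 1")
        if self.mask[0] != 1:
            raise ValueError("pattern must start with a match position (1)")

    @property
    def length(self) -> int:
        return len(self.mask)

    @property
    def weight(self) -> int:
        return sum(self.mask)

    @property
    def match_offsets(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.mask))

    @property
    def dont_care_offsets(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.mask) == 0)

    def __str__(self) -> str:
        return "".join(str(b) for b in self.mask)


def parse_pattern(text: str) -> Pattern:
    """Parse a '0'/'1' string into a :class:`Pattern`.

    Rejects empty strings, foreign characters and a leading '0'.
    """
    if not text:
        raise ValueError("empty pattern string")
    if set(text) - {"0", "1"}:
        raise ValueError(f"pattern may contain only '0'/'1': {text!r}")
    if text[0] != "1":
        raise ValueError("pattern must start with '1'")
    return Pattern(tuple(int(c) for c in text))


def default_pattern() -> Pattern:
    """Default reference-block pattern: length 110, weight 10.

    The 10 match positions sit at offsets 0, 12, 24, ..., 108 (evenly
    spread, first position a match), giving 100 don't-care positions.
    """
    mask = [0] * 110
    for off in range(0, 110, 12):
        mask[off] = 1
    return Pattern(tuple(mask))


def second_block_pattern() -> Pattern:
    """Default second-block pattern: seven contiguous match positions."""
    return parse_pattern("1111111")


def load_patterns(path: str | Path) -> list[Pattern]:
    """Read patterns from a text file: one '0'/'1' string per line, '#' comments."""
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            patterns.append(parse_pattern(line))
    return patterns


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric 4x4 nucleotide score table over A, C, G, T.

    Diagonal entries must be strictly positive and off-diagonal entries
    strictly negative, so that the don't-care score of a homologous match
    is positive in expectation while a background match scores negative.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.int64)
        if s.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")
        if not np.array_equal(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (np.diag(s) > 0).all():
            raise ValueError("diagonal entries must be strictly positive")
        off = s[~np.eye(4, dtype=bool)]
        if not (off < 0).all():
            raise ValueError("off-diagonal entries must be strictly negative")
        object.__setattr__(self, "scores", s)

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        return int(self.scores[ALPHABET.index(a), ALPHABET.index(b)])

    @classmethod
    def default(cls) -> "SubstitutionMatrix":
        return cls(DEFAULT_SCORES.copy())

    @classmethod
    def from_file(cls, path: str | Path) -> "SubstitutionMatrix":
        """Read a matrix file: 4 whitespace-separated rows labelled A C G T."""
        rows: dict[str, list[int]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            label = fields[0].upper()
            if label not in ALPHABET or len(fields) != 5:
                raise ValueError(f"malformed matrix row: {line!r}")
            rows[label] = [int(x) for x in fields[1:]]
        if sorted(rows) != list(ALPHABET):
            raise ValueError("matrix file must contain rows A, C, G, T")
        return cls(np.array([rows[c] for c in ALPHABET], dtype=np.int64))

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{c} " + " ".join(str(int(v)) for v in self.scores[i])
            for i, c in enumerate(ALPHABET)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class SpacedWordOccurrence:
    """One occurrence of a spaced word: (sequence index, start, projected word)."""

    seq_id: int
    pos: int
    word: str


def extract_spaced_word(
    sequence: str | np.ndarray, pos: int, pattern: Pattern
) -> SpacedWordOccurrence | None:
    """Project the pattern-length window at ``pos`` onto the match positions.

    Returns ``None`` if the window overruns the sequence end or if *any*
    symbol in the window (match or don't-care) is ambiguous (non-ACGT):
    the don't-care score would be undefined there.  Coordinates are
    0-based.  Raises on negative ``pos``.
    """
    if pos < 0:
        raise ValueError("position must be non-negative")
    enc = sequence if isinstance(sequence, np.ndarray) else encode_sequence(sequence)
    if pos + pattern.length > len(enc):
        return None
    window = enc[pos : pos + pattern.length]
    if (window >= 4).any():
        return None
    word = decode_codes(window[pattern.match_offsets])
    return SpacedWordOccurrence(seq_id=-1, pos=pos, word=word)


def spam_score(
    occ1: SpacedWordOccurrence,
    occ2: SpacedWordOccurrence,
    sequences,
    pattern: Pattern,
    matrix: SubstitutionMatrix,
) -> int:
    """Score of a spaced-word match: sum of substitution scores at the
    don't-care positions.  For an all-match pattern the sum is empty (0).

    ``sequences`` is indexable by ``seq_id`` and yields either nucleotide
    strings or uint8-encoded arrays.
    """
    if occ1.word != occ2.word:
        raise ValueError("occurrences are not matches of the same spaced word")
    dc = pattern.dont_care_offsets
    if dc.size == 0:
        return 0
    s1 = sequences[occ1.seq_id]
    s2 = sequences[occ2.seq_id]
    e1 = s1 if isinstance(s1, np.ndarray) else encode_sequence(s1)
    e2 = s2 if isinstance(s2, np.ndarray) else encode_sequence(s2)
    a = e1[occ1.pos + dc]
    b = e2[occ2.pos + dc]
    if (a >= 4).any() or (b >= 4).any():
        raise ValueError("ambiguous nucleotide at a don't-care position")
    return int(matrix.scores[a.astype(np.intp), b.astype(np.intp)].sum())
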