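"""Core domain types and Hamming-model arithmetic.

A *simple motif* (a "box") is a consensus word ``w`` over the DNA
alphabet together with an error budget ``e``; its occurrences are all
sequence windows whose Hamming distance to ``w`` is at most ``e``.  A
*structured motif* is an ordered tuple of boxes whose occurrences must
respect pairwise gap constraints.  Everything downstream (enumeration,
assembly, planting) is expressed in terms of the types defined here.

Coordinates are 0-based; a box occupies the half-open interval
``[start, start + length)``.  Only the forward strand over
``{A, C, G, T}`` is considered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

DNA_ALPHABET = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(DNA_ALPHABET)}


class AlphabetError(ValueError):
    """A sequence or word contains characters outside {A, C, G, T}."""


class TemplateError(ValueError):
    """A box/gap/quorum specification violates its constraints."""


def _check_word(w: str, *, what: str = "word") -> str:
    w = w.upper()
    bad = set(w) - set(DNA_ALPHABET)
    if bad:
        raise AlphabetError(
            f"{what} contains non-ACGT characters: {sorted(bad)!r}"
        )
    return w


@dataclass(frozen=True)
class SequenceSet:
    """An ordered set of DNA sequences with unique identifiers.

    Sequences are normalized to uppercase on construction; characters
    outside the DNA alphabet (including ``N``) are rejected rather than
    silently matched, because the motif model is defined only over
    {A, C, G, T}.
    """

    sequences: tuple[str, ...]
    ids: tuple[str, ...]

    def __init__(self, sequences: Iterable[str], ids: Iterable[str] | None = None):
        seqs = tuple(str(s) for s in sequences)
        if ids is None:
            ids = tuple(f"seq{i}" for i in range(len(seqs)))
        else:
            ids = tuple(str(i) for i in ids)
        if len(ids) != len(seqs):
            raise ValueError(
                f"{len(seqs)} sequences but {len(ids)} identifiers"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("sequence identifiers must be unique")
        norm = []
        for sid, s in zip(ids, seqs):
            norm.append(_check_word(s, what=f"sequence {sid!r}"))
        object.__setattr__(self, "sequences", tuple(norm))
        object.__setattr__(self, "ids", ids)

    @property
    def N(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


@dataclass(frozen=True)
class BoxTemplate:
    """A box specification: consensus length and substitution budget."""

    length: int
    errors: int

    def __post_init__(self):
        if self.length < 1:
            raise TemplateError(f"box length must be >= 1, got {self.length}")
        if not 0 <= self.errors < self.length:
            raise TemplateError(
                f"box errors must satisfy 0 <= e < length, "
                f"got e={self.errors}, length={self.length}"
            )

    def __str__(self) -> str:
        return f"({self.length},{self.errors})"


@dataclass(frozen=True)
class GapConstraint:
    """Bounds on the number of bases strictly between two adjacent boxes."""

    dmin: int
    dmax: int

    def __post_init__(self):
        if not 0 <= self.dmin <= self.dmax:
            raise TemplateError(
                f"gap bounds must satisfy 0 <= dmin <= dmax, "
                f"got [{self.dmin},{self.dmax}]"
            )

    def __str__(self) -> str:
        return f"[{self.dmin},{self.dmax}]"


@dataclass(frozen=True)
class StructuredTemplate:
    """An ordered series of boxes separated by bounded gaps.

    ``boxes[i]`` and ``boxes[i+1]`` are separated by ``gaps[i]`` bases
    (counted strictly between the end of one box and the start of the
    next).  At least two boxes are required; a single box is a plain
    simple-motif problem.
    """

    boxes: tuple[BoxTemplate, ...]
    gaps: tuple[GapConstraint, ...]

    def __init__(self, boxes: Iterable[BoxTemplate], gaps: Iterable[GapConstraint]):
        boxes = tuple(boxes)
        gaps = tuple(gaps)
        if len(boxes) < 2:
            raise TemplateError(f"need at least 2 boxes, got {len(boxes)}")
        if len(gaps) != len(boxes) - 1:
            raise TemplateError(
                f"{len(boxes)} boxes require {len(boxes) - 1} gaps, "
                f"got {len(gaps)}"
            )
        object.__setattr__(self, "boxes", boxes)
        object.__setattr__(self, "gaps", gaps)

    @property
    def b(self) -> int:
        return len(self.boxes)

    def min_span(self) -> int:
        """Smallest total width of a conforming occurrence."""
        return sum(x.length for x in self.boxes) + sum(g.dmin for g in self.gaps)

    def max_span(self) -> int:
        """Largest total width of a conforming occurrence."""
        return sum(x.length for x in self.boxes) + sum(g.dmax for g in self.gaps)

    def __str__(self) -> str:
        parts = [str(self.boxes[0])]
        for gap, box in zip(self.gaps, self.boxes[1:]):
            parts.append(str(gap))
            parts.append(str(box))
        return "-".join(parts)


class Occurrence(NamedTuple):
    """One placement of a word: sequence index and 0-based start."""

    seq_index: int
    start: int


def validate_occurrence_list(occs: list[Occurrence]) -> None:
    """Assert sortedness (seq asc, start asc) and absence of duplicates."""
    for prev, cur in zip(occs, occs[1:]):
        if cur <= prev:
            raise ValueError(f"occurrence list not sorted/unique at {prev} -> {cur}")


def hamming_distance(u: str, v: str) -> int:
    """Number of mismatching positions between two equal-length words."""
    if len(u) != len(v):
        raise ValueError(
            f"cannot compare words of different lengths ({len(u)} vs {len(v)})"
        )
    u = _check_word(u)
    v = _check_word(v)
    return sum(a != b for a, b in zip(u, v))


def neighborhood_size(length: int, errors: int) -> int:
    """Exact count of words within Hamming distance ``errors`` of a word.

    nu(e, l) = sum_{i=0}^{e} C(l, i) * 3**i, independent of the center
    word.  Satisfies nu(e, l) <= l**e * 4**e.
    """
    if length < 1 or errors < 0 or errors >= length:
        raise ValueError(
            f"need 0 <= errors < length, got errors={errors}, length={length}"
        )
    return sum(math.comb(length, i) * 3**i for i in range(errors + 1))


def quorum_threshold(q: float, N: int) -> int:
    """Minimum number of distinct sequences a valid motif must hit.

    The quorum ``q`` is a fraction of the input set; the threshold is
    ceil(q * N).  A small epsilon guards against binary floating-point
    artifacts such as 0.7 * 10 == 7.000000000000001.
    """
    if not 0 < q <= 1:
        raise ValueError(f"quorum must lie in (0, 1], got {q}")
    if N < 1:
        raise ValueError(f"need at least one sequence, got N={N}")
    return max(1, math.ceil(q * N - 1e-9))


def expected_random_motif_count(length: int, errors: int, N: int, L: int) -> float:
    """Expected number of (length, errors) motifs at full quorum in noise.

    For N i.i.d.-uniform sequences of length L, a fixed word w of length
    ``l`` is present (within distance e) in one sequence with probability
    approximately ``1 - (1 - nu(e,l)/4**l) ** (L - l + 1)``, treating the
    L - l + 1 windows as independent.  Summing over all 4**l words:

        E(l, e) = 4**l * [1 - (1 - nu/4**l)**(L-l+1)] ** N

    This window-independence approximation is used only to label
    instances of the planted-motif benchmark as easy (E large) or hard
    (E close to 1); it never filters discovery output.
    """
    if not 0 <= errors < length:
        raise ValueError(f"need 0 <= errors < length, got {errors}, {length}")
    if length > L:
        raise ValueError(f"motif length {length} exceeds sequence length {L}")
    if N < 1:
        raise ValueError(f"need N >= 1, got {N}")
    nwords = 4**length
    p_window = neighborhood_size(length, errors) / nwords
    windows = L - length + 1
    p_seq = 1.0 - (1.0 - p_window) ** windows
    return nwords * p_seq**N

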