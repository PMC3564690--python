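"""Stage 1: exhaustive simple-motif enumeration per box template.

For a box ``(l, e)`` and a quorum threshold ``qmin``, this module finds
*every* consensus word ``w`` in {A,C,G,T}^l whose occurrences (windows at
Hamming distance <= e) hit at least ``qmin`` distinct sequences, together
with the complete, sorted list of those occurrences.  Two modes exist:

``unconstrained``
    candidate consensus words range over the whole of Sigma^l.

``frequent``
    candidates are additionally required to appear *exactly* (distance 0)
    somewhere in the input — the frequent-motif restriction used by
    spelling-style finders.

No statistical filtering of any kind is applied: a structured motif can
reach quorum even when built from individually weak boxes, so every
quorum-satisfying word is kept.

The engine spells candidate words letter by letter over the set of input
windows, carrying (window, mismatch-count) pairs and pruning a branch as
soon as its sequence support drops below the quorum threshold (support is
monotone non-increasing along a branch).  In frequent mode a branch is
additionally pruned when no carried window matches the spelled prefix
exactly, since an exact occurrence of a word is exact on every prefix.
The inner loop is JIT-compiled; a naive per-word scan
(:func:`scan_occurrences`) serves as an independent oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import (
    DNA_ALPHABET,
    AlphabetError,
    BoxTemplate,
    Occurrence,
    SequenceSet,
    StructuredTemplate,
    hamming_distance,
)

__all__ = [
    "SimpleMotif",
    "BoxCandidateSet",
    "CandidateMemoryError",
    "scan_occurrences",
    "find_simple_motifs",
    "build_candidate_sets",
]


class CandidateMemoryError(MemoryError):
    """Candidate sets grew too large to hold in memory.

    Raised so that a stage-1 memory failure is distinguishable from any
    other error: it is the one failure mode that the space-saving option
    (which slices stage 2 only) cannot mitigate.
    """


@dataclass(frozen=True)
class SimpleMotif:
    """A consensus word with its complete sorted occurrence list."""

    consensus: str
    occurrences: tuple[Occurrence, ...]

    @property
    def support(self) -> int:
        """Number of distinct sequences with at least one occurrence."""
        return len({o.seq_index for o in self.occurrences})


@dataclass(frozen=True)
class BoxCandidateSet:
    """The set K_i of simple motifs eligible for box i (1-based)."""

    box_index: int
    box: BoxTemplate
    motifs: tuple[SimpleMotif, ...]

    @property
    def total_occurrences(self) -> int:
        """B_i: the summed occurrence-list length over all members."""
        return sum(len(m.occurrences) for m in self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)


# ---------------------------------------------------------------------------
# sequence encoding

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(DNA_ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequences(seqs: SequenceSet):
    """Concatenate sequences into one int8 code array.

    Returns ``(codes, offsets, seq_of_pos)`` where ``offsets[i]`` is the
    global position of the first base of sequence i (with a final
    sentinel) and ``seq_of_pos`` maps every global position to its
    sequence index.
    """
    joined = "".join(seqs.sequences)
    codes = _CODE[np.frombuffer(joined.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise AlphabetError("sequences contain non-ACGT characters")
    lengths = np.array([len(s) for s in seqs.sequences], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    seq_of_pos = np.repeat(np.arange(len(seqs), dtype=np.int32), lengths)
    return codes, offsets, seq_of_pos


def _window_starts(offsets: np.ndarray, length: int) -> np.ndarray:
    """Global start positions of every window of ``length`` bases."""
    parts = []
    for i in range(len(offsets) - 1):
        lo, hi = offsets[i], offsets[i + 1]
        if hi - lo >= length:
            parts.append(np.arange(lo, hi - length + 1, dtype=np.int32))
    if not parts:
        return np.empty(0, dtype=np.int32)
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# naive scan (test oracle and single-word back-end)


def scan_occurrences(seqs: SequenceSet, consensus: str, errors: int) -> list[Occurrence]:
    """All windows within Hamming distance ``errors`` of ``consensus``.

    Direct per-window comparison; quadratic but obviously correct, which
    is exactly what makes it the oracle for the spelling engine.
    """
    consensus = consensus.upper()
    if set(consensus) - set(DNA_ALPHABET):
        raise AlphabetError(f"consensus {consensus!r} contains non-ACGT characters")
    ell = len(consensus)
    if errors >= ell:
        raise ValueError(f"errors={errors} must be < word length {ell}")
    out: list[Occurrence] = []
    for si, seq in enumerate(seqs.sequences):
        for start in range(len(seq) - ell + 1):
            if hamming_distance(seq[start : start + ell], consensus) <= errors:
                out.append(Occurrence(si, start))
    return out


# ---------------------------------------------------------------------------
# spelling engine


@njit(cache=True)
def _spell(codes, seq_of_pos, win0, ell, errors, qmin, require_exact):  # pragma: no cover
    """Depth-first spelling of all quorum-satisfying consensus words.

    Returns (word_codes, occ_offsets, occ_wins) where word t spans
    occ_wins[occ_offsets[t]:occ_offsets[t+1]] (global window starts, in
    (sequence, position) order).
    """
    n0 = win0.shape[0]
    # one (window, mismatch) buffer per spelling depth; a child node's
    # occurrence list is always a subset of its parent's
    wins = np.empty((ell + 1, n0), dtype=np.int32)
    miss = np.empty((ell + 1, n0), dtype=np.int8)
    counts = np.empty(ell + 1, dtype=np.int64)
    next_letter = np.zeros(ell + 1, dtype=np.int8)
    path = np.zeros(ell, dtype=np.int64)

    wins[0, :n0] = win0
    miss[0, :n0] = 0
    counts[0] = n0

    # growable output buffers (manual doubling)
    cap_w = 256
    word_buf = np.empty(cap_w, dtype=np.int64)
    off_buf = np.empty(cap_w + 1, dtype=np.int64)
    off_buf[0] = 0
    cap_o = 4096
    occ_buf = np.empty(cap_o, dtype=np.int32)
    n_words = 0
    n_occ = 0

    depth = 0
    while depth >= 0:
        if next_letter[depth] == 4:
            next_letter[depth] = 0
            depth -= 1
            continue
        c = next_letter[depth]
        next_letter[depth] += 1

        cnt = 0
        support = 0
        last_seq = -1
        exact = False
        n_par = counts[depth]
        for i in range(n_par):
            w = wins[depth, i]
            m = miss[depth, i]
            if codes[w + depth] != c:
                m += 1
            if m <= errors:
                wins[depth + 1, cnt] = w
                miss[depth + 1, cnt] = m
                cnt += 1
                s = seq_of_pos[w]
                if s != last_seq:
                    support += 1
                    last_seq = s
                if m == 0:
                    exact = True
        if cnt == 0 or support < qmin:
            continue
        if require_exact and not exact:
            continue
        path[depth] = c
        if depth + 1 == ell:
            code = np.int64(0)
            for k in range(ell):
                code = code * 4 + path[k]
            if n_words == cap_w:
                cap_w *= 2
                nw = np.empty(cap_w, dtype=np.int64)
                nw[:n_words] = word_buf[:n_words]
                word_buf = nw
                no = np.empty(cap_w + 1, dtype=np.int64)
                no[: n_words + 1] = off_buf[: n_words + 1]
                off_buf = no
            while n_occ + cnt > cap_o:
                cap_o *= 2
                nb = np.empty(cap_o, dtype=np.int32)
                nb[:n_occ] = occ_buf[:n_occ]
                occ_buf = nb
            word_buf[n_words] = code
            occ_buf[n_occ : n_occ + cnt] = wins[depth + 1, :cnt]
            n_occ += cnt
            n_words += 1
            off_buf[n_words] = n_occ
        else:
            counts[depth + 1] = cnt
            depth += 1

    return word_buf[:n_words].copy(), off_buf[: n_words + 1].copy(), occ_buf[:n_occ].copy()


def _decode(code: int, ell: int) -> str:
    letters = []
    for _ in range(ell):
        letters.append(DNA_ALPHABET[code % 4])
        code //= 4
    return "".join(reversed(letters))


def find_simple_motifs(
    seqs: SequenceSet,
    box: BoxTemplate,
    qmin: int,
    mode: str = "unconstrained",
) -> list[SimpleMotif]:
    """Enumerate every quorum-satisfying simple motif for one box.

    Parameters
    ----------
    seqs
        Input sequences.
    box
        Consensus length and substitution budget ``(l, e)``.
    qmin
        Minimum number of distinct sequences that must contain an
        occurrence (an absolute count, not a fraction).
    mode
        ``"unconstrained"`` or ``"frequent"`` (see module docstring).

    Returns motifs sorted lexicographically by consensus, each with its
    complete occurrence list sorted by (sequence index, start).
    """
    if mode not in ("unconstrained", "frequent"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    if qmin < 1:
        raise ValueError(f"quorum threshold must be >= 1, got {qmin}")

    codes, offsets, seq_of_pos = encode_sequences(seqs)
    win0 = _window_starts(offsets, box.length)
    if win0.size == 0:
        return []
    try:
        word_codes, occ_offsets, occ_wins = _spell(
            codes,
            seq_of_pos,
            win0,
            box.length,
            box.errors,
            qmin,
            mode == "frequent",
        )
    except MemoryError as exc:  # candidate space too large to hold
        raise CandidateMemoryError(
            f"stage-1 candidate sets for box {box} exhausted memory"
        ) from exc

    starts_in_seq = occ_wins - offsets[:-1][seq_of_pos[occ_wins]].astype(np.int32)
    seq_idx = seq_of_pos[occ_wins]
    motifs = []
    for t in range(len(word_codes)):
        lo, hi = occ_offsets[t], occ_offsets[t + 1]
        occs = tuple(
            Occurrence(int(s), int(p))
            for s, p in zip(seq_idx[lo:hi], starts_in_seq[lo:hi])
        )
        motifs.append(SimpleMotif(_decode(int(word_codes[t]), box.length), occs))
    motifs.sort(key=lambda m: m.consensus)
    return motifs


def build_candidate_sets(
    seqs: SequenceSet,
    template: StructuredTemplate,
    qmin: int,
    mode: str = "unconstrained",
) -> list[BoxCandidateSet]:
    """Compute K_1..K_b, running the enumeration once per distinct box.

    Boxes sharing the same (length, errors) pair yield identical
    candidate sets, so the spelling engine is invoked only once for each
    distinct pair and the result is shared.
    """
    cache: dict[BoxTemplate, list[SimpleMotif]] = {}
    sets = []
    for i, box in enumerate(template.boxes, start=1):
        if box not in cache:
            cache[box] = find_simple_motifs(seqs, box, qmin, mode)
        sets.append(BoxCandidateSet(i, box, tuple(cache[box])))
    return sets
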