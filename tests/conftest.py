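"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's spelling/assembly engines:
simple motifs are found by scanning every word of Sigma^l with the naive
window scan, and structured motifs by exhaustive enumeration of word
tuples with a recursive chain check over all occurrence combinations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from structmotif import (
    BoxTemplate,
    GapConstraint,
    SequenceSet,
    StructuredTemplate,
    scan_occurrences,
)

ALPHABET = "ACGT"


def all_words(length: int):
    return ("".join(t) for t in itertools.product(ALPHABET, repeat=length))


def brute_force_simple_motifs(
    seqs: SequenceSet, box: BoxTemplate, qmin: int, mode: str = "unconstrained"
) -> dict[str, list]:
    """Oracle: every quorum-satisfying word, by scanning all of Sigma^l."""
    out = {}
    for w in all_words(box.length):
        occs = scan_occurrences(seqs, w, box.errors)
        if len({o.seq_index for o in occs}) < qmin:
            continue
        if mode == "frequent":
            exact = any(
                seqs.sequences[o.seq_index][o.start : o.start + box.length] == w
                for o in occs
            )
            if not exact:
                continue
        out[w] = occs
    return out


def _chain_exists(starts_per_box: list[list[int]], template: StructuredTemplate) -> bool:
    """Is there a start tuple satisfying every adjacent gap constraint?"""

    def rec(i: int, prev_end: int) -> bool:
        if i == template.b:
            return True
        gap = template.gaps[i - 1]
        for s in starts_per_box[i]:
            if gap.dmin <= s - prev_end <= gap.dmax:
                if rec(i + 1, s + template.boxes[i].length):
                    return True
        return False

    for s0 in starts_per_box[0]:
        if rec(1, s0 + template.boxes[0].length):
            return True
    return False


def brute_force_structured(
    seqs: SequenceSet, template: StructuredTemplate, qmin: int,
    mode: str = "unconstrained",
) -> dict[tuple[str, ...], int]:
    """Oracle: every valid word tuple with its support, by full enumeration."""
    per_box = []
    for box in template.boxes:
        occ_by_word = {}
        for w in all_words(box.length):
            occs = scan_occurrences(seqs, w, box.errors)
            if mode == "frequent":
                if not any(
                    seqs.sequences[o.seq_index][o.start : o.start + box.length] == w
                    for o in occs
                ):
                    continue
            by_seq: dict[int, list[int]] = {}
            for o in occs:
                by_seq.setdefault(o.seq_index, []).append(o.start)
            occ_by_word[w] = by_seq
        per_box.append(occ_by_word)

    results = {}
    N = seqs.N
    for words in itertools.product(*(sorted(p) for p in per_box)):
        support = 0
        for si in range(N):
            if support + (N - si) < qmin:
                break
            starts = []
            ok = True
            for box_i, w in enumerate(words):
                lst = per_box[box_i][w].get(si)
                if not lst:
                    ok = False
                    break
                starts.append(lst)
            if ok and _chain_exists(starts, template):
                support += 1
        if support >= qmin:
            results[words] = support
    return results


def random_sequences(rng: np.random.Generator, N: int, L: int) -> SequenceSet:
    return SequenceSet(
        ["".join(rng.choice(list(ALPHABET), size=L)) for _ in range(N)]
    )


def random_small_instance(rng: np.random.Generator, b: int | None = None):
    """A random tiny structured-motif problem for oracle comparison."""
    if b is None:
        b = int(rng.integers(2, 4))
    N = int(rng.integers(2, 6))
    L = int(rng.integers(15, 41))
    boxes = []
    for _ in range(b):
        # keep the exhaustive 4^(l1+...+lb) oracle affordable: word
        # lengths up to 3 for dyads, up to 2 when there are three boxes
        ell = int(rng.integers(1, 4 if b == 2 else 3))
        e = int(rng.integers(0, ell))
        boxes.append(BoxTemplate(ell, e))
    gaps = []
    for _ in range(b - 1):
        d = int(rng.integers(0, 4))
        D = d + int(rng.integers(0, 5))
        gaps.append(GapConstraint(d, D))
    template = StructuredTemplate(boxes, gaps)
    seqs = random_sequences(rng, N, L)
    qmin = int(rng.integers(1, N + 1))
    return seqs, template, qmin


@pytest.fixture(scope="session")
def tiny_seqs() -> SequenceSet:
    return SequenceSet(["AAACCTTT", "AAAGGTTT"], ["s1", "s2"])
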