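"""Stage 2: assembly of simple motifs into structured motifs.

Starting from the per-box candidate sets K_1..K_b produced by stage 1,
the assembler builds partially placed structured motifs ("prefixes") of
increasing size by intersecting sorted occurrence lists.  Each extension
step performs a *distance check* (binary search for the first candidate
occurrence satisfying the minimum-gap constraint, then a forward scan
until the maximum gap is violated) and a *quorum check* (a prefix whose
occurrences hit fewer than ``qmin`` distinct sequences is discarded —
extension can only shrink support, so the pruning is safe and exact).

Boxes may be placed left-to-right (*basic* order) or in ascending order
of total occurrence count (*box-index selection*), which tends to prune
useless intermediates when the final output is small.  When two placed
boxes sandwich unplaced ones, the compound gap between them is bounded
by the sum of the intervening gap bounds plus the intervening box
lengths; the flanking constraints are re-checked exactly once the holes
are filled, so both orders produce identical result sets.

The *space-saving* option partitions each K_i into slices of at most
``v`` motifs and runs the assembly once per cell of the Cartesian
product of slices, bounding the number of intermediates held at once;
the union of the per-cell outputs equals the single-run output.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from math import ceil

from .model import GapConstraint, StructuredTemplate
from .stage1 import BoxCandidateSet, SimpleMotif

__all__ = [
    "PrefixMotif",
    "StructuredMotifResult",
    "compatible_range",
    "extend_prefix",
    "select_box_order",
    "partition_slices",
    "assemble",
    "gap_bounds",
    "check_occurrence_tuple",
]


@dataclass(frozen=True)
class PrefixMotif:
    """A partial structured motif: some boxes placed, with occurrences.

    ``placed`` holds 1-based box indices in ascending order; ``words``
    is aligned with it.  Each occurrence is ``(seq_index, starts)`` with
    ``starts`` aligned with ``placed``.
    """

    placed: tuple[int, ...]
    words: tuple[str, ...]
    occurrences: tuple[tuple[int, tuple[int, ...]], ...]

    @property
    def support(self) -> int:
        return len({seq for seq, _ in self.occurrences})


EMPTY_PREFIX = PrefixMotif((), (), ())


@dataclass(frozen=True)
class StructuredMotifResult:
    """A fully assembled structured motif meeting the quorum."""

    words: tuple[str, ...]
    support: int
    occurrences: tuple[tuple[int, tuple[int, ...]], ...] | None = None


def gap_bounds(template: StructuredTemplate, i: int, k: int) -> tuple[int, int]:
    """Bounds on the bases between the end of box i and start of box k.

    For adjacent boxes this is the template gap itself; across unplaced
    boxes the bounds accumulate the intervening gap bounds plus the
    intervening box lengths (1-based indices, ``i < k``).
    """
    if not 1 <= i < k <= template.b:
        raise ValueError(f"need 1 <= i < k <= {template.b}, got i={i}, k={k}")
    lo = sum(g.dmin for g in template.gaps[i - 1 : k - 1])
    hi = sum(g.dmax for g in template.gaps[i - 1 : k - 1])
    inner = sum(x.length for x in template.boxes[i : k - 1])
    return lo + inner, hi + inner


def compatible_range(
    occs_in_seq: list[int], prev_end: int, gap: GapConstraint
) -> list[int]:
    """Starts ``s`` with ``prev_end + dmin <= s <= prev_end + dmax``.

    ``occs_in_seq`` must be sorted ascending; the lower bound is found
    by binary search and the scan stops at the first start violating the
    maximum-distance constraint.
    """
    lo = bisect_left(occs_in_seq, prev_end + gap.dmin)
    hi_val = prev_end + gap.dmax
    out = []
    for j in range(lo, len(occs_in_seq)):
        if occs_in_seq[j] > hi_val:
            break
        out.append(occs_in_seq[j])
    return out


def _starts_by_seq(motif: SimpleMotif) -> dict[int, list[int]]:
    by_seq: dict[int, list[int]] = {}
    for occ in motif.occurrences:
        by_seq.setdefault(occ.seq_index, []).append(occ.start)
    return by_seq


def extend_prefix(
    prefix: PrefixMotif,
    candidate: SimpleMotif,
    box_index: int,
    template: StructuredTemplate,
    qmin: int,
    _cand_by_seq: dict[int, list[int]] | None = None,
) -> PrefixMotif | None:
    """Place ``candidate`` at ``box_index`` within ``prefix``.

    Returns the extended prefix, or ``None`` when its support falls
    below ``qmin``.  The joined occurrence list contains every
    combination of a prefix occurrence with a candidate occurrence in
    the same sequence that satisfies the gap constraints towards both
    flanking placed boxes (compound bounds when holes intervene).
    """
    if box_index in prefix.placed:
        raise ValueError(f"box {box_index} is already placed")
    if not 1 <= box_index <= template.b:
        raise ValueError(f"box index {box_index} outside 1..{template.b}")
    ell = template.boxes[box_index - 1].length

    cand_by_seq = _cand_by_seq if _cand_by_seq is not None else _starts_by_seq(candidate)

    if not prefix.placed:
        occs = tuple((o.seq_index, (o.start,)) for o in candidate.occurrences)
        new = PrefixMotif((box_index,), (candidate.consensus,), occs)
        return new if new.support >= qmin else None

    # flanking placed boxes
    left = max((j for j in prefix.placed if j < box_index), default=None)
    right = min((j for j in prefix.placed if j > box_index), default=None)
    if left is not None:
        l_pos = prefix.placed.index(left)
        l_len = template.boxes[left - 1].length
        l_lo, l_hi = gap_bounds(template, left, box_index)
    if right is not None:
        r_pos = prefix.placed.index(right)
        r_lo, r_hi = gap_bounds(template, box_index, right)

    insert_at = sum(1 for j in prefix.placed if j < box_index)
    new_placed = prefix.placed[:insert_at] + (box_index,) + prefix.placed[insert_at:]
    new_words = prefix.words[:insert_at] + (candidate.consensus,) + prefix.words[insert_at:]

    joined: list[tuple[int, tuple[int, ...]]] = []
    for seq, starts in prefix.occurrences:
        cand_starts = cand_by_seq.get(seq)
        if not cand_starts:
            continue
        lo = cand_starts[0]
        hi = cand_starts[-1]
        if left is not None:
            end = starts[l_pos] + l_len
            lo = max(lo, end + l_lo)
            hi = min(hi, end + l_hi)
        if right is not None:
            lo = max(lo, starts[r_pos] - ell - r_hi)
            hi = min(hi, starts[r_pos] - ell - r_lo)
        if lo > hi:
            continue
        j = bisect_left(cand_starts, lo)
        while j < len(cand_starts) and cand_starts[j] <= hi:
            s = cand_starts[j]
            joined.append((seq, starts[:insert_at] + (s,) + starts[insert_at:]))
            j += 1
    new = PrefixMotif(new_placed, new_words, tuple(joined))
    return new if new.support >= qmin else None


def select_box_order(candidate_sets: list[BoxCandidateSet]) -> list[int]:
    """Box indices sorted by ascending total occurrence count B_i.

    Ties break by ascending box index (the sort is stable).
    """
    return [
        cs.box_index
        for cs in sorted(candidate_sets, key=lambda cs: cs.total_occurrences)
    ]


def partition_slices(candidate_set: BoxCandidateSet, v: int) -> list[BoxCandidateSet]:
    """Split K_i into ceil(|K_i|/v) order-preserving slices of size <= v."""
    if v < 1:
        raise ValueError(f"space-saving parameter must be >= 1, got {v}")
    motifs = candidate_set.motifs
    n_slices = max(1, ceil(len(motifs) / v))
    return [
        BoxCandidateSet(
            candidate_set.box_index,
            candidate_set.box,
            motifs[j * v : (j + 1) * v],
        )
        for j in range(n_slices)
    ]


def _run_assembly(
    template: StructuredTemplate,
    slices_by_index: dict[int, list[tuple[SimpleMotif, ...]]],
    qmin: int,
    order: list[int],
    sink: list[PrefixMotif],
) -> None:
    """Assemble along ``order``, one candidate-set slice at a time.

    The Cartesian product over slices is walked depth-first, so at any
    moment only the prefixes arising from one slice per box are held —
    the space-saving contract — while each (prefix, candidate) pair is
    still extended exactly once.  Full assemblies are appended to
    ``sink``.
    """
    by_seq_cache: dict[int, dict[int, list[int]]] = {}

    def rec(level: int, prefixes: list[PrefixMotif]) -> None:
        if level == len(order):
            sink.extend(prefixes)
            return
        j = order[level]
        for chunk in slices_by_index[j]:
            nxt: list[PrefixMotif] = []
            for p in prefixes:
                for m in chunk:
                    cache = by_seq_cache.get(id(m))
                    if cache is None:
                        cache = by_seq_cache[id(m)] = _starts_by_seq(m)
                    r = extend_prefix(p, m, j, template, qmin, _cand_by_seq=cache)
                    if r is not None:
                        nxt.append(r)
            if nxt:
                rec(level + 1, nxt)

    rec(0, [EMPTY_PREFIX])


def assemble(
    template: StructuredTemplate,
    candidate_sets: list[BoxCandidateSet],
    qmin: int,
    *,
    order: str = "basic",
    space_saving: int | None = None,
    print_occurrences: bool = False,
) -> list[StructuredMotifResult]:
    """Enumerate every structured motif meeting the quorum threshold.

    Parameters
    ----------
    template
        The structured-motif template (boxes and gaps).
    candidate_sets
        Stage-1 output, one set per box, in box order.
    qmin
        Minimum number of distinct sequences a result must hit.
    order
        ``"basic"`` (left-to-right) or ``"selection"`` (ascending B_i).
    space_saving
        If given, slice size ``v >= 1`` for Cartesian-product runs.
    print_occurrences
        Retain the full occurrence tuples on each result.

    The result set (words and supports) is identical for every option
    combination; options trade memory against time only.  Results are
    sorted lexicographically by their concatenated box words.
    """
    if len(candidate_sets) != template.b:
        raise ValueError(
            f"template has {template.b} boxes but got "
            f"{len(candidate_sets)} candidate sets"
        )
    for box, cs in zip(template.boxes, candidate_sets):
        if cs.box != box:
            raise ValueError(
                f"candidate set for box {cs.box_index} was built for {cs.box}, "
                f"template expects {box}"
            )
    if order not in ("basic", "selection"):
        raise ValueError(f"unknown assembly order {order!r}")

    if order == "selection":
        # B_i is defined on the full candidate sets (Cartesian-product
        # slices reuse the global order)
        order_list = select_box_order(candidate_sets)
    else:
        order_list = list(range(1, template.b + 1))

    if space_saving is None:
        slices_by_index = {cs.box_index: [cs.motifs] for cs in candidate_sets}
    else:
        slices_by_index = {
            cs.box_index: [s.motifs for s in partition_slices(cs, space_saving)]
            for cs in candidate_sets
        }

    sink: list[PrefixMotif] = []
    _run_assembly(template, slices_by_index, qmin, order_list, sink)

    collected: dict[tuple[str, ...], PrefixMotif] = {}
    for full in sink:
        key = full.words
        if key in collected:
            # each word lives in exactly one slice, so a word tuple can
            # arise from one slice cell only; merge defensively anyway
            merged = tuple(
                sorted(set(collected[key].occurrences) | set(full.occurrences))
            )
            collected[key] = PrefixMotif(full.placed, full.words, merged)
        else:
            collected[key] = full

    results = []
    for words in sorted(collected, key=lambda w: "".join(w)):
        p = collected[words]
        occs = tuple(sorted(set(p.occurrences))) if print_occurrences else None
        results.append(StructuredMotifResult(words, p.support, occs))
    return results


def check_occurrence_tuple(
    template: StructuredTemplate, starts: tuple[int, ...]
) -> bool:
    """Post-hoc validator: do the b starts satisfy every gap constraint?"""
    if len(starts) != template.b:
        raise ValueError(f"expected {template.b} starts, got {len(starts)}")
    for i in range(template.b - 1):
        gap = starts[i + 1] - (starts[i] + template.boxes[i].length)
        g = template.gaps[i]
        if not g.dmin <= gap <= g.dmax:
            return False
    return True
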