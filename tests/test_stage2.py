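"""Stage-2 assembly: distance/quorum checks, options, oracle equivalence."""

import numpy as np
import pytest

from structmotif import (
    BoxTemplate,
    GapConstraint,
    Occurrence,
    SequenceSet,
    SimpleMotif,
    StructuredTemplate,
    assemble,
    build_candidate_sets,
    check_occurrence_tuple,
    compatible_range,
    extend_prefix,
    parse_template,
    partition_slices,
    quorum_threshold,
    select_box_order,
)
from structmotif.stage1 import BoxCandidateSet
from structmotif.stage2 import EMPTY_PREFIX, gap_bounds

from conftest import brute_force_structured, random_small_instance


@pytest.mark.parametrize(
    "starts, prev_end, gap, expected",
    [
        ([4, 5, 8, 10], 3, (2, 4), [5]),
        ([], 3, (0, 5), []),
        ([0, 1, 2], 0, (0, 2), [0, 1, 2]),
    ],
)
def test_compatible_range(starts, prev_end, gap, expected):
    assert compatible_range(starts, prev_end, GapConstraint(*gap)) == expected
    # exhaustive cross-check
    assert expected == [
        s for s in starts if gap[0] <= s - prev_end <= gap[1]
    ]


def _motif(word, occs):
    return SimpleMotif(word, tuple(Occurrence(*o) for o in occs))


def test_extend_prefix_joins_by_gap_and_rejects_on_quorum():
    template = StructuredTemplate(
        [BoxTemplate(3, 0), BoxTemplate(3, 0)], [GapConstraint(2, 4)]
    )
    first = _motif("AAA", [(0, 0)])
    p = extend_prefix(EMPTY_PREFIX, first, 1, template, qmin=1)
    cand = _motif("TTT", [(0, 4), (0, 5), (0, 8)])
    r = extend_prefix(p, cand, 2, template, qmin=1)
    # end of box 1 is 3; allowed starts are 5..7; only 5 is present
    assert r.occurrences == ((0, (0, 5)),)
    assert r.words == ("AAA", "TTT")

    # candidate living in other sequences only -> support 0 -> rejection
    elsewhere = _motif("TTT", [(1, 10)])
    assert extend_prefix(p, elsewhere, 2, template, qmin=1) is None

    with pytest.raises(ValueError):
        extend_prefix(p, cand, 1, template, qmin=1)


def test_extend_prefix_quorum_threshold_boundary():
    # support 6 < threshold 7 (q=0.7 of 10) is discarded; 7 is kept
    template = StructuredTemplate(
        [BoxTemplate(2, 0), BoxTemplate(2, 0)], [GapConstraint(0, 0)]
    )
    qmin = quorum_threshold(0.7, 10)
    first = _motif("AA", [(i, 0) for i in range(7)])
    p = extend_prefix(EMPTY_PREFIX, first, 1, template, qmin)
    cand6 = _motif("CC", [(i, 2) for i in range(6)])
    cand7 = _motif("CC", [(i, 2) for i in range(7)])
    assert extend_prefix(p, cand6, 2, template, qmin) is None
    assert extend_prefix(p, cand7, 2, template, qmin).support == 7


def _cs(i, box, motifs):
    return BoxCandidateSet(i, box, tuple(motifs))


def test_select_box_order_sorts_by_total_occurrences():
    box = BoxTemplate(2, 0)

    def with_total(i, n):
        return _cs(i, box, [_motif("AA", [(0, k) for k in range(n)])])

    assert select_box_order([with_total(1, 50), with_total(2, 10), with_total(3, 30)]) == [2, 3, 1]
    assert select_box_order([with_total(1, 5), with_total(2, 5)]) == [1, 2]
    assert select_box_order([with_total(1, 1), with_total(2, 2), with_total(3, 3)]) == [1, 2, 3]


def test_partition_slices_ceiling_arithmetic():
    box = BoxTemplate(2, 0)
    motifs = [_motif(f"A{c}", [(0, 0)]) for c in "ACGT"] * 3  # |K| = 12
    cs = _cs(1, box, motifs[:10])
    sizes = [len(s) for s in partition_slices(cs, 4)]
    assert sizes == [4, 4, 2]
    assert [len(s) for s in partition_slices(_cs(1, box, motifs[:3]), 10)] == [3]
    with pytest.raises(ValueError):
        partition_slices(cs, 0)
    # slices preserve order and cover K_i
    rebuilt = [m for s in partition_slices(cs, 3) for m in s.motifs]
    assert rebuilt == list(cs.motifs)


def test_gap_bounds_compound_over_holes():
    t = parse_template("(3,1)-[1,2]-(4,0)-[3,5]-(2,1)")
    assert gap_bounds(t, 1, 2) == (1, 2)
    assert gap_bounds(t, 2, 3) == (3, 5)
    # across the unplaced middle box: gaps plus its length
    assert gap_bounds(t, 1, 3) == (1 + 3 + 4, 2 + 5 + 4)


def test_assemble_toy_instance(tiny_seqs):
    template = parse_template("(3,0)-[2,2]-(3,0)")
    sets = build_candidate_sets(tiny_seqs, template, qmin=2)
    results = assemble(template, sets, qmin=2, print_occurrences=True)
    assert [(r.words, r.support) for r in results] == [(("AAA", "TTT"), 2)]
    assert results[0].occurrences == ((0, (0, 5)), (1, (0, 5)))
    # cross-check against exhaustive enumeration of all 64x64 word pairs
    assert brute_force_structured(tiny_seqs, template, 2) == {("AAA", "TTT"): 2}


def test_assemble_empty_candidate_set_yields_nothing(tiny_seqs):
    template = parse_template("(3,0)-[2,2]-(3,0)")
    sets = build_candidate_sets(tiny_seqs, template, qmin=2)
    empty = [sets[0], _cs(2, template.boxes[1], [])]
    assert assemble(template, empty, qmin=2) == []


def test_assemble_validates_inputs(tiny_seqs):
    template = parse_template("(3,0)-[2,2]-(3,0)")
    sets = build_candidate_sets(tiny_seqs, template, qmin=2)
    with pytest.raises(ValueError):
        assemble(template, sets[:1], qmin=2)
    other = parse_template("(4,0)-[2,2]-(3,0)")
    with pytest.raises(ValueError):
        assemble(other, sets, qmin=2)


@pytest.mark.parametrize("seed", range(12))
def test_assembly_matches_brute_force_and_options_agree(seed):
    """Full pipeline equals exhaustive tuple enumeration; options are inert."""
    rng = np.random.default_rng(1000 + seed)
    seqs, template, qmin = random_small_instance(rng)
    for mode in ("unconstrained", "frequent"):
        sets = build_candidate_sets(seqs, template, qmin, mode)
        expected = brute_force_structured(seqs, template, qmin, mode)
        baseline = assemble(template, sets, qmin)
        assert {r.words: r.support for r in baseline} == expected
        for order in ("basic", "selection"):
            for v in (None, 1, 2, 5):
                alt = assemble(template, sets, qmin, order=order, space_saving=v)
                assert [(r.words, r.support) for r in alt] == [
                    (r.words, r.support) for r in baseline
                ]


@pytest.mark.parametrize("seed", range(4))
def test_reported_occurrences_satisfy_all_gap_constraints(seed):
    rng = np.random.default_rng(2000 + seed)
    seqs, template, qmin = random_small_instance(rng)
    sets = build_candidate_sets(seqs, template, qmin)
    for r in assemble(template, sets, qmin, order="selection", print_occurrences=True):
        assert r.support >= qmin
        assert len({s for s, _ in r.occurrences}) == r.support
        for seq_index, starts in r.occurrences:
            assert check_occurrence_tuple(template, starts)
            # each start really carries the word within its error budget
            for w, box, s in zip(r.words, template.boxes, starts):
                window = seqs.sequences[seq_index][s : s + box.length]
                assert sum(a != b for a, b in zip(window, w)) <= box.errors


def test_quorum_and_gap_monotonicity():
    rng = np.random.default_rng(77)
    seqs, template, _ = random_small_instance(rng, b=2)
    sets1 = build_candidate_sets(seqs, template, 1)
    loose = {r.words for r in assemble(template, sets1, qmin=1)}
    sets2 = build_candidate_sets(seqs, template, 2)
    tight = {r.words for r in assemble(template, sets2, qmin=2)}
    assert tight <= loose

    g = template.gaps[0]
    wider = StructuredTemplate(template.boxes, [GapConstraint(g.dmin, g.dmax + 3)])
    wide_res = {r.words for r in assemble(wider, sets1, qmin=1)}
    assert loose <= wide_res


def test_prefix_support_dominates_extension_support():
    rng = np.random.default_rng(88)
    seqs, template, qmin = random_small_instance(rng, b=2)
    sets = build_candidate_sets(seqs, template, 1)
    for m1 in sets[0].motifs:
        p = extend_prefix(EMPTY_PREFIX, m1, 1, template, 1)
        for m2 in sets[1].motifs:
            r = extend_prefix(p, m2, 2, template, 1)
            if r is not None:
                assert r.support <= p.support
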