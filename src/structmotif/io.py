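"""FASTA and template-string I/O, result writing, pipeline orchestration.

A structured-motif problem is specified on the command line (or in
code) by a template string such as ``(3,1)-[1,1]-(5,2)-[1,200]-(9,1)``:
round-bracket pairs are boxes ``(length, errors)``, square-bracket pairs
are gap bounds ``[dmin, dmax]`` on the bases separating adjacent boxes.
The quorum is supplied separately as a fraction of the input sequences.
"""

from __future__ import annotations

import logging
import re
import time
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO

from .model import (
    BoxTemplate,
    GapConstraint,
    SequenceSet,
    StructuredTemplate,
    TemplateError,
    quorum_threshold,
)
from .stage1 import build_candidate_sets
from .stage2 import StructuredMotifResult, assemble

__all__ = [
    "RunConfig",
    "parse_template",
    "render_template",
    "read_fasta",
    "write_fasta",
    "write_ground_truth",
    "write_results",
    "run_pipeline",
]

logger = logging.getLogger("structmotif")

_BOX = re.compile(r"\(\s*(\d+)\s*,\s*(\d+)\s*\)")
_GAP = re.compile(r"\[\s*(\d+)\s*,\s*(\d+)\s*\]")


class TemplateParseError(TemplateError):
    """Malformed template string; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def parse_template(text: str) -> StructuredTemplate:
    """Parse ``(l1,e1)-[d1,D1]-(l2,e2)-...-(lb,eb)``.

    Whitespace around tokens is tolerated.  Validation (0 <= e < l,
    0 <= d <= D, at least two boxes) is enforced by the domain types.
    """

    pos = 0
    n = len(text)

    def skip_ws():
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def expect(regex: re.Pattern, what: str) -> tuple[int, int]:
        nonlocal pos
        skip_ws()
        m = regex.match(text, pos)
        if m is None:
            raise TemplateParseError(f"expected {what}", pos)
        pos = m.end()
        return int(m.group(1)), int(m.group(2))

    def expect_dash():
        nonlocal pos
        skip_ws()
        if pos >= n or text[pos] != "-":
            raise TemplateParseError("expected '-'", pos)
        pos += 1

    boxes = []
    gaps = []
    ell, err = expect(_BOX, "a box '(length,errors)'")
    boxes.append(BoxTemplate(ell, err))
    skip_ws()
    while pos < n:
        expect_dash()
        d, D = expect(_GAP, "a gap '[dmin,dmax]'")
        gaps.append(GapConstraint(d, D))
        expect_dash()
        ell, err = expect(_BOX, "a box '(length,errors)'")
        boxes.append(BoxTemplate(ell, err))
        skip_ws()
    return StructuredTemplate(boxes, gaps)


def render_template(template: StructuredTemplate) -> str:
    """Inverse of :func:`parse_template` (canonical spacing)."""
    return str(template)


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a multi-record FASTA file, preserving record order.

    Sequences are uppercased; any character outside {A,C,G,T}
    (including ``N``) raises an error naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceSet([str(r.seq) for r in records], [r.id for r in records])


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(seqs.ids, seqs.sequences):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_ground_truth(truth, template: StructuredTemplate, seqs: SequenceSet,
                       path: str | Path) -> None:
    """Planted ground truth as TSV: seq_id, box index, consensus, start."""
    with open(path, "w") as fh:
        fh.write(f"# template\t{render_template(template)}\n")
        fh.write("seq_id\tbox\tconsensus\tstart\n")
        for sid, starts in zip(seqs.ids, truth.starts):
            for i, (word, start) in enumerate(zip(truth.consensus_words, starts), 1):
                fh.write(f"{sid}\t{i}\t{word}\t{start}\n")


def write_results(
    results: Iterable[StructuredMotifResult],
    template: StructuredTemplate,
    out: IO[str],
    seq_ids: tuple[str, ...] | None = None,
) -> None:
    """One TSV record per structured motif.

    ``words-joined-by-dash <TAB> template <TAB> support``; when a result
    carries occurrences, each is printed on a following line as
    ``seq_id <TAB> start_1,start_2,...,start_b`` (0-based).
    """
    tmpl = render_template(template)
    for res in results:
        out.write(f"{'-'.join(res.words)}\t{tmpl}\t{res.support}\n")
        if res.occurrences is not None:
            for seq_index, starts in res.occurrences:
                sid = seq_ids[seq_index] if seq_ids else str(seq_index)
                out.write(f"{sid}\t{','.join(str(s) for s in starts)}\n")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one discovery run."""

    fasta: str | Path
    template: str
    quorum: float
    mode: str = "unconstrained"
    box_order_selection: bool = False
    space_saving: int | None = None
    print_occurrences: bool = False
    out: str | Path | None = None

    def __post_init__(self):
        if self.mode not in ("unconstrained", "frequent"):
            raise ValueError(f"mode must be unconstrained|frequent, got {self.mode!r}")
        if not 0 < self.quorum <= 1:
            raise ValueError(f"quorum must lie in (0, 1], got {self.quorum}")
        if self.space_saving is not None and self.space_saving < 1:
            raise ValueError(
                f"space-saving parameter must be >= 1, got {self.space_saving}"
            )


def run_pipeline(config: RunConfig) -> list[StructuredMotifResult]:
    """Run stage 1 then stage 2 and optionally write the result TSV.

    Logs per-stage wall time and, per box, the candidate-set size |K_i|
    and total occurrence count B_i — the quantities that govern the
    cost of the assembly stage.
    """
    template = parse_template(str(config.template))
    seqs = read_fasta(config.fasta)
    qmin = quorum_threshold(config.quorum, seqs.N)
    logger.info(
        "discovery on %d sequences, template %s, quorum %.3g (>= %d sequences), mode %s",
        seqs.N, template, config.quorum, qmin, config.mode,
    )

    t0 = time.perf_counter()
    candidate_sets = build_candidate_sets(seqs, template, qmin, config.mode)
    t1 = time.perf_counter()
    for cs in candidate_sets:
        logger.info(
            "box %d %s: |K_%d| = %d simple motifs, B_%d = %d occurrences",
            cs.box_index, cs.box, cs.box_index, len(cs),
            cs.box_index, cs.total_occurrences,
        )
    logger.info("stage 1 (simple-motif enumeration): %.2f s", t1 - t0)

    results = assemble(
        template,
        candidate_sets,
        qmin,
        order="selection" if config.box_order_selection else "basic",
        space_saving=config.space_saving,
        print_occurrences=config.print_occurrences,
    )
    t2 = time.perf_counter()
    logger.info(
        "stage 2 (assembly): %.2f s, %d structured motifs", t2 - t1, len(results)
    )

    if config.out is not None:
        with open(config.out, "w") as fh:
            write_results(results, template, fh, seqs.ids)
    return results
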