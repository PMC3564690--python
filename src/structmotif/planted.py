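"""Synthetic planted-motif benchmark datasets.

Emulates the classical Planted Motif Problem extended to structured
motifs: background sequences are i.i.d. uniform over {A,C,G,T}, and one
structured-motif occurrence is written into every sequence at positions
respecting box order and gap constraints.  The consensus words, the
substituted box instances, the gap widths and the leftmost start are all
drawn from a single seeded generator in a fixed order, so datasets are
bit-reproducible.

With quorum 1.0 the planted consensus tuple is guaranteed to appear in
the discovery output, which makes these datasets ground truth for
end-to-end recovery tests.  Background windows may by chance form extra
occurrences; they are deliberately left in place, as in the standard
benchmark setting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DNA_ALPHABET, SequenceSet, StructuredTemplate

__all__ = [
    "PlantedDatasetSpec",
    "PlantedGroundTruth",
    "generate_sequences",
    "mutate_word",
    "plant_dataset",
]


@dataclass(frozen=True)
class PlantedDatasetSpec:
    """Parameters of one synthetic benchmark dataset.

    The template's maximum span (box lengths plus maximum gaps) must fit
    inside the sequence length so that any random gap draw is placeable.
    """

    N: int
    L: int
    template: StructuredTemplate
    seed: int
    plant_exact: bool = False

    def __post_init__(self):
        if self.N < 1 or self.L < 1:
            raise ValueError(f"need N >= 1 and L >= 1, got N={self.N}, L={self.L}")
        span = self.template.max_span()
        if span > self.L:
            raise ValueError(
                f"template maximum span {span} does not fit in sequences "
                f"of length {self.L}"
            )


@dataclass(frozen=True)
class PlantedGroundTruth:
    """The planted consensus words and per-sequence planted positions."""

    consensus_words: tuple[str, ...]
    starts: tuple[tuple[int, ...], ...]  # one b-tuple per sequence


def _random_word(length: int, rng: np.random.Generator) -> str:
    return "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))


def generate_sequences(
    N: int, L: int, rng: np.random.Generator | int
) -> SequenceSet:
    """N i.i.d.-uniform DNA sequences of length L."""
    if N < 1 or L < 1:
        raise ValueError(f"need N >= 1 and L >= 1, got N={N}, L={L}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = rng.integers(0, 4, size=(N, L))
    alphabet = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    seqs = [alphabet[row].tobytes().decode() for row in draws]
    return SequenceSet(seqs)


def mutate_word(
    w: str, e: int, rng: np.random.Generator, *, force_distance: bool = False
) -> str:
    """Substitute ``e`` distinct positions of ``w`` with uniform bases.

    Replacement characters are drawn from all four bases, so the
    realized Hamming distance may be smaller than ``e`` (a redraw may
    reproduce the original base).  With ``force_distance`` each
    replacement is drawn from the three *other* bases, making the
    distance exactly ``e``.
    """
    if not 0 <= e < len(w):
        raise ValueError(f"need 0 <= e < |w|, got e={e}, |w|={len(w)}")
    if e == 0:
        return w
    positions = rng.choice(len(w), size=e, replace=False)
    chars = list(w)
    for pos in positions:
        if force_distance:
            others = DNA_ALPHABET.replace(chars[pos], "")
            chars[pos] = others[rng.integers(0, 3)]
        else:
            chars[pos] = DNA_ALPHABET[rng.integers(0, 4)]
    return "".join(chars)


def plant_dataset(
    spec: PlantedDatasetSpec, *, force_distance: bool = False
) -> tuple[SequenceSet, PlantedGroundTruth]:
    """Generate background sequences and plant one occurrence in each.

    Draw order per dataset: (1) background bases, (2) the b consensus
    words, then per sequence (3) the mutated box instances, (4) the gap
    widths uniform in [dmin, dmax], (5) the leftmost start uniform over
    the feasible range for the realized span.  If ``plant_exact`` is
    set, one randomly chosen sequence receives the unmutated consensus
    words so that every box has at least one exact occurrence.
    """
    rng = np.random.default_rng(spec.seed)
    template = spec.template
    b = template.b
    background = generate_sequences(spec.N, spec.L, rng)
    words = tuple(_random_word(box.length, rng) for box in template.boxes)

    exact_seq = int(rng.integers(0, spec.N)) if spec.plant_exact else -1

    sequences = []
    all_starts = []
    for si, seq in enumerate(background.sequences):
        if si == exact_seq:
            instances = list(words)
        else:
            instances = [
                mutate_word(w, box.errors, rng, force_distance=force_distance)
                for w, box in zip(words, template.boxes)
            ]
        gaps = [int(rng.integers(g.dmin, g.dmax + 1)) for g in template.gaps]
        span = sum(box.length for box in template.boxes) + sum(gaps)
        first = int(rng.integers(0, spec.L - span + 1))
        starts = [first]
        for i in range(1, b):
            starts.append(starts[-1] + template.boxes[i - 1].length + gaps[i - 1])
        chars = list(seq)
        for start, inst in zip(starts, instances):
            chars[start : start + len(inst)] = inst
        sequences.append("".join(chars))
        all_starts.append(tuple(starts))

    return (
        SequenceSet(sequences, background.ids),
        PlantedGroundTruth(words, tuple(all_starts)),
    )
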