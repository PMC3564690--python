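# Methods

## Model

A simple motif is a pair (w, e): a consensus word w ∈ {A,C,G,T}^ℓ and an
error budget 0 ≤ e < ℓ.  Its occurrences in a sequence are the windows at
Hamming distance ≤ e from w (substitutions only; no indels, no
reverse-complement matching, no degenerate alphabet).  A structured motif
is an ordered tuple of b ≥ 2 boxes; between consecutive boxes i and i+1
there must lie between d_i and D_i bases, counted strictly between the end
of box i and the start of box i+1:

    gap_i = start_{i+1} − (start_i + ℓ_i),   d_i ≤ gap_i ≤ D_i.

Since d_i ≥ 0, boxes never overlap.  Coordinates are 0-based with
half-open box intervals [start, start+ℓ).  A motif is valid when at least
⌈qN⌉ of the N input sequences contain at least one full occurrence; the
ceiling is computed as `ceil(q·N − 1e−9)` to neutralise binary-float
artifacts (0.7·10 = 7.000000000000001).  Sequences are uppercased on
input; any character outside {A,C,G,T} (including N) is rejected rather
than silently matched, because the model is defined only on the 4-letter
alphabet.

## Stage 1: simple-motif enumeration

For each distinct (ℓ, e) pair — boxes sharing a template share one run —
the engine spells candidate words letter by letter over the set of all
length-ℓ windows, carrying (window, mismatch-count) pairs.  A branch is
abandoned when its occurrence list empties or its sequence support falls
below the quorum threshold (support is monotone non-increasing along a
branch, so this pruning is exact).  In *frequent* mode a branch must also
retain at least one mismatch-free window, because an exact occurrence of a
word is exact on every prefix; at the leaf this guarantees the word
appears exactly somewhere in the input.  Frequent-mode exactness is
enforced **per box**: each box word needs an exact occurrence somewhere,
not necessarily jointly in one sequence with the other boxes.  The kernel
is JIT-compiled (numba) over an int8 encoding of the concatenated
sequences; occurrence lists come out sorted by (sequence, position) for
free because the window set is spelled in that order and filtering
preserves it.  The worst-case work per (ℓ, e) pair is O(N·L·ν(e,ℓ)) with
ν(e,ℓ) = Σ_{i≤e} C(ℓ,i)·3^i ≤ ℓ^e·4^e, but quorum pruning makes realistic
hard instances (e.g. (13,3) at full quorum on 20×600 bp) run in seconds.

No filtering beyond the quorum is ever applied: significance of simple
motifs says nothing about the existence of structured motifs built from
them, so every candidate is kept.  A naive per-word window scan
(`scan_occurrences`) is kept as the independent oracle; the test suite
checks set equality of the two routes on randomized small inputs.

If the candidate sets outgrow memory this is raised as a distinct
`CandidateMemoryError` (CLI exit code 3): it is the one failure the
space-saving option cannot mitigate, since that option slices stage 2
only.

## Stage 2: assembly

Prefixes (partial structured motifs) are extended one box at a time.
Joining a prefix occurrence with a candidate occurrence in the same
sequence uses a binary search into the candidate's sorted start list for
the smallest start satisfying the minimum distance, then scans forward
until the maximum distance is violated.  A partial motif whose support
drops below ⌈qN⌉ is discarded immediately.

With **box-index selection**, boxes are placed in ascending order of
B_i = Σ_t |occ_{i,t}| instead of left to right (ties break by box index).
Two placed boxes i < k sandwiching unplaced ones are constrained by the
compound interval

    [Σ_{m=i}^{k−1} d_m + Σ_{m=i+1}^{k−1} ℓ_m ,
     Σ_{m=i}^{k−1} D_m + Σ_{m=i+1}^{k−1} ℓ_m]

on the bases between them; when a hole is later filled, both flanking
constraints are checked exactly, so occurrences that only satisfied the
compound bound are dropped.  This is the unique semantics under which the
selection order returns exactly the basic-order result set, which the
suite verifies by direct comparison on randomized instances.

**Space saving** partitions each K_i into ⌈|K_i|/v⌉ order-preserving
slices of at most v motifs and assembles once per cell of the Cartesian
product of slices.  The product is walked depth-first, so only the
prefixes arising from one slice per box are alive at any moment (the
memory contract), while each (prefix, candidate) extension is still
performed exactly once; the union of per-cell outputs equals the
single-run output because every word tuple lives in exactly one cell.
Under selection order the slices are formed in original box-index space
and the globally computed order is used inside every cell, keeping the
two options composable.

Multiple occurrences of one motif in a sequence are all enumerated and
deduplicated by (sequence, start tuple); support counts each sequence
once.  Gap upper bounds larger than the sequences are legal — the distance
check truncates naturally.  Results are sorted lexicographically by
concatenated box words so output files are deterministic.

## Synthetic benchmark (planted structured motifs)

`plant_dataset` emulates the planted-motif benchmark: N i.i.d.-uniform
sequences of length L (default study condition 20 × 600), one structured
occurrence written into each.  Per dataset, a single seeded generator
draws, in fixed order: background bases; the b consensus words; then per
sequence the mutated box instances, the gap widths (uniform in
[d_i, D_i], independently per sequence), and the leftmost start (uniform
over the feasible range for the realized span).  Substituted positions
are distinct and the replacement base is drawn uniformly from **all
four** bases, so the realized distance is ≤ e_i (a `force_distance`
switch draws from the three other bases when exactly e_i is wanted; it is
off by default).  Feasibility requires Σℓ_i + ΣD_i ≤ L.  With
`plant_exact`, one randomly chosen sequence receives the unmutated words,
giving every box an exact occurrence (needed for frequent-mode recovery).

The generator reproduces the benchmark's statistical design, not real
promoters: the background is 0-order uniform (no GC bias, no repeats, no
Markov structure), exactly one occurrence is planted per sequence, and
chance occurrences arising in the background are deliberately left in.
Recovery tests on these data therefore demonstrate algorithmic
correctness and exactness — at q = 1.0 the planted tuple is guaranteed
by construction to be in the output — not biological sensitivity.

The difficulty label E(ℓ,e) — the expected number of simple motifs at
full quorum in pure noise — uses the window-independence approximation

    E(ℓ,e) = 4^ℓ · [1 − (1 − ν(e,ℓ)/4^ℓ)^(L−ℓ+1)]^N,

cross-validated by Monte Carlo in the tests (agreement within a few
percent at small sizes despite overlapping-window correlation).  It is a
labelling device only and never filters output.  Boxes with E ≈ 1, such
as (9,2) or (11,3) at 20×600, make the interesting benchmark instances.

## Test problem sizes

The suite checks oracle equivalence of the full pipeline (both modes,
both assembly orders, slice widths v ∈ {1, 2, 5, ∞}) against exhaustive
word-tuple enumeration on 200 randomized instances with N ≤ 5, L ≤ 40 and
word lengths ≤ 3 (dyads) or ≤ 2 (triads) — sizes chosen so the 4^Σℓ
oracle remains exact — and planted-motif recovery on 50 seeded 20×600
datasets with b ∈ 2..5 and boxes drawn from {(9,2), (10,2), (11,2),
(11,3), (12,3), (13,3)}.  Saturation counts (the full 4^ℓ candidate space
reaching quorum for (3,1), (5,2), (4,1), (2,1) on promoter-set-sized
random data) are combinatorially forced: the per-word failure probability
is below 10^−10, so the expected counts are exact for any seed.

## Known limitations

- Forward strand only; no reverse-complement search.
- Substitution-only divergence; no insertions/deletions, no PSSMs.
- Stage 1 holds all candidate sets in memory; pathological templates
  (long boxes with near-ℓ error budgets at low quorum) can exhaust it.
- E(ℓ,e) ignores window overlap correlation; it is a difficulty label,
  not a significance score, and no significance scoring is provided.
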