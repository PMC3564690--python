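# structmotif

Exact two-stage discovery of **structured DNA motifs** — ordered groups of
transcription-factor binding sites separated by bounded spacers — in a set
of DNA sequences, together with the planted-motif synthetic benchmark used
to validate recovery.

## The problem

In higher eukaryotes, transcription factors often act in concert: several
short binding sites occur in a fixed order, separated by variable but
bounded numbers of irrelevant bases (a *cis-regulatory module*).  Under the
Hamming-distance model a *simple motif* (a **box**) is a consensus word
*w* of length *ℓ* over {A,C,G,T} together with an error budget *e*
(0 ≤ *e* < *ℓ*); its occurrences are all sequence windows *v* with
*d*<sub>H</sub>(*w*, *v*) ≤ *e*.  A *structured motif* is an ordered tuple
of *b* ≥ 2 boxes; an occurrence must place the boxes in order with
*d*<sub>i</sub> ≤ gap ≤ *D*<sub>i</sub> bases strictly between consecutive
boxes.  A problem instance is written as a template string

```
(ℓ1,e1)-[d1,D1]-(ℓ2,e2)-...-(ℓb,eb)
```

plus a quorum *q* ∈ (0,1]: a motif is reported iff it occurs in at least
⌈*qN*⌉ of the *N* input sequences.  Discovery is **exact and enumerative**:
the output is *every* word tuple conforming to the specification, with no
statistical filtering (a structured motif can reach quorum even when each
box alone is a weak signal).

Discovery proceeds in two stages:

1. **Simple-motif enumeration** — for each distinct box template
   (ℓ<sub>i</sub>,e<sub>i</sub>), spell all quorum-satisfying consensus
   words over a shared window set, collecting complete occurrence lists
   sorted by (sequence, position).  *Unconstrained* mode ranges over all of
   Σ<sup>ℓ</sup>; *frequent* mode additionally requires at least one exact
   occurrence per box word.
2. **Assembly** — build partial structured motifs of increasing size by
   intersecting sorted occurrence lists, with a binary-search *distance
   check* against the gap bounds and a *quorum check* that prunes any
   partial motif whose support already fell below ⌈*qN*⌉ (extension can
   only shrink support, so the pruning is exact).

Two options trade resources without changing the output: *box-index
selection* assembles boxes in ascending order of total occurrence count
B<sub>i</sub> = Σ<sub>t</sub>|occ<sub>i,t</sub>|, and *space saving* slices
each candidate set into chunks of at most *v* motifs, walking the Cartesian
product of chunks to bound the number of intermediates held at once.

## Worked example

Plant a `(9,2)-[5,10]-(10,2)` structured motif once per sequence in 20
random sequences of 600 bp, then recover it at full quorum
(`examples/planted_recovery.py`):

```text
planted TTTGCATCT-GGTGGAGAGA in 20 sequences
  box (9,2): ~1.6 chance motifs expected at full quorum
  box (10,2): ~0.0 chance motifs expected at full quorum
  K_1: 11 simple motifs, B_1 = 381 occurrences
  K_2: 1 simple motifs, B_2 = 24 occurrences
1 structured motif(s) at quorum 1.0:
  TTTGCATCT-GGTGGAGAGA  support 20  <- planted
```

`K_i` is the stage-1 candidate set for box *i* and `B_i` its total
occurrence count; the (9,2) box sits in the "expectation near one" regime,
so a handful of chance simple motifs appear, but only the planted pair
satisfies the gap and quorum constraints jointly.

The same pipeline is available from the shell:

```sh
structmotif generate --n 20 --len 600 -t '(9,2)-[5,10]-(10,2)' --seed 11 -o bench
structmotif discover -f bench.fasta -t '(9,2)-[5,10]-(10,2)' -q 1.0 -o found.tsv
```

Results are TSV: `box-words <TAB> template <TAB> support`, optionally
followed by per-occurrence lines (`--print-occurrences`).  Other examples:
`examples/discover_in_fasta.py` (pipeline on a FASTA file),
`examples/saturation_counts.py` (candidate-space saturation of permissive
boxes), `examples/instance_difficulty.py` (expected chance-motif counts
E(ℓ,e) used to rank benchmark difficulty).

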