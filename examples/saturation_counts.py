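"""Stage-1 candidate-space saturation on permissive box templates.

Short boxes with a generous error budget are weak constraints: on
random DNA of realistic promoter-set size, *every* word of Sigma^l
reaches the quorum, so the enumeration returns the full 4^l candidate
space.  This reproduces the simple-motif counts observed on the yeast
co-regulation datasets, whose sizes are mimicked here.
"""

from structmotif import BoxTemplate, find_simple_motifs, generate_sequences, quorum_threshold

SETTINGS = [
    # N, L, (l, e), quorum  — sized like the 10-gene and 23-gene sets
    (10, 300, (3, 1), 0.70),
    (10, 300, (5, 2), 0.70),
    (23, 800, (4, 1), 0.68),
    (23, 800, (2, 1), 0.68),
]

for N, L, (ell, e), q in SETTINGS:
    seqs = generate_sequences(N, L, 5 * ell)
    qmin = quorum_threshold(q, N)
    motifs = find_simple_motifs(seqs, BoxTemplate(ell, e), qmin)
    print(
        f"({ell},{e}) on {N} x {L} bp, quorum >= {qmin}: "
        f"{len(motifs)} motifs (4^{ell} = {4**ell})"
    )
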