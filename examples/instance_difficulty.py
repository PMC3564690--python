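"""Rank box templates by expected chance-motif count.

E(l, e) estimates how many simple motifs of a given template reach full
quorum in 20 random sequences of 600 bp purely by chance.  Templates
with E near 1 are the interesting planted-benchmark instances: the
planted motif emerges alongside only a handful of impostors.  E far
above 1 means the box is an uninformative (saturated) constraint.
"""

from structmotif import expected_random_motif_count, neighborhood_size

POOL = [(9, 2), (10, 2), (11, 2), (11, 3), (12, 3), (13, 3), (3, 1), (5, 2)]

print(f"{'box':>8} {'nu(e,l)':>8} {'E(l,e) at 20x600':>18}")
for ell, e in sorted(POOL):
    E = expected_random_motif_count(ell, e, N=20, L=600)
    print(f"({ell:>2},{e}) {neighborhood_size(ell, e):>8} {E:>18.3g}")
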