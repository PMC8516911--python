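"""Predict canonical G4 motifs on both strands of a short sequence.

A canonical motif is four runs of three or more guanines joined by 1-7 nt
loops.  Minus-strand motifs are found on the reverse complement and
reported in plus-strand coordinates.
"""

from g4miner import predict_canonical, reverse_complement

core = "GGGAGGGAGGGAGGG"
seq = "TTACT" + core + "ACTAT" + reverse_complement("GGGTTGGGTTGGGTTGGG") + "ACT"

motifs = predict_canonical(seq, "both", contig="demo")
print(f"{len(motifs)} motifs in a {len(seq)}-nt sequence")
for m in motifs:
    print(f"  {m.contig}\t{m.start}\t{m.end}\t{m.strand}\t{m.sequence}")
# Each line is a motif interval (0-based half-open), its strand, and the
# plus-strand sequence it spans; the second motif folds on the minus strand.
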