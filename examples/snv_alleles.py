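"""SNV effects on G4 formation: homozygous motif turnover and an
allele-split call at a heterozygous locus.

A single substitution can complete or destroy a G4 motif; for heterozygous
variants the reads are partitioned by the base they carry and MG4 calling
is repeated per allele group.
"""

import tempfile

from g4miner import apply_homozygous, pg4_delta
from g4miner.scanner import ScannerParams
from g4miner.simulate import SimConfig, make_genome, simulate_reads
from g4miner.snv import Variant, allele_split_call

# homozygous: an A->G completes the fourth tract and a motif is gained
ref = {"c": "TTACT" + "GGGAGGGAGGGAGAG" + "TCATT"}
mod = apply_homozygous(ref, [Variant("c", 18, "A", "G", "hom")])
delta = pg4_delta(ref, mod)
print("homozygous edit:", ref["c"], "->", mod["c"])
print(f"  motifs gained={len(delta['gained'])} lost={len(delta['lost'])}")

# heterozygous: simulate a locus where only the alternate allele completes
# a motif and folds; classify it from the reads
cfg = SimConfig(length=40_000, n_canonical=4, n_long_loops=0, n_bulges=0,
                n_two_tracts=0, n_i_motif=0, n_poly_at=0, n_null=0,
                n_het=3, depth=60.0, p_fold=0.9, seed=8)
genome, truth, het = make_genome(cfg)
with tempfile.NamedTemporaryFile(suffix=".sam") as tmp:
    simulate_reads(genome, truth, het, cfg, tmp.name)
    params = ScannerParams(M=3, N=10)
    for h in het:
        call = allele_split_call(
            tmp.name, Variant(h.contig, h.position, h.ref, h.alt, "het"),
            genome[h.contig], params,
        )
        print(f"het {h.contig}:{h.position} {h.ref}>{h.alt} "
              f"ref_reads={call.ref_reads} alt_reads={call.alt_reads} "
              f"ref_mg4={call.ref_mg4} alt_mg4={call.alt_mg4} -> {call.klass}")
# 'minus_plus' means the reference allele does not form a G4 while the
# alternate allele does -- an allele-specific structure call.
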