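"""Per-region G4 densities from a gene model and interval-set comparison.

Builds UTR/exon/intron/CDS/promoter/TSS/splice regions from a refGene-like
table, counts features overlapping each region class, and reports densities
per kilobase.
"""

import pandas as pd

from g4miner import build_region_models, compare_sets, region_density

genes = pd.DataFrame([
    {"chrom": "chr1", "strand": "+", "txStart": 10_000, "txEnd": 20_000,
     "cdsStart": 11_000, "cdsEnd": 19_000,
     "exonStarts": "10000,15000,", "exonEnds": "12000,20000,"},
    {"chrom": "chr1", "strand": "-", "txStart": 30_000, "txEnd": 36_000,
     "cdsStart": 30_500, "cdsEnd": 35_500,
     "exonStarts": "30000,33000,", "exonEnds": "31000,36000,"},
])
regions = build_region_models(genes)

features = [("chr1", s, s + 30, "+") for s in
            (9_500, 10_100, 11_500, 12_500, 16_000, 19_500, 30_200, 35_800)]
table = region_density(features, regions)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# count = features overlapping >=1 bp any region of the class (once per
# class); density = count per kilobase of summed region length.

rep1 = [("chr1", 100, 220, "+"), ("chr1", 400, 520, "-")]
rep2 = [("chr1", 150, 260, "+"), ("chr1", 900, 1000, "-")]
print("replicate overlap:", compare_sets(rep1, rep2))
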