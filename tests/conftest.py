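import numpy as np
import pysam
import pytest


def write_sam(path, reads, contigs=(("chr1", 100_000),), sort=True, so="coordinate"):
    """Write a SAM from (contig, pos, strand, seq, quals[, mapq]) tuples."""
    hd = {"VN": "1.6"}
    if so:
        hd["SO"] = so
    header = pysam.AlignmentHeader.from_dict(
        {"HD": hd, "SQ": [{"SN": c, "LN": ln} for c, ln in contigs]}
    )
    rows = list(reads)
    if sort:
        rows.sort(key=lambda r: (r[0], r[1]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, row in enumerate(rows):
            contig, pos, strand, seq, quals = row[:5]
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.flag = 16 if strand == "-" else 0
            a.reference_id = out.get_tid(contig)
            a.reference_start = pos
            a.mapping_quality = row[5] if len(row) > 5 else 60
            a.cigarstring = f"{len(seq)}M"
            a.query_sequence = seq
            if quals is not None:
                a.query_qualities = list(quals)
            out.write(a)
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
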