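"""Synthetic genomes and reads with the unstable-G4 quality-drop model.

The generator emulates the mechanism the detector targets: in a standard
sequencing run a G4 folds in only a fraction of the template molecules of a
cluster, so a fraction ``p_fold`` of the reads on the motif strand show a
quality drop of magnitude ``delta`` beginning at the motif start and running
to the end of the read, while base calls themselves stay correct.

A simulated genome is i.i.d. background sequence with structured features
implanted at well-separated loci: canonical and noncanonical G4 motifs
(drop-bearing), i-motif and poly-A/T elements and G-rich shuffled null loci
(not drop-bearing), and optional heterozygous loci where only one allele
completes a G4 motif.  Any canonical motif arising in the background also
folds, so the predicted-motif truth set and the drop model stay consistent.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .motifs import predict_canonical, reverse_complement

__all__ = [
    "SimConfig",
    "SimFeature",
    "HetLocus",
    "make_genome",
    "simulate_reads",
    "evaluate",
    "sample_family",
    "write_fasta",
    "write_truth_bed",
    "write_het_vcf",
]

#: implanted families that fold and drop quality on their own strand
DROP_FAMILIES = ("canonical", "long_loops", "bulges", "two_tracts")

# non-G pad around every implant; 8 nt exceeds the 7-nt canonical loop bound
# so flanking background sequence can never extend an implanted motif
_PAD = "TACTACTA"


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Depth is per strand.  Qualities model Illumina's dominant read-to-read
    variation: each read draws a quality level ``Normal(q_baseline,
    q_jitter)`` held along the read, each base adds ``Normal(0,
    q_base_jitter)``, and scores are rounded and clipped to [2, 41].
    ``delta`` is the per-read drop magnitude and ``p_fold`` the per-read
    fold probability on the motif strand.  ``drop_span=None`` drops to the
    end of the read.
    """

    length: int = 200_000
    contig: str = "sim1"
    n_canonical: int = 24
    n_long_loops: int = 2
    n_bulges: int = 2
    n_two_tracts: int = 2
    n_i_motif: int = 2
    n_poly_at: int = 2
    n_null: int = 2
    n_het: int = 0
    read_length: int = 150
    depth: float = 30.0
    q_baseline: int = 37
    q_jitter: float = 2.0
    q_base_jitter: float = 0.5
    delta: int = 6
    p_fold: float = 0.3
    drop_span: Optional[int] = None
    gc_content: float = 0.5
    min_spacing: int = 500
    het_alt_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("p_fold", "het_alt_fraction", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SimFeature:
    contig: str
    start: int
    end: int
    strand: str
    family: str
    drop_bearing: bool

    @property
    def drop_start(self) -> int:
        """Strand-oriented 5' start locus of the feature (plus coordinate)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class HetLocus:
    """A heterozygous SNV where only the alternate allele completes a motif."""

    contig: str
    position: int  # 0-based plus-strand coordinate
    ref: str  # plus-strand bases
    alt: str
    strand: str  # strand of the motif the alt allele completes
    motif_start: int
    motif_end: int
    alt_fraction: float = 0.5

    @property
    def drop_start(self) -> int:
        return self.motif_start if self.strand == "+" else self.motif_end - 1


# ---------------------------------------------------------------------------
# Family samplers
# ---------------------------------------------------------------------------

def _bases(rng, n: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), int(n)))


def _loop(rng, lo: int, hi: int, allow_g: bool) -> str:
    return _bases(rng, rng.integers(lo, hi + 1), "ATCG" if allow_g else "ACT")


def sample_family(family: str, rng, allow_g_loops: bool = False) -> str:
    """Draw a random sequence from a family's grammar.

    With ``allow_g_loops=False`` loops are drawn from {A,C,T}, so the sample
    belongs to exactly its generating family; with ``allow_g_loops=True``
    loops cover the full grammar alphabet and the sample may additionally
    match a more stable family.
    """
    if family == "canonical":
        tracts = ["G" * int(rng.integers(3, 6)) for _ in range(4)]
        loops = [_loop(rng, 1, 7, allow_g_loops) for _ in range(3)]
    elif family == "long_loops":
        # loop-length arrangements of the grammar (L = 8-12 nt, S = 1-7 nt)
        arrangements = ["LSS", "SLS", "LLS", "LSL", "LLL"]
        arr = arrangements[int(rng.integers(0, 5))]
        tracts = ["G" * 3 for _ in range(4)]
        tracts[0] = "G" * int(rng.integers(3, 6))
        tracts[3] = "G" * int(rng.integers(3, 6))
        loops = [
            _loop(rng, 8, 12, allow_g_loops) if c == "L" else _loop(rng, 1, 7, allow_g_loops)
            for c in arr
        ]
    elif family == "bulges":
        tracts = ["G" * int(rng.integers(3, 6)) for _ in range(4)]
        if rng.integers(0, 2) == 0:
            i = int(rng.integers(0, 4))
            tracts[i] = "G" + _bases(rng, rng.integers(1, 8), "ATC") + "GG"
        else:
            k = int(rng.integers(2, 5))
            for i in rng.permutation(4)[:k]:
                tracts[i] = "G" + _bases(rng, rng.integers(1, 3), "ATC") + "GG"
        loops = [_loop(rng, 1, 7, allow_g_loops) for _ in range(3)]
    elif family == "two_tracts":
        tracts = ["GG"] * 4
        loops = [_loop(rng, 1, 12, False) for _ in range(3)]
        if allow_g_loops:
            loops = [_loop(rng, 1, 12, True) for _ in range(3)]
    elif family == "i_motif":
        tracts = ["C" * int(rng.integers(3, 6)) for _ in range(4)]
        loops = [_bases(rng, rng.integers(1, 8), "AT") for _ in range(3)]
    elif family == "poly_at":
        return _bases(rng, 1, "AT") * int(rng.integers(10, 16))
    elif family == "null":
        return _null_sequence(rng)
    else:
        raise ValueError(f"unknown family {family!r}")
    out = tracts[0]
    for loop, tract in zip(loops, tracts[1:]):
        out += loop + tract
    return out


def _null_sequence(rng, length: int = 30, g_frac: float = 0.4) -> str:
    """A guanine-rich sequence with all G>=3 and C>=3 runs broken, so it
    passes the guanine-content filter without forming a canonical motif on
    either strand."""
    n_g = int(round(length * g_frac))
    pool = list("G" * n_g + _bases(rng, length - n_g, "ACT"))
    seq = list(np.array(pool)[rng.permutation(length)])
    for i in range(1, length - 1):
        if seq[i - 1] == seq[i] == seq[i + 1] and seq[i] in "GC":
            seq[i] = "A" if seq[i] == "G" else "T"
    return "".join(seq)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def make_genome(
    config: SimConfig,
) -> Tuple[Dict[str, str], List[SimFeature], List[HetLocus]]:
    """Build a genome with implanted features and truth records.

    Features (and heterozygous loci) are placed in equal slots along the
    contig with pairwise gaps of at least ``min_spacing``; each implant is
    padded with 8 non-G bases on both sides so flanking sequence cannot
    extend it.  After assembly, canonical motifs arising in the background
    are appended to the truth as drop-bearing features, so every predicted
    canonical motif in the genome folds.
    """
    rng = np.random.default_rng(config.seed)
    plan = (
        ["canonical"] * config.n_canonical
        + ["long_loops"] * config.n_long_loops
        + ["bulges"] * config.n_bulges
        + ["two_tracts"] * config.n_two_tracts
        + ["i_motif"] * config.n_i_motif
        + ["poly_at"] * config.n_poly_at
        + ["null"] * config.n_null
        + ["het"] * config.n_het
    )
    n_slots = len(plan)
    L = config.length
    margin = 1000
    slot = (L - 2 * margin) // max(n_slots, 1) if n_slots else 0
    if n_slots and slot < config.min_spacing + 120:
        raise ValueError(
            f"{n_slots} features do not fit in {L} bp at >= "
            f"{config.min_spacing} bp spacing"
        )
    order = rng.permutation(n_slots)

    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = bytearray(
        "".join(np.array(list("ACGT"))[rng.choice(4, L, p=probs)]), "ascii"
    )

    contig = config.contig
    features: List[SimFeature] = []
    het: List[HetLocus] = []
    for k in range(n_slots):
        family = plan[order[k]]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if family == "het":
            seq = sample_family("canonical", rng)
            seq, off = _break_last_tract(seq)
        else:
            seq = sample_family(family, rng)
        pad_len = slot - len(seq) - 2 * len(_PAD)
        offset = int(rng.integers(0, max(1, pad_len - config.min_spacing)))
        start = margin + k * slot + offset + len(_PAD)
        oriented = seq if strand == "+" else reverse_complement(seq)
        block = _PAD + oriented + _PAD
        genome[start - len(_PAD) : start - len(_PAD) + len(block)] = block.encode()
        end = start + len(seq)
        if family == "het":
            if strand == "+":
                pos = start + off
                ref_b, alt_b = "A", "G"
            else:
                pos = end - 1 - off
                ref_b, alt_b = "T", "C"
            het.append(
                HetLocus(
                    contig, pos, ref_b, alt_b, strand, start, end,
                    config.het_alt_fraction,
                )
            )
        else:
            features.append(
                SimFeature(contig, start, end, strand, family,
                           family in DROP_FAMILIES)
            )

    seq_str = genome.decode("ascii")
    # background canonical motifs fold too; add them to the truth
    for m in predict_canonical(seq_str, "both", contig=contig):
        if not any(
            f.strand == m.strand and m.start < f.end and f.start < m.end
            for f in features
        ) and not any(h.motif_start - 8 <= m.start < h.motif_end + 8 for h in het):
            features.append(
                SimFeature(contig, m.start, m.end, m.strand, "canonical", True)
            )
    features.sort(key=lambda f: f.start)
    return {contig: seq_str}, features, het


def _break_last_tract(seq: str) -> Tuple[str, int]:
    """Replace the middle G of the final tract with A; returns the broken
    sequence and the offset of the substitution."""
    i = len(seq) - 1
    while seq[i] == "G":
        i -= 1
    run_start = i + 1
    off = run_start + (len(seq) - run_start) // 2
    return seq[:off] + "A" + seq[off + 1 :], off


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: Dict[str, str],
    truth: Sequence[SimFeature],
    het: Sequence[HetLocus],
    config: SimConfig,
    path: str,
) -> str:
    """Write a coordinate-sorted SAM of error-free reads with the drop model.

    Reads are single-end, uniform starts, both strands at ``config.depth``
    per strand, CIGAR all-match.  A read on a drop-bearing feature's strand
    whose span includes the feature's strand-oriented start has, with
    probability ``p_fold``, all qualities from that locus onward (in read
    orientation) reduced by ``delta``.  At heterozygous loci each read draws
    its allele; only alternate-allele reads on the motif strand can drop.
    Deterministic for a fixed config (seed included).
    """
    rng = np.random.default_rng((config.seed + 1) * 7919 % (2**31))
    rl = config.read_length
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
        }
    )
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for contig, seq in genome.items():
            L = len(seq)
            if L < rl:
                continue
            n_per_strand = int(round(config.depth * L / rl))
            drop_pos = {"+": [], "-": []}
            for f in truth:
                if f.contig == contig and f.drop_bearing:
                    drop_pos[f.strand].append(f.drop_start)
            for s in drop_pos:
                drop_pos[s].sort()
            het_here = sorted(
                (h for h in het if h.contig == contig), key=lambda h: h.position
            )
            het_pos = [h.position for h in het_here]

            reads = []
            for strand in "+-":
                starts = rng.integers(0, L - rl + 1, n_per_strand)
                reads.extend((int(t), strand) for t in starts)
            reads.sort()

            for i, (t, strand) in enumerate(reads):
                bases = bytearray(seq[t : t + rl], "ascii")
                level = rng.normal(config.q_baseline, config.q_jitter)
                quals = np.clip(
                    np.rint(level + rng.normal(0.0, config.q_base_jitter, rl)),
                    2, 41,
                ).astype(np.int64)

                # allele draws at covered heterozygous loci
                alleles = {}
                lo = bisect_left(het_pos, t)
                hi = bisect_right(het_pos, t + rl - 1)
                for h in het_here[lo:hi]:
                    is_alt = rng.random() < h.alt_fraction
                    alleles[h.position] = is_alt
                    if is_alt:
                        bases[h.position - t] = ord(h.alt)

                # constitutive drops
                dp = drop_pos[strand]
                for d in dp[bisect_left(dp, t) : bisect_right(dp, t + rl - 1)]:
                    if rng.random() < config.p_fold:
                        _apply_drop(quals, t, d, strand, rl, config)
                # allele-conditional drops
                for h in het_here[lo:hi]:
                    if (
                        h.strand == strand
                        and alleles.get(h.position)
                        and t <= h.drop_start < t + rl
                        and rng.random() < config.p_fold
                    ):
                        _apply_drop(quals, t, h.drop_start, strand, rl, config)

                a = pysam.AlignedSegment(header)
                a.query_name = f"r{i:07d}"
                a.flag = 16 if strand == "-" else 0
                a.reference_id = out.get_tid(contig)
                a.reference_start = t
                a.mapping_quality = 60
                a.cigarstring = f"{rl}M"
                a.query_sequence = bases.decode("ascii")
                a.query_qualities = quals.tolist()
                out.write(a)
    return path


def _apply_drop(quals: np.ndarray, t: int, d: int, strand: str, rl: int, config) -> None:
    i = d - t
    if strand == "+":
        sl = slice(i, rl if config.drop_span is None else min(rl, i + config.drop_span))
    else:
        sl = slice(0 if config.drop_span is None else max(0, i + 1 - config.drop_span), i + 1)
    quals[sl] = np.maximum(quals[sl] - config.delta, 2)


# ---------------------------------------------------------------------------
# Evaluation against truth
# ---------------------------------------------------------------------------

def evaluate(calls, truth: Sequence[SimFeature]) -> Dict[str, object]:
    """Recall/precision of detection calls against drop-bearing truth.

    A truth feature is recovered iff it shares >=1 bp same-strand overlap
    with a call; a call is a true positive iff it overlaps any drop-bearing
    truth feature.  Returns recall, precision, fdr and per-family recall.
    """
    pos = [f for f in truth if f.drop_bearing]

    def overlaps(a, b) -> bool:
        return (
            a.contig == b.contig
            and a.strand == b.strand
            and a.start < b.end
            and b.start < a.end
        )

    recovered = [f for f in pos if any(overlaps(f, c) for c in calls)]
    tp_calls = [c for c in calls if any(overlaps(c, f) for f in pos)]
    recall = len(recovered) / len(pos) if pos else None
    precision = len(tp_calls) / len(calls) if calls else None
    per_family: Dict[str, float] = {}
    for fam in sorted({f.family for f in pos}):
        fam_pos = [f for f in pos if f.family == fam]
        fam_rec = [f for f in recovered if f.family == fam]
        per_family[fam] = len(fam_rec) / len(fam_pos)
    return {
        "n_truth": len(pos),
        "n_calls": len(calls),
        "recall": recall,
        "precision": precision,
        "fdr": (1.0 - precision) if precision is not None else None,
        "per_family_recall": per_family,
    }


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fasta(genome: Dict[str, str], path: str, width: int = 60) -> str:
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def write_truth_bed(truth: Sequence[SimFeature], path: str) -> str:
    with open(path, "w") as fh:
        for f in truth:
            drop = "drop" if f.drop_bearing else "nodrop"
            fh.write(
                f"{f.contig}\t{f.start}\t{f.end}\t{f.family};{drop}\t0\t{f.strand}\n"
            )
    return path


def write_het_vcf(het: Sequence[HetLocus], genome: Dict[str, str], path: str) -> str:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig, seq in genome.items():
            fh.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsim\n")
        for h in sorted(het, key=lambda x: (x.contig, x.position)):
            fh.write(
                f"{h.contig}\t{h.position + 1}\t.\t{h.ref}\t{h.alt}\t.\tPASS\t.\tGT\t0/1\n"
            )
    return path
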