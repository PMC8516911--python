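"""SNV effects on G4 formation.

Homozygous variants are applied to the reference and the predicted-motif
sets of the two genomes are differenced (motifs gained and lost).  For
heterozygous variants, reads are partitioned by the base observed at the
variant; mined-G4 calling is repeated per allele group and the variant is
classed by the two per-allele outcomes: ``++`` (both alleles form), ``+-`` /
``-+`` (only one allele forms), ``--`` (neither), or ``insufficient`` when
an allele group has too few reads for a usable median track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pysam

from .detect import MG4Record, call_mg4
from .motifs import PG4Motif, predict_canonical
from .qualtrack import build_tracks_from_reads
from .scanner import ScannerParams

__all__ = [
    "SnvCall",
    "apply_homozygous",
    "read_vcf",
    "pg4_delta",
    "allele_split_call",
]

log = logging.getLogger(__name__)

CLASSES = ("plus_plus", "plus_minus", "minus_plus", "minus_minus", "insufficient")


@dataclass(frozen=True)
class SnvCall:
    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    zygosity: str
    ref_reads: int = 0
    alt_reads: int = 0
    ref_mg4: str = "insufficient"  # yes | no | insufficient
    alt_mg4: str = "insufficient"
    klass: str = "insufficient"


@dataclass(frozen=True)
class Variant:
    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    zygosity: str  # hom | het


def read_vcf(path: str) -> List[Variant]:
    """Biallelic SNVs from a VCF; zygosity from the first sample's GT.
    Indels and multiallelic records are skipped with a log message."""
    out: List[Variant] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if len(rec.alts or ()) != 1:
                log.warning("skipping multiallelic record at %s:%d", rec.chrom, rec.pos)
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                log.warning("skipping indel at %s:%d", rec.chrom, rec.pos)
                continue
            if rec.samples:
                gt = rec.samples[0].get("GT", ())
                alleles = {a for a in gt if a is not None}
                zyg = "het" if len(alleles) > 1 else "hom"
            else:
                zyg = "hom"
            out.append(Variant(rec.chrom, rec.pos - 1, ref, alt, zyg))
    return out


def apply_homozygous(
    reference: Mapping[str, str], variants: Sequence[Variant]
) -> Dict[str, str]:
    """Apply homozygous SNVs to a reference (``{contig: sequence}``).

    Sequence lengths are preserved; records whose stated reference allele
    disagrees with the genome are rejected with a log message, as are
    heterozygous records and indels.
    """
    seqs = {c: bytearray(s, "ascii") for c, s in reference.items()}
    for v in variants:
        if v.zygosity != "hom":
            continue
        if len(v.ref) != 1 or len(v.alt) != 1:
            log.warning("skipping indel at %s:%d", v.contig, v.position)
            continue
        buf = seqs.get(v.contig)
        if buf is None:
            log.warning("contig %r not in reference; record skipped", v.contig)
            continue
        if chr(buf[v.position]).upper() != v.ref.upper():
            log.warning(
                "reference mismatch at %s:%d (genome %s, VCF %s); record rejected",
                v.contig, v.position, chr(buf[v.position]), v.ref,
            )
            continue
        buf[v.position] = ord(v.alt.upper())
    return {c: b.decode("ascii") for c, b in seqs.items()}


def pg4_delta(
    reference: Mapping[str, str], modified: Mapping[str, str]
) -> Dict[str, List[PG4Motif]]:
    """Motifs gained and lost between two same-shape genomes.

    Motifs are matched by identical (contig, start, end, strand) interval —
    a shifted motif counts as one loss plus one gain, never silently as
    neither.
    """
    if set(reference) != set(modified) or any(
        len(reference[c]) != len(modified[c]) for c in reference
    ):
        raise ValueError("genomes must share contigs and lengths")

    def key_set(genome):
        keys = {}
        for c, seq in sorted(genome.items()):
            for m in predict_canonical(seq, "both", contig=c):
                keys[(m.contig, m.start, m.end, m.strand)] = m
        return keys

    ref_k = key_set(reference)
    mod_k = key_set(modified)
    gained = [mod_k[k] for k in sorted(set(mod_k) - set(ref_k))]
    lost = [ref_k[k] for k in sorted(set(ref_k) - set(mod_k))]
    return {"gained": gained, "lost": lost}


def _base_at(read, position: int) -> Optional[str]:
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == position:
            return read.query_sequence[qpos].upper()
    return None


def allele_split_call(
    alignments,
    variant: Variant,
    sequence: str,
    params: Union[ScannerParams, Mapping[str, ScannerParams]],
    r_min: int = 10,
    d_min: int = 10,
    g_mode: str = "GC",
) -> SnvCall:
    """Allele-split MG4 call at one heterozygous SNV.

    Reads with an aligned base at the variant are partitioned by that base
    into a reference and an alternate group (other bases discarded with a
    log message); per group, local median tracks are built over the variant
    position +- (window + extension) and MG4s are called with the shared
    calibrated parameters.  ``sequence`` is the plus-strand contig sequence.
    """
    p0 = params["+"] if isinstance(params, Mapping) else params
    half = p0.window + p0.extension
    lo = max(0, variant.position - half)
    hi = min(len(sequence), variant.position + half + 1)

    own = isinstance(alignments, (str, bytes))
    af = pysam.AlignmentFile(alignments) if own else alignments
    groups: Dict[str, List] = {variant.ref.upper(): [], variant.alt.upper(): []}
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != variant.contig:
                continue
            if read.reference_start >= hi or read.reference_end <= lo:
                continue
            base = _base_at(read, variant.position)
            if base is None:
                continue  # read does not cover the variant with an aligned base
            if base in groups:
                groups[base].append(read)
            else:
                log.warning(
                    "third allele %s at %s:%d; read discarded",
                    base, variant.contig, variant.position,
                )
    finally:
        if own:
            af.close()

    n_ref = len(groups[variant.ref.upper()])
    n_alt = len(groups[variant.alt.upper()])

    def group_mg4(reads) -> str:
        if len(reads) < r_min:
            return "insufficient"
        tracks = build_tracks_from_reads(
            reads, variant.contig, (lo, hi), d_min=d_min
        )
        calls = call_mg4(tracks, params, sequence, g_mode=g_mode)
        local = [c for c in calls if c.start < hi and lo < c.end]
        return "yes" if local else "no"

    ref_mg4 = group_mg4(groups[variant.ref.upper()])
    alt_mg4 = group_mg4(groups[variant.alt.upper()])
    if "insufficient" in (ref_mg4, alt_mg4):
        klass = "insufficient"
    else:
        klass = {
            ("yes", "yes"): "plus_plus",
            ("yes", "no"): "plus_minus",
            ("no", "yes"): "minus_plus",
            ("no", "no"): "minus_minus",
        }[(ref_mg4, alt_mg4)]
    return SnvCall(
        variant.contig, variant.position, variant.ref, variant.alt, "het",
        n_ref, n_alt, ref_mg4, alt_mg4, klass,
    )
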