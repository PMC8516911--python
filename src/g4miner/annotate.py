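"""Genomic-region statistics and interval-set comparison.

Region models (UTRs, exons, introns, CDS, promoter/TSS windows, splice
junctions) are built from a refGene-like gene table; feature densities are
reported per kilobase of region.  ``compare_sets`` gives the symmetric
overlap report used to compare mined G4s against external G4 interval sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import pandas as pd

__all__ = [
    "LabeledRegion",
    "REGION_LABELS",
    "build_region_models",
    "region_density",
    "density_per_kb",
    "compare_sets",
]

log = logging.getLogger(__name__)

REGION_LABELS = (
    "3'-UTR",
    "5'-UTR",
    "exon",
    "intron",
    "CDS",
    "TSS-up",
    "TSS-up-down",
    "splice-50",
)

TSS_FLANK = 1000
SPLICE_FLANK = 50


@dataclass(frozen=True)
class LabeledRegion:
    contig: str
    start: int
    end: int
    strand: str
    label: str


def _as_interval_list(features) -> List[Tuple[str, int, int, str]]:
    out = []
    for f in features:
        if isinstance(f, tuple):
            out.append(f if len(f) == 4 else (*f, "."))
        else:  # MG4Record / PG4Motif-like
            out.append((f.contig, f.start, f.end, getattr(f, "strand", ".")))
    return out


def build_region_models(gene_table: pd.DataFrame) -> List[LabeledRegion]:
    """Labeled region intervals from a refGene-like gene table.

    Expected columns: ``chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonStarts, exonEnds`` (exon columns as comma-separated strings or
    sequences of ints; coordinates 0-based half-open as in refGene).

    Promoters ("TSS-up") are the 1000 nt upstream of the TSS; "TSS-up-down"
    spans 1000 nt on both sides; splice regions span +-50 nt around each
    internal exon boundary (donor and acceptor of every intron).  UTRs are
    the exonic sequence outside the CDS, 5' or 3' by gene strand.
    Malformed rows are skipped with a log message.
    """
    regions: List[LabeledRegion] = []
    for _, row in gene_table.iterrows():
        try:
            chrom = row["chrom"]
            strand = row["strand"]
            tx_s, tx_e = int(row["txStart"]), int(row["txEnd"])
            cds_s, cds_e = int(row["cdsStart"]), int(row["cdsEnd"])
            ex_s = _parse_coords(row["exonStarts"])
            ex_e = _parse_coords(row["exonEnds"])
            if strand not in "+-" or len(ex_s) != len(ex_e) or not ex_s:
                raise ValueError("bad strand or exon lists")
        except (KeyError, ValueError, TypeError) as exc:
            log.warning("skipping malformed gene row: %s", exc)
            continue

        add = lambda label, s, e: regions.append(
            LabeledRegion(chrom, max(0, s), e, strand, label)
        ) if e > max(0, s) else None

        exons = list(zip(ex_s, ex_e))
        for s, e in exons:
            add("exon", s, e)
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            add("intron", e1, s2)
        if cds_e > cds_s:
            for s, e in exons:
                add("CDS", max(s, cds_s), min(e, cds_e))
            left = [(max(s, tx_s), min(e, cds_s)) for s, e in exons if s < cds_s]
            right = [(max(s, cds_e), min(e, tx_e)) for s, e in exons if e > cds_e]
            five, three = (left, right) if strand == "+" else (right, left)
            for s, e in five:
                add("5'-UTR", s, e)
            for s, e in three:
                add("3'-UTR", s, e)
        tss = tx_s if strand == "+" else tx_e
        if strand == "+":
            add("TSS-up", tss - TSS_FLANK, tss)
        else:
            add("TSS-up", tss, tss + TSS_FLANK)
        add("TSS-up-down", tss - TSS_FLANK, tss + TSS_FLANK)
        # internal exon boundaries = splice sites (donor + acceptor per intron)
        sites = [e for _, e in exons[:-1]] + [s for s, _ in exons[1:]]
        for site in sites:
            add("splice-50", site - SPLICE_FLANK, site + SPLICE_FLANK)
    return regions


def _parse_coords(value) -> List[int]:
    if isinstance(value, str):
        return [int(x) for x in value.strip(",").split(",") if x]
    return [int(x) for x in value]


def density_per_kb(count: int, total_size_mb: float) -> float:
    """Features per kilobase of region: ``count / (total_size_mb * 1000)``.
    Rounding is left to presentation."""
    if total_size_mb <= 0:
        raise ValueError("total region size must be positive")
    return count / (total_size_mb * 1000.0)


def region_density(
    features,
    regions: Sequence[LabeledRegion],
    stranded: bool = False,
) -> pd.DataFrame:
    """Per-label feature counts and densities.

    A feature counts once per label if it overlaps >=1 bp any region of the
    label (a count of features, not of overlap pairs).  Strand is ignored
    by default (regions are gene-stranded while mined G4s come from both
    strands); set ``stranded=True`` to require same-strand overlap.

    Returns a frame with columns label, n_regions, total_size_mb, count,
    density_per_kb (density None when a label has zero total size).
    """
    feats = _as_interval_list(features)
    rows = []
    labels = sorted({r.label for r in regions}, key=lambda l: (
        REGION_LABELS.index(l) if l in REGION_LABELS else len(REGION_LABELS), l))
    for label in labels:
        sub = [r for r in regions if r.label == label]
        total_bp = sum(r.end - r.start for r in sub)
        by_contig: Dict[str, List[LabeledRegion]] = {}
        for r in sub:
            by_contig.setdefault(r.contig, []).append(r)
        count = 0
        for c, s, e, st in feats:
            pool = by_contig.get(c, [])
            for r in pool:
                if s < r.end and r.start < e and (
                    not stranded or st == r.strand or st == "." ):
                    count += 1
                    break
        size_mb = total_bp / 1e6
        rows.append(
            {
                "label": label,
                "n_regions": len(sub),
                "total_size_mb": size_mb,
                "count": count,
                "density_per_kb": density_per_kb(count, size_mb) if total_bp else None,
            }
        )
    return pd.DataFrame(rows)


def compare_sets(a, b) -> Dict[str, float]:
    """Symmetric >=1 bp same-strand overlap report between two interval sets.

    Returns ``fraction_a_in_b``, ``fraction_b_in_a`` and ``n_overlap`` (the
    number of ``a`` records overlapping ``b``).
    """
    ia, ib = _as_interval_list(a), _as_interval_list(b)

    def frac(x, y):
        pools: Dict[tuple, List[Tuple[int, int]]] = {}
        for c, s, e, st in y:
            pools.setdefault((c, st), []).append((s, e))
        hits = 0
        for c, s, e, st in x:
            pool = pools.get((c, st), [])
            if any(s < oe and os_ < e for os_, oe in pool):
                hits += 1
        return hits, (hits / len(x) if x else 0.0)

    n_ab, f_ab = frac(ia, ib)
    _, f_ba = frac(ib, ia)
    return {"fraction_a_in_b": f_ab, "fraction_b_in_a": f_ba, "n_overlap": n_ab}
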