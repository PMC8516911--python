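"""Whole-genome mined-G4 (MG4) calling.

Each strand track is scanned with its calibrated parameters; hits are
extended 35 nt upstream (the longest canonical G4), merged, filtered by the
guanine content of their strand sequence, and classified into structural
families.  The surviving regions are the MG4s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Union

from .calibrate import g_fraction
from .motifs import PG4Motif, classify_family, reverse_complement
from .qualtrack import QualityTrack
from .scanner import ScannerParams, hit_regions, scan

__all__ = [
    "MG4Record",
    "call_mg4",
    "family_summary",
    "intersect_replicates",
    "pg4_recovery",
]


@dataclass(frozen=True)
class MG4Record:
    """A mined G4 region (plus-strand BED coordinates)."""

    contig: str
    start: int
    end: int
    strand: str
    family: str
    n_low: int
    flag_value: int
    replicate: str = ""

    def overlaps(self, other: "MG4Record") -> bool:
        return (
            self.contig == other.contig
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def _strand_sequence(sequence: str, start: int, end: int, strand: str) -> str:
    sub = sequence[start:end]
    return reverse_complement(sub) if strand == "-" else sub


def call_mg4(
    tracks: Mapping[str, QualityTrack],
    params: Union[ScannerParams, Mapping[str, ScannerParams]],
    sequence: str,
    g_mode: str = "GC",
    replicate: str = "",
) -> List[MG4Record]:
    """Call MG4s on one contig from its strand tracks.

    Parameters
    ----------
    tracks
        ``{'+': QualityTrack, '-': QualityTrack}`` for one contig.
    params
        A single :class:`ScannerParams` for both strands, or a per-strand
        mapping (strands are calibrated independently).
    sequence
        Plus-strand contig sequence; guanine content and family
        classification are evaluated on each region's own strand sequence.
    """
    records: List[MG4Record] = []
    L = len(sequence)
    for strand in "+-":
        track = tracks[strand]
        p = params[strand] if isinstance(params, Mapping) else params
        hits = scan(track, p)
        if not hits:
            continue
        regions = hit_regions(hits, p, contig_length=L)
        for s, e in regions:
            seq = _strand_sequence(sequence, s, e, strand)
            if g_fraction(sequence[s:e], strand, g_mode) < p.g_min:
                continue
            sub = [h for h in hits if s <= h.start_site < e]
            records.append(
                MG4Record(
                    contig=track.contig,
                    start=s,
                    end=e,
                    strand=strand,
                    family=classify_family(seq),
                    n_low=max(h.n_low for h in sub) if sub else 0,
                    flag_value=max(h.flag_value for h in sub) if sub else 0,
                    replicate=replicate,
                )
            )
    records.sort(key=lambda r: (r.contig, r.start, r.end, r.strand))
    for strand in "+-":
        ivs = [(r.start, r.end) for r in records if r.strand == strand]
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert s2 >= e1, "called MG4s must be disjoint within a strand"
    return records


def _overlaps_any(rec: MG4Record, pool: Sequence[MG4Record]) -> bool:
    return any(rec.overlaps(o) for o in pool)


def intersect_replicates(
    a: Sequence[MG4Record], b: Sequence[MG4Record]
) -> List[MG4Record]:
    """Records of ``a`` sharing >=1 bp same-strand overlap with ``b``."""
    by_key: Dict[tuple, List[MG4Record]] = {}
    for r in b:
        by_key.setdefault((r.contig, r.strand), []).append(r)
    for pool in by_key.values():
        pool.sort(key=lambda r: r.start)
    out = []
    for r in a:
        pool = by_key.get((r.contig, r.strand), [])
        # pools are small at desk scale; linear check with early exit
        if any(r.start < o.end and o.start < r.end for o in pool):
            out.append(r)
    return out


def pg4_recovery(
    pg4s: Sequence[PG4Motif], mg4s: Sequence[MG4Record]
) -> Dict[str, object]:
    """Fraction of predicted motifs recovered by mined regions.

    A motif is detected iff it overlaps >=1 bp an MG4 on the same strand.
    Returns ``{n_pg4, n_detected, fraction}`` with the fraction as a
    percentage rounded to 2 decimals (``None`` when there are no motifs).
    """
    by_key: Dict[tuple, List[MG4Record]] = {}
    for r in mg4s:
        by_key.setdefault((r.contig, r.strand), []).append(r)
    n_det = 0
    for m in pg4s:
        pool = by_key.get((m.contig, m.strand), [])
        if any(m.start < o.end and o.start < m.end for o in pool):
            n_det += 1
    n = len(pg4s)
    frac = round(100.0 * n_det / n, 2) if n else None
    return {"n_pg4": n, "n_detected": n_det, "fraction": frac}


def family_summary(records: Sequence[MG4Record]):
    """Per-family call counts and fractions as a small table."""
    import pandas as pd

    from .motifs import FAMILIES

    n = len(records)
    rows = []
    for fam in FAMILIES:
        k = sum(1 for r in records if r.family == fam)
        rows.append({"family": fam, "count": k,
                     "fraction": round(k / n, 4) if n else None})
    return pd.DataFrame(rows)
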