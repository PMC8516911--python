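"""Strand-specific per-locus median base-quality tracks from aligned reads.

Every aligned (match/mismatch) base of every primary alignment contributes
its Phred score to the locus it covers; per strand (alignment FLAG bit 0x10)
the per-locus median is the track the low-quality scanner operates on.
Soft-clipped, inserted and deleted positions contribute nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pysam

__all__ = [
    "QualityTrack",
    "build_tracks",
    "build_tracks_from_reads",
    "median_rule",
    "dump_tsv",
    "load_tsv",
]

log = logging.getLogger(__name__)

MAX_Q = 60  # Phred ceiling; histogram bins 0..MAX_Q


@dataclass
class QualityTrack:
    """Per-locus median Phred scores for one contig strand.

    Arrays are indexed by reference position minus ``offset``.  Loci with
    depth below the construction-time minimum are masked ``no_data``; their
    ``median_q`` is -1.
    """

    contig: str
    strand: str
    offset: int
    median_q: np.ndarray
    depth: np.ndarray
    no_data: np.ndarray

    def __len__(self) -> int:
        return len(self.median_q)

    def to_frame(self):
        """Tabular dump (contig, pos, strand, depth, median_q) of covered loci."""
        import pandas as pd

        idx = np.nonzero(self.depth > 0)[0]
        return pd.DataFrame(
            {
                "contig": self.contig,
                "pos": idx + self.offset,
                "strand": self.strand,
                "depth": self.depth[idx],
                "median_q": self.median_q[idx],
            }
        )


def median_rule(values) -> int:
    """Median of an integer multiset: middle value for odd counts, the lower
    of the two middle values for even counts (integer-preserving)."""
    vals = sorted(values)
    if not vals:
        raise ValueError("median of empty multiset is no-data")
    return vals[(len(vals) - 1) // 2]


def _hist_to_track(
    hist: np.ndarray, contig: str, strand: str, offset: int, d_min: int
) -> QualityTrack:
    depth = hist.sum(axis=1)
    # lower-middle median: smallest q with cumulative count > (depth-1)//2
    k = (depth - 1) // 2
    cum = hist.cumsum(axis=1)
    median = (cum <= k[:, None]).sum(axis=1).astype(np.int16)
    no_data = depth < max(d_min, 1)
    median[no_data] = -1
    return QualityTrack(contig, strand, offset, median, depth, no_data)


def _accumulate(
    reads: Iterable,
    start: int,
    length: int,
    min_mapq: int,
    check_sorted: bool,
) -> Tuple[np.ndarray, np.ndarray]:
    hists = {
        "+": np.zeros((length, MAX_Q + 1), dtype=np.int32),
        "-": np.zeros((length, MAX_Q + 1), dtype=np.int32),
    }
    last_pos = -1
    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_mapq:
            continue
        if check_sorted:
            if read.reference_start < last_pos:
                raise ValueError("alignments are not coordinate-sorted")
            last_pos = read.reference_start
        quals = read.query_qualities
        if quals is None:
            log.warning("read %s has no base qualities; skipped", read.query_name)
            continue
        strand = "-" if read.is_reverse else "+"
        pairs = read.get_aligned_pairs(matches_only=True)
        if not pairs:
            continue
        qpos = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
        rpos = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
        q = np.minimum(np.asarray(quals, dtype=np.int64)[qpos], MAX_Q)
        rel = rpos - start
        keep = (rel >= 0) & (rel < length)
        np.add.at(hists[strand], (rel[keep], q[keep]), 1)
    return hists["+"], hists["-"]


def build_tracks(
    alignments,
    contig: str,
    region: Optional[Tuple[int, int]] = None,
    d_min: int = 10,
    min_mapq: int = 0,
) -> Dict[str, QualityTrack]:
    """Build the two strand tracks for a contig (or a sub-range of it).

    Parameters
    ----------
    alignments
        Path to a coordinate-sorted SAM/BAM file, or an open
        :class:`pysam.AlignmentFile`.
    region
        Optional ``(start, end)`` 0-based half-open reference range; default
        is the whole contig.
    d_min
        Loci covered by fewer than this many reads of a strand are masked
        no-data on that strand.
    min_mapq
        Minimum mapping quality for a read to contribute.
    """
    own = isinstance(alignments, (str, bytes))
    af = pysam.AlignmentFile(alignments) if own else alignments
    try:
        if contig not in af.references:
            raise ValueError(f"contig {contig!r} absent from alignment header")
        clen = af.get_reference_length(contig)
        start, end = region if region is not None else (0, clen)
        so = (af.header.get("HD") or {}).get("SO")
        reads = (r for r in af.fetch(until_eof=True) if r.reference_name == contig)
        hp, hm = _accumulate(
            reads, start, end - start, min_mapq, check_sorted=so != "coordinate"
        )
    finally:
        if own:
            af.close()
    return {
        "+": _hist_to_track(hp, contig, "+", start, d_min),
        "-": _hist_to_track(hm, contig, "-", start, d_min),
    }


def build_tracks_from_reads(
    reads: Iterable,
    contig: str,
    region: Tuple[int, int],
    d_min: int = 10,
    min_mapq: int = 0,
) -> Dict[str, QualityTrack]:
    """Tracks from an explicit read iterable (e.g. an allele-split subset)
    over a fixed reference range; input order is irrelevant."""
    start, end = region
    hp, hm = _accumulate(reads, start, end - start, min_mapq, check_sorted=False)
    return {
        "+": _hist_to_track(hp, contig, "+", start, d_min),
        "-": _hist_to_track(hm, contig, "-", start, d_min),
    }


def dump_tsv(tracks: Dict[str, QualityTrack], path: str) -> str:
    """Write covered loci of both strand tracks as a TSV
    (contig, pos, strand, depth, median_q)."""
    import pandas as pd

    frames = [tracks[s].to_frame() for s in "+-" if s in tracks]
    pd.concat(frames).sort_values(["pos", "strand"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def load_tsv(path: str, contig: str, length: int, d_min: int = 10):
    """Rebuild strand tracks from a dump_tsv file (uncovered loci no-data)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = {}
    for strand in "+-":
        med = np.full(length, -1, dtype=np.int16)
        depth = np.zeros(length, dtype=np.int64)
        sub = df[(df["strand"] == strand) & (df["contig"] == contig)]
        med[sub["pos"].to_numpy()] = sub["median_q"].to_numpy()
        depth[sub["pos"].to_numpy()] = sub["depth"].to_numpy()
        no_data = depth < max(d_min, 1)
        med[no_data] = -1
        out[strand] = QualityTrack(contig, strand, 0, med, depth, no_data)
    return out
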