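"""Low-quality region scanner.

Walking a median-quality track in the strand's 5'->3' direction, any adjacent
pair of loci whose medians differ by at least M defines a transition: the
higher-quality base is the *flag site* (its quality the *flag value*) and the
lower-quality base is the *start site* of a putative low-quality region.
From the start site on, loci within a 75-nt window whose quality sits at
least M below the flag value are *low-quality sites*; if at least N such
loci occur the window is a *hit*.  Hits are the raw evidence for mined G4s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .qualtrack import QualityTrack

__all__ = ["ScannerParams", "LowQualityHit", "scan", "hit_regions", "merge_intervals"]

_SENTINEL = 10**6  # stands in for no-data loci: never low, never a flag


@dataclass(frozen=True)
class ScannerParams:
    """All scanner and caller tuning in one place.

    M : minimum median-quality drop (Phred units) defining a transition and
        the low-quality criterion within the window.
    N : minimum number of low-quality loci in the window for a hit.
    window : window length in nt laid 5'->3' from the start site (default 75,
        half a 150-nt read).
    extension : upstream extension of hit regions in nt (default 35, the
        longest canonical G4).
    g_min : minimum guanine fraction of a called region's strand sequence.
    """

    M: int
    N: int
    window: int = 75
    extension: int = 35
    g_min: float = 0.28

    def __post_init__(self):
        if not 1 <= self.M:
            raise ValueError("M must be >= 1")
        if not 1 <= self.N <= self.window:
            raise ValueError("N must be in [1, window]")
        if self.window <= 0:
            raise ValueError("window must be positive")


@dataclass(frozen=True)
class LowQualityHit:
    contig: str
    strand: str
    start_site: int  # reference position (plus-strand coordinate)
    flag_value: int
    n_low: int


def candidate_transitions(
    q: np.ndarray, defined: np.ndarray, M: int, window: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All transitions of an oriented quality array, with window low counts.

    ``q``/``defined`` are laid out in scan (5'->3') direction.  Returns
    (start_index, flag_value, n_low) arrays covering every adjacent defined
    pair with |diff| >= M; the N threshold is applied by the caller, so one
    pass serves a whole (M, *) grid column.
    """
    n = len(q)
    if n < 2:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy(), z.copy()
    qv = np.where(defined, q, _SENTINEL).astype(np.int64)
    pair = defined[1:] & defined[:-1]
    d = q[1:].astype(np.int64) - q[:-1].astype(np.int64)
    idx = np.nonzero(pair & (np.abs(d) >= M))[0]
    if len(idx) == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy(), z.copy()
    down = d[idx] < 0
    starts = np.where(down, idx + 1, idx)
    flags = np.where(down, q[idx], q[idx + 1]).astype(np.int64)
    # count loci with flag - q >= M over `window` loci from the start site,
    # truncated at the array end; no-data loci count as neither
    pad = np.full(window - 1, _SENTINEL, dtype=np.int64)
    wins = sliding_window_view(np.concatenate([qv, pad]), window)
    low = (wins[starts] <= flags[:, None] - M).sum(axis=1)
    return starts, flags, low


def _oriented(track: QualityTrack) -> Tuple[np.ndarray, np.ndarray]:
    q = track.median_q
    defined = ~track.no_data
    if track.strand == "-":
        return q[::-1], defined[::-1]
    return q, defined


def _to_ref(track: QualityTrack, scan_idx: np.ndarray) -> np.ndarray:
    if track.strand == "-":
        return track.offset + (len(track) - 1 - scan_idx)
    return track.offset + scan_idx


def scan(track: QualityTrack, params: ScannerParams) -> List[LowQualityHit]:
    """Scan one strand track; returns hits sorted by reference position.

    The minus strand is scanned toward decreasing reference coordinates;
    reported ``start_site`` values are plus-strand reference positions.
    """
    q, defined = _oriented(track)
    starts, flags, low = candidate_transitions(q, defined, params.M, params.window)
    keep = low >= params.N
    ref = _to_ref(track, starts[keep])
    hits = [
        LowQualityHit(track.contig, track.strand, int(r), int(f), int(nl))
        for r, f, nl in zip(ref, flags[keep], low[keep])
    ]
    hits.sort(key=lambda h: h.start_site)
    return hits


def merge_intervals(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge intervals sharing >=1 bp; touching intervals stay separate."""
    out: List[list] = []
    for s, e in sorted(intervals):
        if out and s < out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def hit_regions(
    hits: Sequence[LowQualityHit],
    params: ScannerParams,
    contig_length: int | None = None,
) -> List[Tuple[int, int]]:
    """Expand hits into merged low-quality regions (plus-strand half-open).

    Each hit spans its window downstream of the start site plus an
    ``extension``-nt stretch upstream (both in the strand's own orientation);
    overlapping regions are merged into single disjoint intervals.
    """
    if not hits:
        return []
    strands = {h.strand for h in hits}
    if len(strands) > 1:
        raise ValueError("hits must come from a single strand")
    strand = strands.pop()
    ivs = []
    for h in hits:
        if strand == "+":
            s = h.start_site - params.extension
            e = h.start_site + params.window
        else:
            s = h.start_site - params.window + 1
            e = h.start_site + params.extension + 1
        s = max(0, s)
        if contig_length is not None:
            e = min(e, contig_length)
        if e > s:
            ivs.append((s, e))
    return merge_intervals(ivs)
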