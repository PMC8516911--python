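"""Scanner parameter calibration against predicted-motif regions.

Positive regions start 12 nt (the approximate DNA-polymerase footprint)
upstream of each predicted canonical motif start and span 75 nt; everything
at least 300 nt away from any positive region is tiled into 75-nt negative
windows.  A grid of (M, N) settings is scored by the fraction of positive
regions hit (sensitivity) and the fraction of guanine-filtered negative
windows hit (false-positive rate); the chosen setting maximises sensitivity
subject to FPR < 1%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .motifs import PG4Motif
from .qualtrack import QualityTrack
from .scanner import ScannerParams, candidate_transitions, _oriented, _to_ref

__all__ = [
    "CalibrationRegion",
    "GridCell",
    "CalibrationError",
    "build_regions",
    "grid_search",
    "g_threshold",
    "g_fraction",
]

log = logging.getLogger(__name__)

POLYMERASE_FOOTPRINT = 12  # nt upstream of a motif start included in its region
REGION_SIZE = 75
EXCLUSION = 300  # nt around positive regions removed before tiling negatives
DEFAULT_G_MIN = 0.28


class CalibrationError(RuntimeError):
    """No parameter cell satisfies the false-positive-rate constraint."""


@dataclass(frozen=True)
class CalibrationRegion:
    contig: str
    strand: str
    start: int
    end: int
    label: str  # positive | negative
    g_fraction: float
    clipped: bool = False


@dataclass(frozen=True)
class GridCell:
    M: int
    N: int
    positive_rate: float
    fpr: float


def g_fraction(sequence: str, strand: str = "+", mode: str = "G") -> float:
    """Guanine (or G+C) fraction of a region on the scanned strand.

    ``mode='G'`` counts guanine only (the primary definition); ``mode='GC'``
    counts G and C, in which case strand is immaterial.
    """
    if not sequence:
        return 0.0
    seq = sequence.upper()
    if mode == "GC":
        return (seq.count("G") + seq.count("C")) / len(seq)
    if mode != "G":
        raise ValueError(f"unknown g_fraction mode {mode!r}")
    base = "G" if strand == "+" else "C"  # G on minus strand is C on plus
    return seq.count(base) / len(seq)


def build_regions(
    sequence: str,
    pg4s: Sequence[PG4Motif],
    strand: str,
    contig: str = "seq",
    g_mode: str = "GC",
) -> List[CalibrationRegion]:
    """Positive and negative calibration regions for one contig strand.

    ``sequence`` is the plus-strand contig sequence; ``pg4s`` are motifs of
    the requested strand.  One positive region per motif (clipped at contig
    bounds and flagged when clipped); the remainder, after excluding
    positives +-300 nt, is tiled into 75-nt negative windows.
    """
    L = len(sequence)
    regions: List[CalibrationRegion] = []
    pos_ivs: List[Tuple[int, int]] = []
    for m in pg4s:
        if m.strand != strand:
            continue
        if strand == "+":
            s = m.start - POLYMERASE_FOOTPRINT
        else:
            # the strand-oriented motif start is the plus-coordinate end
            s = m.end + POLYMERASE_FOOTPRINT - REGION_SIZE
        e = s + REGION_SIZE
        clipped = s < 0 or e > L
        s, e = max(0, s), min(L, e)
        if e <= s:
            continue
        pos_ivs.append((s, e))
        regions.append(
            CalibrationRegion(
                contig, strand, s, e, "positive",
                g_fraction(sequence[s:e], strand, g_mode), clipped,
            )
        )
    # tile negatives outside positives +- EXCLUSION
    excluded = sorted((max(0, s - EXCLUSION), min(L, e + EXCLUSION)) for s, e in pos_ivs)
    merged: List[list] = []
    for s, e in excluded:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    free: List[Tuple[int, int]] = []
    prev = 0
    for s, e in merged:
        if s > prev:
            free.append((prev, s))
        prev = max(prev, e)
    if prev < L:
        free.append((prev, L))
    for s, e in free:
        for w in range(s, e - REGION_SIZE + 1, REGION_SIZE):
            regions.append(
                CalibrationRegion(
                    contig, strand, w, w + REGION_SIZE, "negative",
                    g_fraction(sequence[w : w + REGION_SIZE], strand, g_mode),
                )
            )
    return regions


def _max_nlow_per_region(
    track: QualityTrack, regions: Sequence[CalibrationRegion], M: int, window: int
) -> np.ndarray:
    """For one M, the largest window low-count of any transition whose start
    site falls inside each region (0 if none)."""
    q, defined = _oriented(track)
    starts, _flags, low = candidate_transitions(q, defined, M, window)
    ref = _to_ref(track, starts)
    order = np.argsort(ref, kind="stable")
    ref, low = ref[order], low[order]
    out = np.zeros(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        lo = np.searchsorted(ref, r.start, side="left")
        hi = np.searchsorted(ref, r.end, side="left")
        if hi > lo:
            out[i] = low[lo:hi].max()
    return out


def grid_search(
    track: QualityTrack,
    regions: Sequence[CalibrationRegion],
    M_range: Iterable[int] = range(1, 13),
    N_range: Iterable[int] = range(1, 21),
    fpr_max: float = 0.01,
    g_min: float = DEFAULT_G_MIN,
    window: int = REGION_SIZE,
    extension: int = 35,
) -> Tuple[ScannerParams, List[GridCell]]:
    """Choose (M, N) maximising the positive rate at FPR < ``fpr_max``.

    The false-positive rate is computed on negative windows whose guanine
    fraction is at least ``g_min`` (low-G windows cannot be mined G4s and
    are filtered before FPR computation).  Ties on the positive rate are
    broken by lower FPR, then higher M, then higher N.

    ``track`` may also be a list of ``(track, regions)`` pairs (one per
    contig), in which case ``regions`` is ignored and the regions are pooled.

    Returns the chosen :class:`ScannerParams` and the full grid.
    Raises :class:`CalibrationError` if no cell satisfies the constraint.
    """
    pairs = track if isinstance(track, list) else [(track, list(regions))]
    pos_pairs = [
        (t, [r for r in rs if r.label == "positive"]) for t, rs in pairs
    ]
    neg_pairs = [
        (t, [r for r in rs if r.label == "negative" and r.g_fraction >= g_min])
        for t, rs in pairs
    ]
    n_pos = sum(len(rs) for _, rs in pos_pairs)
    n_neg = sum(len(rs) for _, rs in neg_pairs)
    if not n_pos:
        raise CalibrationError("no positive regions to calibrate on")
    if not n_neg:
        raise CalibrationError("no guanine-filtered negative regions")

    M_range = list(M_range)
    N_range = list(N_range)
    grid: List[GridCell] = []
    best = None
    best_key = None
    for M in M_range:
        pos_low = np.concatenate(
            [_max_nlow_per_region(t, rs, M, window) for t, rs in pos_pairs]
        )
        neg_low = np.concatenate(
            [_max_nlow_per_region(t, rs, M, window) for t, rs in neg_pairs]
        )
        for N in N_range:
            pr = float((pos_low >= N).mean())
            fpr = float((neg_low >= N).mean())
            grid.append(GridCell(M, N, pr, fpr))
            if fpr < fpr_max:
                key = (pr, -fpr, M, N)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (M, N)
    if best is None:
        raise CalibrationError(
            f"no (M, N) cell keeps the false-positive rate below {fpr_max:g}"
        )
    if best_key[0] == 0:
        raise CalibrationError(
            "no admissible (M, N) cell detects any positive region"
        )
    params = ScannerParams(
        M=best[0], N=best[1], window=window, extension=extension, g_min=g_min
    )
    log.info(
        "calibrated strand %s: M=%d N=%d (positive rate %.3f, FPR %.4f)",
        pairs[0][0].strand, params.M, params.N, best_key[0], -best_key[1],
    )
    return params, grid


def g_threshold(
    positive_regions: Sequence[CalibrationRegion], min_regions: int = 100
) -> float:
    """Per-genome guanine-content threshold: the nearest-rank 1st percentile
    of positive-region guanine fractions, so that 99% of motif-positive
    segments exceed it.  Falls back to the 0.28 default below
    ``min_regions`` regions."""
    g = sorted(r.g_fraction for r in positive_regions if r.label == "positive")
    if len(g) < min_regions:
        log.warning(
            "only %d positive regions (< %d); using default guanine threshold %.2f",
            len(g), min_regions, DEFAULT_G_MIN,
        )
        return DEFAULT_G_MIN
    # nearest-rank percentile: ceil(p/100 * n)-th smallest value
    import math

    rank = max(1, math.ceil(0.01 * len(g)))
    return g[rank - 1]
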