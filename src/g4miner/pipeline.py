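"""End-to-end wiring: calibrate per strand, then mine a genome.

These helpers run the per-contig building blocks over a whole genome
(a ``{contig: sequence}`` mapping or a FASTA path) against one alignment
file, pooling calibration regions across contigs per strand.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Tuple, Union

from .calibrate import (
    CalibrationRegion,
    GridCell,
    build_regions,
    grid_search,
)
from .detect import MG4Record, call_mg4
from .motifs import PG4Motif, predict_canonical
from .qualtrack import QualityTrack, build_tracks
from .scanner import ScannerParams

__all__ = ["load_genome", "calibrate_genome", "detect_genome"]

log = logging.getLogger(__name__)


def load_genome(reference) -> Dict[str, str]:
    """A ``{contig: sequence}`` mapping from a FASTA path (or pass-through)."""
    if isinstance(reference, Mapping):
        return dict(reference)
    from pyfaidx import Fasta

    with Fasta(reference) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def calibrate_genome(
    genome,
    alignments,
    d_min: int = 10,
    fpr_max: float = 0.01,
    g_min: float = 0.28,
    g_mode: str = "GC",
    M_range=range(1, 13),
    N_range=range(1, 21),
) -> Tuple[Dict[str, ScannerParams], Dict[str, List[GridCell]]]:
    """Per-strand scanner calibration over a whole genome.

    Predicts canonical motifs, builds positive/negative regions per contig
    and strand, pools them across contigs, and grid-searches (M, N) per
    strand.  Returns ``({strand: params}, {strand: grid})``.
    """
    genome = load_genome(genome)
    pooled: Dict[str, List[Tuple[QualityTrack, List[CalibrationRegion]]]] = {
        "+": [], "-": []
    }
    for contig, seq in genome.items():
        tracks = build_tracks(alignments, contig, d_min=d_min)
        pg4s = predict_canonical(seq, "both", contig=contig)
        for strand in "+-":
            regions = build_regions(seq, pg4s, strand, contig=contig, g_mode=g_mode)
            pooled[strand].append((tracks[strand], regions))
    params: Dict[str, ScannerParams] = {}
    grids: Dict[str, List[GridCell]] = {}
    for strand in "+-":
        params[strand], grids[strand] = grid_search(
            pooled[strand], None,
            M_range=M_range, N_range=N_range, fpr_max=fpr_max, g_min=g_min,
        )
    return params, grids


def detect_genome(
    genome,
    alignments,
    params: Union[ScannerParams, Mapping[str, ScannerParams]],
    d_min: int = 10,
    g_mode: str = "GC",
    replicate: str = "",
) -> List[MG4Record]:
    """Mine MG4s over every contig of a genome with calibrated parameters."""
    genome = load_genome(genome)
    records: List[MG4Record] = []
    for contig, seq in genome.items():
        tracks = build_tracks(alignments, contig, d_min=d_min)
        records.extend(
            call_mg4(tracks, params, seq, g_mode=g_mode, replicate=replicate)
        )
    return records
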