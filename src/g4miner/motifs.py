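"""G-quadruplex motif grammar: prediction, structural families, subfeatures.

The canonical G4 motif is four runs of three or more guanines joined by
1-7 nt loops, ``(G{3,}[ATCG]{1,7}){3}G{3,}`` (the Quadparser pattern).
Noncanonical structures are described by a fixed hierarchy of relaxed
grammars -- long loops, bulged tracts, and two-guanine tracts -- ordered by
the predicted thermodynamic stability of the folded structure.  A sequence
matching several grammars is assigned the most stable one only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, List, Optional

__all__ = [
    "PG4Motif",
    "Subfeature",
    "FAMILIES",
    "FAMILY_RANK",
    "predict_canonical",
    "classify_family",
    "classify_subfeature",
    "pg4_density",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Grammar
# ---------------------------------------------------------------------------

#: any base (loops may themselves contain guanine)
_N17 = "[ATCG]{1,7}"
_N812 = "[ATCG]{8,12}"

CANONICAL_PATTERN = r"(?:G{3,}[ATCG]{1,7}){3}G{3,}"

# Long-loop quadruplexes: at least one loop of 8-12 nt, in the five listed
# loop arrangements (L = long loop, S = short loop): LSS, SLS, LLS, LSL, LLL.
_LONG_LOOP_ALTS = [
    f"G{{3,}}{_N812}(?:G{{3}}{_N17}){{2}}G{{3,}}",
    f"G{{3,}}{_N17}G{{3,}}{_N812}G{{3,}}{_N17}G{{3,}}",
    f"(?:G{{3,}}{_N812}){{2}}G{{3}}{_N17}G{{3,}}",
    f"G{{3,}}{_N812}G{{3,}}{_N17}G{{3,}}{_N812}G{{3,}}",
    f"(?:G{{3,}}{_N812}){{3}}G{{3,}}",
]
LONG_LOOP_PATTERN = "|".join(f"(?:{p})" for p in _LONG_LOOP_ALTS)

# Bulged quadruplexes: four tracts with 1-7 nt loops where either exactly one
# tract carries a 1-7 nt bulge (G H{1,7} GG, H = A/T/C) or two or more tracts
# carry short 1-2 nt bulges.
_T = "G{3,}"
_B7 = "G[ATC]{1,7}G{2}"
_B2 = "G[ATC]{1,2}G{2}"


def _tract_arrangements() -> List[str]:
    alts = []
    # exactly one bulged tract with a 1-7 nt bulge
    for i in range(4):
        tracts = [_B7 if j == i else _T for j in range(4)]
        alts.append(_N17.join(tracts))
    # two or more tracts with 1-2 nt bulges
    for mask in range(16):
        if bin(mask).count("1") >= 2:
            tracts = [_B2 if (mask >> j) & 1 else _T for j in range(4)]
            alts.append(_N17.join(tracts))
    return alts


BULGE_PATTERN = "|".join(f"(?:{p})" for p in _tract_arrangements())

TWO_TRACT_PATTERN = r"(?:G{2}[ATCG]{1,12}){3}G{2}"

I_MOTIF_PATTERN = r"(?:C{3,}[ATCG]{1,7}){3}C{3,}"
POLY_AT_PATTERN = r"[AT]{10,}"

_RE_CANONICAL = re.compile(CANONICAL_PATTERN)
_RE_LONG_LOOP = re.compile(LONG_LOOP_PATTERN)
_RE_BULGE = re.compile(BULGE_PATTERN)
_RE_TWO_TRACT = re.compile(TWO_TRACT_PATTERN)
_RE_I_MOTIF = re.compile(I_MOTIF_PATTERN)
_RE_POLY_AT = re.compile(POLY_AT_PATTERN)

#: structural families, most stable first
FAMILIES = ("canonical", "long_loops", "bulges", "two_tracts", "other")
FAMILY_RANK = {name: i for i, name in enumerate(FAMILIES)}

_FAMILY_REGEX = (
    ("canonical", _RE_CANONICAL),
    ("long_loops", _RE_LONG_LOOP),
    ("bulges", _RE_BULGE),
    ("two_tracts", _RE_TWO_TRACT),
)

_VALID_RE = re.compile("[^ACGTN]")


@dataclass(frozen=True)
class PG4Motif:
    """A predicted G4-forming interval (0-based half-open, plus-strand coords)."""

    contig: str
    start: int
    end: int
    strand: str
    family: str = "canonical"
    sequence: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("motif end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def interval(self):
        return (self.start, self.end)


@dataclass(frozen=True)
class Subfeature:
    """A non-G4 secondary-structure element within an 'other' sequence."""

    kind: str  # i_motif | hairpin | poly_at | unassigned
    start: int = 0
    end: int = 0


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    m = _VALID_RE.search(seq)
    if m:
        raise ValueError(f"invalid base {m.group()!r} at position {m.start()}")
    return seq


# ---------------------------------------------------------------------------
# Canonical motif prediction
# ---------------------------------------------------------------------------

def _candidate_intervals(seq: str) -> List[tuple]:
    """All maximal canonical-match intervals starting at G-run starts.

    A canonical match is a parse into four G-tracts (>=3 G) separated by
    three 1-7 nt loops over {A,C,G,T}.  For each G-run start the longest
    reachable end is found by memoised search over tract/loop splits; any
    shorter match starting inside the run is contained in that interval, so
    these maximal intervals generate the same overlap-merged motif set as the
    full set of matching substrings.
    """
    n = len(seq)
    grun = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        grun[i] = grun[i + 1] + 1 if seq[i] == "G" else 0
    # next position at or after i holding a non-ACGT character
    next_bad = [n] * (n + 1)
    for i in range(n - 1, -1, -1):
        next_bad[i] = i if seq[i] not in "ACGT" else next_bad[i + 1]

    memo: dict = {}

    def max_end(p: int, rem: int) -> Optional[int]:
        # p starts a G-run of length grun[p] >= 3; rem tracts still needed
        if rem == 1:
            return p + grun[p]
        key = (p, rem)
        if key in memo:
            return memo[key]
        best = None
        r = grun[p]
        for t in range(3, r + 1):
            for loop in range(1, 8):
                q = p + t + loop
                if q + 3 > n:
                    break
                if next_bad[p + t] < q:
                    continue  # loop spans an N
                if grun[q] >= 3:
                    e = max_end(q, rem - 1)
                    if e is not None and (best is None or e > best):
                        best = e
        memo[key] = best
        return best

    out = []
    i = 0
    while i < n:
        if grun[i] >= 3 and (i == 0 or seq[i - 1] != "G"):
            e = max_end(i, 4)
            if e is not None:
                out.append((i, e))
            i += grun[i]
        else:
            i += 1
    return out


def _merge_overlapping(intervals: Iterable[tuple]) -> List[tuple]:
    """Merge intervals sharing >=1 bp (touching intervals stay separate)."""
    ivs = sorted(intervals)
    merged: List[list] = []
    for s, e in ivs:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def predict_canonical(
    sequence: str,
    strand_mode: str = "both",
    contig: str = "seq",
    offset: int = 0,
) -> List[PG4Motif]:
    """Predict canonical G4 motifs on a sequence.

    Parameters
    ----------
    sequence
        DNA over {A,C,G,T,N}; N never matches any pattern position.
    strand_mode
        ``"given_strand"`` scans only the sequence as given (reported on +);
        ``"both"`` also scans the reverse complement, reporting minus-strand
        motifs in plus-strand coordinates with strand '-'.
    contig, offset
        Attached to the reported motifs so genome slices keep genomic
        coordinates.
    """
    if strand_mode not in ("given_strand", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if not sequence:
        return []
    seq = _check_sequence(sequence)
    n = len(seq)

    motifs = []
    for s, e in _merge_overlapping(_candidate_intervals(seq)):
        motifs.append(
            PG4Motif(contig, offset + s, offset + e, "+", "canonical", seq[s:e])
        )
    if strand_mode == "both":
        rc = reverse_complement(seq)
        for s, e in _merge_overlapping(_candidate_intervals(rc)):
            gs, ge = n - e, n - s
            motifs.append(
                PG4Motif(contig, offset + gs, offset + ge, "-", "canonical", seq[gs:ge])
            )
    motifs.sort(key=lambda m: (m.start, m.end, m.strand))
    return motifs


# ---------------------------------------------------------------------------
# Family classification
# ---------------------------------------------------------------------------

def classify_family(sequence: str) -> str:
    """Assign a sequence to its most stable matching G4 structural family.

    Patterns are searched anywhere in the sequence, in fixed order
    canonical > long_loops > bulges > two_tracts; a sequence matching none
    is 'other'.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    for name, rx in _FAMILY_REGEX:
        if rx.search(seq):
            return name
    return "other"


def classify_subfeature(sequence: str) -> Subfeature:
    """Identify the non-G4 secondary structure in an 'other' sequence.

    Checks, in order: i-motif ``(C{3,}N{1,7}){3}C{3,}``; hairpin (a >=7 bp
    stem whose exact reverse complement recurs downstream with a loop of at
    most 30 nt); a poly-A/T run of >=10 bases.
    """
    seq = sequence.upper()
    m = _RE_I_MOTIF.search(seq)
    if m:
        return Subfeature("i_motif", m.start(), m.end())
    hp = _find_hairpin(seq)
    if hp is not None:
        return Subfeature("hairpin", hp[0], hp[1])
    m = _RE_POLY_AT.search(seq)
    if m:
        return Subfeature("poly_at", m.start(), m.end())
    return Subfeature("unassigned")


def _find_hairpin(seq: str, stem: int = 7, max_loop: int = 30):
    # A stem of length >= `stem` exists iff some `stem`-mer has its reverse
    # complement downstream within the loop bound, so scanning fixed-size
    # stems is exhaustive.  First (leftmost stem, shortest loop) hit wins.
    n = len(seq)
    for i in range(max(0, n - 2 * stem + 1)):
        kmer = seq[i : i + stem]
        if "N" in kmer:
            continue
        rc = reverse_complement(kmer)
        lo = i + stem
        hi = min(n, i + stem + max_loop + stem)
        j = seq.find(rc, lo, hi)
        if j >= 0:
            return (i, j + stem)
    return None


def pg4_density(count: int, genome_size_mb: float) -> float:
    """Motif density in motifs per Mb, counting both strands of the genome:
    ``count / (genome_size_mb * 2)``.  Rounding is left to presentation."""
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / (genome_size_mb * 2)
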