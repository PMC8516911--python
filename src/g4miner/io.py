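"""Plain-text serialisation: BED6 and TSV outputs."""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

__all__ = ["write_bed", "read_bed", "write_hits_bed", "write_mg4_bed", "write_grid_tsv"]


def write_bed(records, path: str) -> str:
    """BED6 from (contig, start, end, name, score, strand) tuples or objects
    exposing those attributes (motifs use family as name, hits use n_low)."""
    with open(path, "w") as fh:
        for r in records:
            if isinstance(r, tuple):
                row = r
            else:
                name = getattr(r, "family", getattr(r, "n_low", "."))
                score = getattr(r, "flag_value", 0)
                row = (r.contig, r.start, r.end, name, score, r.strand)
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


def read_bed(path: str) -> List[Tuple[str, int, int, str, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(
                (
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    f[3] if len(f) > 3 else ".",
                    int(float(f[4])) if len(f) > 4 else 0,
                    f[5] if len(f) > 5 else ".",
                )
            )
    return out


def write_mg4_bed(records, path: str) -> str:
    """BED6 + family, n_low, flag_value extra columns for MG4 records."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.family}\t0\t{r.strand}"
                f"\t{r.n_low}\t{r.flag_value}\n"
            )
    return path


def write_grid_tsv(grid, path: str) -> str:
    with open(path, "w") as fh:
        fh.write("M\tN\tpositive_rate\tfpr\n")
        for c in grid:
            fh.write(f"{c.M}\t{c.N}\t{c.positive_rate:.6f}\t{c.fpr:.6f}\n")
    return path


def write_hits_bed(hits, params, path: str) -> str:
    """Scanner hits as BED6: the hit window interval in plus coordinates,
    name = n_low, score = flag_value."""
    rows = []
    for h in hits:
        if h.strand == "+":
            s, e = h.start_site, h.start_site + params.window
        else:
            s, e = h.start_site - params.window + 1, h.start_site + 1
        rows.append((h.contig, max(0, s), e, h.n_low, h.flag_value, h.strand))
    return write_bed(rows, path)
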