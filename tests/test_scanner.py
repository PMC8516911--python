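"""The low-quality region scanner: flag/start sites, window counts,
region extension and merging."""

import numpy as np
import pytest

from g4miner.qualtrack import QualityTrack
from g4miner.scanner import (
    LowQualityHit,
    ScannerParams,
    hit_regions,
    merge_intervals,
    scan,
)


def make_track(values, strand="+", offset=0, mask=None, contig="chr1"):
    q = np.asarray(values, dtype=np.int16)
    no_data = np.zeros(len(q), dtype=bool) if mask is None else np.asarray(mask)
    med = q.copy()
    med[no_data] = -1
    depth = np.where(no_data, 0, 30)
    return QualityTrack(contig, strand, offset, med, depth, no_data)


class TestScan:
    def test_constant_track_no_hits(self):
        t = make_track([37] * 200)
        for M in (1, 4, 12):
            assert scan(t, ScannerParams(M=M, N=1)) == []

    def test_step_drop_hand_traced(self):
        # 50 loci at 37 then 75 at 31: one transition, flag 37, start at the
        # first low locus, all 75 window loci at least 4 below the flag
        t = make_track([37] * 50 + [31] * 75)
        hits = scan(t, ScannerParams(M=4, N=15))
        assert hits == [LowQualityHit("chr1", "+", 50, 37, 75)]

    def test_drop_below_threshold(self):
        t = make_track([37] * 50 + [34] * 75)
        assert scan(t, ScannerParams(M=4, N=1)) == []

    def test_window_truncated_at_contig_end(self):
        t = make_track([37] * 50 + [31] * 20)  # only 20 loci available
        assert scan(t, ScannerParams(M=4, N=21)) == []
        hits = scan(t, ScannerParams(M=4, N=20))
        assert hits[0].n_low == 20

    def test_minus_strand_scans_toward_lower_coords(self):
        # on the minus strand 5'->3' runs right to left: the low region must
        # sit at LOWER coordinates than the flag site
        t = make_track([31] * 75 + [37] * 50, strand="-")
        hits = scan(t, ScannerParams(M=4, N=15))
        assert len(hits) == 1
        assert hits[0].start_site == 74 and hits[0].n_low == 75
        # the plus-strand reading of the same array has no hit (window runs
        # into the high region)
        tp = make_track([31] * 75 + [37] * 50, strand="+")
        assert scan(tp, ScannerParams(M=4, N=15)) == []

    def test_mirror_symmetry(self, rng):
        vals = rng.integers(30, 40, 300)
        tm = make_track(vals, strand="-")
        tp = make_track(vals[::-1], strand="+")
        p = ScannerParams(M=3, N=5)
        hm = scan(tm, p)
        hp = scan(tp, p)
        n = len(vals)
        assert sorted((n - 1 - h.start_site, h.flag_value, h.n_low) for h in hm) == \
            sorted((h.start_site, h.flag_value, h.n_low) for h in hp)

    def test_no_data_pairs_skipped(self):
        vals = [37] * 50 + [31] * 75
        mask = np.zeros(125, dtype=bool)
        mask[49:51] = True  # mask the transition pair
        t = make_track(vals, mask=mask)
        assert scan(t, ScannerParams(M=4, N=10)) == []

    def test_no_data_excluded_from_low_count(self):
        vals = [37] * 50 + [31] * 75
        mask = np.zeros(125, dtype=bool)
        mask[60:125] = True  # most of the window is no-data
        t = make_track(vals, mask=mask)
        hits = scan(t, ScannerParams(M=4, N=1))
        assert hits[0].n_low == 10

    def test_monotone_in_M_and_N(self, rng):
        vals = rng.integers(28, 42, 500)
        t = make_track(vals)
        prev = None
        for M in range(1, 8):
            counts = [len(scan(t, ScannerParams(M=M, N=N))) for N in (1, 5, 10)]
            assert counts == sorted(counts, reverse=True)  # decreasing in N
            if prev is not None:
                assert all(c <= p for c, p in zip(counts, prev))
            prev = counts

    def test_upward_transition_starts_at_lower_base(self):
        # quality jump up: the earlier (lower) base is the start site
        t = make_track([31] * 5 + [37] * 120)
        hits = scan(t, ScannerParams(M=4, N=1))
        assert hits and hits[0].start_site == 4 and hits[0].flag_value == 37
        # the window runs forward from the start site, so only the start
        # site itself is low
        assert hits[0].n_low == 1


class TestHitRegions:
    def test_plus_arithmetic(self):
        h = LowQualityHit("chr1", "+", 1000, 37, 20)
        assert hit_regions([h], ScannerParams(M=4, N=15)) == [(965, 1075)]

    def test_plus_merge(self):
        hits = [
            LowQualityHit("chr1", "+", 1000, 37, 20),
            LowQualityHit("chr1", "+", 1030, 37, 20),
        ]
        assert hit_regions(hits, ScannerParams(M=4, N=15)) == [(965, 1105)]

    def test_minus_arithmetic(self):
        # window runs toward lower coordinates, extension toward higher
        h = LowQualityHit("chr1", "-", 1000, 37, 20)
        assert hit_regions([h], ScannerParams(M=4, N=15)) == [(926, 1036)]

    def test_clipping(self):
        h = LowQualityHit("chr1", "+", 10, 37, 20)
        assert hit_regions([h], ScannerParams(M=4, N=15), contig_length=50) == [(0, 50)]

    def test_mixed_strands_rejected(self):
        hits = [
            LowQualityHit("chr1", "+", 1000, 37, 20),
            LowQualityHit("chr1", "-", 1030, 37, 20),
        ]
        with pytest.raises(ValueError):
            hit_regions(hits, ScannerParams(M=4, N=15))

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_against_naive_oracle(self, seed):
        rng = np.random.default_rng(4000 + seed)
        ivs = []
        for _ in range(50):
            s = int(rng.integers(0, 5000))
            ivs.append((s, s + int(rng.integers(1, 300))))
        got = merge_intervals(ivs)
        # oracle: repeatedly merge any strictly overlapping pair to fixpoint
        pool = [list(iv) for iv in ivs]
        changed = True
        while changed:
            changed = False
            for i in range(len(pool)):
                for j in range(i + 1, len(pool)):
                    a, b = pool[i], pool[j]
                    if a[0] < b[1] and b[0] < a[1]:
                        a[0], a[1] = min(a[0], b[0]), max(a[1], b[1])
                        pool.pop(j)
                        changed = True
                        break
                if changed:
                    break
        assert got == sorted((s, e) for s, e in pool)
        # disjoint and sorted
        for (s1, e1), (s2, e2) in zip(got, got[1:]):
            assert e1 <= s2
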