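"""Calibration regions, grid search and the guanine-content threshold."""

import numpy as np
import pytest

from g4miner.calibrate import (
    CalibrationError,
    CalibrationRegion,
    build_regions,
    g_fraction,
    g_threshold,
    grid_search,
)
from g4miner.motifs import PG4Motif, predict_canonical, reverse_complement
from g4miner.qualtrack import QualityTrack


def flat_track(n, q=37, strand="+", contig="seq"):
    med = np.full(n, q, dtype=np.int16)
    depth = np.full(n, 30)
    return QualityTrack(contig, strand, 0, med, depth, np.zeros(n, dtype=bool))


class TestBuildRegions:
    def test_single_pg4_arithmetic(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20_000)])
        m = PG4Motif("seq", 5000, 5030, "+", "canonical")
        regions = build_regions(seq, [m], "+")
        pos = [r for r in regions if r.label == "positive"]
        assert [(r.start, r.end) for r in pos] == [(4988, 5063)]
        negs = [(r.start, r.end) for r in regions if r.label == "negative"]
        # negatives tile [0, 4688) and [5363, 20000) in 75-nt windows
        assert negs[0] == (0, 75)
        assert max(e for _, e in negs if e <= 4688) == 4650
        assert min(s for s, _ in negs if s >= 5363) == 5363
        assert all(e - s == 75 for s, e in negs)
        assert not any(4688 <= s < 5363 for s, _ in negs)

    def test_no_pg4(self):
        seq = "A" * 1000
        regions = build_regions(seq, [], "+")
        assert sum(r.label == "positive" for r in regions) == 0
        assert sum(r.label == "negative" for r in regions) == 1000 // 75

    def test_minus_strand_region_placement(self):
        seq = "A" * 1000
        m = PG4Motif("seq", 500, 530, "-", "canonical")
        pos = [r for r in build_regions(seq, [m], "-") if r.label == "positive"]
        # strand-oriented: 12 nt upstream of the motif's 5' start (= plus
        # coordinate end), spanning 75 nt toward lower coordinates
        assert [(r.start, r.end) for r in pos] == [(530 - 63, 530 + 12)]

    def test_clipping_flagged(self):
        seq = "A" * 1000
        m = PG4Motif("seq", 5, 25, "+", "canonical")
        pos = [r for r in build_regions(seq, [m], "+") if r.label == "positive"]
        assert pos[0].clipped and pos[0].start == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_against_set_subtraction_oracle(self, seed):
        rng = np.random.default_rng(5000 + seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
        pg4s = predict_canonical(seq, "both", contig="seq")
        plus = [m for m in pg4s if m.strand == "+"]
        regions = build_regions(seq, pg4s, "+")
        negs = [(r.start, r.end) for r in regions if r.label == "negative"]
        # oracle: excluded mask from positives +- 300, then greedy tiling
        excluded = np.zeros(len(seq), dtype=bool)
        pos_iv = [(m.start - 12, m.start - 12 + 75) for m in plus]
        for s, e in pos_iv:
            excluded[max(0, s - 300) : min(len(seq), e + 300)] = True
        oracle = []
        i = 0
        while i <= len(seq) - 75:
            if not excluded[i : i + 75].any():
                oracle.append((i, i + 75))
                i += 75
            else:
                nxt = i + int(np.argmax(~excluded[i:])) if excluded[i] else i + 1
                i = max(nxt, i + 1)
        # oracle above tiles from each free-run start; compare as sets of
        # covered windows: every emitted negative must be >=300 from any
        # positive and 75 long
        for s, e in negs:
            assert e - s == 75
            assert not excluded[s:e].any()
        # and the emitted tiling is maximal within each free run
        assert len(negs) == len(oracle)

    def test_positive_negative_separation(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50_000)])
        pg4s = predict_canonical(seq, "both", contig="seq")
        regions = build_regions(seq, pg4s, "+")
        pos = [r for r in regions if r.label == "positive"]
        for r in regions:
            if r.label == "negative":
                for p in pos:
                    assert r.end + 300 <= p.start or p.end + 300 <= r.start


class TestGFraction:
    def test_strand_aware_g_mode(self):
        assert g_fraction("GGGGA", "+", "G") == pytest.approx(0.8)
        # G on the minus strand is C on the plus slice
        assert g_fraction("CCCCA", "-", "G") == pytest.approx(0.8)
        assert g_fraction("GCGC", "+", "GC") == 1.0


class TestGThreshold:
    def test_constant(self):
        regs = [
            CalibrationRegion("c", "+", i, i + 75, "positive", 0.30)
            for i in range(0, 100 * 75, 75)
        ]
        assert g_threshold(regs) == pytest.approx(0.30)

    def test_nearest_rank_vs_sort_oracle(self, rng):
        fr = rng.uniform(0.1, 0.6, 500)
        regs = [
            CalibrationRegion("c", "+", i, i + 75, "positive", float(f))
            for i, f in enumerate(fr)
        ]
        got = g_threshold(regs)
        s = sorted(fr)
        import math

        assert got == pytest.approx(s[math.ceil(0.01 * len(s)) - 1])

    def test_default_fallback(self):
        regs = [CalibrationRegion("c", "+", 0, 75, "positive", 0.5)] * 10
        assert g_threshold(regs) == pytest.approx(0.28)


class TestGridSearch:
    def _regions(self, n_pos=5, n_neg=50, g=0.5):
        regs = []
        for i in range(n_pos):
            regs.append(CalibrationRegion("c", "+", 400 * i + 100, 400 * i + 175,
                                          "positive", g))
        for i in range(n_neg):
            s = 3000 + 75 * i
            regs.append(CalibrationRegion("c", "+", s, s + 75, "negative", g))
        return regs

    def test_zero_variance_fails(self):
        t = flat_track(10_000)
        with pytest.raises(CalibrationError):
            grid_search(t, self._regions())

    def test_no_positives_fails(self):
        t = flat_track(10_000)
        with pytest.raises(CalibrationError):
            grid_search(t, [r for r in self._regions() if r.label == "negative"])

    def test_recovers_implanted_drop(self):
        # a clean 6-unit drop inside every positive region and a flat
        # background: the chosen cell must catch all positives at zero FPR
        med = np.full(10_000, 37, dtype=np.int16)
        for i in range(5):
            s = 400 * i + 120
            med[s : s + 80] = 31
        t = QualityTrack("c", "+", 0, med, np.full(10_000, 30),
                         np.zeros(10_000, dtype=bool))
        params, grid = grid_search(t, self._regions())
        cell = [c for c in grid if (c.M, c.N) == (params.M, params.N)][0]
        assert cell.positive_rate == 1.0
        assert cell.fpr == 0.0
        assert params.M <= 6

    def test_grid_monotonicity(self, rng):
        med = rng.integers(30, 42, 10_000).astype(np.int16)
        t = QualityTrack("c", "+", 0, med, np.full(10_000, 30),
                         np.zeros(10_000, dtype=bool))
        try:
            _, grid = grid_search(t, self._regions(), fpr_max=1.1)
        except CalibrationError:
            pytest.skip("degenerate random grid")
        by = {(c.M, c.N): c for c in grid}
        for M in range(1, 12):
            for N in range(1, 20):
                assert by[(M, N)].positive_rate >= by[(M + 1, N)].positive_rate
                assert by[(M, N)].fpr >= by[(M, N + 1)].fpr
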