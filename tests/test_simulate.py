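"""Simulator: genome construction, read/quality model, truth evaluation."""

import re

import numpy as np
import pytest

from g4miner.motifs import (
    BULGE_PATTERN,
    CANONICAL_PATTERN,
    I_MOTIF_PATTERN,
    LONG_LOOP_PATTERN,
    POLY_AT_PATTERN,
    TWO_TRACT_PATTERN,
    predict_canonical,
)
from g4miner.qualtrack import build_tracks
from g4miner.scanner import ScannerParams, scan
from g4miner.simulate import (
    SimConfig,
    SimFeature,
    evaluate,
    make_genome,
    sample_family,
    simulate_reads,
    write_fasta,
)

SMALL = dict(length=30_000, n_canonical=4, n_long_loops=1, n_bulges=1,
             n_two_tracts=1, n_i_motif=1, n_poly_at=1, n_null=1)


class TestMakeGenome:
    def test_deterministic_under_seed(self, tmp_path):
        g1, t1, _ = make_genome(SimConfig(**SMALL, seed=7))
        g2, t2, _ = make_genome(SimConfig(**SMALL, seed=7))
        assert g1 == g2 and t1 == t2
        f1 = write_fasta(g1, tmp_path / "a.fa")
        f2 = write_fasta(g2, tmp_path / "b.fa")
        assert open(f1, "rb").read() == open(f2, "rb").read()

    def test_different_seed_differs(self):
        g1, _, _ = make_genome(SimConfig(**SMALL, seed=7))
        g2, _, _ = make_genome(SimConfig(**SMALL, seed=8))
        assert g1 != g2

    def test_implanted_motif_predicted_at_truth_locus(self):
        genome, truth, _ = make_genome(SimConfig(**SMALL, seed=7))
        seq = genome["sim1"]
        motifs = predict_canonical(seq, "both", contig="sim1")
        for f in truth:
            if f.family == "canonical":
                assert any(
                    m.strand == f.strand and m.start < f.end and f.start < m.end
                    for m in motifs
                ), f
                # padding prevents extension past the implant
                exact = [m for m in motifs
                         if (m.start, m.end, m.strand) == (f.start, f.end, f.strand)]
                assert exact

    def test_spacing_and_counts(self):
        genome, truth, _ = make_genome(SimConfig(**SMALL, seed=3))
        # truth records are disjoint within a strand (an i-motif implant and
        # the canonical motif on its complementary face share coordinates)
        for strand in "+-":
            ivs = sorted((f.start, f.end) for f in truth if f.strand == strand)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert s2 >= e1
        n_implants = sum(SMALL[k] for k in SMALL if k.startswith("n_"))
        assert len(truth) >= n_implants

    def test_features_do_not_fit_raises(self):
        with pytest.raises(ValueError):
            make_genome(SimConfig(length=5000, n_canonical=20, seed=1))

    def test_null_locus_has_no_motif_on_either_strand(self):
        genome, truth, _ = make_genome(SimConfig(**SMALL, seed=11))
        seq = genome["sim1"]
        for f in truth:
            if f.family == "null":
                assert not f.drop_bearing
                sub = seq[f.start : f.end]
                assert not re.search(CANONICAL_PATTERN, sub)


class TestFamilySamplers:
    RX = {
        "canonical": re.compile(CANONICAL_PATTERN),
        "long_loops": re.compile(LONG_LOOP_PATTERN),
        "bulges": re.compile(BULGE_PATTERN),
        "two_tracts": re.compile(TWO_TRACT_PATTERN),
        "i_motif": re.compile(I_MOTIF_PATTERN),
        "poly_at": re.compile(POLY_AT_PATTERN),
    }

    @pytest.mark.parametrize("family", list(RX))
    def test_samples_match_their_grammar(self, family, rng):
        for _ in range(50):
            s = sample_family(family, rng)
            assert self.RX[family].search(s), (family, s)


class TestSimulateReads:
    def test_no_fold_no_hits(self, tmp_path):
        cfg = SimConfig(**SMALL, p_fold=0.0, seed=5)
        genome, truth, het = make_genome(cfg)
        sam = simulate_reads(genome, truth, het, cfg, str(tmp_path / "r.sam"))
        tracks = build_tracks(sam, "sim1")
        for strand in "+-":
            hits = scan(tracks[strand], ScannerParams(M=3, N=10))
            for f in truth:
                if f.strand == strand:
                    assert not any(abs(h.start_site - f.drop_start) < 80 for h in hits)

    def test_full_fold_full_recall(self, tmp_path):
        cfg = SimConfig(**SMALL, p_fold=1.0, delta=10, seed=5)
        genome, truth, het = make_genome(cfg)
        sam = simulate_reads(genome, truth, het, cfg, str(tmp_path / "r.sam"))
        tracks = build_tracks(sam, "sim1")
        drop = [f for f in truth if f.drop_bearing]
        for f in drop:
            hits = scan(tracks[f.strand], ScannerParams(M=8, N=20))
            assert any(abs(h.start_site - f.drop_start) <= 5 for h in hits), f

    def test_background_median_near_baseline(self, tmp_path):
        cfg = SimConfig(**SMALL, seed=5)
        genome, truth, het = make_genome(cfg)
        sam = simulate_reads(genome, truth, het, cfg, str(tmp_path / "r.sam"))
        t = build_tracks(sam, "sim1")["+"]
        keep = ~t.no_data.copy()
        for f in truth:
            keep[max(0, f.start - 200) : f.end + 200] = False
        vals = t.median_q[keep]
        assert np.abs(vals - cfg.q_baseline).mean() < 2
        assert np.abs(np.median(vals) - cfg.q_baseline) <= 2

    def test_deterministic_sam(self, tmp_path):
        cfg = SimConfig(**SMALL, seed=5)
        genome, truth, het = make_genome(cfg)
        a = simulate_reads(genome, truth, het, cfg, str(tmp_path / "a.sam"))
        b = simulate_reads(genome, truth, het, cfg, str(tmp_path / "b.sam"))
        assert open(a, "rb").read() == open(b, "rb").read()

    def test_zero_depth_empty_sam(self, tmp_path):
        cfg = SimConfig(**SMALL, depth=0.0, seed=5)
        genome, truth, het = make_genome(cfg)
        sam = simulate_reads(genome, truth, het, cfg, str(tmp_path / "r.sam"))
        import pysam

        with pysam.AlignmentFile(sam) as af:
            assert sum(1 for _ in af.fetch(until_eof=True)) == 0


class TestEvaluate:
    def mk(self, ivs, strand="+", drop=True, family="canonical"):
        return [SimFeature("c", s, e, strand, family, drop) for s, e in ivs]

    def test_identity(self):
        t = self.mk([(0, 30), (100, 140)])
        out = evaluate(t, t)
        assert out["recall"] == 1.0 and out["precision"] == 1.0

    def test_empty_calls(self):
        out = evaluate([], self.mk([(0, 30)]))
        assert out["recall"] == 0.0 and out["precision"] is None

    def test_against_all_pairs_oracle(self, rng):
        truth = self.mk(
            [(int(s), int(s) + 40) for s in rng.integers(0, 3000, 20)]
        )
        calls = self.mk(
            [(int(s), int(s) + 60) for s in rng.integers(0, 3000, 15)]
        )
        out = evaluate(calls, truth)
        rec = sum(
            1 for f in truth
            if any(c.start < f.end and f.start < c.end for c in calls)
        )
        assert out["recall"] == pytest.approx(rec / len(truth))
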