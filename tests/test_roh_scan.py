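"""Sliding-window ROH detection, length classes, F_ROH and islands."""

import numpy as np
import pandas as pd
import pytest

import sweepsignal as ss
from sweepsignal.genotype_io import MISSING
from sweepsignal.roh_scan import ROHParams, ROHSegment

from conftest import make_gm


def brute_force_scores(calls, params=None):
    """Independent per-SNP score oracle: enumerate every covering window."""
    params = params or ROHParams()
    calls = np.asarray(calls)
    m = calls.size
    w = min(params.window_snps, m)
    scores = np.zeros(m)
    for j in range(m):
        hom = tot = 0
        for s in range(max(0, j - w + 1), min(j, m - w) + 1):
            win = calls[s:s + w]
            tot += 1
            if ((win == 1).sum() <= params.max_opp_window
                    and (win == MISSING).sum() <= params.max_miss_window):
                hom += 1
        scores[j] = hom / tot
    return scores


# ---------------------------------------------------------------------------
# per-SNP scores


def test_scores_all_homozygous_is_one():
    assert (ss.snp_run_scores(np.zeros(100, dtype=np.int8)) == 1).all()


def test_scores_alternating_het_is_zero():
    calls = np.zeros(100, dtype=np.int8)
    calls[1::2] = 1  # every 2nd SNP het: every 15-SNP window holds >= 7 hets
    assert (ss.snp_run_scores(calls) == 0).all()


def test_scores_single_het_tolerated():
    """One het inside a long homozygous stretch leaves every window
    homozygous (1 <= max_opp_window), so all scores stay 1."""
    calls = np.zeros(100, dtype=np.int8)
    calls[50] = 1
    scores = ss.snp_run_scores(calls)
    assert (scores == 1).all()
    np.testing.assert_allclose(scores, brute_force_scores(calls))


def test_scores_match_brute_force_on_random_vectors(rng):
    for _ in range(20):
        calls = rng.choice([0, 1, 2, MISSING], size=60,
                           p=[0.5, 0.15, 0.3, 0.05]).astype(np.int8)
        np.testing.assert_allclose(ss.snp_run_scores(calls),
                                   brute_force_scores(calls))


def test_scores_short_chromosome_single_window():
    calls = np.zeros(8, dtype=np.int8)
    calls[3] = 1
    scores = ss.snp_run_scores(calls)
    assert scores.shape == (8,)
    assert (scores == 1).all()  # 1 het <= max_opp in the one truncated window


def test_lower_threshold_never_shrinks_in_run_set(rng):
    for _ in range(10):
        calls = rng.choice([0, 1, 2], size=80, p=[0.45, 0.2, 0.35]).astype(np.int8)
        scores = ss.snp_run_scores(calls)
        strict = scores > 0.5
        loose = scores > 0.05
        assert not np.any(strict & ~loose)


# ---------------------------------------------------------------------------
# run calling


def _run_fixture():
    """One chromosome: 20 het SNPs, 200 hom SNPs at 10 kb spacing, 20 hets.

    The window score semantics pull the single adjacent flanking het on each
    side into the run (a window ending at that het has exactly one het), so
    the expected segment holds 202 SNPs; frozen from the brute-force oracle.
    """
    calls = np.concatenate([np.ones(20), np.zeros(200), np.ones(20)]).astype(np.int8)
    return make_gm(calls[None, :], spacing=10_000)


def test_call_roh_constructed_run():
    segs = ss.call_roh(_run_fixture())
    assert len(segs) == 1
    seg = segs[0]
    assert seg.n_snps == 202
    assert seg.length_bp == pytest.approx(2.01e6, rel=0.001)
    pos = _run_fixture().variants["pos"].to_numpy()
    scores = ss.snp_run_scores(_run_fixture().calls[0])
    in_run = np.where(scores > 0.05)[0]
    assert seg.start_bp == pos[in_run[0]] and seg.end_bp == pos[in_run[-1]]


def test_call_roh_short_stretch_fails_min_length():
    # 50 hom SNPs over ~0.5 Mb, flanked by het blocks
    calls = np.concatenate([np.ones(20), np.zeros(50), np.ones(20)]).astype(np.int8)
    assert ss.call_roh(make_gm(calls[None, :])) == []


def test_call_roh_sparse_run_fails_min_density():
    """3 homozygous SNPs spanning 1.2 Mb: density 1/400 kb < 1/100 kb."""
    gm = make_gm(np.zeros((1, 3), dtype=np.int8),
                 positions=[1, 600_001, 1_200_001])
    assert ss.call_roh(gm) == []


def test_call_roh_output_respects_all_filters_and_disjoint():
    cfg = ss.SimConfig(seed=3)
    hm = ss.simulate_panel(cfg, 50)
    pos = hm.variants["pos"].to_numpy()[hm.chrom_slice("1")]
    focal = int(pos[len(pos) // 2])
    hm, _ = ss.plant_sweep(hm, "1", focal, 0.9, 3e6, seed=30)
    segs = ss.call_roh(hm.to_genotype_matrix())
    assert segs
    p = ROHParams()
    for s in segs:
        assert s.n_snps >= p.min_snp
        assert s.length_bp >= p.min_length_bp
        assert s.n_snps / s.length_bp >= p.min_density
    by_key = {}
    for s in segs:
        by_key.setdefault((s.sample, s.chrom), []).append((s.start_bp, s.end_bp))
    for spans in by_key.values():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2


# ---------------------------------------------------------------------------
# length classes


def _segments_with_lengths(lengths_mb, sample="S00"):
    return [ROHSegment(sample, "1", 1, int(mb * 1e6), 100) for mb in lengths_mb]


def test_bin_roh_single_segment():
    df = ss.bin_roh(_segments_with_lengths([7]), {"S00": "b"})
    row = df[df["class"] == "6-12"].iloc[0]
    assert row["n"] == 1 and row["pct"] == 100.00


def test_bin_roh_boundaries_go_right():
    df = ss.bin_roh(_segments_with_lengths([2, 6, 12, 24, 48]), {"S00": "b"})
    assert list(df["n"]) == [1, 1, 1, 1, 1]


def test_bin_roh_percentages_sum_to_100(rng):
    lengths = rng.uniform(1, 60, size=500)
    df = ss.bin_roh(_segments_with_lengths(lengths), {"S00": "b"})
    assert df["pct"].sum() == pytest.approx(100, abs=0.02)


# ---------------------------------------------------------------------------
# F_ROH


def test_f_roh_examples():
    pops = {"S00": "b", "S01": "b"}
    segs = [ROHSegment("S00", "1", 1, 25_000_000, 500)]
    per_sample, per_breed = ss.f_roh(segs, 2_500_000_000, ["S00", "S01"], pops)
    assert per_sample["S00"] == pytest.approx(0.01)
    assert per_sample["S01"] == 0.0
    assert per_breed["b"] == pytest.approx(0.005)


def test_f_roh_additive():
    segs = [ROHSegment("S00", "1", 1, 10_000_000, 200),
            ROHSegment("S00", "2", 1, 15_000_000, 300)]
    per_sample, _ = ss.f_roh(segs, 1_000_000_000, ["S00"], {"S00": "b"})
    assert per_sample["S00"] == pytest.approx(0.025)


def test_f_roh_segment_beyond_chromosome_raises():
    segs = [ROHSegment("S00", "1", 1, 2_000_000, 50)]
    with pytest.raises(ValueError, match="exceeds"):
        ss.f_roh(segs, 1_000_000_000, ["S00"], {"S00": "b"},
                 chrom_lengths={"1": 1_500_000})


# ---------------------------------------------------------------------------
# islands


def _island_gm(n=10):
    calls = np.zeros((n, 300), dtype=np.int8)
    return make_gm(calls, spacing=10_000)


def _cover(sample_ids, lo_snp, hi_snp, spacing=10_000):
    return [ROHSegment(f"S{i:02d}", "1", (lo_snp + 1) * spacing,
                       (hi_snp + 1) * spacing, hi_snp - lo_snp + 1)
            for i in sample_ids]


def test_roh_islands_basic():
    gm = _island_gm()
    segs = _cover(range(7), 100, 150) + _cover(range(2), 200, 250)
    islands = ss.roh_islands(segs, gm)
    assert len(islands) == 1
    isl = islands[0]
    pos = gm.variants["pos"].to_numpy()
    assert isl.start_bp == pos[100] and isl.end_bp == pos[150]
    assert isl.peak_incidence == pytest.approx(0.7)
    assert isl.n_snps == 51


def test_roh_islands_strict_threshold():
    gm = _island_gm()
    segs = _cover(range(6), 100, 150)  # incidence exactly 0.60 everywhere
    assert ss.roh_islands(segs, gm) == []


def test_roh_islands_split_by_low_snp():
    gm = _island_gm()
    # samples 0-6 cover SNPs 100..150 except SNP 120 where only 5 overlap
    segs = (_cover(range(5), 100, 150)
            + _cover([5, 6], 100, 119) + _cover([5, 6], 121, 150))
    islands = ss.roh_islands(segs, gm)
    assert len(islands) == 2
    pos = gm.variants["pos"].to_numpy()
    assert islands[0].end_bp == pos[119]
    assert islands[1].start_bp == pos[121]


def test_roh_islands_overlap_planted_sweep():
    """A near-fixed sweep with multi-Mb flanks creates a breed-wide ROH
    island overlapping the truth interval (10/10 seeds expected >= 8)."""
    hits = 0
    for seed in range(10):
        cfg = ss.SimConfig(seed=seed)
        hm = ss.simulate_panel(cfg, 50)
        pos = hm.variants["pos"].to_numpy()[hm.chrom_slice("1")]
        focal = int(pos[np.argmin(np.abs(pos - 20_000_000))])
        hm, truth = ss.plant_sweep(hm, "1", focal, 0.95, 4_000_000, seed + 500)
        gm = hm.to_genotype_matrix()
        islands = ss.roh_islands(ss.call_roh(gm), gm)
        ts, te = truth.interval()
        hits += any(i.chrom == "1" and i.start_bp <= te and i.end_bp >= ts
                    for i in islands)
    assert hits >= 8
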