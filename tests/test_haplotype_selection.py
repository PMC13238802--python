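"""EHH pair-counting, iHH integration, iHS standardization, XP-EHH."""

import itertools

import numpy as np
import pandas as pd
import pytest

import sweepsignal as ss
from sweepsignal.consensus_regions import CandidateInterval
from sweepsignal.haplotype_selection import (EHHCurve, _pooled_curve,
                                             merge_outlier_snps)

from conftest import make_hm


def ehh_oracle(haps, core, allele, upto):
    """Brute-force EHH: fraction of carrier pairs identical from core to
    ``upto`` inclusive."""
    lo, hi = sorted((core, upto))
    carriers = [h for h in haps if h[core] == allele]
    pairs = list(itertools.combinations(range(len(carriers)), 2))
    same = sum(1 for i, j in pairs
               if np.array_equal(carriers[i][lo:hi + 1], carriers[j][lo:hi + 1]))
    return same / len(pairs)


# ---------------------------------------------------------------------------
# EHH


def test_ehh_pair_counting_example():
    """4 carriers grouping {2,1,1} at the next SNP: EHH = C(2,2)/C(4,2)."""
    haps = np.array([
        [1, 0, 0],
        [1, 0, 0],
        [1, 0, 1],
        [1, 1, 0],
        [0, 0, 0],
    ], dtype=np.uint8)
    hm = make_hm(np.vstack([haps, np.zeros((1, 3), dtype=np.uint8)]))
    curve = ss.ehh(hm, "1", 0, 1)
    # at offset 2 the four carriers split {2,1,1}
    assert curve.right_ehh[1] == pytest.approx(1 / 6)
    assert curve.right_ehh[1] == pytest.approx(ehh_oracle(hm.haps, 0, 1, 2))


def test_ehh_identical_carriers_is_one():
    haps = np.tile(np.array([1, 0, 1, 1, 0], dtype=np.uint8), (4, 1))
    hm = make_hm(haps)
    curve = ss.ehh(hm, "1", 2, 1)
    assert curve.ehh0 == 1.0
    assert (curve.left_ehh == 1).all() and (curve.right_ehh == 1).all()


def test_ehh_requires_two_carriers():
    haps = np.zeros((4, 3), dtype=np.uint8)
    haps[0, 1] = 1
    with pytest.raises(ValueError, match="carriers"):
        ss.ehh(make_hm(haps), "1", 1, 1)


def test_ehh_matches_brute_force_oracle(rng):
    """Exhaustive pair-identity oracle on random small panels."""
    for _ in range(200):
        n = int(rng.integers(4, 13) // 2 * 2)
        m = int(rng.integers(3, 11))
        haps = (rng.random((n, m)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
        core = int(rng.integers(0, m))
        for allele in (0, 1):
            if (haps[:, core] == allele).sum() < 2:
                continue
            curve = ss.ehh(make_hm(haps), "1", core, allele)
            pos = np.arange(1, m + 1) * 10_000
            for offs, vals, step in ((curve.left_offsets, curve.left_ehh, -1),
                                     (curve.right_offsets, curve.right_ehh, 1)):
                for k, v in enumerate(vals):
                    j = core + step * (k + 1)
                    assert v == pytest.approx(ehh_oracle(haps, core, allele, j))
                # monotone non-increasing outward
                assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
                if curve.ehh0 == 1 and len(vals):
                    assert vals[0] <= 1


# ---------------------------------------------------------------------------
# iHH


def _curve(offs, vals, ehh0=1.0, reached_end=False):
    z = np.empty(0)
    return EHHCurve("1", 0, 1, ehh0, z, z, np.asarray(offs, float),
                    np.asarray(vals, float), False, reached_end)


def test_ihh_piecewise_toy_matches_numeric_oracle():
    """Right side 1 -> 0.5 (10 kb) -> 0.04 (20 kb): trapezoid + interpolated
    cutoff crossing vs a fine-grid numeric integration oracle."""
    area, truncated = ss.ihh(_curve([10_000, 20_000], [0.5, 0.04]))
    x = np.linspace(0, 20_000, 2_000_001)
    y = np.interp(x, [0, 10_000, 20_000], [1, 0.5, 0.04])
    oracle = np.trapezoid(np.where(y >= 0.05, y, 0), x)
    # the oracle clips below-cutoff tail to 0; correct for the sliver past the
    # crossing by integrating only up to it
    xc = 10_000 + 10_000 * (0.5 - 0.05) / (0.5 - 0.04)
    oracle = np.trapezoid(np.interp(np.linspace(0, xc, 2_000_001),
                                    [0, 10_000, 20_000], [1, 0.5, 0.04]),
                          np.linspace(0, xc, 2_000_001))
    assert area == pytest.approx(oracle, rel=1e-6)
    assert not truncated


def test_ihh_rectangle_lower_bound():
    """EHH constant 1 over 100 kb each side then below cutoff."""
    c = EHHCurve("1", 0, 1, 1.0,
                 np.array([50_000.0, 100_000.0, 110_000.0]),
                 np.array([1.0, 1.0, 0.01]),
                 np.array([50_000.0, 100_000.0, 110_000.0]),
                 np.array([1.0, 1.0, 0.01]), False, False)
    area, _ = ss.ihh(c)
    assert area >= 200_000


def test_ihh_immediate_drop_is_near_zero():
    c = EHHCurve("1", 0, 1, 1.0, np.array([1000.0]), np.array([0.0]),
                 np.array([1000.0]), np.array([0.0]), False, False)
    area, _ = ss.ihh(c)
    assert area < 1100  # only the interpolated crossing slivers


def test_ihh_truncation_flag_at_chromosome_end():
    area, truncated = ss.ihh(_curve([10_000], [0.8], reached_end=True))
    assert truncated


# ---------------------------------------------------------------------------
# iHS


def test_ihs_symmetric_alleles_give_raw_zero():
    """Mirrored haplotype structure between the two core alleles."""
    block = np.array([
        [0, 1, 1, 0, 1],
        [0, 1, 1, 0, 1],
        [1, 0, 0, 1, 0],
        [1, 0, 0, 1, 0],
    ], dtype=np.uint8)
    hm = make_hm(block)
    scores = ss.ihs_scan(hm, maf_min=0.05, n_bins=2)
    core = scores[scores["pos"] == 30_000]
    assert core["raw"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_ihs_bins_standardized_to_mean0_sd1():
    """Within every retained frequency bin: mean z ~ 0, sample sd z ~ 1."""
    cfg = ss.SimConfig(seed=21, n_chrom=1, chrom_length=20_000_000,
                       n_snps_per_chrom=400)
    hm = ss.simulate_panel(cfg, 50)
    scores = ss.ihs_scan(hm)
    ok = scores.dropna(subset=["z"])
    for b, grp in ok.groupby("bin"):
        assert grp["z"].mean() == pytest.approx(0.0, abs=1e-9)
        if len(grp) > 1:
            assert grp["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_ihs_skips_low_maf():
    block = np.zeros((20, 5), dtype=np.uint8)
    block[:, 2] = 1
    block[0, 0] = 1  # freq 0.05 < ... equals maf_min -> retained? 1/20=0.05
    hm = make_hm(block)
    with pytest.raises(ValueError, match="no SNP"):
        # every SNP is monomorphic or too-rare/common to score both alleles
        ss.ihs_scan(hm, maf_min=0.2)


# ---------------------------------------------------------------------------
# iHS windows


def _scores_df(pos, z, chrom="1"):
    return pd.DataFrame({"chrom": chrom, "pos": pos,
                         "freq": 0.5, "raw": z, "z": z})


def test_ihs_windows_extreme_window_tops_candidates():
    """One window with mean 5 against near-zero noise: it ranks first, is a
    candidate, and the candidate fraction stays near the top quantile."""
    rng = np.random.default_rng(0)
    pos = np.arange(1, 4001) * 25_000  # 100 Mb
    z = rng.normal(0, 0.01, size=4000)
    hot = (pos > 50_000_000) & (pos <= 50_500_000)
    z[hot] = 5.0
    wins, ivs = ss.ihs_windows(_scores_df(pos, z), "b", {"1": 100_000_000})
    best = wins.loc[wins["mean_abs_z"].idxmax()]
    assert best["start"] <= 50_000_001 and best["end"] >= 50_250_000
    assert any(iv.start_bp <= 50_000_001 and iv.end_bp >= 50_500_000
               for iv in ivs)
    frac = sum(iv.end_bp - iv.start_bp + 1 for iv in ivs) / 100_000_000
    assert frac <= 0.03  # ~top 1% of the genome plus merge slack
    assert all(iv.method == "iHS" and iv.breeds == ("b",) for iv in ivs)


def test_ihs_windows_degenerate_all_equal():
    pos = np.arange(1, 2001) * 25_000
    wins, ivs = ss.ihs_windows(_scores_df(pos, np.ones(2000)), "b",
                               {"1": 50_000_000})
    # every retained window ties at the single quantile value: all included
    assert sum(e - s + 1 for i in ivs for s, e in [(i.start_bp, i.end_bp)]) \
        >= 50_000_000 - 500_000


def test_ihs_windows_merge_overlapping():
    ivs = [CandidateInterval("1", 1, 500_000, "iHS", ("b",)),
           CandidateInterval("1", 250_001, 750_000, "iHS", ("b",))]
    from sweepsignal._util import merge_touching
    assert merge_touching([(1, 500_000), (250_001, 750_000)]) == [(1, 750_000)]


def test_ihs_windows_min_snps():
    pos = np.array([1_000, 2_000, 100_000_000])
    with pytest.raises(ValueError, match="minimum SNP count"):
        ss.ihs_windows(_scores_df(pos, np.zeros(3)), "b", {"1": 100_000_000})


# ---------------------------------------------------------------------------
# XP-EHH


def test_xpehh_identical_panels_raw_zero():
    cfg = ss.SimConfig(seed=13, n_chrom=1, chrom_length=5_000_000,
                       n_snps_per_chrom=100)
    hm = ss.simulate_panel(cfg, 20)
    scores, _ = ss.xpehh_scan(hm, hm, "a", "b")
    assert np.allclose(scores["raw"], 0.0)


def test_xpehh_antisymmetry_exact():
    cfg = ss.SimConfig(seed=14, n_chrom=1, chrom_length=10_000_000,
                       n_snps_per_chrom=200)
    hmA, hmB, _ = ss.split_populations(None, 0.1, 10, cfg)
    ab, _ = ss.xpehh_scan(hmA, hmB, "a", "b")
    ba, _ = ss.xpehh_scan(hmB, hmA, "b", "a")
    np.testing.assert_allclose(ab["raw"], -ba["raw"], atol=1e-12)


def test_xpehh_marker_map_mismatch_raises():
    cfg = ss.SimConfig(seed=15, n_chrom=1, chrom_length=5_000_000,
                       n_snps_per_chrom=100)
    hmA = ss.simulate_panel(cfg, 10)
    hmB = ss.simulate_panel(ss.SimConfig(seed=16, n_chrom=1,
                                         chrom_length=5_000_000,
                                         n_snps_per_chrom=100), 10)
    with pytest.raises(ValueError, match="marker maps"):
        ss.xpehh_scan(hmA, hmB, "a", "b")


def test_xpehh_outlier_merge_gap_rule():
    """200 kb apart: one interval; 300 kb apart: two."""
    near = pd.DataFrame({"chrom": "1", "pos": [1_000_000, 1_200_000],
                         "z": [4.0, 4.5]})
    far = pd.DataFrame({"chrom": "1", "pos": [1_000_000, 1_300_000],
                        "z": [4.0, 4.5]})
    assert len(merge_outlier_snps(near, "a", "b")) == 1
    assert len(merge_outlier_snps(far, "a", "b")) == 2
    mixed = pd.DataFrame({"chrom": "1", "pos": [1_000_000, 1_200_000],
                          "z": [-4.0, -4.5]})
    (iv,) = merge_outlier_snps(mixed, "a", "b")
    assert iv.breeds == ("b",)  # negative mean z favors population B


def test_xpehh_pooled_curve_starts_below_one():
    haps = np.array([[1, 0], [1, 0], [0, 0], [0, 1]], dtype=np.uint8)
    pos = np.array([10_000, 20_000])
    c = _pooled_curve(haps, pos, 0)
    # groups at core: {2 carriers of 1} and {2 of 0} -> (1+1)/6
    assert c.ehh0 == pytest.approx(2 / 6)
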