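"""Two-population Weir-Cockerham FST: per-SNP variance components and
windowed candidate-interval calling.

Per SNP the 1984 variance components are computed from diploid sample sizes,
alt-allele frequencies and observed heterozygote fractions: ``a`` (among
populations), ``b`` (among individuals within populations) and ``c`` (within
individuals); theta = a / (a + b + c). Windows aggregate as a ratio of sums
(sum a / sum(a + b + c)), never a mean of per-SNP ratios, which is unstable
at low-information SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import (assign_windows, merge_touching, quantile_upper,
                    tile_windows)
from .consensus_regions import CandidateInterval
from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class FstComponents:
    snp: str
    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        tot = self.a + self.b + self.c
        return self.a / tot if tot != 0 else float("nan")


def _counts_to_stats(counts):
    hom_ref, het, hom_alt = counts
    n = hom_ref + het + hom_alt
    if n < 2:
        raise ValueError("need >= 2 genotyped diploids per population")
    p = (2 * hom_alt + het) / (2 * n)
    h = het / n
    return float(n), float(p), float(h)


def wc_fst_snp(countsA, countsB) -> FstComponents:
    """Weir-Cockerham (1984) a, b, c for one biallelic SNP between two
    populations given genotype counts (hom-ref, het, hom-alt)."""
    nA, pA, hA = _counts_to_stats(countsA)
    nB, pB, hB = _counts_to_stats(countsB)
    a, b, c = _wc_components(np.array([nA]), np.array([pA]), np.array([hA]),
                             np.array([nB]), np.array([pB]), np.array([hB]))
    return FstComponents("snp", float(a[0]), float(b[0]), float(c[0]))


def _wc_components(nA, pA, hA, nB, pB, hB):
    """Vectorized two-population WC components over SNP arrays."""
    r = 2.0
    nbar = (nA + nB) / r
    nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1)
    pbar = (nA * pA + nB * pB) / (r * nbar)
    s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (nA * hA + nB * hB) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def _pop_stats(calls: np.ndarray):
    miss = calls == MISSING
    n = (~miss).sum(axis=0).astype(float)
    alt = np.where(miss, 0, calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, (calls == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
    return n, p, h


def pairwise_components(gm: GenotypeMatrix, breedA: str, breedB: str) -> pd.DataFrame:
    """Per-SNP WC components between two breeds of one panel.

    SNPs monomorphic across the pooled pair, or with < 2 genotyped diploids in
    either breed, are excluded. Returns chrom, pos, a, b, c, theta.
    """
    idxA = [i for i, s in enumerate(gm.samples) if gm.populations[s] == breedA]
    idxB = [i for i, s in enumerate(gm.samples) if gm.populations[s] == breedB]
    if not idxA or not idxB:
        raise ValueError(f"empty population among {breedA!r}/{breedB!r}")
    nA, pA, hA = _pop_stats(gm.calls[idxA])
    nB, pB, hB = _pop_stats(gm.calls[idxB])
    pooled = (nA * pA + nB * pB) / (nA + nB)
    keep = (nA >= 2) & (nB >= 2) & (pooled > 0) & (pooled < 1)
    a, b, c = _wc_components(nA[keep], pA[keep], hA[keep],
                             nB[keep], pB[keep], hB[keep])
    out = gm.variants.loc[keep, ["chrom", "pos"]].reset_index(drop=True)
    out["a"], out["b"], out["c"] = a, b, c
    tot = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        out["theta"] = np.where(tot != 0, a / np.where(tot != 0, tot, 1), np.nan)
    return out


def genome_fst(components: pd.DataFrame) -> float:
    """Genome-wide ratio-of-sums FST over all component rows."""
    tot = (components["a"] + components["b"] + components["c"]).sum()
    return float(components["a"].sum() / tot)


def fst_windows(components: pd.DataFrame, pair: tuple[str, str],
                chrom_lengths: dict[str, int] | None = None,
                window: int = 500_000, step: int = 250_000,
                min_snps: int = 3, top_q: float = 0.01):
    """Windowed ratio-of-sums FST and top-fraction candidate intervals.

    Windows below min_snps SNPs, or whose component total is zero, are
    dropped. Candidates are windows at or above the empirical (1 - top_q)
    quantile, merged when overlapping/book-ended and labelled with the breed
    pair. Returns (window table, CandidateInterval list).
    """
    recs = []
    for chrom, grp in components.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        a = grp["a"].to_numpy()
        tot = (grp["a"] + grp["b"] + grp["c"]).to_numpy()
        span = chrom_lengths.get(str(chrom), int(pos.max())) if chrom_lengths \
            else int(pos.max())
        for start, idx in assign_windows(pos, tile_windows(span, window, step), window):
            if idx.size < min_snps:
                continue
            denom = tot[idx].sum()
            if denom == 0:
                continue
            recs.append((chrom, start + 1, start + window, idx.size,
                         float(a[idx].sum() / denom)))
    if not recs:
        raise ValueError("fst_windows: no retained window")
    wins = pd.DataFrame(recs, columns=["chrom", "start", "end", "n_snps", "fst"])
    thr = quantile_upper(wins["fst"].to_numpy(), 1 - top_q)
    cand = wins[wins["fst"] >= thr]
    intervals = []
    for chrom, grp in cand.groupby("chrom", sort=False):
        for s, e in merge_touching(list(zip(grp["start"], grp["end"]))):
            intervals.append(CandidateInterval(str(chrom), s, e, "FST",
                                               tuple(sorted(pair))))
    return wins, intervals
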