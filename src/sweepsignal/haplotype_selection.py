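"""Extended haplotype homozygosity statistics: EHH, iHH, iHS and XP-EHH.

EHH at a distance x from a core SNP is the probability that two randomly
chosen haplotypes carrying the core allele are identical at every SNP from
the core out to x. iHH integrates the EHH curve over physical distance
(trapezoids, truncated where EHH drops below a cutoff); iHS is the log-ratio
of iHH between the two core alleles, standardized within allele-frequency
bins; XP-EHH is the log-ratio of whole-population iHH between two
populations, standardized genome-wide.

Scores are unpolarized (allele 1 = alt): SNP arrays carry no ancestral-allele
call, so all downstream outlier thresholds operate on |z|.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import (assign_windows, chrom_sort_key, log, merge_touching,
                    order_chroms, quantile_upper, tile_windows)
from .consensus_regions import CandidateInterval
from .genotype_io import MISSING, GenotypeMatrix

EHH_CUTOFF = 0.05


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes (2N x variants) with positions and breed labels.

    Haplotypes 2i and 2i+1 belong to sample i. Variants are sorted by
    (chromosome, position) like :class:`GenotypeMatrix`.
    """

    samples: list[str]
    populations: dict[str, str]
    variants: pd.DataFrame  # columns chrom, pos (id/ref/alt optional)
    haps: np.ndarray  # uint8 (2N, M)

    def __post_init__(self):
        self.haps = np.asarray(self.haps, dtype=np.uint8)
        if self.haps.shape != (2 * len(self.samples), len(self.variants)):
            raise ValueError("haps shape must be (2*n_samples, n_variants)")
        if not np.isin(self.haps, [0, 1]).all():
            raise ValueError("haplotype alleles must be 0/1 with no missing")
        self.variants = self.variants.reset_index(drop=True)
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[0]

    def chroms(self) -> list:
        return order_chroms(self.variants["chrom"])

    def chrom_slice(self, chrom) -> np.ndarray:
        return self.variants.index[self.variants["chrom"] == chrom].to_numpy()

    def subset_population(self, breed: str) -> "HaplotypeMatrix":
        keep = [i for i, s in enumerate(self.samples) if self.populations[s] == breed]
        rows = np.array([[2 * i, 2 * i + 1] for i in keep]).ravel()
        samples = [self.samples[i] for i in keep]
        return HaplotypeMatrix(
            samples, {s: self.populations[s] for s in samples},
            self.variants.copy(), self.haps[rows],
        )

    def to_genotype_matrix(self) -> GenotypeMatrix:
        calls = (self.haps[0::2].astype(np.int8) + self.haps[1::2])
        variants = self.variants.copy()
        if "id" not in variants:
            variants["id"] = [f"{c}:{p}" for c, p in zip(variants["chrom"], variants["pos"])]
        if "ref" not in variants:
            variants["ref"] = "A"
            variants["alt"] = "G"
        variants = variants[["chrom", "pos", "id", "ref", "alt"]]
        return GenotypeMatrix(self.samples, dict(self.populations), variants,
                              calls, phased=True)


def read_haplotypes(path, populations: dict[str, str] | None = None) -> HaplotypeMatrix:
    """Read a fully phased VCF into a HaplotypeMatrix (errors on missing or
    unphased heterozygous genotypes)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(v.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                raise ValueError(f"missing genotype at {v.CHROM}:{v.POS}; "
                                 "haplotype statistics need complete phased data")
            if a0 != a1 and not gt[2]:
                raise ValueError(f"unphased heterozygote at {v.CHROM}:{v.POS}")
            col[2 * i], col[2 * i + 1] = a0, a1
        rows.append((str(v.CHROM), int(v.POS)))
        cols.append(col)
    vcf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos"])
    haps = np.stack(cols, axis=1)
    order = sorted(range(len(variants)), key=lambda i: (
        chrom_sort_key(variants["chrom"].iat[i]), variants["pos"].iat[i]))
    variants = variants.iloc[order].reset_index(drop=True)
    haps = haps[:, order]
    if populations is None:
        populations = {s: "all" for s in samples}
    return HaplotypeMatrix(samples, populations, variants, haps)


def write_phased_vcf(hm: HaplotypeMatrix, path,
                     chrom_lengths: dict[str, int] | None = None):
    """Write a HaplotypeMatrix as a phased VCF, preserving which haplotype of
    each sample carries each allele (unlike genotype-level VCF writing, which
    cannot represent heterozygote phase)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=sweepsignal\n")
        if chrom_lengths:
            for c in sorted(chrom_lengths, key=chrom_sort_key):
                fh.write(f"##contig=<ID={c},length={chrom_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(hm.samples) + "\n")
        v = hm.variants
        ref = list(v["ref"]) if "ref" in v else ["A"] * len(v)
        alt = list(v["alt"]) if "alt" in v else ["G"] * len(v)
        for j in range(len(v)):
            gts = "\t".join(f"{hm.haps[2 * i, j]}|{hm.haps[2 * i + 1, j]}"
                            for i in range(len(hm.samples)))
            fh.write(f"{v['chrom'].iat[j]}\t{v['pos'].iat[j]}\t"
                     f"{v['chrom'].iat[j]}:{v['pos'].iat[j]}\t{ref[j]}\t"
                     f"{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# EHH


@dataclass
class EHHCurve:
    """One core SNP's EHH decay, both directions.

    Offsets are positive bp distances from the core, per side; values start
    from ``ehh0`` (1 for an allele-conditional curve). ``reached_end_*`` marks
    a side that ran to the chromosome's terminal SNP without decaying to 0.
    """

    chrom: str
    core_pos: int
    allele: int | None
    ehh0: float
    left_offsets: np.ndarray
    left_ehh: np.ndarray
    right_offsets: np.ndarray
    right_ehh: np.ndarray
    reached_end_left: bool
    reached_end_right: bool


def _pair_fraction(group_ids: np.ndarray) -> float:
    counts = np.bincount(group_ids)
    n = group_ids.size
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _ehh_decay(haps: np.ndarray, pos: np.ndarray, rows: np.ndarray, core: int,
               step: int, ids0: np.ndarray):
    """Walk outward from the core refining haplotype identity groups.

    Stops once EHH hits 0 (it cannot recover). Returns (offsets, values,
    reached_end).
    """
    m = haps.shape[1]
    offsets, values = [], []
    ids = ids0
    j = core + step
    reached_end = True
    while 0 <= j < m:
        keys = ids * 2 + haps[rows, j]
        _, ids = np.unique(keys, return_inverse=True)
        e = _pair_fraction(ids)
        offsets.append(abs(int(pos[j]) - int(pos[core])))
        values.append(e)
        if e == 0.0:
            reached_end = False
            break
        j += step
    return np.asarray(offsets, dtype=float), np.asarray(values), reached_end


def ehh(hm: HaplotypeMatrix, chrom, core_index: int, allele: int) -> EHHCurve:
    """Allele-conditional EHH curve around one core SNP.

    ``core_index`` indexes SNPs within ``chrom``. Requires >= 2 carrier
    haplotypes of ``allele`` at the core.
    """
    vidx = hm.chrom_slice(chrom)
    haps = hm.haps[:, vidx]
    pos = hm.variants["pos"].to_numpy()[vidx]
    rows = np.where(haps[:, core_index] == allele)[0]
    if rows.size < 2:
        raise ValueError(
            f"EHH undefined: {rows.size} carriers of allele {allele} at "
            f"{chrom} index {core_index}")
    ids0 = np.zeros(rows.size, dtype=np.int64)
    lo, le, lend = _ehh_decay(haps, pos, rows, core_index, -1, ids0)
    ro, re_, rend = _ehh_decay(haps, pos, rows, core_index, +1, ids0)
    return EHHCurve(str(chrom), int(pos[core_index]), allele, 1.0,
                    lo, le, ro, re_, lend, rend)


def _pooled_curve(haps: np.ndarray, pos: np.ndarray, core_index: int) -> EHHCurve:
    """Whole-population (unconditional) EHH used by XP-EHH: identity groups
    start from the core allele classes themselves, so ehh0 < 1 in general."""
    rows = np.arange(haps.shape[0])
    _, ids0 = np.unique(haps[:, core_index], return_inverse=True)
    ehh0 = _pair_fraction(ids0)
    lo, le, lend = _ehh_decay(haps, pos, rows, core_index, -1, ids0)
    ro, re_, rend = _ehh_decay(haps, pos, rows, core_index, +1, ids0)
    return EHHCurve("", int(pos[core_index]), None, ehh0, lo, le, ro, re_, lend, rend)


def _side_area(offs: np.ndarray, vals: np.ndarray, ehh0: float, cutoff: float):
    """Trapezoid area of one side, truncated at the linear crossing of the
    cutoff; returns (area, hit_cutoff)."""
    x = np.concatenate([[0.0], offs])
    y = np.concatenate([[ehh0], vals])
    below = np.where(y < cutoff)[0]
    if below.size == 0:
        return float(np.trapezoid(y, x)), False
    k = int(below[0])
    if k == 0:
        return 0.0, True
    area = float(np.trapezoid(y[:k], x[:k]))
    # interpolate where the curve crosses the cutoff between k-1 and k
    x_star = x[k - 1] + (x[k] - x[k - 1]) * (y[k - 1] - cutoff) / (y[k - 1] - y[k])
    area += 0.5 * (y[k - 1] + cutoff) * (x_star - x[k - 1])
    return area, True


def ihh(curve: EHHCurve, cutoff: float = EHH_CUTOFF) -> tuple[float, bool]:
    """Integrated EHH (bp-weighted, both sides). ``truncated`` is True when a
    side ran into the chromosome end while still above the cutoff."""
    la, lhit = _side_area(curve.left_offsets, curve.left_ehh, curve.ehh0, cutoff)
    ra, rhit = _side_area(curve.right_offsets, curve.right_ehh, curve.ehh0, cutoff)
    truncated = (curve.reached_end_left and not lhit) or (
        curve.reached_end_right and not rhit)
    return la + ra, truncated


# ---------------------------------------------------------------------------
# iHS


def _merge_small_bins(bin_ids: np.ndarray, n_bins: int, min_count: int = 10) -> np.ndarray:
    """Merge frequency bins holding < min_count SNPs into an adjacent bin
    (the smaller neighbour; ties go left). Returns relabelled bin ids."""
    groups = [[b] for b in range(n_bins)]
    counts = [int((bin_ids == b).sum()) for b in range(n_bins)]
    groups = [g for g, c in zip(groups, counts) if c > 0]
    counts = [c for c in counts if c > 0]
    while len(groups) > 1 and min(counts) < min_count:
        i = int(np.argmin(counts))
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            j = i - 1 if counts[i - 1] <= counts[i + 1] else i + 1
        lo, hi = sorted((i, j))
        groups[lo] = groups[lo] + groups[hi]
        counts[lo] = counts[lo] + counts[hi]
        del groups[hi], counts[hi]
    relabel = {}
    for new, g in enumerate(groups):
        for b in g:
            relabel[b] = new
    return np.array([relabel[b] for b in bin_ids])


def ihs_scan(hm: HaplotypeMatrix, maf_min: float = 0.05,
             n_bins: int = 20) -> pd.DataFrame:
    """Unstandardized and bin-standardized iHS for every eligible SNP of one
    population's panel.

    raw = ln(iHH_allele1 / iHH_allele0); z standardizes raw within equal-width
    allele-1-frequency bins (bins with < 10 SNPs merged with a neighbour;
    sample sd, ddof=1). SNPs with within-panel MAF < maf_min or < 2 carriers
    of either allele are skipped.
    """
    recs = []
    skipped = 0
    for chrom in hm.chroms():
        vidx = hm.chrom_slice(chrom)
        haps = hm.haps[:, vidx]
        pos = hm.variants["pos"].to_numpy()[vidx]
        freq = haps.mean(axis=0)
        for j in range(haps.shape[1]):
            p = freq[j]
            if min(p, 1 - p) < maf_min:
                continue
            n1 = int(round(p * haps.shape[0]))
            if n1 < 2 or haps.shape[0] - n1 < 2:
                skipped += 1
                continue
            ihh1, t1 = ihh(ehh(hm, chrom, j, 1))
            ihh0, t0 = ihh(ehh(hm, chrom, j, 0))
            if ihh1 <= 0 or ihh0 <= 0:
                skipped += 1
                continue
            recs.append((chrom, int(pos[j]), float(p),
                         math.log(ihh1 / ihh0), bool(t1 or t0)))
    if skipped:
        log.info("ihs_scan: skipped %d SNPs (carrier count or zero iHH)", skipped)
    if not recs:
        raise ValueError("ihs_scan: no SNP produced a score")
    df = pd.DataFrame(recs, columns=["chrom", "pos", "freq", "raw", "truncated"])

    edges = np.linspace(0, 1, n_bins + 1)
    bin_ids = np.clip(np.digitize(df["freq"], edges[1:-1]), 0, n_bins - 1)
    bin_ids = _merge_small_bins(bin_ids, n_bins)
    z = np.full(len(df), np.nan)
    for b in np.unique(bin_ids):
        sel = bin_ids == b
        vals = df.loc[sel, "raw"].to_numpy()
        sd = vals.std(ddof=1) if sel.sum() > 1 else 0.0
        if sd > 0:
            z[sel] = (vals - vals.mean()) / sd
    df["z"] = z
    df["bin"] = bin_ids
    return df


def ihs_windows(scores: pd.DataFrame, breed: str,
                chrom_lengths: dict[str, int] | None = None,
                window: int = 500_000, step: int = 250_000,
                min_snps: int = 5, top_q: float = 0.01):
    """Windowed mean |iHS| and top-fraction candidate intervals.

    Windows of ``window`` bp tile each chromosome from coordinate 0 advancing
    ``step``; windows with >= min_snps scored SNPs are retained; candidates
    are windows at or above the empirical (1 - top_q) quantile of mean |z|,
    merged when overlapping or book-ended. Returns (window table,
    CandidateInterval list).
    """
    recs = []
    scores = scores.dropna(subset=["z"])
    for chrom, grp in scores.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        az = np.abs(grp["z"].to_numpy())
        span = chrom_lengths.get(str(chrom), int(pos.max())) if chrom_lengths \
            else int(pos.max())
        for start, idx in assign_windows(pos, tile_windows(span, window, step), window):
            if idx.size >= min_snps:
                recs.append((chrom, start + 1, start + window, idx.size,
                             float(az[idx].mean())))
    if not recs:
        raise ValueError("ihs_windows: no window reached the minimum SNP count")
    wins = pd.DataFrame(recs, columns=["chrom", "start", "end", "n_snps", "mean_abs_z"])
    if len(wins) < 100:
        warnings.warn(f"only {len(wins)} retained windows; top-quantile unstable")
    thr = quantile_upper(wins["mean_abs_z"].to_numpy(), 1 - top_q)
    cand = wins[wins["mean_abs_z"] >= thr]
    intervals = []
    for chrom, grp in cand.groupby("chrom", sort=False):
        for s, e in merge_touching(list(zip(grp["start"], grp["end"]))):
            intervals.append(CandidateInterval(str(chrom), s, e, "iHS", (breed,)))
    return wins, intervals


# ---------------------------------------------------------------------------
# XP-EHH


def xpehh_scan(hmA: HaplotypeMatrix, hmB: HaplotypeMatrix,
               popA: str, popB: str, top_q: float = 0.01,
               merge_gap: int = 250_000, cutoff: float = EHH_CUTOFF):
    """Cross-population EHH scan between two panels on identical marker maps.

    Per SNP, iHH is integrated over the whole-population (pooled) EHH curve of
    each panel; raw = ln(iHH_A / iHH_B), z = genome-standardized raw. Outlier
    SNPs (|z| at or above the empirical (1 - top_q) quantile) are merged into
    intervals when <= merge_gap bp apart, each labelled with the favored
    population by mean z sign (z > 0 means longer haplotypes in popA).
    Returns (score table, CandidateInterval list).
    """
    va = hmA.variants[["chrom", "pos"]].reset_index(drop=True)
    vb = hmB.variants[["chrom", "pos"]].reset_index(drop=True)
    if len(va) != len(vb) or not va.equals(vb):
        raise ValueError("xpehh_scan: the two panels are not on identical marker maps")
    recs = []
    for chrom in hmA.chroms():
        vidx = hmA.chrom_slice(chrom)
        hapsA, hapsB = hmA.haps[:, vidx], hmB.haps[:, vidx]
        pos = hmA.variants["pos"].to_numpy()[vidx]
        for j in range(len(vidx)):
            ia, ta = ihh(_pooled_curve(hapsA, pos, j), cutoff)
            ib, tb = ihh(_pooled_curve(hapsB, pos, j), cutoff)
            if ia <= 0 or ib <= 0:
                continue
            recs.append((chrom, int(pos[j]), math.log(ia / ib), bool(ta or tb)))
    if not recs:
        raise ValueError("xpehh_scan: no SNP produced a score")
    df = pd.DataFrame(recs, columns=["chrom", "pos", "raw", "truncated"])
    raw = df["raw"].to_numpy()
    sd = raw.std(ddof=1)
    if sd == 0:
        df["z"] = 0.0
    else:
        df["z"] = (raw - raw.mean()) / sd
    thr = quantile_upper(np.abs(df["z"].to_numpy()), 1 - top_q)
    out = df[np.abs(df["z"]) >= thr]
    return df, merge_outlier_snps(out, popA, popB, merge_gap)


def merge_outlier_snps(outliers: pd.DataFrame, popA: str, popB: str,
                       merge_gap: int = 250_000) -> list[CandidateInterval]:
    """Merge outlier SNPs (columns chrom, pos, z) into XPEHH candidate
    intervals: successive SNPs <= merge_gap bp apart join one interval,
    labelled with the favored population by mean z sign."""
    intervals = []
    for chrom, grp in outliers.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        zz = grp["z"].to_numpy()
        brk = np.where(np.diff(pos) > merge_gap)[0] + 1
        for block in np.split(np.arange(len(pos)), brk):
            favored = popA if zz[block].mean() > 0 else popB
            intervals.append(CandidateInterval(
                str(chrom), int(pos[block[0]]), int(pos[block[-1]]),
                "XPEHH", (favored,)))
    return intervals
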