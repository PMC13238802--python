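"""Genotype containers, VCF/PED-MAP input, PLINK-style QC and diversity statistics.

The central container is :class:`GenotypeMatrix`: diploid alt-allele dosages
(0/1/2, ``MISSING`` = -1) for samples x variants, with 1-based physical
positions and a sample->breed map. Filters mirror the PLINK flags
``--geno 0.05 --mind 0.05 --maf 0.05`` and ``--indep-pairwise 50 5 0.2``
commonly used for SNP-array panels, with a fixed, documented stage order
(mind -> geno -> maf) so results are reproducible across versions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import chrom_sort_key, log

MISSING = -1

_VARIANT_COLS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for samples x variants.

    calls[i, j] counts alt alleles of sample i at variant j (0, 1, 2) or is
    ``MISSING``. Variants are sorted by (chromosome, position); positions are
    1-based and strictly increasing within each chromosome.
    """

    samples: list[str]
    populations: dict[str, str]
    variants: pd.DataFrame
    calls: np.ndarray
    phased: bool = False

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError("calls shape does not match samples x variants")
        bad = ~np.isin(self.calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {MISSING, 0, 1, 2}")
        missing_pop = [s for s in self.samples if s not in self.populations]
        if missing_pop:
            raise ValueError(f"samples without a population label: {missing_pop[:5]}")
        self.variants = self.variants.reset_index(drop=True)
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                i = int(np.where(np.diff(p) <= 0)[0][0])
                raise ValueError(
                    f"positions not strictly increasing on {chrom} near pos {p[i]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def pop_of(self, sample: str) -> str:
        return self.populations[sample]

    def breeds(self) -> list[str]:
        seen = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        samples = [self.samples[i] for i in si]
        return GenotypeMatrix(
            samples=samples,
            populations={s: self.populations[s] for s in samples},
            variants=self.variants.iloc[vi].reset_index(drop=True),
            calls=self.calls[np.ix_(si, vi)],
            phased=self.phased,
        )


@dataclass
class QCReport:
    variants_removed_geno: int
    samples_removed_mind: int
    variants_removed_maf: int
    remaining_variants: int
    remaining_samples: int
    genotyping_rate: float


@dataclass
class DiversityStats:
    """Per-breed panel summaries: mean MAF, observed/expected heterozygosity and
    the inbreeding coefficient F = 1 - mean(Ho)/mean(He)."""

    breed: str
    n: int
    maf: float
    ho: float
    he: float
    f: float


# ---------------------------------------------------------------------------
# input


def read_popmap(path) -> dict[str, str]:
    """Read a two-column TSV sample_id<TAB>breed."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"population map {path} needs two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_chrom_lengths(path) -> dict[str, int]:
    """Read a two-column TSV chrom<TAB>length_bp."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return {str(c): int(l) for c, l in zip(df.iloc[:, 0], df.iloc[:, 1])}


def _sort_variants(variants: pd.DataFrame, calls: np.ndarray):
    order = sorted(
        range(len(variants)),
        key=lambda i: (chrom_sort_key(variants["chrom"].iat[i]), variants["pos"].iat[i]),
    )
    variants = variants.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    dup = variants.duplicated(subset=["chrom", "pos"])
    if dup.any():
        r = variants[dup].iloc[0]
        raise ValueError(f"duplicate variant site {r['chrom']}:{r['pos']}")
    return variants, calls


def read_vcf(path, populations: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a GenotypeMatrix.

    Non-SNP or multi-allelic records are skipped (count logged). ``phased`` is
    true iff every non-missing genotype uses the phased '|' separator.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosages = []
    skipped = 0
    all_phased = True
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                col[i] = MISSING
            else:
                col[i] = a0 + a1
                if not gt[2]:
                    all_phased = False
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        rows.append((str(v.CHROM), int(v.POS), vid, v.REF, v.ALT[0]))
        dosages.append(col)
    vcf.close()
    if skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    variants = pd.DataFrame(rows, columns=_VARIANT_COLS)
    calls = np.stack(dosages, axis=1)
    variants, calls = _sort_variants(variants, calls)
    if populations is None:
        populations = {s: "all" for s in samples}
    return GenotypeMatrix(samples, populations, variants, calls, phased=all_phased)


def read_pedmap(prefix, populations: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read PLINK text PED/MAP. Alt allele = lexicographically larger observed
    allele at each site (documented convention); '0 0' genotypes are missing."""
    map_df = pd.read_csv(
        f"{prefix}.map", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos"], dtype={"chrom": str, "id": str},
    )
    n_var = len(map_df)
    samples, pops, geno_rows = [], {}, []
    with open(f"{prefix}.ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_var:
                raise ValueError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * n_var} columns, "
                    f"got {len(parts)}"
                )
            samples.append(parts[1])
            pops[parts[1]] = parts[0]
            geno_rows.append(parts[6:])
    alleles = np.array(geno_rows, dtype="U1").reshape(len(samples), n_var, 2)
    calls = np.full((len(samples), n_var), MISSING, dtype=np.int8)
    refs, alts = [], []
    for j in range(n_var):
        a = alleles[:, j, :]
        obs = sorted(set(a.ravel()) - {"0"})
        if not obs:
            refs.append("N"); alts.append("N")
            continue
        ref = obs[0]
        alt = obs[-1] if len(obs) > 1 else obs[0]
        refs.append(ref); alts.append(alt)
        miss = (a == "0").any(axis=1)
        calls[:, j] = (a == alt).sum(axis=1)
        calls[miss, j] = MISSING
    variants = pd.DataFrame({
        "chrom": map_df["chrom"].astype(str), "pos": map_df["pos"].astype(int),
        "id": map_df["id"], "ref": refs, "alt": alts,
    })[_VARIANT_COLS]
    variants, calls = _sort_variants(variants, calls)
    if populations is None:
        populations = pops
    return GenotypeMatrix(samples, populations, variants, calls, phased=False)


def write_vcf(gm: GenotypeMatrix, path, chrom_lengths: dict[str, int] | None = None):
    """Write a minimal VCF 4.2 with GT fields ('|' separators when phased).

    A GenotypeMatrix stores dosages, so heterozygotes are emitted as 0|1
    regardless of which haplotype carries the alt allele; for output that
    haplotype-aware consumers will re-read, use
    :func:`sweepsignal.write_phased_vcf` on the HaplotypeMatrix instead.
    """
    sep = "|" if gm.phased else "/"
    gt_str = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepsignal\n")
        if chrom_lengths:
            for c in sorted(chrom_lengths, key=chrom_sort_key):
                fh.write(f"##contig=<ID={c},length={chrom_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j, row in gm.variants.iterrows():
            gts = "\t".join(gt_str[int(c)] for c in gm.calls[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# QC


def _alt_freq(calls: np.ndarray) -> np.ndarray:
    """Per-variant alt-allele frequency over non-missing calls (nan if none)."""
    miss = calls == MISSING
    alt = np.where(miss, 0, calls).sum(axis=0)
    an = 2 * (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(an > 0, alt / np.maximum(an, 1), np.nan)


def variant_maf(calls: np.ndarray) -> np.ndarray:
    p = _alt_freq(calls)
    return np.minimum(p, 1 - p)


def qc_filter(gm: GenotypeMatrix, geno: float = 0.05, mind: float = 0.05,
              maf: float = 0.05) -> tuple[GenotypeMatrix, QCReport]:
    """PLINK-style QC in one fixed pass: drop samples with missingness > mind,
    then variants with missingness > geno, then variants with MAF < maf."""
    for name, t in (("geno", geno), ("mind", mind), ("maf", maf)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} threshold must be in [0, 1], got {t}")
    miss = gm.calls == MISSING

    keep_s = miss.mean(axis=1) <= mind
    n_s_removed = int((~keep_s).sum())
    if not keep_s.any():
        raise ValueError("qc_filter: all samples removed at the mind stage")
    calls = gm.calls[keep_s]

    vmiss = (calls == MISSING).mean(axis=0)
    keep_geno = vmiss <= geno
    n_geno = int((~keep_geno).sum())

    mafs = variant_maf(calls)
    keep_maf = keep_geno & ~np.isnan(mafs) & (mafs >= maf)
    n_maf = int(keep_geno.sum() - keep_maf.sum())
    if not keep_maf.any():
        stage = "geno" if not keep_geno.any() else "maf"
        raise ValueError(f"qc_filter: all variants removed at the {stage} stage")

    out = gm.subset(np.where(keep_s)[0], np.where(keep_maf)[0])
    rate = float((out.calls != MISSING).mean())
    report = QCReport(
        variants_removed_geno=n_geno,
        samples_removed_mind=n_s_removed,
        variants_removed_maf=n_maf,
        remaining_variants=out.n_variants,
        remaining_samples=out.n_samples,
        genotyping_rate=rate,
    )
    return out, report


# ---------------------------------------------------------------------------
# diversity


def diversity_stats(gm: GenotypeMatrix) -> list[DiversityStats]:
    """Per-breed mean MAF, Ho, He (small-sample corrected) and F.

    Per SNP within a breed, with n genotyped diploids and alt frequency p:
    Ho = fraction heterozygous, He = 2 p (1-p) * 2n/(2n-1), MAF = min(p, 1-p).
    Breed values are means over SNPs; F = 1 - mean(Ho)/mean(He). SNPs with
    fewer than two genotyped samples in the breed are left out of its means.
    """
    out = []
    for breed in gm.breeds():
        idx = [i for i, s in enumerate(gm.samples) if gm.populations[s] == breed]
        if len(idx) < 2:
            warnings.warn(f"breed {breed!r} has <2 samples; excluded from diversity")
            continue
        calls = gm.calls[idx]
        miss = calls == MISSING
        n = (~miss).sum(axis=0)
        ok = n >= 2
        an = 2 * n[ok]
        p = np.where(miss, 0, calls)[:, ok].sum(axis=0) / an
        ho = (calls[:, ok] == 1).sum(axis=0) / n[ok]
        he = 2 * p * (1 - p) * an / (an - 1)
        maf = np.minimum(p, 1 - p)
        ho_m, he_m = float(ho.mean()), float(he.mean())
        f = 1 - ho_m / he_m if he_m > 0 else float("nan")
        out.append(DiversityStats(breed, len(idx), float(maf.mean()), ho_m, he_m, f))
    return out


# ---------------------------------------------------------------------------
# LD pruning


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))
    return r * r


def ld_prune(gm: GenotypeMatrix, window_snps: int = 50, step_snps: int = 5,
             r2: float = 0.2) -> list[str]:
    """Greedy windowed LD pruning, PLINK --indep-pairwise style.

    Within each window of ``window_snps`` consecutive SNPs (advancing
    ``step_snps``) any pair with squared dosage correlation > ``r2`` loses its
    lower-MAF member (tie: the later position is removed). Returns kept
    variant IDs, position-sorted.
    """
    if gm.n_samples < 2:
        raise ValueError("ld_prune needs at least 2 samples")
    mafs = variant_maf(gm.calls)
    removed = np.zeros(gm.n_variants, dtype=bool)
    for chrom, grp in gm.variants.groupby("chrom", sort=False):
        vidx = grp.index.to_numpy()
        m = len(vidx)
        start = 0
        while start < m:
            win = vidx[start:start + window_snps]
            changed = True
            while changed:
                changed = False
                kept = [v for v in win if not removed[v]]
                for a in range(len(kept)):
                    for b in range(a + 1, len(kept)):
                        i, j = kept[a], kept[b]
                        if _dosage_r2(gm.calls[:, i], gm.calls[:, j]) > r2:
                            # j is the later position; drop lower MAF, tie -> j
                            drop = i if mafs[i] < mafs[j] else j
                            removed[drop] = True
                            changed = True
                            break
                    if changed:
                        break
            if start + window_snps >= m:
                break
            start += step_snps
    kept_idx = np.where(~removed)[0]
    return [gm.variants["id"].iat[i] for i in kept_idx]
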