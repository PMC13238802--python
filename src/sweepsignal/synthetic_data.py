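"""Synthetic phased SNP panels: Li-Stephens-style mosaics, Balding-Nichols
population splits and planted selective sweeps with ground truth.

The generator is a deliberately simple caricature of an array-genotyped
multi-breed panel, not a demographic model: K founder haplotypes are drawn
per chromosome and every sample haplotype is a copying mosaic over them,
switching founders between adjacent SNPs with probability 1 - exp(-rho * d)
for inter-SNP distance d. This yields linkage disequilibrium that decays
with physical distance and haplotype sharing that the EHH statistics consume.
Population pairs differ by Balding-Nichols Beta-perturbed site frequencies
at a target FST; sweeps are hard copy-paste events with exponentially
eroded edges whose detectability is tuned by (sweep frequency, mean flank).

Defaults emulate the study panel at desk scale: two ~40-Mb chromosomes at
one SNP per 50 kb (array-like density) and 25 diploids per population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .haplotype_selection import HaplotypeMatrix


@dataclass
class SimConfig:
    n_chrom: int = 2
    chrom_length: int = 40_000_000
    n_snps_per_chrom: int = 800
    n_founders: int = 20
    switch_rate: float = 1e-6  # per-bp copying switch intensity
    freq_low: float = 0.1
    freq_high: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not 0 < self.freq_low < self.freq_high <= 0.5:
            raise ValueError("require 0 < freq_low < freq_high <= 0.5")
        if self.switch_rate <= 0:
            raise ValueError("switch_rate must be positive")

    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chrom)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}


@dataclass
class SweepTruth:
    chrom: str
    focal_pos: int
    sweep_freq: float
    mean_flank: float
    affected_haplotypes: list[int]

    def interval(self) -> tuple[int, int]:
        """Nominal truth span: focal position +/- one mean flank length."""
        return (max(1, int(self.focal_pos - self.mean_flank)),
                int(self.focal_pos + self.mean_flank))


def draw_map(cfg: SimConfig, rng: np.random.Generator):
    """Per chromosome: sorted deduplicated uniform positions and Uniform
    (freq_low, freq_high) site frequencies."""
    out = []
    for chrom in cfg.chrom_names():
        pos = np.unique(rng.integers(1, cfg.chrom_length + 1,
                                     size=cfg.n_snps_per_chrom))
        tries = 0
        while pos.size < cfg.n_snps_per_chrom:
            extra = rng.integers(1, cfg.chrom_length + 1,
                                 size=cfg.n_snps_per_chrom - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
            tries += 1
            if tries > 100:
                raise ValueError("n_snps exceeds distinct achievable positions")
        freqs = rng.uniform(cfg.freq_low, cfg.freq_high, size=pos.size)
        out.append((chrom, pos.astype(np.int64), freqs))
    return out


def _mosaic(founders: np.ndarray, pos: np.ndarray, rho: float, n_hap: int,
            rng: np.random.Generator) -> np.ndarray:
    """Sample haplotypes as founder-copying mosaics along one chromosome."""
    k, m = founders.shape
    switch_p = 1.0 - np.exp(-rho * np.diff(pos))
    haps = np.empty((n_hap, m), dtype=np.uint8)
    for h in range(n_hap):
        switches = rng.random(m - 1) < switch_p
        n_seg = int(switches.sum()) + 1
        choices = rng.integers(0, k, size=n_seg)
        seg_idx = np.concatenate([[0], np.cumsum(switches)])
        path = choices[seg_idx]
        haps[h] = founders[path, np.arange(m)]
    return haps


def _panel_from_founders(per_chrom, n_hap, rho, rng, samples, populations):
    variants, blocks = [], []
    for chrom, pos, founders in per_chrom:
        blocks.append(_mosaic(founders, pos, rho, n_hap, rng))
        variants.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    return HaplotypeMatrix(samples, populations,
                           pd.concat(variants, ignore_index=True),
                           np.concatenate(blocks, axis=1))


def _sample_names(n_dip: int, label: str) -> list[str]:
    return [f"{label}_S{i:03d}" for i in range(n_dip)]


def simulate_panel(cfg: SimConfig, n_haplotypes: int, pop_label: str = "pop1",
                   return_founders: bool = False):
    """One-population panel: Bernoulli(p_j) founders, mosaic haplotypes.

    ``n_haplotypes`` must be even; consecutive haplotype pairs form diploids.
    Fully reproducible from cfg.seed. With ``return_founders`` also returns
    the per-chromosome founder pools [(chrom, positions, founders), ...].
    """
    if n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even (pairs form diploids)")
    rng = np.random.default_rng(cfg.seed)
    per_chrom = []
    for chrom, pos, freqs in draw_map(cfg, rng):
        founders = (rng.random((cfg.n_founders, pos.size)) < freqs).astype(np.uint8)
        per_chrom.append((chrom, pos, founders))
    samples = _sample_names(n_haplotypes // 2, pop_label)
    pops = {s: pop_label for s in samples}
    hm = _panel_from_founders(per_chrom, n_haplotypes, cfg.switch_rate, rng,
                              samples, pops)
    if return_founders:
        return hm, per_chrom
    return hm


def balding_nichols(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Subpopulation frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F); sites fixed
    at 0 or 1 are carried over unchanged."""
    p = np.asarray(p, dtype=float)
    out = np.array(p, copy=True)
    free = (p > 0) & (p < 1)
    scale = (1 - F) / F
    out[free] = rng.beta(p[free] * scale, (1 - p[free]) * scale)
    return out


def _matched_founders(p_prime: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Founder pool whose realized allele frequency tracks p' per site:
    counts by randomized rounding of k*p', placed on random founder rows."""
    m = p_prime.size
    count = np.floor(k * p_prime + rng.random(m)).astype(np.int64)
    ranks = np.argsort(rng.random((k, m)), axis=0)
    return (ranks < count).astype(np.uint8)


def split_populations(freqs, F: float, n_per_pop: int, cfg: SimConfig,
                      pop_labels: tuple[str, str] = ("pop1", "pop2")):
    """Two panels on one marker map diverged at target Weir-Cockerham FST ~ F.

    ``freqs`` may be None (ancestral frequencies drawn from cfg) or a list of
    per-chromosome frequency arrays matching cfg's map. Per population and
    site a Balding-Nichols Beta draw perturbs the ancestral frequency; each
    population's founders are built at the perturbed frequency
    (frequency-matched so the realized pool tracks the draw) and mosaics are
    sampled as in :func:`simulate_panel`. Returns (hmA, hmB, truth_freqs).
    """
    if not 0 < F < 1:
        raise ValueError("F must be in (0, 1)")
    rng = np.random.default_rng(cfg.seed)
    chrom_map = draw_map(cfg, rng)
    if freqs is not None:
        chrom_map = [(c, pos, np.asarray(f, dtype=float))
                     for (c, pos, _), f in zip(chrom_map, freqs)]
    panels = []
    for label in pop_labels:
        per_chrom = []
        for chrom, pos, p in chrom_map:
            p_prime = balding_nichols(p, F, rng)
            per_chrom.append((chrom, pos, _matched_founders(p_prime, cfg.n_founders, rng)))
        samples = _sample_names(n_per_pop, label)
        pops = {s: label for s in samples}
        panels.append(_panel_from_founders(per_chrom, 2 * n_per_pop,
                                           cfg.switch_rate, rng, samples, pops))
    return panels[0], panels[1], [f for _, _, f in chrom_map]


def plant_sweep(hm: HaplotypeMatrix, chrom: str, focal_pos: int, f_s: float,
                mean_flank: float, seed: int) -> tuple[HaplotypeMatrix, SweepTruth]:
    """Overwrite a fraction f_s of haplotypes with one core haplotype's
    alleles around the focal SNP, with Exponential(mean_flank) eroded edges.

    The core's focal allele is set to 1 before copying, so every affected
    haplotype carries the focal allele. Returns a new matrix and the truth
    record; the input is not modified.
    """
    if not 0 < f_s <= 1:
        raise ValueError("f_s must be in (0, 1]")
    rng = np.random.default_rng(seed)
    vidx = hm.chrom_slice(str(chrom))
    pos = hm.variants["pos"].to_numpy()[vidx]
    hit = np.where(pos == focal_pos)[0]
    if hit.size != 1:
        raise ValueError(f"focal_pos {focal_pos} is not a SNP on chromosome {chrom}")
    focal = int(vidx[hit[0]])
    n_hap = hm.n_haplotypes
    n_aff = math.ceil(f_s * n_hap)
    if n_aff < 2:
        raise ValueError("f_s * n_haplotypes < 2: sweep undetectable")
    affected = rng.choice(n_hap, size=n_aff, replace=False)
    core = int(affected[0])

    haps = hm.haps.copy()
    haps[core, focal] = 1
    core_alleles = haps[core, vidx].copy()
    for h in affected:
        if h == core:
            continue
        left = rng.exponential(mean_flank) if mean_flank > 0 else 0.0
        right = rng.exponential(mean_flank) if mean_flank > 0 else 0.0
        span = (pos >= focal_pos - left) & (pos <= focal_pos + right)
        haps[h, vidx[span]] = core_alleles[span]
    out = HaplotypeMatrix(list(hm.samples), dict(hm.populations),
                          hm.variants.copy(), haps)
    truth = SweepTruth(str(chrom), int(focal_pos), f_s, float(mean_flank),
                       sorted(int(h) for h in affected))
    return out, truth


# ---------------------------------------------------------------------------
# text artifacts


def write_popmap(hm: HaplotypeMatrix, path):
    with open(path, "w") as fh:
        for s in hm.samples:
            fh.write(f"{s}\t{hm.populations[s]}\n")


def write_chrom_lengths(cfg: SimConfig, path):
    with open(path, "w") as fh:
        for c, l in cfg.chrom_lengths().items():
            fh.write(f"{c}\t{l}\n")


def write_truth_bed(truths: list[SweepTruth], path):
    """Sweep truth intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for t in truths:
            s, e = t.interval()
            fh.write(f"{t.chrom}\t{s - 1}\t{e}\tsweep_f{t.sweep_freq:g}\n")


def combine_panels(*panels: HaplotypeMatrix) -> HaplotypeMatrix:
    """Stack panels sharing one marker map into a single multi-breed panel."""
    first = panels[0]
    for p in panels[1:]:
        if not first.variants[["chrom", "pos"]].equals(p.variants[["chrom", "pos"]]):
            raise ValueError("panels are not on identical marker maps")
    samples, pops = [], {}
    for p in panels:
        samples.extend(p.samples)
        pops.update(p.populations)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample names across panels")
    return HaplotypeMatrix(samples, pops, first.variants.copy(),
                           np.concatenate([p.haps for p in panels], axis=0))
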