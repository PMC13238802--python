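"""Sliding-window runs of homozygosity, length classes, F_ROH and ROH islands.

The per-SNP scoring follows detectRUNS' sliding-window semantics: a
15-SNP window is "homozygous" when it holds at most one heterozygous and one
missing call; each SNP's score is the fraction of windows covering it that
are homozygous (edge SNPs use their smaller denominator), and a SNP is
in-run when its score strictly exceeds the SNP-state threshold (0.05).
Maximal in-run stretches become ROH when they hold >= 3 SNPs, span >= 1 Mb
(first to last SNP, inclusive) and carry >= 1 SNP per 100 kb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import log, order_chroms
from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class ROHParams:
    window_snps: int = 15
    snp_state_threshold: float = 0.05
    min_snp: int = 3
    max_opp_window: int = 1
    max_miss_window: int = 1
    min_length_bp: int = 1_000_000
    min_density: float = 1 / 100_000  # SNPs per bp

    def __post_init__(self):
        if not 0 < self.snp_state_threshold < 1:
            raise ValueError("snp_state_threshold must be in (0, 1)")
        for name in ("window_snps", "min_snp", "min_length_bp", "min_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class ROHIsland:
    breed: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_incidence: float


LENGTH_CLASSES_MB = ((1, 6), (6, 12), (12, 24), (24, 48), (48, float("inf")))
CLASS_LABELS = ["1-6", "6-12", "12-24", "24-48", ">48"]


def snp_run_scores(calls: np.ndarray, params: ROHParams | None = None) -> np.ndarray:
    """Per-SNP homozygous-window score in [0, 1] for one sample/chromosome.

    A chromosome shorter than the window is scored over the single truncated
    window (warning logged).
    """
    params = params or ROHParams()
    calls = np.asarray(calls)
    m = calls.size
    w = params.window_snps
    if m < w:
        log.warning("chromosome has %d SNPs < window of %d; using one "
                    "truncated window", m, w)
        w = m
    het = (calls == 1).astype(np.int64)
    miss = (calls == MISSING).astype(np.int64)
    het_c = np.concatenate([[0], np.cumsum(het)])
    miss_c = np.concatenate([[0], np.cumsum(miss)])
    n_win = m - w + 1
    starts = np.arange(n_win)
    win_ok = ((het_c[starts + w] - het_c[starts]) <= params.max_opp_window) & \
             ((miss_c[starts + w] - miss_c[starts]) <= params.max_miss_window)
    ok_c = np.concatenate([[0], np.cumsum(win_ok)])
    j = np.arange(m)
    first = np.maximum(0, j - w + 1)
    last = np.minimum(j, n_win - 1)
    covered = last - first + 1
    hom_covering = ok_c[last + 1] - ok_c[first]
    return hom_covering / covered


def _runs_of_true(mask: np.ndarray):
    """Yield (start_idx, end_idx) inclusive for maximal True stretches."""
    idx = np.where(mask)[0]
    if idx.size == 0:
        return
    brk = np.where(np.diff(idx) > 1)[0] + 1
    for block in np.split(idx, brk):
        yield int(block[0]), int(block[-1])


def call_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH for every sample and chromosome of a panel."""
    params = params or ROHParams()
    segments = []
    for chrom in order_chroms(gm.variants["chrom"]):
        vidx = gm.variants.index[gm.variants["chrom"] == chrom].to_numpy()
        pos = gm.variants["pos"].to_numpy()[vidx]
        for i, sample in enumerate(gm.samples):
            scores = snp_run_scores(gm.calls[i, vidx], params)
            in_run = scores > params.snp_state_threshold
            for a, b in _runs_of_true(in_run):
                n = b - a + 1
                start, end = int(pos[a]), int(pos[b])
                length = end - start + 1
                if (n >= params.min_snp and length >= params.min_length_bp
                        and n / length >= params.min_density):
                    segments.append(ROHSegment(sample, str(chrom), start, end, n))
    return segments


def bin_roh(segments: list[ROHSegment], populations: dict[str, str]) -> pd.DataFrame:
    """Count ROH per breed and length class; percentages of the breed total.

    Classes are left-closed right-open in Mb: [1,6), [6,12), [12,24), [24,48),
    [48, inf). Percentages are rounded to 2 decimals.
    """
    rows = []
    for seg in segments:
        mb = seg.length_bp / 1e6
        for label, (lo, hi) in zip(CLASS_LABELS, LENGTH_CLASSES_MB):
            if lo <= mb < hi:
                rows.append((populations[seg.sample], label))
                break
    df = pd.DataFrame(rows, columns=["breed", "class"])
    out = []
    for breed, grp in df.groupby("breed", sort=True):
        total = len(grp)
        for label in CLASS_LABELS:
            n = int((grp["class"] == label).sum())
            out.append((breed, label, n, round(100 * n / total, 2)))
    return pd.DataFrame(out, columns=["breed", "class", "n", "pct"])


def f_roh(segments: list[ROHSegment], genome_length: int,
          samples: list[str], populations: dict[str, str],
          chrom_lengths: dict[str, int] | None = None):
    """Per-sample F_ROH = total ROH length / genome length, plus breed means.

    Samples with no ROH get F_ROH = 0. Returns (per-sample Series,
    per-breed Series).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if chrom_lengths:
        for seg in segments:
            limit = chrom_lengths.get(seg.chrom)
            if limit is not None and seg.end_bp > limit:
                raise ValueError(
                    f"segment {seg.sample} {seg.chrom}:{seg.start_bp}-{seg.end_bp} "
                    f"exceeds chromosome length {limit}")
    total = {s: 0 for s in samples}
    for seg in segments:
        total[seg.sample] += seg.length_bp
    per_sample = pd.Series({s: total[s] / genome_length for s in samples},
                           name="f_roh")
    breed = pd.Series({s: populations[s] for s in samples})
    per_breed = per_sample.groupby(breed).mean()
    return per_sample, per_breed


def roh_islands(segments: list[ROHSegment], gm: GenotypeMatrix,
                incidence_threshold: float = 0.60) -> list[ROHIsland]:
    """Per-breed ROH islands: maximal runs of consecutive map SNPs whose ROH
    incidence across the breed's individuals strictly exceeds the threshold."""
    by_breed_sample: dict[str, list[str]] = {}
    for s in gm.samples:
        by_breed_sample.setdefault(gm.populations[s], []).append(s)
    segs_by_sample: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        segs_by_sample.setdefault(seg.sample, []).append(seg)

    islands = []
    for breed, members in by_breed_sample.items():
        if len(members) < 2:
            warnings.warn(f"breed {breed!r} has <2 samples; no island call")
            continue
        for chrom in order_chroms(gm.variants["chrom"]):
            vidx = gm.variants.index[gm.variants["chrom"] == chrom].to_numpy()
            pos = gm.variants["pos"].to_numpy()[vidx]
            cover = np.zeros(pos.size, dtype=np.int64)
            for s in members:
                for seg in segs_by_sample.get(s, []):
                    if seg.chrom != str(chrom):
                        continue
                    cover[(pos >= seg.start_bp) & (pos <= seg.end_bp)] += 1
            incidence = cover / len(members)
            for a, b in _runs_of_true(incidence > incidence_threshold):
                islands.append(ROHIsland(
                    breed, str(chrom), int(pos[a]), int(pos[b]), b - a + 1,
                    float(incidence[a:b + 1].max())))
    return islands
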