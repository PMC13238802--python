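"""GFF3 gene overlap of consensus regions, pipeline orchestration, outputs.

Gene overlap is span intersection of the gene body with the region (1-based
inclusive, >= 1 bp shared); per-breed gene counts deduplicate genes that
fall in more than one of a breed's regions. ``run_pipeline`` chains
QC -> ROH -> iHS -> FST -> XP-EHH -> consensus -> annotation on a phased VCF
plus population map, writing plain-text TSV/BED artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import chrom_sort_key, log
from .consensus_regions import (CandidateInterval, ConsensusRegion,
                                build_consensus, consensus_table)
from .fst_scan import fst_windows, pairwise_components
from .genotype_io import (GenotypeMatrix, diversity_stats, qc_filter,
                          read_chrom_lengths, read_popmap, write_vcf)
from .haplotype_selection import (HaplotypeMatrix, ihs_scan, ihs_windows,
                                  read_haplotypes, xpehh_scan)
from .roh_scan import ROHParams, bin_roh, call_roh, f_roh, roh_islands


@dataclass
class GeneRecord:
    gene_id: str
    name: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str


def read_gff3(path, feature_type: str = "gene") -> list[GeneRecord]:
    """Parse gene features from a GFF3 file.

    Each candidate line is parsed with gffutils' feature parser; malformed
    lines are skipped with a warning. Raises if no gene feature parses.
    """
    import gffutils

    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8 or parts[2] != feature_type:
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
                gid = feat.attributes.get("ID", [f"{feature_type}_{ln}"])[0]
                name = feat.attributes.get("Name", [gid])[0]
                if gid.startswith(f"{feature_type}:"):
                    gid = gid.split(":", 1)[1]
                genes.append(GeneRecord(gid, name, str(feat.seqid),
                                        int(feat.start), int(feat.end),
                                        feat.strand or "."))
            except Exception as exc:  # malformed attribute column etc.
                log.warning("gff3 line %d skipped: %s", ln, exc)
    if not genes:
        raise ValueError(f"no {feature_type!r} features parsed from {path}")
    return genes


def genes_in_regions(regions: list[ConsensusRegion], genes: list[GeneRecord],
                     chrom_map: dict[str, str] | None = None,
                     flank: int = 0):
    """Genes whose span intersects each region by >= 1 bp.

    ``chrom_map`` renames GFF chromosomes onto the panel's naming. Returns
    (per-region list of GeneRecord lists, per-breed deduplicated gene counts).
    """
    def norm(c: str) -> str:
        return chrom_map.get(c, c) if chrom_map else c

    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(norm(g.chrom), []).append(g)
    per_region = []
    any_hit_chrom = False
    for r in regions:
        if r.chrom in by_chrom:
            any_hit_chrom = True
        hits = [g for g in by_chrom.get(r.chrom, [])
                if g.start_bp <= r.end_bp + flank and g.end_bp >= r.start_bp - flank]
        per_region.append(sorted(hits, key=lambda g: g.start_bp))
    if regions and genes and not any_hit_chrom:
        raise ValueError(
            "no region chromosome matches any GFF chromosome; pass a "
            "chromosome-name normalization map")
    per_breed: dict[str, set[str]] = {}
    for r, hits in zip(regions, per_region):
        if r.assigned_breed:
            per_breed.setdefault(r.assigned_breed, set()).update(
                g.gene_id for g in hits)
    counts = {b: len(s) for b, s in per_breed.items()}
    return per_region, counts


# ---------------------------------------------------------------------------
# pipeline


_DEFAULTS = {
    "geno": 0.05, "mind": 0.05, "maf": 0.05,
    "roh_window_snps": 15, "roh_threshold": 0.05, "roh_min_snp": 3,
    "roh_max_opp": 1, "roh_max_miss": 1, "roh_min_length": 1_000_000,
    "roh_min_density": 1 / 100_000, "island_incidence": 0.60,
    "ihs_maf": 0.05, "ihs_bins": 20,
    "window": 500_000, "step": 250_000,
    "ihs_min_snps": 5, "fst_min_snps": 3,
    "top_q": 0.01, "xpehh_merge_gap": 250_000, "max_gap": 250_000,
    "gene_feature": "gene",
}
_PATH_KEYS = ("vcf", "popmap", "chrlen", "gff", "outdir")


@dataclass
class PipelineConfig:
    vcf: str
    popmap: str
    chrlen: str
    outdir: str
    gff: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(_DEFAULTS)
        for k, v in self.params.items():
            if k not in _DEFAULTS:
                raise ValueError(f"unknown config key {k!r}")
            want = type(_DEFAULTS[k])
            if want is float and isinstance(v, int):
                v = float(v)
            if not isinstance(v, want):
                raise ValueError(
                    f"config key {k!r} must be {want.__name__}, got {type(v).__name__}")
            merged[k] = v
        self.params = merged

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        paths = {k: raw.pop(k) for k in list(raw) if k in _PATH_KEYS}
        for key in ("vcf", "popmap", "chrlen", "outdir"):
            if key not in paths:
                raise ValueError(f"config is missing required key {key!r}")
        return cls(paths["vcf"], paths["popmap"], paths["chrlen"],
                   paths["outdir"], paths.get("gff"), params=raw)


def _bed(df_rows, path):
    with open(path, "w") as fh:
        for chrom, start, end, name in df_rows:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full scan on a phased VCF; write artifacts under outdir.

    Returns a dict of in-memory results (qc report, diversity table, ROH
    segments, candidate intervals, consensus regions, gene lists). Reruns
    with identical inputs produce identical outputs.
    """
    p = config.params
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    populations = read_popmap(config.popmap)
    chrlens = read_chrom_lengths(config.chrlen)
    genome_length = sum(chrlens.values())

    log.info("stage qc: reading %s", config.vcf)
    hm_all = read_haplotypes(config.vcf, populations)
    gm = hm_all.to_genotype_matrix()
    gm_qc, report = qc_filter(gm, geno=p["geno"], mind=p["mind"], maf=p["maf"])
    kept_sites = set(zip(gm_qc.variants["chrom"], gm_qc.variants["pos"]))
    keep_v = [i for i, (c, q) in
              enumerate(zip(hm_all.variants["chrom"], hm_all.variants["pos"]))
              if (c, q) in kept_sites]
    keep_s = [i for i, s in enumerate(hm_all.samples) if s in set(gm_qc.samples)]
    rows = np.array([[2 * i, 2 * i + 1] for i in keep_s]).ravel()
    samples = [hm_all.samples[i] for i in keep_s]
    hm = HaplotypeMatrix(samples, {s: populations[s] for s in samples},
                         hm_all.variants.iloc[keep_v].reset_index(drop=True),
                         hm_all.haps[np.ix_(rows, np.array(keep_v))])
    gm_qc = hm.to_genotype_matrix()
    log.info("stage qc: %d samples x %d SNPs remain (rate %.4f)",
             report.remaining_samples, report.remaining_variants,
             report.genotyping_rate)
    write_vcf(gm_qc, out / "qc.vcf", chrlens)
    div = pd.DataFrame([vars(d) for d in diversity_stats(gm_qc)])
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    breeds = gm_qc.breeds()

    log.info("stage roh")
    roh_params = ROHParams(
        window_snps=p["roh_window_snps"], snp_state_threshold=p["roh_threshold"],
        min_snp=p["roh_min_snp"], max_opp_window=p["roh_max_opp"],
        max_miss_window=p["roh_max_miss"], min_length_bp=p["roh_min_length"],
        min_density=p["roh_min_density"])
    segments = call_roh(gm_qc, roh_params)
    pd.DataFrame([{**vars(s), "length_bp": s.length_bp} for s in segments]).to_csv(
        out / "roh_segments.tsv", sep="\t", index=False)
    if segments:
        bin_roh(segments, populations).to_csv(out / "roh_classes.tsv", sep="\t",
                                              index=False)
    per_sample, per_breed = f_roh(segments, genome_length, gm_qc.samples,
                                  populations, chrlens)
    pd.DataFrame({"sample": per_sample.index, "f_roh": per_sample.values}).to_csv(
        out / "f_roh.tsv", sep="\t", index=False)
    islands = roh_islands(segments, gm_qc, p["island_incidence"])
    candidates: list[CandidateInterval] = [
        CandidateInterval(i.chrom, i.start_bp, i.end_bp, "ROH", (i.breed,))
        for i in islands]
    _bed([(i.chrom, i.start_bp, i.end_bp, f"ROH:{i.breed}") for i in islands],
         out / "roh_islands.bed")
    log.info("stage roh: %d segments, %d islands", len(segments), len(islands))

    log.info("stage ihs")
    ihs_tables = []
    for breed in breeds:
        sub = hm.subset_population(breed)
        try:
            scores = ihs_scan(sub, maf_min=p["ihs_maf"], n_bins=p["ihs_bins"])
            wins, ivs = ihs_windows(scores, breed, chrlens, p["window"],
                                    p["step"], p["ihs_min_snps"], p["top_q"])
        except ValueError as exc:
            raise RuntimeError(f"stage ihs failed for breed {breed}: {exc}") from exc
        scores.insert(0, "breed", breed)
        ihs_tables.append(scores)
        candidates.extend(ivs)
    pd.concat(ihs_tables, ignore_index=True).to_csv(out / "ihs_scores.tsv",
                                                    sep="\t", index=False)

    log.info("stage fst")
    fst_tables = []
    for a, b in combinations(breeds, 2):
        comp = pairwise_components(gm_qc, a, b)
        wins, ivs = fst_windows(comp, (a, b), chrlens, p["window"], p["step"],
                                p["fst_min_snps"], p["top_q"])
        wins.insert(0, "pair", f"{a}-{b}")
        fst_tables.append(wins)
        candidates.extend(ivs)
    pd.concat(fst_tables, ignore_index=True).to_csv(out / "fst_windows.tsv",
                                                    sep="\t", index=False)

    log.info("stage xpehh")
    xp_tables = []
    for a, b in combinations(breeds, 2):
        scores, ivs = xpehh_scan(hm.subset_population(a), hm.subset_population(b),
                                 a, b, p["top_q"], p["xpehh_merge_gap"])
        scores.insert(0, "pair", f"{a}-{b}")
        xp_tables.append(scores)
        candidates.extend(ivs)
    pd.concat(xp_tables, ignore_index=True).to_csv(out / "xpehh_scores.tsv",
                                                   sep="\t", index=False)

    log.info("stage consensus: %d candidate intervals", len(candidates))
    regions = build_consensus(candidates, p["max_gap"])
    table = consensus_table(regions)
    table.to_csv(out / "consensus.tsv", sep="\t", index=False)
    _bed([(r.chrom, r.start_bp, r.end_bp, f"{r.tier}:{r.assigned_breed or '.'}")
          for r in regions], out / "consensus.bed")

    gene_lists, gene_counts = None, None
    if config.gff:
        log.info("stage annotate")
        genes = read_gff3(config.gff, p["gene_feature"])
        gene_lists, gene_counts = genes_in_regions(regions, genes)
        rows = []
        for r, hits in zip(regions, gene_lists):
            for g in hits:
                rows.append({"chrom": r.chrom, "start": r.start_bp,
                             "end": r.end_bp, "tier": r.tier,
                             "breed": r.assigned_breed or ".",
                             "gene_id": g.gene_id, "gene_name": g.name})
        pd.DataFrame(rows, columns=["chrom", "start", "end", "tier", "breed",
                                    "gene_id", "gene_name"]).to_csv(
            out / "region_genes.tsv", sep="\t", index=False)

    return {
        "qc_report": report, "diversity": div, "segments": segments,
        "islands": islands, "f_roh": per_breed, "candidates": candidates,
        "regions": regions, "consensus": table,
        "gene_lists": gene_lists, "gene_counts": gene_counts,
    }


def plot_genome_scan(df: pd.DataFrame, value_col: str, ax=None, **scatter_kw):
    """Minimal per-chromosome scatter of a genome-wide statistic."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 2.5))
    offset = 0
    for i, chrom in enumerate(sorted(df["chrom"].unique(), key=chrom_sort_key)):
        grp = df[df["chrom"] == chrom]
        ax.scatter(grp["pos"] + offset, grp[value_col], s=4,
                   color=f"C{i % 2}", **scatter_kw)
        offset += int(grp["pos"].max())
    ax.set_xlabel("genome position (bp, concatenated)")
    ax.set_ylabel(value_col)
    return ax
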