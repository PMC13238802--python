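"""Multi-evidence consensus: merge candidate intervals and tier regions.

Candidate intervals from the four scans (ROH islands, iHS, pairwise FST,
XP-EHH) are unioned per chromosome whenever separated by at most a maximum
gap (250 kb by default), regardless of method or breed. Each merged region is
then classified:

* evidence attribution — ROH and iHS intervals support their own breed;
  XP-EHH supports its favored breed; an FST interval (pair-level) supports a
  member breed only when that breed also carries within-population (ROH/iHS)
  or XP-EHH evidence in the same region;
* ``primary`` — one breed supported by >= 3 distinct methods including at
  least one within-population (ROH/iHS) and one between-population
  (FST/XP-EHH) method;
* ``secondary`` — one breed supported by exactly one within- plus one
  between-population method;
* ``unassigned`` — no breed qualifies, or two breeds qualify with no unique
  best (strictly more methods) among them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import chrom_sort_key, log

METHODS = ("ROH", "iHS", "FST", "XPEHH")
WITHIN = frozenset({"ROH", "iHS"})
BETWEEN = frozenset({"FST", "XPEHH"})


@dataclass(frozen=True)
class CandidateInterval:
    """One scan's candidate span. ``breeds`` holds one breed for ROH/iHS, the
    favored breed for XPEHH, and the unordered pair for FST."""

    chrom: str
    start_bp: int
    end_bp: int
    method: str
    breeds: tuple[str, ...]

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(f"interval start {self.start_bp} > end {self.end_bp}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        want = 2 if self.method == "FST" else 1
        if len(self.breeds) != want:
            raise ValueError(f"{self.method} interval needs {want} breed label(s)")


@dataclass
class ConsensusRegion:
    chrom: str
    start_bp: int
    end_bp: int
    evidence: list[tuple[str, tuple[str, ...]]]  # (method, breeds) contributors
    assigned_breed: str | None = None
    tier: str = "unassigned"
    methods: tuple[str, ...] = ()


def merge_intervals(intervals: list[CandidateInterval],
                    max_gap: int = 250_000) -> list[ConsensusRegion]:
    """Transitively union intervals per chromosome when the gap between
    successive spans (next.start - current.end - 1) is <= max_gap."""
    regions: list[ConsensusRegion] = []
    by_chrom: dict[str, list[CandidateInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start_bp, x.end_bp))
        cur = [ivs[0]]
        cur_end = ivs[0].end_bp
        for iv in ivs[1:]:
            if iv.start_bp - cur_end - 1 <= max_gap:
                cur.append(iv)
                cur_end = max(cur_end, iv.end_bp)
            else:
                regions.append(_skeleton(chrom, cur))
                cur, cur_end = [iv], iv.end_bp
        regions.append(_skeleton(chrom, cur))
    return regions


def _skeleton(chrom: str, members: list[CandidateInterval]) -> ConsensusRegion:
    return ConsensusRegion(
        chrom=chrom,
        start_bp=min(m.start_bp for m in members),
        end_bp=max(m.end_bp for m in members),
        evidence=[(m.method, m.breeds) for m in members],
    )


def _attributed_methods(evidence) -> dict[str, set[str]]:
    """Breed -> set of supporting methods after the FST attribution rule."""
    direct: dict[str, set[str]] = {}
    fst_pairs: list[tuple[str, ...]] = []
    for method, breeds in evidence:
        if method == "FST":
            fst_pairs.append(breeds)
        else:
            direct.setdefault(breeds[0], set()).add(method)
    support = {b: set(m) for b, m in direct.items()}
    for pair in fst_pairs:
        for b in pair:
            # FST is pair-level: it backs a breed only if that breed already
            # has its own within-population or XP-EHH signal here
            if b in direct and direct[b]:
                support.setdefault(b, set()).add("FST")
    return support


def classify_region(region: ConsensusRegion) -> ConsensusRegion:
    """Assign tier and breed to a merged region (see module docstring)."""
    if not region.evidence:
        raise ValueError("cannot classify a region with no evidence")
    support = _attributed_methods(region.evidence)
    qualifying: dict[str, tuple[int, int]] = {}  # breed -> (tier_rank, n_methods)
    for breed, methods in support.items():
        w = methods & WITHIN
        b = methods & BETWEEN
        if len(methods) >= 3 and w and b:
            qualifying[breed] = (2, len(methods))
        elif len(methods) == 2 and len(w) == 1 and len(b) == 1:
            qualifying[breed] = (1, len(methods))
        elif len(methods) >= 3:
            log.info("region %s:%d-%d: breed %s has %d methods but no "
                     "within/between mix; not tiered", region.chrom,
                     region.start_bp, region.end_bp, breed, len(methods))
    region.assigned_breed = None
    region.tier = "unassigned"
    region.methods = ()
    if qualifying:
        counts = sorted((n for _, n in qualifying.values()), reverse=True)
        best = [b for b, (_, n) in qualifying.items() if n == counts[0]]
        if len(best) == 1 and (len(counts) == 1 or counts[0] > counts[1]):
            breed = best[0]
            region.assigned_breed = breed
            region.tier = "primary" if qualifying[breed][0] == 2 else "secondary"
            region.methods = tuple(m for m in METHODS if m in support[breed])
    return region


def build_consensus(intervals: list[CandidateInterval],
                    max_gap: int = 250_000) -> list[ConsensusRegion]:
    """merge_intervals followed by classify_region on every merged region."""
    return [classify_region(r) for r in merge_intervals(intervals, max_gap)]


def consensus_table(regions: list[ConsensusRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append({
            "chrom": r.chrom, "start": r.start_bp, "end": r.end_bp,
            "tier": r.tier, "breed": r.assigned_breed or ".",
            "methods": "+".join(r.methods) if r.methods else ".",
            "evidence": ";".join(f"{m}:{','.join(b)}" for m, b in r.evidence),
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tier", "breed",
                                       "methods", "evidence"])
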