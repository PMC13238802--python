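"""Shared small helpers: chromosome ordering, window tiling, quantiles, intervals."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger("sweepsignal")


def chrom_sort_key(chrom: str):
    """Order chromosomes numerically where possible ('2' < '10'), else lexically."""
    s = str(chrom)
    body = s[3:] if s.lower().startswith("chr") else s
    try:
        return (0, int(body), "")
    except ValueError:
        return (1, 0, s)


def order_chroms(chroms) -> list:
    return sorted(set(chroms), key=chrom_sort_key)


def quantile_upper(values: np.ndarray, q: float) -> float:
    """Empirical q-quantile taken at an actual data point from above (right-closed).

    Used for top-fraction outlier thresholds: candidates are values >= this,
    so ties at the threshold are all included.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a quantile of an empty set")
    return float(np.quantile(values, q, method="higher"))


def tile_windows(chrom_span: int, window: int, step: int) -> np.ndarray:
    """Window start coordinates (0-based) tiling [0, chrom_span).

    Returns starts 0, step, 2*step, ... while start < chrom_span. A window
    covers 1-based positions [start+1, start+window].
    """
    if chrom_span <= 0:
        return np.empty(0, dtype=np.int64)
    return np.arange(0, chrom_span, step, dtype=np.int64)


def assign_windows(pos: np.ndarray, starts: np.ndarray, window: int):
    """Yield (start, index-array of pos inside the window) for each window start."""
    pos = np.asarray(pos)
    lo = np.searchsorted(pos, starts + 1, side="left")
    hi = np.searchsorted(pos, starts + window, side="right")
    for s, a, b in zip(starts, lo, hi):
        yield int(s), np.arange(a, b)


def merge_touching(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive spans that overlap or are book-ended (gap 0)."""
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]
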