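"""High-occupancy-target (HOT) site analysis of a focal peak set.

For each focal peak, count the distinct *other* transcription factors in a
compendium with at least one peak intersecting the window
``[centroid - window_bp, centroid + window_bp]``; peaks bound by at least
``hot_threshold`` (default 15) distinct other TFs are flagged HOT.  A TF
counts once per focal peak no matter how many of its peaks fall in the
window, and the focal factor itself is excluded from counting.

Counting is by interval intersection with the window by default ("the TF
binds the site's region"); requiring the TF peak *center* to fall inside
the window is available via ``mode="center_in_window"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_tables import PeakSet, TfCompendium

__all__ = ["CoOccupancyRecord", "tf_cooccupancy", "hot_fraction"]

MODES = ("intersects", "center_in_window")


@dataclass
class CoOccupancyRecord:
    peak_index: int
    chrom: str
    centroid: int
    tf_count: int
    is_hot: bool


class _ChromIndex:
    """Sorted starts with prefix-max ends: O(log n) interval stabbing."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        order = np.argsort(starts, kind="stable")
        self.starts = starts[order]
        self.prefix_max_end = np.maximum.accumulate(ends[order])

    def any_intersecting(self, lo: int, hi: int) -> bool:
        # exists a peak with start <= hi and end >= lo
        k = int(np.searchsorted(self.starts, hi, side="right"))
        return k > 0 and int(self.prefix_max_end[k - 1]) >= lo


def tf_cooccupancy(
    focal: PeakSet,
    compendium: TfCompendium,
    window_bp: int = 400,
    hot_threshold: int = 15,
    mode: str = "intersects",
) -> list[CoOccupancyRecord]:
    """Per-focal-peak count of distinct other TFs bound within the window."""
    if len(compendium) == 0:
        raise ValueError("empty TF compendium")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")

    indexes: dict[str, dict[str, _ChromIndex]] = {}
    for label in compendium.labels():
        if label == focal.factor:
            continue
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for p in compendium[label]:
            s, e = (p.start, p.end) if mode == "intersects" else (p.centroid, p.centroid)
            by_chrom.setdefault(p.chrom, ([], []))[0].append(s)
            by_chrom[p.chrom][1].append(e)
        indexes[label] = {
            c: _ChromIndex(np.asarray(ss, dtype=np.int64), np.asarray(ee, dtype=np.int64))
            for c, (ss, ee) in by_chrom.items()
        }

    records: list[CoOccupancyRecord] = []
    for i, peak in enumerate(focal):
        center = peak.centroid
        lo, hi = center - window_bp, center + window_bp
        count = 0
        for label, by_chrom in indexes.items():
            idx = by_chrom.get(peak.chrom)
            if idx is not None and idx.any_intersecting(lo, hi):
                count += 1
        records.append(
            CoOccupancyRecord(
                peak_index=i,
                chrom=peak.chrom,
                centroid=center,
                tf_count=count,
                is_hot=count >= hot_threshold,
            )
        )
    return records


def hot_fraction(
    records: Sequence[CoOccupancyRecord],
    subset_ids: Sequence[int] | None = None,
) -> dict:
    """HOT fraction of a subset of focal peaks plus the tf_count CDF.

    ``subset_ids`` are focal peak indices; default is all peaks.  Returns
    the fraction of subset peaks flagged HOT and the empirical cumulative
    distribution of tf_count over the subset.
    """
    by_id = {r.peak_index: r for r in records}
    if subset_ids is None:
        subset = list(records)
    else:
        missing = [i for i in subset_ids if i not in by_id]
        if missing:
            raise ValueError(f"subset ids not among focal peaks: {missing[:5]}")
        subset = [by_id[i] for i in subset_ids]
    if not subset:
        raise ValueError("empty subset")
    counts = np.asarray(sorted(r.tf_count for r in subset))
    frac = sum(r.is_hot for r in subset) / len(subset)
    return {
        "fraction_hot": frac,
        "n": len(subset),
        "cdf_counts": counts,
        "cdf_probs": np.arange(1, len(counts) + 1) / len(counts),
    }
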