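"""Co-binding geometry of two ChIP-seq peak sets.

Each peak is reduced to its centroid (floored midpoint of the interval
borders).  The geometry of association between two factors is then measured
three ways: the distribution of nearest-neighbor inter-centroid distances,
the same distribution after re-randomizing centroid positions uniformly
along each chromosome (the independence null), and an explicit base-pair
overlap partition of the two interval sets.

Two intervals overlap iff they share at least one base (1-based inclusive:
``a.start <= b.end and b.start <= a.end`` on the same chromosome);
adjacency is not overlap.  The number of overlap *events* is the number of
connected components of the bipartite overlap graph, so a single wide peak
spanning two partners counts once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_tables import GenomicInterval, PeakSet

__all__ = [
    "WS245_CHROM_LENGTHS",
    "CentroidSet",
    "DistanceDistribution",
    "OverlapPartition",
    "compute_centroids",
    "nearest_neighbor_distances",
    "randomize_centroids",
    "overlap_partition",
    "peak_width_distribution",
]

#: Chromosome lengths (bp) of the C. elegans WS245 reference assembly,
#: used as the default per-chromosome range for centroid randomization.
WS245_CHROM_LENGTHS: dict[str, int] = {
    "I": 15_072_434,
    "II": 15_279_421,
    "III": 13_783_801,
    "IV": 17_493_829,
    "V": 20_924_180,
    "X": 17_718_942,
    "MtDNA": 13_794,
}

NN_DIRECTIONS = ("A_to_B", "B_to_A", "union")


@dataclass
class CentroidSet:
    """Per-chromosome ascending centroid positions for one factor."""

    factor: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def chromosomes(self) -> list[str]:
        return list(self.positions)


@dataclass
class DistanceDistribution:
    """Empirical nearest-neighbor distance distribution.

    ``midpoint`` is the 50% point of the empirical cumulative distribution,
    i.e. the median distance.  ``n_skipped`` counts query centroids on
    chromosomes absent from the reference set.
    """

    distances: np.ndarray
    midpoint: float
    n: int
    n_skipped: int = 0

    def cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted distances and their cumulative probabilities."""
        d = np.sort(self.distances)
        return d, np.arange(1, len(d) + 1) / len(d)


@dataclass
class OverlapPartition:
    """Result of partitioning two peak sets by base-pair overlap."""

    n_events: int
    a_overlapped: list[int]
    a_exclusive: list[int]
    b_overlapped: list[int]
    b_exclusive: list[int]
    pairs: list[tuple[int, int]]
    n_a: int
    n_b: int

    @property
    def frac_a_overlapped(self) -> float:
        return len(self.a_overlapped) / self.n_a if self.n_a else 0.0

    @property
    def frac_b_overlapped(self) -> float:
        return len(self.b_overlapped) / self.n_b if self.n_b else 0.0


def compute_centroids(peaks: PeakSet) -> CentroidSet:
    """Reduce each peak to its centroid, grouped per chromosome and sorted."""
    by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p.centroid)
    return CentroidSet(
        factor=peaks.factor,
        positions={c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()},
    )


def _nn_one_way(query: CentroidSet, reference: CentroidSet) -> tuple[list[int], int]:
    """Min |q - r| per query centroid against same-chromosome references.

    Ties between the two flanking reference centroids break toward the
    lower coordinate (both give the same distance; the distance is what is
    recorded).  Returns (distances, n_skipped).
    """
    distances: list[int] = []
    skipped = 0
    for chrom, qpos in query.positions.items():
        rpos = reference.positions.get(chrom)
        if rpos is None or len(rpos) == 0:
            skipped += len(qpos)
            continue
        idx = np.searchsorted(rpos, qpos)
        left = np.clip(idx - 1, 0, len(rpos) - 1)
        right = np.clip(idx, 0, len(rpos) - 1)
        d = np.minimum(np.abs(qpos - rpos[left]), np.abs(qpos - rpos[right]))
        distances.extend(d.tolist())
    return distances, skipped


def nearest_neighbor_distances(
    query: CentroidSet,
    reference: CentroidSet,
    direction: str = "A_to_B",
) -> DistanceDistribution:
    """Nearest-neighbor inter-centroid distances between two factors.

    ``direction`` chooses which set supplies the query points:
    ``"A_to_B"`` (query is ``query``), ``"B_to_A"`` (roles swapped), or
    ``"union"`` (both passes pooled).  The reported ``midpoint`` is the
    median of the pooled distances.
    """
    if direction not in NN_DIRECTIONS:
        raise ValueError(f"direction must be one of {NN_DIRECTIONS}, got {direction!r}")
    shared = set(query.positions) & set(reference.positions)
    if not shared:
        raise ValueError(
            f"no shared chromosomes between {query.factor!r} and {reference.factor!r}"
        )
    dists: list[int] = []
    skipped = 0
    if direction in ("A_to_B", "union"):
        d, s = _nn_one_way(query, reference)
        dists.extend(d)
        skipped += s
    if direction in ("B_to_A", "union"):
        d, s = _nn_one_way(reference, query)
        dists.extend(d)
        skipped += s
    arr = np.asarray(dists, dtype=np.int64)
    return DistanceDistribution(
        distances=arr,
        midpoint=float(np.median(arr)),
        n=len(arr),
        n_skipped=skipped,
    )


def randomize_centroids(
    cset: CentroidSet,
    ranges: dict[str, tuple[int, int]],
    seed: int,
) -> CentroidSet:
    """Reassign every centroid to a uniform position on its chromosome.

    ``ranges`` maps chromosome -> inclusive (low, high) bounds; every
    chromosome present in ``cset`` must have a range.  Deterministic for a
    given seed.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for chrom, pos in cset.positions.items():
        if chrom not in ranges:
            raise ValueError(f"no randomization range supplied for chromosome {chrom!r}")
        low, high = ranges[chrom]
        if high < low:
            raise ValueError(f"invalid range for {chrom!r}: ({low}, {high})")
        out[chrom] = np.sort(rng.integers(low, high + 1, size=len(pos), dtype=np.int64))
    return CentroidSet(factor=f"{cset.factor}:randomized", positions=out)


def genome_ranges(
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, tuple[int, int]]:
    """Full-chromosome randomization ranges, [1, length] per chromosome."""
    lengths = WS245_CHROM_LENGTHS if chrom_lengths is None else chrom_lengths
    return {c: (1, length) for c, length in lengths.items()}


def observed_ranges(*peaksets: PeakSet) -> dict[str, tuple[int, int]]:
    """Randomization ranges from the observed min/max peak coordinates."""
    bounds: dict[str, tuple[int, int]] = {}
    for ps in peaksets:
        for p in ps:
            lo, hi = bounds.get(p.chrom, (p.start, p.end))
            bounds[p.chrom] = (min(lo, p.start), max(hi, p.end))
    return bounds


def overlap_partition(a: PeakSet, b: PeakSet) -> OverlapPartition:
    """Partition two peak sets into overlapping and exclusive peaks.

    Pairs are enumerated by a per-chromosome sorted sweep; ``n_events`` is
    the number of connected components of the bipartite overlap graph.
    """
    pairs: list[tuple[int, int]] = []
    a_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    b_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, p in enumerate(a):
        a_by_chrom.setdefault(p.chrom, []).append((p.start, p.end, i))
    for j, p in enumerate(b):
        b_by_chrom.setdefault(p.chrom, []).append((p.start, p.end, j))

    for chrom, a_items in a_by_chrom.items():
        b_items = b_by_chrom.get(chrom)
        if not b_items:
            continue
        a_items = sorted(a_items)
        b_items = sorted(b_items)
        start_j = 0
        max_b_end_seen = -1
        # sweep: for each a interval, scan b intervals whose start <= a.end;
        # advance the lower cursor past b intervals that can never overlap
        # later a intervals (their end < current a.start and all later a
        # starts are >= current a.start because a_items is sorted).
        for a_start, a_end, ai in a_items:
            while start_j < len(b_items) and b_items[start_j][1] < a_start:
                start_j += 1
            k = start_j
            while k < len(b_items) and b_items[k][0] <= a_end:
                b_start, b_end, bj = b_items[k]
                if b_end >= a_start:  # starts already bounded by a_end
                    pairs.append((ai, bj))
                k += 1

    # connected components via union-find over the bipartite graph
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for ai, bj in pairs:
        for node in (("a", ai), ("b", bj)):
            parent.setdefault(node, node)
        ra, rb = find(("a", ai)), find(("b", bj))
        if ra != rb:
            parent[ra] = rb

    n_events = len({find(n) for n in parent})
    a_over = sorted({ai for ai, _ in pairs})
    b_over = sorted({bj for _, bj in pairs})
    return OverlapPartition(
        n_events=n_events,
        a_overlapped=a_over,
        a_exclusive=sorted(set(range(len(a))) - set(a_over)),
        b_overlapped=b_over,
        b_exclusive=sorted(set(range(len(b))) - set(b_over)),
        pairs=sorted(pairs),
        n_a=len(a),
        n_b=len(b),
    )


def peak_width_distribution(peaks: PeakSet, bin_bp: int = 50) -> dict:
    """Peak-width distribution summary (width = end - start + 1).

    Returns widths, mean, median and a histogram with ``bin_bp``-wide bins.
    """
    if len(peaks) == 0:
        raise ValueError("cannot summarize widths of an empty peak set")
    widths = np.asarray([p.width for p in peaks], dtype=np.int64)
    edges = np.arange(0, widths.max() + bin_bp + 1, bin_bp)
    counts, _ = np.histogram(widths, bins=edges)
    return {
        "widths": widths,
        "mean": float(widths.mean()),
        "median": float(np.median(widths)),
        "hist_edges": edges,
        "hist_counts": counts,
    }
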