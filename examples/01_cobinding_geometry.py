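"""Co-binding geometry of two transcription factors.

Simulates two peak sets in which 70% of factor-A peaks have a factor-B
partner, then measures the nearest-neighbor inter-centroid distance
distribution against a randomized null and partitions the peaks by
base-pair overlap.
"""

import numpy as np

from chipexpr import (
    SynthConfig,
    compute_centroids,
    nearest_neighbor_distances,
    overlap_partition,
    randomize_centroids,
)
from chipexpr.peak_geometry import genome_ranges
from chipexpr.synthetic_data import make_genome, make_peaks

cfg = SynthConfig(seed=1)
peaks_a, peaks_b, _ = make_peaks(cfg, make_genome(cfg))

cen_a, cen_b = compute_centroids(peaks_a), compute_centroids(peaks_b)
observed = nearest_neighbor_distances(cen_a, cen_b)
ranges = genome_ranges(cfg.chrom_lengths)
null_midpoints = [
    nearest_neighbor_distances(
        randomize_centroids(cen_a, ranges, seed=s),
        randomize_centroids(cen_b, ranges, seed=s + 1),
    ).midpoint
    for s in range(20)
]
part = overlap_partition(peaks_a, peaks_b)

print(f"observed nearest-neighbor CDF midpoint: {observed.midpoint:.0f} bp")
print(f"randomized-null midpoint (20 seeds):    {np.mean(null_midpoints):.0f} bp")
print(f"A peaks overlapping a B peak: {part.frac_a_overlapped:.1%}")
print(f"B peaks overlapping an A peak: {part.frac_b_overlapped:.1%}")
print(f"distinct overlap events: {part.n_events}")
# A median inter-centroid distance far below the null indicates the two
# factors bind together far more often than independent placement allows.
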