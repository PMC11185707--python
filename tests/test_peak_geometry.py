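import numpy as np
import pytest
from scipy import stats

from chipexpr.io_tables import GenomicInterval, PeakSet
from chipexpr.peak_geometry import (
    CentroidSet,
    compute_centroids,
    genome_ranges,
    nearest_neighbor_distances,
    overlap_partition,
    peak_width_distribution,
    randomize_centroids,
)
from chipexpr.synthetic_data import SynthConfig, make_genome, make_peaks


def _cset(factor, **positions):
    return CentroidSet(
        factor, {c: np.asarray(sorted(v), dtype=np.int64) for c, v in positions.items()}
    )


class TestCentroids:
    @pytest.mark.parametrize(
        "start,end,expected", [(100, 500, 300), (7, 8, 7), (42, 42, 42)]
    )
    def test_floored_midpoint(self, start, end, expected):
        ps = PeakSet("F", [GenomicInterval("chrI", start, end)])
        assert compute_centroids(ps).positions["chrI"][0] == expected

    def test_counts_per_chromosome_match_source(self, small_bundle):
        cset = compute_centroids(small_bundle.peaks_a)
        per_chrom = {c: 0 for c in cset.positions}
        for p in small_bundle.peaks_a:
            per_chrom[p.chrom] += 1
        assert {c: len(v) for c, v in cset.positions.items()} == per_chrom


class TestNearestNeighbor:
    def test_hand_computed_example(self):
        a = _cset("A", chrI=[100, 1000])
        b = _cset("B", chrI=[120, 5000])
        dist = nearest_neighbor_distances(a, b, "A_to_B")
        assert sorted(dist.distances.tolist()) == [20, 880]
        assert dist.midpoint == 450

    def test_coincident_single_centroid(self):
        dist = nearest_neighbor_distances(_cset("A", chrI=[42]), _cset("B", chrI=[42]))
        assert dist.distances.tolist() == [0] and dist.midpoint == 0

    def test_no_shared_chromosomes_is_error(self):
        with pytest.raises(ValueError, match="shared"):
            nearest_neighbor_distances(_cset("A", chrI=[1]), _cset("B", chrX=[1]))

    def test_queries_on_missing_chromosomes_are_skipped_and_counted(self):
        a = _cset("A", chrI=[100], chrII=[5, 6])
        b = _cset("B", chrI=[150])
        dist = nearest_neighbor_distances(a, b, "A_to_B")
        assert dist.n == 1 and dist.n_skipped == 2

    def test_matches_exhaustive_matrix_minimum(self):
        """Searchsorted nearest-neighbor equals the brute-force matrix min."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            a_pos = {
                "c1": np.sort(rng.integers(1, 10_000, size=rng.integers(1, 50))),
                "c2": np.sort(rng.integers(1, 10_000, size=rng.integers(1, 50))),
            }
            b_pos = {
                "c1": np.sort(rng.integers(1, 10_000, size=rng.integers(1, 50))),
                "c2": np.sort(rng.integers(1, 10_000, size=rng.integers(1, 50))),
            }
            a = CentroidSet("A", a_pos)
            b = CentroidSet("B", b_pos)
            got = sorted(nearest_neighbor_distances(a, b, "A_to_B").distances.tolist())
            expected = sorted(
                int(np.min(np.abs(q - b_pos[c])))
                for c in a_pos
                for q in a_pos[c]
            )
            assert got == expected


class TestRandomization:
    def test_positions_within_range_and_counts_preserved(self):
        cset = _cset("A", chrI=list(range(100, 200)))
        out = randomize_centroids(cset, {"chrI": (1, 1000)}, seed=3)
        assert len(out.positions["chrI"]) == 100
        assert out.positions["chrI"].min() >= 1
        assert out.positions["chrI"].max() <= 1000

    def test_deterministic_given_seed(self):
        cset = _cset("A", chrI=list(range(50)))
        r1 = randomize_centroids(cset, {"chrI": (1, 10_000)}, seed=9)
        r2 = randomize_centroids(cset, {"chrI": (1, 10_000)}, seed=9)
        assert np.array_equal(r1.positions["chrI"], r2.positions["chrI"])

    def test_missing_range_is_error(self):
        with pytest.raises(ValueError, match="range"):
            randomize_centroids(_cset("A", chrI=[1]), {}, seed=0)

    def test_randomized_positions_are_uniform(self):
        """KS test against Uniform cannot reject at alpha=0.001, n=10,000."""
        cset = _cset("A", chrI=np.arange(10_000))
        out = randomize_centroids(cset, {"chrI": (1, 1_000_000)}, seed=5)
        p = stats.kstest(
            out.positions["chrI"], stats.uniform(loc=1, scale=1_000_000).cdf
        ).pvalue
        assert p > 0.001

    def test_null_midpoint_exceeds_observed_under_cobinding(self):
        """With planted co-binding the randomized null midpoint is larger."""
        cfg = SynthConfig(
            seed=21,
            chrom_lengths={"I": 3_000_000},
            n_peaks_a=300,
            n_peaks_b=300,
            cobind_fraction=0.5,
            n_genes=300,
            class_mix={},
        )
        tss = make_genome(cfg)
        a, b, _ = make_peaks(cfg, tss)
        ca, cb = compute_centroids(a), compute_centroids(b)
        observed = nearest_neighbor_distances(ca, cb).midpoint
        ranges = genome_ranges(cfg.chrom_lengths)
        nulls = [
            nearest_neighbor_distances(
                randomize_centroids(ca, ranges, seed=s),
                randomize_centroids(cb, ranges, seed=s + 1),
            ).midpoint
            for s in range(40, 80, 2)
        ]
        assert min(nulls) > observed


class TestOverlapPartition:
    def test_single_overlap_pair(self):
        a = PeakSet("A", [GenomicInterval("c", 100, 500)])
        b = PeakSet("B", [GenomicInterval("c", 450, 700)])
        part = overlap_partition(a, b)
        assert part.pairs == [(0, 0)]
        assert part.a_overlapped == [0] and part.b_overlapped == [0]
        assert part.n_events == 1

    def test_adjacency_is_not_overlap(self):
        a = PeakSet("A", [GenomicInterval("c", 100, 200)])
        b = PeakSet("B", [GenomicInterval("c", 201, 300)])
        part = overlap_partition(a, b)
        assert part.pairs == [] and part.n_events == 0

    def test_one_wide_peak_spanning_two_partners_is_one_event(self):
        a = PeakSet("A", [GenomicInterval("c", 100, 1000)])
        b = PeakSet("B", [GenomicInterval("c", 150, 250), GenomicInterval("c", 800, 900)])
        part = overlap_partition(a, b)
        assert len(part.pairs) == 2
        assert part.n_events == 1

    def test_symmetric_in_event_count(self, small_bundle):
        ab = overlap_partition(small_bundle.peaks_a, small_bundle.peaks_b)
        ba = overlap_partition(small_bundle.peaks_b, small_bundle.peaks_a)
        assert ab.n_events == ba.n_events
        assert len(ab.pairs) == len(ba.pairs)

    def test_partition_counts_are_consistent(self, small_bundle):
        part = overlap_partition(small_bundle.peaks_a, small_bundle.peaks_b)
        assert len(part.a_overlapped) + len(part.a_exclusive) == part.n_a
        assert len(part.b_overlapped) + len(part.b_exclusive) == part.n_b

    def test_sweep_equals_brute_force_enumeration(self):
        """Sorted sweep matches O(n*m) enumeration on random intervals."""
        rng = np.random.default_rng(13)
        for _ in range(5):
            def random_set(label, n):
                peaks = []
                for _ in range(n):
                    chrom = str(rng.choice(["c1", "c2"]))
                    s = int(rng.integers(1, 5000))
                    peaks.append(GenomicInterval(chrom, s, s + int(rng.integers(0, 400))))
                return PeakSet(label, peaks)

            a = random_set("A", int(rng.integers(50, 200)))
            b = random_set("B", int(rng.integers(50, 200)))
            brute = sorted(
                (i, j)
                for i, pa in enumerate(a)
                for j, pb in enumerate(b)
                if pa.intersects(pb)
            )
            assert overlap_partition(a, b).pairs == brute


class TestWidths:
    def test_width_is_inclusive_span(self):
        summary = peak_width_distribution(PeakSet("F", [GenomicInterval("c", 100, 499)]))
        assert summary["widths"].tolist() == [400]

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            peak_width_distribution(PeakSet("F", []))

    def test_generator_width_means_match_factor_settings(self, default_bundle):
        wa = peak_width_distribution(default_bundle.peaks_a)["mean"]
        wb = peak_width_distribution(default_bundle.peaks_b)["mean"]
        assert wa == pytest.approx(400, rel=0.05)
        assert wb == pytest.approx(250, rel=0.05)
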