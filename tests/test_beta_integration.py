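import math

import numpy as np
import pytest

from chipexpr.beta_integration import (
    RegulatoryPotential,
    assign_peaks_to_genes,
    call_direct_targets,
    decay_weight,
    ks_function_test,
    regulatory_potential,
)
from chipexpr.io_tables import DegRecord, GenomicInterval, PeakSet, TssRecord


def rec(gid, log2fc, p, fdr):
    return DegRecord(gid, gid, log2fc, p, fdr)


class TestAssignment:
    @pytest.mark.parametrize(
        "centroid,assigned", [(8000, True), (14000, False), (13000, True)]
    )
    def test_window_membership_with_closed_boundary(self, centroid, assigned):
        peaks = PeakSet("F", [GenomicInterval("c", centroid - 10, centroid + 10)])
        tss = [TssRecord("g1", "c", 10_000, "+")]
        asn = assign_peaks_to_genes(peaks, tss, window_bp=3000)
        assert bool(asn["g1"].peaks) is assigned
        if assigned:
            assert asn["g1"].peaks[0][1] == abs(centroid - 10_000)

    def test_one_peak_may_serve_multiple_genes(self):
        peaks = PeakSet("F", [GenomicInterval("c", 9990, 10_010)])
        tss = [TssRecord("g1", "c", 9000, "+"), TssRecord("g2", "c", 11_000, "-")]
        asn = assign_peaks_to_genes(peaks, tss, 3000)
        assert asn["g1"].peaks and asn["g2"].peaks

    def test_empty_tss_table_is_error(self):
        with pytest.raises(ValueError, match="TSS"):
            assign_peaks_to_genes(PeakSet("F", []), [], 3000)

    def test_most_upstream_tss_selected_per_strand(self):
        peaks = PeakSet("F", [GenomicInterval("c", 990, 1010)])
        tss = [TssRecord("g1", "c", 1000, "+"), TssRecord("g1", "c", 9000, "+")]
        asn = assign_peaks_to_genes(peaks, tss, 3000)
        assert asn["g1"].tss.tss == 1000


class TestRegulatoryPotential:
    def test_decay_weights_match_closed_forms(self):
        assert decay_weight(0) == pytest.approx(math.exp(-0.5), abs=1e-12)
        assert decay_weight(3000) == pytest.approx(math.exp(-4.5), abs=1e-12)
        assert decay_weight(1500) == pytest.approx(math.exp(-2.5), abs=1e-12)

    def test_score_is_additive_over_peaks(self):
        peaks = PeakSet(
            "F",
            [GenomicInterval("c", 9990, 10_010), GenomicInterval("c", 11_490, 11_510)],
        )
        tss = [TssRecord("g1", "c", 10_000, "+")]
        rp = regulatory_potential(assign_peaks_to_genes(peaks, tss, 3000), 3000)
        assert rp["g1"].score == pytest.approx(
            math.exp(-0.5) + math.exp(-2.5), abs=1e-12
        )

    def test_weight_strictly_decreasing_in_distance(self):
        d = np.linspace(0, 3000, 50)
        w = [decay_weight(x) for x in d]
        assert all(a > b for a, b in zip(w, w[1:]))


class TestCallDirectTargets:
    def _rp(self, scores):
        return {g: RegulatoryPotential(g, s) for g, s in scores.items()}

    def test_rank_product_example_with_lexicographic_tie_break(self):
        rp = self._rp({"ga": 3.0, "gb": 2.0, "gc": 1.0})
        degs = [
            rec("ga", -1, 0.002, 0.01),  # rank_rp 1, rank_de 2
            rec("gb", -1, 0.001, 0.01),  # rank_rp 2, rank_de 1
            rec("gc", -1, 0.003, 0.01),  # rank_rp 3, rank_de 3
        ]
        calls = call_direct_targets(rp, degs)
        assert [c.gene_id for c in calls] == ["ga", "gb", "gc"]
        assert calls[0].rank_product == pytest.approx(2 / 9)
        assert calls[1].rank_product == pytest.approx(2 / 9)
        assert calls[2].rank_product == pytest.approx(1.0)

    def test_deg_without_peak_in_window_is_excluded(self):
        rp = self._rp({"ga": 1.0, "gb": 0.0})
        degs = [rec("ga", -1, 0.01, 0.01), rec("gb", -1, 0.001, 0.001)]
        calls = call_direct_targets(rp, degs)
        assert [c.gene_id for c in calls] == ["ga"]

    def test_no_candidates_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert call_direct_targets({}, [rec("g", -1, 0.01, 0.01)]) == []

    def test_calls_are_contained_in_deg_and_assignment_sets(self, small_bundle):
        from chipexpr.beta_integration import assign_peaks_to_genes

        asn = assign_peaks_to_genes(small_bundle.peaks_a, small_bundle.tss, 3000)
        rp = regulatory_potential(asn, 3000)
        calls = call_direct_targets(rp, small_bundle.degs_a, 0.05)
        degs_ok = {r.gene_id for r in small_bundle.degs_a if r.fdr <= 0.05}
        for c in calls:
            assert c.gene_id in degs_ok
            assert asn[c.gene_id].peaks

    def test_ordering_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(5)
        scores = {f"g{i}": float(s) for i, s in enumerate(rng.uniform(0.1, 5, 40))}
        degs = [rec(g, -1, float(p), 0.01) for g, p in
                zip(scores, rng.uniform(0, 0.04, 40))]
        base = call_direct_targets(self._rp(scores), degs)
        squashed = {g: math.log1p(s) for g, s in scores.items()}
        trans = call_direct_targets(self._rp(squashed), degs)
        assert [c.gene_id for c in base] == [c.gene_id for c in trans]


class TestFunctionTest:
    def _null_background(self, rng, n):
        return {
            f"bg{i}": RegulatoryPotential(f"bg{i}", float(s))
            for i, s in enumerate(rng.lognormal(0, 1, n))
        }

    def test_all_targets_down_in_mutant_reads_as_activator(self):
        rng = np.random.default_rng(0)
        rp = self._null_background(rng, 400)
        degs = []
        for i, s in enumerate(rng.lognormal(1.5, 0.5, 60)):
            g = f"dn{i}"
            rp[g] = RegulatoryPotential(g, float(s))
            degs.append(rec(g, -2, 1e-6, 1e-4))
        for i in range(10):  # a few up-regulated genes with background scores
            g = f"up{i}"
            rp[g] = RegulatoryPotential(g, float(rng.lognormal(0, 1)))
            degs.append(rec(g, +2, 1e-6, 1e-4))
        assert ks_function_test(rp, degs).verdict == "activator"

    def test_elevated_scores_in_both_directions_reads_as_dual(self):
        rng = np.random.default_rng(1)
        rp = self._null_background(rng, 400)
        degs = []
        for i, s in enumerate(rng.lognormal(1.5, 0.5, 100)):
            sign = -1 if i % 2 else 1
            g = f"t{i}"
            rp[g] = RegulatoryPotential(g, float(s))
            degs.append(rec(g, sign * 2.0, 1e-6, 1e-4))
        assert ks_function_test(rp, degs).verdict == "dual"

    def test_scores_independent_of_de_status_reads_as_none(self):
        rng = np.random.default_rng(2)
        rp = self._null_background(rng, 400)
        degs = []
        for i in range(100):
            g = f"t{i}"
            rp[g] = RegulatoryPotential(g, float(rng.lognormal(0, 1)))
            degs.append(rec(g, 2.0 * (-1) ** i, 1e-6, 1e-4))
        assert ks_function_test(rp, degs).verdict == "none"

    def test_small_groups_warn_and_abstain(self):
        rp = {"g1": RegulatoryPotential("g1", 1.0)}
        with pytest.warns(UserWarning):
            result = ks_function_test(rp, [rec("g1", -1, 0.01, 0.01)])
        assert result.verdict == "none"
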