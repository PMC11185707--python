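import pandas as pd
import pytest

from chipexpr.beta_integration import PeakAssignment, TargetCall
from chipexpr.deg_loa import SharedDegResult
from chipexpr.io_tables import TssRecord
from chipexpr.peak_geometry import OverlapPartition
from chipexpr.target_classes import CLASS_LABELS, class_counts, classify_targets


def call(gid, log2fc):
    return TargetCall(gid, 1, 1, 0.1, log2fc, "activated" if log2fc < 0 else "repressed", 1.0)


def shared_result(genes):
    """genes: {gene_id: (log2fc_a, log2fc_b)}"""
    rows = [
        {
            "gene_id": g,
            "gene_name": g,
            "log2fc_a": fa,
            "log2fc_b": fb,
            "pvalue_a": 1e-4,
            "pvalue_b": 1e-4,
            "adj_a_stratified": 1e-3,
            "adj_b_stratified": 1e-3,
            "concordant": (fa < 0) == (fb < 0),
        }
        for g, (fa, fb) in genes.items()
    ]
    table = pd.DataFrame(rows)
    return SharedDegResult(
        table=table, shared=set(genes), shared_a_pass=set(genes), shared_b_pass=set(genes)
    )


def assignment(gene_peaks):
    """gene_peaks: {gene_id: [peak_index, ...]}"""
    return {
        g: PeakAssignment(g, TssRecord(g, "c", 1000, "+"), [(i, 100) for i in idx])
        for g, idx in gene_peaks.items()
    }


def partition(pairs, n_a=5, n_b=5):
    a_over = sorted({i for i, _ in pairs})
    b_over = sorted({j for _, j in pairs})
    return OverlapPartition(
        n_events=len(pairs),
        a_overlapped=a_over,
        a_exclusive=[i for i in range(n_a) if i not in a_over],
        b_overlapped=b_over,
        b_exclusive=[j for j in range(n_b) if j not in b_over],
        pairs=sorted(pairs),
        n_a=n_a,
        n_b=n_b,
    )


class TestClassification:
    def test_concordant_coregulated_gene(self):
        out = classify_targets(
            calls_a=[call("g1", -1.5)],
            calls_b=[call("g1", -0.8)],
            shared_degs=shared_result({"g1": (-1.5, -0.8)}),
            overlap=partition([(0, 0)]),
            assignments_a=assignment({"g1": [0]}),
            assignments_b=assignment({"g1": [0]}),
            calls_common=[call("g1", -1.5)],
        )
        assert out[0].label == "coreg_concordant"

    def test_antagonistic_coregulated_gene(self):
        out = classify_targets(
            calls_a=[call("g1", -1.2)],
            calls_b=[call("g1", +0.9)],
            shared_degs=shared_result({"g1": (-1.2, 0.9)}),
            overlap=partition([(0, 0)]),
            assignments_a=assignment({"g1": [0]}),
            assignments_b=assignment({"g1": [0]}),
            calls_common=[call("g1", -1.2)],
        )
        assert out[0].label == "coreg_antagonistic"

    def test_b_only_gene_with_positive_fold_change_is_repressed(self):
        out = classify_targets(
            calls_a=[],
            calls_b=[call("g1", +1.1)],
            shared_degs=shared_result({}),
            overlap=partition([]),
            assignments_a=assignment({}),
            assignments_b=assignment({"g1": [0]}),
        )
        assert out[0].label == "B_exclusive_repressed"

    def test_missing_common_call_demotes_to_exclusive(self):
        """Overlapping peaks + shared DEG without a common-peak call is not
        co-regulated."""
        out = classify_targets(
            calls_a=[call("g1", -1.0)],
            calls_b=[call("g1", -1.0)],
            shared_degs=shared_result({"g1": (-1.0, -1.0)}),
            overlap=partition([(0, 0)]),
            assignments_a=assignment({"g1": [0]}),
            assignments_b=assignment({"g1": [0]}),
            calls_common=[],
        )
        assert out[0].label == "A_exclusive"

    def test_a_exclusive_upregulated_gene_warns(self):
        with pytest.warns(UserWarning, match="up-regulated"):
            out = classify_targets(
                calls_a=[call("g1", +1.0)],
                calls_b=[],
                shared_degs=shared_result({}),
                overlap=partition([]),
                assignments_a=assignment({"g1": [0]}),
                assignments_b=assignment({}),
            )
        assert out[0].label == "A_exclusive"


class TestPartitionProperties:
    @pytest.fixture(scope="class")
    def pipeline_result(self, small_bundle):
        from chipexpr.pipeline import run_full_analysis

        return run_full_analysis({"synthetic": True, "seed": 11})

    def test_every_called_target_gets_exactly_one_class(self, pipeline_result):
        classified = pipeline_result["classes"]["classified"]
        betar = pipeline_result["beta"]
        universe = (
            {c.gene_id for c in betar["calls_a"]}
            | {c.gene_id for c in betar["calls_b"]}
            | {c.gene_id for c in betar["calls_common"]}
        )
        assert {t.gene_id for t in classified} == universe
        assert len({t.gene_id for t in classified}) == len(classified)
        counts = class_counts(classified)
        assert sum(counts.values()) == len(universe)
        assert set(counts) == set(CLASS_LABELS)

    def test_coregulated_classes_are_shared_degs(self, pipeline_result):
        shared = pipeline_result["loa"]["shared"].shared
        for t in pipeline_result["classes"]["classified"]:
            if t.label.startswith("coreg"):
                assert t.gene_id in shared

    def test_planted_classes_recovered(self, pipeline_result):
        """>=90% of recovered targets carry their planted class label."""
        gene_class = pipeline_result["inputs"]["truth"]["gene_class"]
        mapping = {
            "coreg_concordant": "coreg_concordant",
            "coreg_antagonistic": "coreg_antagonistic",
            "A_exclusive": "A_exclusive",
            "B_exclusive_down": "B_exclusive_activated",
            "B_exclusive_up": "B_exclusive_repressed",
        }
        classified = {t.gene_id: t.label for t in pipeline_result["classes"]["classified"]}
        total = match = 0
        for g, cls in gene_class.items():
            if cls in mapping and g in classified:
                total += 1
                match += classified[g] == mapping[cls]
        assert total > 0
        assert match / total >= 0.9
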