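"""Partition direct targets into co-regulated and factor-exclusive classes.

A gene is *co-regulated* only when three independent lines of evidence
agree: it is a shared DEG by the conditional overlap analysis, at least one
overlapping A/B peak pair lies within its TSS window, and it is called by
the regulatory-potential pass run on the common (overlapping) peaks alone.
Any missing criterion demotes the gene to an exclusive class, which is why
genes with overlapping peaks but single-mutant differential expression land
in exclusive classes.

Classes (mutually exclusive, exhaustive over the union of called targets):
``coreg_concordant`` / ``coreg_antagonistic`` (log2FC signs agree /
disagree across the two mutant comparisons), ``A_exclusive`` (called for
factor A and not co-regulated), ``B_exclusive_activated`` /
``B_exclusive_repressed`` (called for B only; down / up in the B mutant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .beta_integration import PeakAssignment, TargetCall
from .deg_loa import SharedDegResult
from .peak_geometry import OverlapPartition

__all__ = ["ClassifiedTarget", "CLASS_LABELS", "classify_targets", "class_counts"]

CLASS_LABELS = (
    "coreg_concordant",
    "coreg_antagonistic",
    "A_exclusive",
    "B_exclusive_activated",
    "B_exclusive_repressed",
)


@dataclass
class ClassifiedTarget:
    gene_id: str
    label: str
    log2fc_a: float | None
    log2fc_b: float | None
    evidence: dict = field(default_factory=dict)


def _genes_with_overlapping_pair(
    overlap: OverlapPartition,
    assignments_a: Mapping[str, PeakAssignment],
    assignments_b: Mapping[str, PeakAssignment],
) -> set[str]:
    """Genes whose assigned peaks include >=1 overlapping A/B pair."""
    pair_set = set(overlap.pairs)
    b_peaks_by_gene = {
        gid: {i for i, _ in asn.peaks} for gid, asn in assignments_b.items()
    }
    out: set[str] = set()
    for gid, asn in assignments_a.items():
        b_near = b_peaks_by_gene.get(gid)
        if not b_near:
            continue
        for ai, _ in asn.peaks:
            if any((ai, bj) in pair_set for bj in b_near):
                out.add(gid)
                break
    return out


def classify_targets(
    calls_a: Sequence[TargetCall],
    calls_b: Sequence[TargetCall],
    shared_degs: SharedDegResult,
    overlap: OverlapPartition,
    assignments_a: Mapping[str, PeakAssignment],
    assignments_b: Mapping[str, PeakAssignment],
    calls_common: Sequence[TargetCall] = (),
) -> list[ClassifiedTarget]:
    """Assign every called target gene to exactly one regulation class.

    ``calls_common`` are target calls from the regulatory-potential pass on
    the overlapping peaks with the shared-DEG table; co-regulation requires
    membership there in addition to shared-DEG status and a nearby
    overlapping peak pair.
    """
    a_ids = {c.gene_id for c in calls_a}
    b_ids = {c.gene_id for c in calls_b}
    common_ids = {c.gene_id for c in calls_common}
    universe = a_ids | b_ids | common_ids
    if not universe:
        return []

    l2fc_a = {c.gene_id: c.log2fc for c in calls_a}
    l2fc_b = {c.gene_id: c.log2fc for c in calls_b}
    shared_tab = shared_degs.table.set_index("gene_id") if len(shared_degs.table) else None
    genes_with_pair = _genes_with_overlapping_pair(overlap, assignments_a, assignments_b)

    out: list[ClassifiedTarget] = []
    for gid in sorted(universe):
        in_shared = gid in shared_degs.shared
        has_pair = gid in genes_with_pair
        in_common = gid in common_ids
        fa = l2fc_a.get(gid)
        fb = l2fc_b.get(gid)
        if fa is None and shared_tab is not None and gid in shared_tab.index:
            fa = float(shared_tab.loc[gid, "log2fc_a"])
        if fb is None and shared_tab is not None and gid in shared_tab.index:
            fb = float(shared_tab.loc[gid, "log2fc_b"])

        evidence = {
            "called_a": gid in a_ids,
            "called_b": gid in b_ids,
            "shared_deg": in_shared,
            "overlapping_pair_in_window": has_pair,
            "common_peak_call": in_common,
        }
        if in_shared and has_pair and in_common and fa is not None and fb is not None:
            label = (
                "coreg_concordant"
                if (fa < 0) == (fb < 0)
                else "coreg_antagonistic"
            )
        elif gid in a_ids:
            label = "A_exclusive"
            if fa is not None and fa > 0:
                warnings.warn(
                    f"A-exclusive target {gid} is up-regulated in the A mutant"
                )
        elif gid in b_ids:
            label = "B_exclusive_activated" if (fb is not None and fb < 0) else "B_exclusive_repressed"
        else:
            # common-pass-only gene lacking full co-regulation evidence:
            # attribute by whichever single comparison is significant
            if fa is not None and fb is None:
                label = "A_exclusive"
            else:
                label = (
                    "B_exclusive_activated"
                    if (fb is not None and fb < 0)
                    else "B_exclusive_repressed"
                )
        out.append(
            ClassifiedTarget(
                gene_id=gid, label=label, log2fc_a=fa, log2fc_b=fb, evidence=evidence
            )
        )
    return out


def class_counts(classified: Sequence[ClassifiedTarget]) -> dict[str, int]:
    counts = {label: 0 for label in CLASS_LABELS}
    for t in classified:
        counts[t.label] += 1
    return counts
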