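"""DEG thresholding and conditional overlap analysis of two comparisons.

The overlap analysis (after Luperchio et al.) asks which genes are
differentially expressed in *both* of two mutant-vs-wild-type comparisons
without paying the full genome-wide multiplicity price twice.  Genes are
split into two strata conditional on the first comparison: S1 = genes DE in
comparison A at the conditional FDR, S2 = the rest.  Within each stratum the
*raw* p-values of comparison B are re-adjusted by Benjamini-Hochberg, and
the shared DEGs are the S1 genes whose stratum-adjusted B statistic clears
the same FDR.  Because |S1| is small relative to the genome, the
within-stratum adjustment is less punishing than a genome-wide one, so the
shared list is a superset of the naive intersection of two independent DEG
lists at the same cutoff.

Both directional passes (condition on A then re-test B, and vice versa) are
computed; the default "shared" output is their union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_tables import DegRecord

__all__ = ["DegSet", "SharedDegResult", "filter_degs", "loa_shared_degs", "bh_adjust"]


@dataclass
class DegSet:
    """DEGs surviving an FDR (and optional direction) filter."""

    comparison: str
    records: list[DegRecord]
    fdr_cutoff: float
    direction: str = "both"
    n_up: int = 0
    n_down: int = 0

    def gene_ids(self) -> set[str]:
        return {r.gene_id for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SharedDegResult:
    """Genes called DE in both comparisons by the conditional analysis.

    ``table`` has one row per shared gene with both comparisons' log2FC,
    raw p, and the stratum-adjusted statistic from the pass that called it;
    ``concordant`` flags log2FC sign agreement.
    """

    table: pd.DataFrame
    shared: set[str]
    shared_a_pass: set[str]
    shared_b_pass: set[str]
    strata_sizes: dict[str, int] = field(default_factory=dict)
    n_absent_assigned_s2: int = 0

    def __len__(self) -> int:
        return len(self.shared)


def filter_degs(
    table: Sequence[DegRecord],
    fdr_cutoff: float = 0.05,
    direction: str = "both",
    comparison: str = "",
) -> DegSet:
    """Keep records with fdr <= cutoff whose log2FC sign matches direction.

    ``direction`` is ``"up"`` (log2fc > 0), ``"down"`` (log2fc < 0) or
    ``"both"``.  Up/down counts are always reported.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    if not (0 <= fdr_cutoff < 1):
        raise ValueError(f"fdr_cutoff must be in [0,1), got {fdr_cutoff}")
    sig = [r for r in table if r.fdr <= fdr_cutoff]
    n_up = sum(1 for r in sig if r.log2fc > 0)
    n_down = sum(1 for r in sig if r.log2fc < 0)
    if direction == "up":
        kept = [r for r in sig if r.log2fc > 0]
    elif direction == "down":
        kept = [r for r in sig if r.log2fc < 0]
    else:
        kept = sig
    return DegSet(
        comparison=comparison,
        records=kept,
        fdr_cutoff=fdr_cutoff,
        direction=direction,
        n_up=n_up,
        n_down=n_down,
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    if len(pvalues) == 0:
        return np.asarray([], dtype=float)
    return multipletests(pvalues, method="fdr_bh")[1]


def _one_pass(
    cond: pd.DataFrame, retest: pd.DataFrame, fdr_stratify: float, fdr_call: float
) -> tuple[set[str], pd.Series, int, int]:
    """Condition on ``cond``'s FDR, re-test ``retest``'s raw p within S1.

    Genes absent from the conditioning table are assigned to S2 (not DE)
    rather than dropped; their count is returned.
    """
    universe = retest.index
    cond_fdr = cond["fdr"].reindex(universe)
    n_absent = int(cond_fdr.isna().sum())
    in_s1 = (cond_fdr <= fdr_stratify).fillna(False)
    s1 = universe[in_s1]
    s2 = universe[~in_s1]

    adj = pd.Series(np.nan, index=universe, dtype=float)
    for stratum in (s1, s2):
        if len(stratum):
            adj.loc[stratum] = bh_adjust(retest.loc[stratum, "pvalue"].to_numpy())
    shared = set(s1[adj.loc[s1] <= fdr_call])
    return shared, adj, len(s1), n_absent


def loa_shared_degs(
    table_a: Sequence[DegRecord],
    table_b: Sequence[DegRecord],
    fdr_conditional: float = 0.01,
    fdr_call: float | None = None,
    output: str = "union",
) -> SharedDegResult:
    """Conditional, stratified identification of DEGs shared by A and B.

    Parameters
    ----------
    table_a, table_b
        Full per-gene DE tables (must carry raw p-values) for the two
        mutant-vs-wild-type comparisons.
    fdr_conditional
        FDR used both to stratify on the conditioning comparison and (by
        default) to call within-stratum significance.
    fdr_call
        Final call threshold on the stratum-adjusted statistic; defaults to
        ``fdr_conditional``.
    output
        ``"union"`` (default) or ``"intersection"`` of the two directional
        passes; both sets are reported either way.
    """
    if output not in ("union", "intersection"):
        raise ValueError(f"output must be union/intersection, got {output!r}")
    fdr_call = fdr_conditional if fdr_call is None else fdr_call

    def frame(recs: Sequence[DegRecord], label: str) -> pd.DataFrame:
        if not recs:
            return pd.DataFrame(columns=["gene_name", "log2fc", "pvalue", "fdr"])
        df = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in recs],
                "gene_name": [r.gene_name for r in recs],
                "log2fc": [r.log2fc for r in recs],
                "pvalue": [r.pvalue for r in recs],
                "fdr": [r.fdr for r in recs],
            }
        ).set_index("gene_id")
        if df["pvalue"].isna().any():
            raise ValueError(f"table {label}: missing raw p-values")
        return df

    df_a = frame(table_a, "A")
    df_b = frame(table_b, "B")
    if len(df_a.index.intersection(df_b.index)) == 0:
        raise ValueError("gene universes of the two tables are disjoint")

    shared_a_pass, adj_b, n_s1_a, absent_a = _one_pass(
        df_a, df_b, fdr_conditional, fdr_call
    )
    shared_b_pass, adj_a, n_s1_b, absent_b = _one_pass(
        df_b, df_a, fdr_conditional, fdr_call
    )
    shared = (
        shared_a_pass | shared_b_pass
        if output == "union"
        else shared_a_pass & shared_b_pass
    )

    rows = []
    for gid in sorted(shared):
        a_row = df_a.loc[gid] if gid in df_a.index else None
        b_row = df_b.loc[gid] if gid in df_b.index else None
        l2fc_a = float(a_row["log2fc"]) if a_row is not None else np.nan
        l2fc_b = float(b_row["log2fc"]) if b_row is not None else np.nan
        rows.append(
            {
                "gene_id": gid,
                "gene_name": (
                    a_row["gene_name"] if a_row is not None else b_row["gene_name"]
                ),
                "log2fc_a": l2fc_a,
                "log2fc_b": l2fc_b,
                "pvalue_a": float(a_row["pvalue"]) if a_row is not None else np.nan,
                "pvalue_b": float(b_row["pvalue"]) if b_row is not None else np.nan,
                "adj_a_stratified": float(adj_a.get(gid, np.nan)),
                "adj_b_stratified": float(adj_b.get(gid, np.nan)),
                "concordant": bool(np.sign(l2fc_a) == np.sign(l2fc_b)),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "gene_name",
            "log2fc_a",
            "log2fc_b",
            "pvalue_a",
            "pvalue_b",
            "adj_a_stratified",
            "adj_b_stratified",
            "concordant",
        ],
    )
    return SharedDegResult(
        table=table,
        shared=shared,
        shared_a_pass=shared_a_pass,
        shared_b_pass=shared_b_pass,
        strata_sizes={
            "s1_condition_on_a": n_s1_a,
            "s2_condition_on_a": len(df_b) - n_s1_a,
            "s1_condition_on_b": n_s1_b,
            "s2_condition_on_b": len(df_a) - n_s1_b,
        },
        n_absent_assigned_s2=absent_a + absent_b,
    )
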