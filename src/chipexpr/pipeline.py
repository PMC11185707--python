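"""End-to-end orchestration: geometry -> LOA -> target calling -> classes.

``run_full_analysis`` executes the whole integration on either synthetic
inputs (a seed plus generator overrides) or file paths, writes every output
table as TSV plus a single JSON run report echoing all decision flags, and
returns the in-memory results.  Stage failures are re-raised with the stage
name attached.
"""

from __future__ import annotations

import os
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import beta_integration as beta
from . import deg_loa, hot_sites, peak_geometry, phenotype_stats
from .io_tables import (
    DegRecord,
    PeakSet,
    read_deg_table,
    read_peak_table,
    read_phenotypes,
    read_tf_compendium,
    read_tss_table,
    write_run_report,
)
from .synthetic_data import SynthConfig, simulate_all
from .target_classes import class_counts, classify_targets

__all__ = ["PipelineError", "run_full_analysis", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "fdr": 0.05,
    "loa_fdr": 0.01,
    "window_bp": 3000,
    "window_norm_bp": None,  # None -> same as window_bp
    "hot_window": 400,
    "hot_threshold": 15,
    "nn_direction": "A_to_B",
    "random_range": "genome",  # or "observed"
    "n_random_seeds": 20,
    "seed": 0,
    "dialect": "tsv_1based_inclusive",
    "overlap_count": "events",  # or "per_factor"
    "factor_a": "SMA-3",
    "factor_b": "SMA-9",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _shared_degs_as_records(shared) -> list[DegRecord]:
    """Recast the LOA shared table as a DEG table for the common-peak pass.

    The stratum-adjusted statistic (more significant pass) serves as the
    FDR; raw p and log2FC come from the more significant comparison.
    """
    records = []
    for row in shared.table.itertuples():
        adj = np.nanmin([row.adj_a_stratified, row.adj_b_stratified])
        use_a = (
            np.isnan(row.pvalue_b)
            or (not np.isnan(row.pvalue_a) and row.pvalue_a <= row.pvalue_b)
        )
        records.append(
            DegRecord(
                gene_id=row.gene_id,
                gene_name=str(row.gene_name),
                log2fc=float(row.log2fc_a if use_a else row.log2fc_b),
                pvalue=float(row.pvalue_a if use_a else row.pvalue_b),
                fdr=float(adj),
            )
        )
    return records


@_stage("load_inputs")
def _load_inputs(config: Mapping) -> dict:
    if config.get("synthetic"):
        overrides = {
            k: v
            for k, v in config.items()
            if k in SynthConfig.__dataclass_fields__ and k != "seed"
        }
        bundle = simulate_all(SynthConfig(seed=int(config["seed"]), **overrides))
        return {
            "peaks_a": bundle.peaks_a,
            "peaks_b": bundle.peaks_b,
            "degs_a": bundle.degs_a,
            "degs_b": bundle.degs_b,
            "tss": bundle.tss,
            "compendium": bundle.compendium,
            "phenotypes": bundle.phenotypes,
            "control_genotype": SynthConfig(seed=0).control_genotype,
            "truth": bundle.truth,
            "chrom_lengths": dict(
                config.get("chrom_lengths", SynthConfig(seed=0).chrom_lengths)
            ),
        }

    dialect = config.get("dialect", DEFAULTS["dialect"])
    out: dict = {
        "peaks_a": read_peak_table(
            config["peaks_a"], config.get("factor_a", DEFAULTS["factor_a"]), dialect
        ),
        "peaks_b": read_peak_table(
            config["peaks_b"], config.get("factor_b", DEFAULTS["factor_b"]), dialect
        ),
        "degs_a": read_deg_table(config["degs_a"]),
        "degs_b": read_deg_table(config["degs_b"]),
        "truth": None,
        "chrom_lengths": config.get("chrom_lengths"),
    }
    if "tss" in config:
        out["tss"] = read_tss_table(config["tss"])
    else:
        raise ValueError("config must name a 'tss' annotation for the target-calling stage")
    out["compendium"] = (
        read_tf_compendium(config["compendium"]) if config.get("compendium") else None
    )
    out["phenotypes"] = (
        read_phenotypes(config["phenotypes"]) if config.get("phenotypes") else None
    )
    out["control_genotype"] = config.get("control_genotype", "control")
    return out


@_stage("peak_geometry")
def _run_geometry(inputs: dict, opts: dict) -> dict:
    a, b = inputs["peaks_a"], inputs["peaks_b"]
    cen_a = peak_geometry.compute_centroids(a)
    cen_b = peak_geometry.compute_centroids(b)
    nn = peak_geometry.nearest_neighbor_distances(cen_a, cen_b, opts["nn_direction"])

    if opts["random_range"] == "observed":
        ranges = peak_geometry.observed_ranges(a, b)
    else:
        lengths = inputs.get("chrom_lengths")
        ranges = peak_geometry.genome_ranges(lengths)
    null_midpoints = []
    for k in range(opts["n_random_seeds"]):
        seed = (int(opts["seed"]) + 7919 * (k + 1)) % (2**31)
        ra = peak_geometry.randomize_centroids(cen_a, ranges, seed)
        rb = peak_geometry.randomize_centroids(cen_b, ranges, seed + 1)
        nn_r = peak_geometry.nearest_neighbor_distances(ra, rb, opts["nn_direction"])
        null_midpoints.append(nn_r.midpoint)

    overlap = peak_geometry.overlap_partition(a, b)
    widths_a = peak_geometry.peak_width_distribution(a)
    widths_b = peak_geometry.peak_width_distribution(b)
    return {
        "centroids_a": cen_a,
        "centroids_b": cen_b,
        "nn": nn,
        "null_midpoints": null_midpoints,
        "null_midpoint_mean": float(np.mean(null_midpoints)),
        "overlap": overlap,
        "widths_a": widths_a,
        "widths_b": widths_b,
    }


@_stage("deg_loa")
def _run_loa(inputs: dict, opts: dict) -> dict:
    degs_a = deg_loa.filter_degs(inputs["degs_a"], opts["fdr"], comparison="A")
    degs_b = deg_loa.filter_degs(inputs["degs_b"], opts["fdr"], comparison="B")
    shared = deg_loa.loa_shared_degs(
        inputs["degs_a"], inputs["degs_b"], fdr_conditional=opts["loa_fdr"]
    )
    return {"degs_a": degs_a, "degs_b": degs_b, "shared": shared}


@_stage("beta_integration")
def _run_beta(inputs: dict, geometry: dict, loa: dict, opts: dict) -> dict:
    window = opts["window_bp"]
    norm = opts["window_norm_bp"] or window
    out: dict = {}
    for tag, peaks, degs in (
        ("a", inputs["peaks_a"], inputs["degs_a"]),
        ("b", inputs["peaks_b"], inputs["degs_b"]),
    ):
        asn = beta.assign_peaks_to_genes(peaks, inputs["tss"], window)
        rp = beta.regulatory_potential(asn, norm)
        out[f"assignments_{tag}"] = asn
        out[f"rp_{tag}"] = rp
        out[f"calls_{tag}"] = beta.call_direct_targets(rp, degs, opts["fdr"])
        out[f"function_{tag}"] = beta.ks_function_test(rp, degs, opts["fdr"])

    overlap = geometry["overlap"]
    common_peaks = PeakSet(
        factor="common",
        peaks=[inputs["peaks_a"][i] for i in overlap.a_overlapped]
        + [inputs["peaks_b"][j] for j in overlap.b_overlapped],
    )
    asn_common = beta.assign_peaks_to_genes(common_peaks, inputs["tss"], window)
    rp_common = beta.regulatory_potential(asn_common, norm)
    shared_records = _shared_degs_as_records(loa["shared"])
    out["calls_common"] = beta.call_direct_targets(rp_common, shared_records, opts["fdr"])
    return out


@_stage("target_classes")
def _run_classes(betar: dict, loa: dict, geometry: dict) -> dict:
    classified = classify_targets(
        betar["calls_a"],
        betar["calls_b"],
        loa["shared"],
        geometry["overlap"],
        betar["assignments_a"],
        betar["assignments_b"],
        betar["calls_common"],
    )
    return {"classified": classified, "counts": class_counts(classified)}


@_stage("hot_sites")
def _run_hot(inputs: dict, opts: dict) -> dict:
    out = {}
    for tag in ("a", "b"):
        records = hot_sites.tf_cooccupancy(
            inputs[f"peaks_{tag}"],
            inputs["compendium"],
            window_bp=opts["hot_window"],
            hot_threshold=opts["hot_threshold"],
        )
        out[f"records_{tag}"] = records
        out[f"fraction_{tag}"] = hot_sites.hot_fraction(records)
    return out


@_stage("phenotype_stats")
def _run_phenotypes(inputs: dict) -> dict:
    results = phenotype_stats.screen_effect_sizes(
        inputs["phenotypes"], inputs["control_genotype"]
    )
    return {"effect_sizes": results}


def _write_tables(outdir: str, betar: dict, loa: dict, classes: dict,
                  hot: dict | None, pheno: dict | None) -> list[str]:
    os.makedirs(outdir, exist_ok=True)
    written = []

    def dump(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    for tag in ("a", "b", "common"):
        calls = betar[f"calls_{tag}"]
        dump(
            pd.DataFrame(
                {
                    "gene_id": [c.gene_id for c in calls],
                    "rank_rp": [c.rank_rp for c in calls],
                    "rank_de": [c.rank_de for c in calls],
                    "rank_product": [c.rank_product for c in calls],
                    "log2fc": [c.log2fc for c in calls],
                    "direction": [c.direction for c in calls],
                    "score": [c.score for c in calls],
                }
            ),
            f"direct_targets_{tag}.tsv",
        )
    dump(loa["shared"].table, "shared_degs.tsv")
    dump(
        pd.DataFrame(
            {
                "gene_id": [t.gene_id for t in classes["classified"]],
                "class": [t.label for t in classes["classified"]],
                "log2fc_a": [t.log2fc_a for t in classes["classified"]],
                "log2fc_b": [t.log2fc_b for t in classes["classified"]],
            }
        ),
        "target_classes.tsv",
    )
    if hot is not None:
        for tag in ("a", "b"):
            recs = hot[f"records_{tag}"]
            dump(
                pd.DataFrame(
                    {
                        "peak_index": [r.peak_index for r in recs],
                        "chrom": [r.chrom for r in recs],
                        "centroid": [r.centroid for r in recs],
                        "tf_count": [r.tf_count for r in recs],
                        "is_hot": [r.is_hot for r in recs],
                    }
                ),
                f"hot_sites_{tag}.tsv",
            )
    if pheno is not None:
        res = pheno["effect_sizes"]
        dump(
            pd.DataFrame(
                {
                    "genotype": [r.genotype for r in res],
                    "n": [r.n for r in res],
                    "mean_um": [r.mean_um for r in res],
                    "normalized_mean": [r.normalized_mean for r in res],
                    "glass_delta": [r.glass_delta for r in res],
                    "welch_p": [r.welch_p for r in res],
                }
            ),
            "effect_sizes.tsv",
        )
    return written


def run_full_analysis(config: Mapping, outdir: str | None = None) -> dict:
    """Run every stage; optionally write TSV outputs and a JSON run report.

    ``config`` is a flat mapping: either ``synthetic: true`` with a seed
    and generator overrides, or input paths (peaks_a, peaks_b, degs_a,
    degs_b, tss, optional compendium / phenotypes) plus any of the
    threshold/flag keys in :data:`DEFAULTS`.
    """
    opts = {**DEFAULTS, **{k: v for k, v in config.items() if k in DEFAULTS}}
    inputs = _load_inputs(config)
    geometry = _run_geometry(inputs, opts)
    loa = _run_loa(inputs, opts)
    betar = _run_beta(inputs, geometry, loa, opts)
    classes = _run_classes(betar, loa, geometry)
    hot = _run_hot(inputs, opts) if inputs.get("compendium") else None
    pheno = _run_phenotypes(inputs) if inputs.get("phenotypes") else None

    overlap = geometry["overlap"]
    report = {
        "options": opts,
        "n_peaks_a": overlap.n_a,
        "n_peaks_b": overlap.n_b,
        "mean_width_a": geometry["widths_a"]["mean"],
        "mean_width_b": geometry["widths_b"]["mean"],
        "nn_midpoint_bp": geometry["nn"].midpoint,
        "nn_null_midpoint_bp": geometry["null_midpoint_mean"],
        "nn_null_midpoints": geometry["null_midpoints"],
        "overlap_events": overlap.n_events,
        "frac_a_overlapped": overlap.frac_a_overlapped,
        "frac_b_overlapped": overlap.frac_b_overlapped,
        "degs_a": {"n_down": loa["degs_a"].n_down, "n_up": loa["degs_a"].n_up},
        "degs_b": {"n_down": loa["degs_b"].n_down, "n_up": loa["degs_b"].n_up},
        "n_shared_degs": len(loa["shared"]),
        "n_direct_targets_a": len(betar["calls_a"]),
        "n_direct_targets_b": len(betar["calls_b"]),
        "n_direct_targets_common": len(betar["calls_common"]),
        "function_verdict_a": betar["function_a"].verdict,
        "function_verdict_b": betar["function_b"].verdict,
        "class_counts": classes["counts"],
    }
    if hot is not None:
        report["hot_fraction_a"] = hot["fraction_a"]["fraction_hot"]
        report["hot_fraction_b"] = hot["fraction_b"]["fraction_hot"]
    if pheno is not None:
        report["glass_delta"] = {
            r.genotype: r.glass_delta for r in pheno["effect_sizes"]
        }

    if outdir is not None:
        report["tables"] = _write_tables(outdir, betar, loa, classes, hot, pheno)
        write_run_report(report, os.path.join(outdir, "run_report.json"))

    return {
        "report": report,
        "inputs": inputs,
        "geometry": geometry,
        "loa": loa,
        "beta": betar,
        "classes": classes,
        "hot": hot,
        "phenotypes": pheno,
    }
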