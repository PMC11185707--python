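"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study's data shapes: two ChIP-seq peak sets with
a controllable co-binding fraction and factor-specific width distributions
(400 / 250 bp means), a gene/TSS annotation, two mutant-vs-wild-type DEG
tables in which genes near planted functional peaks carry signed log2
fold-changes with Benjamini-Hochberg FDR structure, a multi-TF peak
compendium containing planted co-occupancy hotspots, and normally
distributed body-length samples with planted Glass' effect sizes.

Ground truth (which gene belongs to which regulation class, which peak is
functional, partnered or background, where hotspots sit, which genotype
carries which effect) is returned alongside the data so each downstream
stage can be scored exactly.  All outputs are deterministic functions of
the config, including its mandatory seed; each artifact uses its own
seed stream so generation order does not matter.

Sign convention throughout: a gene *activated* by a factor has negative
log2FC in that factor's mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deg_loa import bh_adjust
from .io_tables import (
    DegRecord,
    GenomicInterval,
    PeakSet,
    PhenotypeRecord,
    PhenotypeTable,
    TfCompendium,
    TssRecord,
)

__all__ = [
    "SynthConfig",
    "SyntheticBundle",
    "make_genome",
    "make_peaks",
    "make_deg_tables",
    "make_tf_compendium",
    "make_phenotypes",
    "simulate_all",
]

TRUE_CLASSES = (
    "coreg_concordant",
    "coreg_antagonistic",
    "A_exclusive",
    "B_exclusive_down",
    "B_exclusive_up",
    "decoy",
)


@dataclass
class SynthConfig:
    """Generator parameters.  ``class_mix`` fractions must sum to <= 1."""

    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"I": 10_000_000, "II": 10_000_000, "III": 10_000_000}
    )
    n_peaks_a: int = 2000
    n_peaks_b: int = 2000
    cobind_fraction: float = 0.7
    width_mean_a: float = 400.0
    width_mean_b: float = 250.0
    width_shape: float = 8.0  # gamma shape for peak widths
    centroid_jitter_sd: float = 60.0
    n_genes: int = 2000
    min_tss_spacing: int = 8000
    window_bp: int = 3000
    functional_offset_bp: int = 1500  # functional centroids within +/- this of TSS
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "coreg_concordant": 0.04,
            "coreg_antagonistic": 0.01,
            "A_exclusive": 0.04,
            "B_exclusive_down": 0.02,
            "B_exclusive_up": 0.02,
            "decoy": 0.10,
        }
    )
    log2fc_mu: float = 0.5  # lognormal parameters of |log2FC| for planted genes
    log2fc_sigma: float = 0.35
    alt_p_beta_a: float = 0.005  # planted raw p ~ Beta(a, 1)
    null_log2fc_sd: float = 0.2
    n_tfs: int = 28
    hotspot_fraction: float = 0.2
    hot_tf_min: int = 15
    hot_tf_max: int = 24
    tf_background_peaks: int = 100
    tf_peak_width: float = 200.0
    phenotype_arms: dict[str, float] = field(
        default_factory=lambda: {"sma-3": 3.0, "sma-9": 2.0, "target": 1.0, "neutral": 0.0}
    )
    phenotype_n: int = 30
    control_genotype: str = "control"
    control_mean_um: float = 1000.0
    control_sd_um: float = 50.0
    factor_a: str = "SMA-3"
    factor_b: str = "SMA-9"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.cobind_fraction <= 1.0):
            raise ValueError("cobind_fraction must be in [0,1]")
        bad = set(self.class_mix) - set(TRUE_CLASSES)
        if bad:
            raise ValueError(f"unknown class labels in class_mix: {sorted(bad)}")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class_mix fractions must be >= 0")
        if sum(self.class_mix.values()) > 1.0:
            raise ValueError("class_mix fractions must sum to <= 1")
        if min(self.n_peaks_a, self.n_peaks_b, self.n_genes) < 0:
            raise ValueError("counts must be >= 0")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the ground truth."""

    tss: list[TssRecord]
    peaks_a: PeakSet
    peaks_b: PeakSet
    degs_a: list[DegRecord]
    degs_b: list[DegRecord]
    compendium: TfCompendium
    phenotypes: PhenotypeTable
    truth: dict


# ---------------------------------------------------------------------------
# genome / TSS


def make_genome(config: SynthConfig) -> list[TssRecord]:
    """TSS positions uniform per chromosome with a minimum spacing.

    Positions are drawn from a ``min_tss_spacing`` grid (sampling without
    replacement), which enforces the spacing exactly; genes are allocated
    to chromosomes proportionally to length.
    """
    rng = config._rng(1)
    chroms = list(config.chrom_lengths)
    lengths = np.asarray([config.chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    for i in range(int(config.n_genes - alloc.sum())):
        alloc[i % len(alloc)] += 1

    records: list[TssRecord] = []
    gene_no = 0
    margin = config.window_bp + 1
    for chrom, n in zip(chroms, alloc):
        grid = np.arange(margin, config.chrom_lengths[chrom] - margin,
                         config.min_tss_spacing)
        if n > len(grid):
            raise ValueError(
                f"chromosome {chrom}: cannot place {n} genes with spacing "
                f"{config.min_tss_spacing}"
            )
        pos = np.sort(rng.choice(grid, size=n, replace=False))
        strands = rng.choice(["+", "-"], size=n)
        for p, s in zip(pos, strands):
            gene_no += 1
            records.append(TssRecord(f"SYNG{gene_no:05d}", chrom, int(p), str(s)))
    return records


# ---------------------------------------------------------------------------
# peaks


def _draw_widths(rng: np.random.Generator, n: int, mean: float, shape: float) -> np.ndarray:
    w = rng.gamma(shape, mean / shape, size=n)
    return np.maximum(np.round(w).astype(np.int64), 20)


def _interval_at(chrom: str, centroid: int, width: int, chrom_len: int) -> GenomicInterval:
    half = width // 2
    start = max(1, int(centroid) - half)
    end = min(chrom_len, start + int(width) - 1)
    start = max(1, min(start, end))
    return GenomicInterval(chrom, start, end)


def make_peaks(
    config: SynthConfig, tss: list[TssRecord]
) -> tuple[PeakSet, PeakSet, dict]:
    """Two peak sets with planted functional peaks and co-binding structure.

    A fraction ``cobind_fraction`` of A peaks receives a B partner whose
    centroid is the A centroid plus Normal(0, jitter) noise.  Functional
    peaks sit within the TSS window of genes designated by ``class_mix``;
    all remaining peaks are placed uniformly.  Returns (A, B, truth) where
    truth maps genes to their planted class and peaks to their roles.
    """
    rng = config._rng(2)
    chrom_len = config.chrom_lengths

    n_by_class = {
        cls: int(round(config.class_mix.get(cls, 0.0) * config.n_genes))
        for cls in TRUE_CLASSES
    }
    n_planted = sum(n_by_class.values())
    if n_planted > len(tss):
        raise ValueError(
            f"class mix requires {n_planted} genes but only {len(tss)} available"
        )

    gene_order = rng.permutation(len(tss))
    gene_class: dict[str, str] = {}
    cursor = 0
    genes_in_class: dict[str, list[TssRecord]] = {}
    for cls in TRUE_CLASSES:
        chosen = [tss[i] for i in gene_order[cursor : cursor + n_by_class[cls]]]
        cursor += n_by_class[cls]
        genes_in_class[cls] = chosen
        for g in chosen:
            gene_class[g.gene_id] = cls

    a_needs_peak = (
        genes_in_class["coreg_concordant"]
        + genes_in_class["coreg_antagonistic"]
        + genes_in_class["A_exclusive"]
        + genes_in_class["decoy"]
    )
    # genes whose A peak gets an overlapping B partner
    paired_genes = set(
        g.gene_id
        for g in genes_in_class["coreg_concordant"]
        + genes_in_class["coreg_antagonistic"]
        + genes_in_class["decoy"]
    )
    b_only_genes = genes_in_class["B_exclusive_down"] + genes_in_class["B_exclusive_up"]

    if len(a_needs_peak) > config.n_peaks_a:
        raise ValueError("more functional A peaks requested than n_peaks_a")

    a_intervals: list[GenomicInterval] = []
    a_roles: list[dict] = []
    b_intervals: list[GenomicInterval] = []
    b_roles: list[dict] = []

    def add_b_partner(a_centroid: int, chrom: str, gene_id: str | None, role: str) -> None:
        c = int(round(a_centroid + rng.normal(0.0, config.centroid_jitter_sd)))
        w = int(_draw_widths(rng, 1, config.width_mean_b, config.width_shape)[0])
        b_intervals.append(_interval_at(chrom, c, w, chrom_len[chrom]))
        b_roles.append({"role": role, "gene_id": gene_id, "partner_a": len(a_intervals) - 1})

    # functional A peaks (with partners for paired genes)
    for g in a_needs_peak:
        offset = int(rng.integers(-config.functional_offset_bp,
                                  config.functional_offset_bp + 1))
        centroid = g.tss + offset
        w = int(_draw_widths(rng, 1, config.width_mean_a, config.width_shape)[0])
        a_intervals.append(_interval_at(g.chrom, centroid, w, chrom_len[g.chrom]))
        a_roles.append(
            {"role": f"functional:{gene_class[g.gene_id]}", "gene_id": g.gene_id}
        )
        if g.gene_id in paired_genes:
            add_b_partner(centroid, g.chrom, g.gene_id,
                          f"partner:{gene_class[g.gene_id]}")

    # background A peaks, uniformly placed
    chroms = list(chrom_len)
    probs = np.asarray([chrom_len[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    n_bg_a = config.n_peaks_a - len(a_intervals)
    bg_chroms = rng.choice(chroms, size=n_bg_a, p=probs)
    bg_widths = _draw_widths(rng, n_bg_a, config.width_mean_a, config.width_shape)
    n_partnered_target = int(round(config.cobind_fraction * config.n_peaks_a))
    n_more_partners = max(0, n_partnered_target - len(paired_genes))
    if n_more_partners > n_bg_a:
        raise ValueError(
            "cobind_fraction requires more partnered background A peaks than exist"
        )
    for k in range(n_bg_a):
        chrom = str(bg_chroms[k])
        centroid = int(rng.integers(1, chrom_len[chrom] + 1))
        a_intervals.append(_interval_at(chrom, centroid, int(bg_widths[k]), chrom_len[chrom]))
        partnered = k < n_more_partners
        a_roles.append({"role": "background_partnered" if partnered else "background",
                        "gene_id": None})
        if partnered:
            add_b_partner(centroid, chrom, None, "partner:background")

    # functional B-only peaks
    for g in b_only_genes:
        offset = int(rng.integers(-config.functional_offset_bp,
                                  config.functional_offset_bp + 1))
        w = int(_draw_widths(rng, 1, config.width_mean_b, config.width_shape)[0])
        b_intervals.append(
            _interval_at(g.chrom, g.tss + offset, w, chrom_len[g.chrom])
        )
        b_roles.append({"role": f"functional:{gene_class[g.gene_id]}",
                        "gene_id": g.gene_id, "partner_a": None})

    # background B peaks
    n_bg_b = config.n_peaks_b - len(b_intervals)
    if n_bg_b < 0:
        raise ValueError(
            f"n_peaks_b={config.n_peaks_b} too small for "
            f"{len(b_intervals)} partner/functional B peaks"
        )
    bg_chroms_b = rng.choice(chroms, size=n_bg_b, p=probs)
    bg_widths_b = _draw_widths(rng, n_bg_b, config.width_mean_b, config.width_shape)
    for k in range(n_bg_b):
        chrom = str(bg_chroms_b[k])
        centroid = int(rng.integers(1, chrom_len[chrom] + 1))
        b_intervals.append(_interval_at(chrom, centroid, int(bg_widths_b[k]),
                                        chrom_len[chrom]))
        b_roles.append({"role": "background", "gene_id": None, "partner_a": None})

    truth = {
        "gene_class": gene_class,
        "genes": pd.DataFrame(
            {
                "gene_id": [t.gene_id for t in tss],
                "chrom": [t.chrom for t in tss],
                "tss": [t.tss for t in tss],
                "strand": [t.strand for t in tss],
                "true_class": [gene_class.get(t.gene_id, "null") for t in tss],
            }
        ),
        "peaks_a": pd.DataFrame(a_roles),
        "peaks_b": pd.DataFrame(b_roles),
        "n_partnered_a": len(paired_genes) + n_more_partners,
    }
    return (
        PeakSet(factor=config.factor_a, peaks=a_intervals),
        PeakSet(factor=config.factor_b, peaks=b_intervals),
        truth,
    )


# ---------------------------------------------------------------------------
# DEG tables


_SIGNS = {
    # (sign in mutant A, sign in mutant B); 0 = null in that comparison
    "coreg_concordant": (-1, -1),
    "coreg_antagonistic": (-1, +1),
    "A_exclusive": (-1, 0),
    "B_exclusive_down": (0, -1),
    "B_exclusive_up": (0, +1),
    "decoy": (0, 0),
}


def make_deg_tables(
    config: SynthConfig, truth: dict
) -> tuple[list[DegRecord], list[DegRecord]]:
    """Two DEG tables (mutant A vs WT, mutant B vs WT) from the truth table.

    Planted targets draw |log2FC| from a lognormal with the class-
    appropriate sign per comparison and raw p from Beta(a, 1) with a < 1;
    null genes draw Uniform(0,1) p and Normal(0, sd) log2FC.  The FDR
    column is Benjamini-Hochberg over each full table.
    """
    rng = config._rng(3)
    genes = truth["genes"]
    inv_a = 1.0 / config.alt_p_beta_a

    tables: list[list[DegRecord]] = []
    for which in (0, 1):
        ids = genes["gene_id"].tolist()
        classes = genes["true_class"].tolist()
        log2fc = np.empty(len(ids))
        pvals = np.empty(len(ids))
        for i, cls in enumerate(classes):
            sign = _SIGNS.get(cls, (0, 0))[which]
            if sign == 0:
                log2fc[i] = rng.normal(0.0, config.null_log2fc_sd)
                pvals[i] = rng.uniform()
            else:
                log2fc[i] = sign * rng.lognormal(config.log2fc_mu, config.log2fc_sigma)
                pvals[i] = rng.uniform() ** inv_a  # Beta(a, 1) via inverse CDF
        fdr = bh_adjust(pvals)
        tables.append(
            [
                DegRecord(
                    gene_id=gid,
                    gene_name=gid.replace("SYNG", "syn-"),
                    log2fc=float(log2fc[i]),
                    pvalue=float(pvals[i]),
                    fdr=float(fdr[i]),
                )
                for i, gid in enumerate(ids)
            ]
        )
    return tables[0], tables[1]


# ---------------------------------------------------------------------------
# TF compendium


def make_tf_compendium(config: SynthConfig, focal: PeakSet) -> tuple[TfCompendium, dict]:
    """A multi-TF compendium with hotspots planted at focal peak positions.

    A fraction ``hotspot_fraction`` of focal peaks is chosen; at each, a
    randomly sized group of >= ``hot_tf_min`` TFs receives a peak
    overlapping the focal centroid.  Every TF additionally scatters
    ``tf_background_peaks`` uniform background peaks.  Returns the
    compendium and a truth dict with the hotspot focal-peak indices.
    """
    rng = config._rng(4)
    chrom_len = config.chrom_lengths
    labels = [f"TF{k:02d}" for k in range(1, config.n_tfs + 1)]
    peaks_by_tf: dict[str, list[GenomicInterval]] = {lab: [] for lab in labels}

    n_hot = int(round(config.hotspot_fraction * len(focal)))
    hot_idx = sorted(rng.choice(len(focal), size=n_hot, replace=False).tolist())
    for i in hot_idx:
        p = focal[i]
        k = int(rng.integers(config.hot_tf_min,
                             min(config.hot_tf_max, config.n_tfs) + 1))
        chosen = rng.choice(labels, size=k, replace=False)
        for lab in chosen:
            jitter = int(rng.integers(-100, 101))
            peaks_by_tf[str(lab)].append(
                _interval_at(p.chrom, p.centroid + jitter,
                             int(config.tf_peak_width), chrom_len[p.chrom])
            )

    chroms = list(chrom_len)
    probs = np.asarray([chrom_len[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    for lab in labels:
        bg_chroms = rng.choice(chroms, size=config.tf_background_peaks, p=probs)
        for chrom in bg_chroms:
            chrom = str(chrom)
            centroid = int(rng.integers(1, chrom_len[chrom] + 1))
            peaks_by_tf[lab].append(
                _interval_at(chrom, centroid, int(config.tf_peak_width),
                             chrom_len[chrom])
            )

    comp = TfCompendium()
    for lab in labels:
        comp.add(PeakSet(factor=lab, peaks=peaks_by_tf[lab]))
    return comp, {"hot_focal_indices": hot_idx, "hotspot_fraction": config.hotspot_fraction}


# ---------------------------------------------------------------------------
# phenotypes


def make_phenotypes(config: SynthConfig) -> tuple[PhenotypeTable, dict]:
    """Body-length samples with planted Glass' effect sizes per genotype."""
    rng = config._rng(5)
    records: list[PhenotypeRecord] = []
    control = rng.normal(config.control_mean_um, config.control_sd_um,
                         size=config.phenotype_n)
    for j, v in enumerate(control):
        records.append(PhenotypeRecord(config.control_genotype, str(j), float(v)))
    for genotype, delta in config.phenotype_arms.items():
        mean = config.control_mean_um - delta * config.control_sd_um
        vals = rng.normal(mean, config.control_sd_um, size=config.phenotype_n)
        for j, v in enumerate(vals):
            records.append(PhenotypeRecord(genotype, str(j), float(v)))
    return PhenotypeTable(records=records), {"planted_delta": dict(config.phenotype_arms)}


def simulate_all(config: SynthConfig) -> SyntheticBundle:
    """Generate every pipeline input from one config."""
    tss = make_genome(config)
    peaks_a, peaks_b, truth = make_peaks(config, tss)
    degs_a, degs_b = make_deg_tables(config, truth)
    compendium, hot_truth = make_tf_compendium(config, peaks_a)
    phenotypes, pheno_truth = make_phenotypes(config)
    truth = dict(truth)
    truth.update(hot_truth)
    truth.update(pheno_truth)
    return SyntheticBundle(
        tss=tss,
        peaks_a=peaks_a,
        peaks_b=peaks_b,
        degs_a=degs_a,
        degs_b=degs_b,
        compendium=compendium,
        phenotypes=phenotypes,
        truth=truth,
    )
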