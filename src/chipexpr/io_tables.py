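"""Tabular input/output for the integration pipeline.

Every artifact the pipeline touches is a plain-text table: peak intervals,
per-gene differential-expression statistics, TSS annotations, a multi-TF
peak compendium and body-length phenotype measurements.  All coordinates are
normalized at this boundary to 1-based inclusive genomic positions; BED
import/export converts to/from 0-based half-open at read/write time.

Chromosome labels are compared as exact strings.  No "chr"-prefix
normalization is applied unless explicitly requested via
``normalize_chrom_prefix`` where offered, to avoid silent mismatches
between peak and annotation sources.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "DegRecord",
    "TssRecord",
    "TfCompendium",
    "PhenotypeRecord",
    "PhenotypeTable",
    "TableFormatError",
    "read_peak_table",
    "write_peak_table",
    "read_deg_table",
    "write_deg_table",
    "read_tss_table",
    "read_tf_compendium",
    "read_phenotypes",
    "write_run_report",
]

PEAK_DIALECTS = ("tsv_1based_inclusive", "bed_0based_halfopen")


class TableFormatError(ValueError):
    """Raised when an input table violates its schema."""


@dataclass(frozen=True)
class GenomicInterval:
    """A peak: chromosome plus 1-based inclusive start/end coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise TableFormatError("chromosome label must be non-empty")
        if self.start < 1:
            raise TableFormatError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise TableFormatError(
                f"end ({self.end}) < start ({self.start}) on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def centroid(self) -> int:
        # midpoint between the two border coordinates, floored for determinism
        return (self.start + self.end) // 2

    def intersects(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class PeakSet:
    """An ordered collection of peaks for one transcription factor."""

    factor: str
    peaks: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.peaks[i]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.peaks:
            seen.setdefault(p.chrom, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
            }
        )


@dataclass(frozen=True)
class DegRecord:
    """One gene's differential-expression statistics (mutant vs wild type)."""

    gene_id: str
    gene_name: str
    log2fc: float
    pvalue: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise TableFormatError(
                f"p-value out of [0,1] for {self.gene_id}: {self.pvalue}"
            )
        if self.fdr < 0:
            raise TableFormatError(f"negative FDR for {self.gene_id}: {self.fdr}")


@dataclass(frozen=True)
class TssRecord:
    """Transcription start site of one gene (1-based, strand-aware)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise TableFormatError(f"TSS must be >= 1, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise TableFormatError(f"invalid strand {self.strand!r}")


@dataclass
class TfCompendium:
    """Mapping of TF label to its PeakSet (modERN-style compendium)."""

    peaksets: dict[str, PeakSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaksets)

    def __contains__(self, label: str) -> bool:
        return label in self.peaksets

    def __getitem__(self, label: str) -> PeakSet:
        return self.peaksets[label]

    def labels(self) -> list[str]:
        return list(self.peaksets)

    def add(self, peakset: PeakSet) -> None:
        if peakset.factor in self.peaksets:
            raise TableFormatError(f"duplicate TF label {peakset.factor!r}")
        self.peaksets[peakset.factor] = peakset


@dataclass(frozen=True)
class PhenotypeRecord:
    genotype: str
    replicate: str
    length_um: float

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise TableFormatError(
                f"non-positive body length for {self.genotype}: {self.length_um}"
            )


@dataclass
class PhenotypeTable:
    """Body-length measurements keyed by genotype."""

    records: list[PhenotypeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.genotype, None)
        return list(seen)

    def lengths(self, genotype: str) -> list[float]:
        return [r.length_um for r in self.records if r.genotype == genotype]


# ---------------------------------------------------------------------------
# peak tables


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _split_rows(path: str) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                rows.append([])
                continue
            rows.append(line.replace(",", "\t").split())
    return rows


def read_peak_table(
    path: str,
    factor_label: str,
    dialect: str = "tsv_1based_inclusive",
) -> PeakSet:
    """Read a 3-column peak table into a validated, 1-based PeakSet.

    Parameters
    ----------
    path
        Whitespace/tab/comma separated file with columns chrom, start, end.
    factor_label
        Name attached to the returned :class:`PeakSet`.
    dialect
        ``"tsv_1based_inclusive"`` (coordinates taken as-is) or
        ``"bed_0based_halfopen"`` (BED3; start+1 applied on import).

    The first row is treated as a header when either coordinate field is
    non-numeric.  Row order is preserved.
    """
    if dialect not in PEAK_DIALECTS:
        raise TableFormatError(
            f"unknown dialect {dialect!r}; expected one of {PEAK_DIALECTS}"
        )
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    peaks: list[GenomicInterval] = []
    first_data_row = True
    for lineno, fields in enumerate(_split_rows(path), start=1):
        if not fields:
            continue
        if len(fields) < 3:
            raise TableFormatError(
                f"{path}:{lineno}: expected >=3 columns, got {len(fields)}"
            )
        chrom, s_tok, e_tok = fields[0], fields[1], fields[2]
        if first_data_row and (not _is_number(s_tok) or not _is_number(e_tok)):
            first_data_row = False  # header row
            continue
        first_data_row = False
        if not _is_number(s_tok) or not _is_number(e_tok):
            raise TableFormatError(
                f"{path}:{lineno}: non-numeric coordinate {s_tok!r}/{e_tok!r}"
            )
        start, end = int(float(s_tok)), int(float(e_tok))
        if dialect == "bed_0based_halfopen":
            start += 1  # BED start is 0-based; BED end already equals inclusive end
        try:
            peaks.append(GenomicInterval(chrom, start, end))
        except TableFormatError as exc:
            raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(factor=factor_label, peaks=peaks)


def write_peak_table(
    peakset: PeakSet, path: str, dialect: str = "tsv_1based_inclusive"
) -> None:
    """Write a PeakSet as TSV (with header) or headerless BED3."""
    if dialect not in PEAK_DIALECTS:
        raise TableFormatError(
            f"unknown dialect {dialect!r}; expected one of {PEAK_DIALECTS}"
        )
    with open(path, "w") as fh:
        if dialect == "tsv_1based_inclusive":
            fh.write("chrom\tstart\tend\n")
            for p in peakset:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
        else:
            for p in peakset:
                fh.write(f"{p.chrom}\t{p.start - 1}\t{p.end}\n")


# ---------------------------------------------------------------------------
# DEG tables

_DEG_COLUMNS = {
    "gene_id": ("gene_id", "geneid", "wormbase geneid", "wbgene", "id"),
    "gene_name": ("gene_name", "name", "public name", "gene"),
    "log2fc": ("log2fc", "logfc", "log2 fold change", "log fold change", "log2foldchange"),
    "pvalue": ("pvalue", "p-value", "p", "pval"),
    "fdr": ("fdr", "padj", "adjusted p", "qvalue"),
}


def _resolve_columns(df: pd.DataFrame, path: str) -> dict[str, str]:
    lowered = {c.strip().lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    missing: list[str] = []
    for canonical, aliases in _DEG_COLUMNS.items():
        for alias in aliases:
            if alias in lowered:
                resolved[canonical] = lowered[alias]
                break
        else:
            missing.append(f"{canonical} (any of: {', '.join(aliases)})")
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s): " + "; ".join(missing)
        )
    return resolved


def read_deg_table(path: str, sep: str | None = None) -> list[DegRecord]:
    """Read a per-gene DE table (gene id, name, log2FC, p, FDR) by header.

    Header names are matched case-insensitively against common aliases.
    Duplicate gene ids are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    cols = _resolve_columns(df, path)
    records: list[DegRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        gid = str(row[cols["gene_id"]])
        if gid in seen:
            raise TableFormatError(f"{path}: duplicated gene id {gid!r}")
        seen.add(gid)
        try:
            rec = DegRecord(
                gene_id=gid,
                gene_name=str(row[cols["gene_name"]]),
                log2fc=float(row[cols["log2fc"]]),
                pvalue=float(row[cols["pvalue"]]),
                fdr=float(row[cols["fdr"]]),
            )
        except (TypeError, ValueError) as exc:
            raise TableFormatError(
                f"{path}: row {int(idx) + 2}: non-numeric statistic ({exc})"
            ) from exc
        records.append(rec)
    return records


def write_deg_table(records: Sequence[DegRecord], path: str) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "gene_name": [r.gene_name for r in records],
            "log2fc": [repr(r.log2fc) for r in records],
            "pvalue": [repr(r.pvalue) for r in records],
            "fdr": [repr(r.fdr) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def deg_records_to_frame(records: Iterable[DegRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "gene_name": [r.gene_name for r in records],
            "log2fc": [r.log2fc for r in records],
            "pvalue": [r.pvalue for r in records],
            "fdr": [r.fdr for r in records],
        }
    )


# ---------------------------------------------------------------------------
# TSS annotation


def read_tss_table(path: str) -> list[TssRecord]:
    """Read TSS annotations from a 4-column table or a GFF3 of gene features.

    For GFF3, the TSS is the strand-aware 5' end of each ``gene`` feature
    (start on '+', end on '-'); the gene id is taken from the ``ID``
    attribute with any ``gene:`` prefix stripped.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        head = fh.read(2048)
    if head.startswith("##gff-version") or "\tgene\t" in head:
        return _read_tss_gff3(path)

    records: list[TssRecord] = []
    seen: set[str] = set()
    for lineno, fields in enumerate(_split_rows(path), start=1):
        if not fields:
            continue
        if len(fields) < 4:
            raise TableFormatError(
                f"{path}:{lineno}: expected 4 columns (gene, chrom, tss, strand)"
            )
        gid, chrom, tss_tok, strand = fields[0], fields[1], fields[2], fields[3]
        if lineno == 1 and not _is_number(tss_tok):
            continue  # header
        if gid in seen:
            raise TableFormatError(f"{path}:{lineno}: duplicated gene id {gid!r}")
        seen.add(gid)
        try:
            records.append(TssRecord(gid, chrom, int(float(tss_tok)), strand))
        except TableFormatError as exc:
            raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def _read_tss_gff3(path: str) -> list[TssRecord]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[TssRecord] = []
    for gene in db.features_of_type("gene"):
        gid = gene.id.removeprefix("gene:")
        tss = gene.start if gene.strand == "+" else gene.end
        records.append(TssRecord(gid, gene.seqid, tss, gene.strand))
    if not records:
        raise TableFormatError(f"{path}: no gene features found in GFF3")
    return records


# ---------------------------------------------------------------------------
# TF compendium


def read_tf_compendium(source: str) -> TfCompendium:
    """Build a TF compendium from a directory of BED files or a long table.

    Directory mode: every ``*.bed`` file contributes one TF whose label is
    the file stem.  Long-table mode: columns tf, chrom, start, end (1-based
    inclusive).
    """
    comp = TfCompendium()
    if os.path.isdir(source):
        for name in sorted(os.listdir(source)):
            if not name.endswith(".bed"):
                continue
            label = name[: -len(".bed")]
            comp.add(read_peak_table(os.path.join(source, name), label,
                                     dialect="bed_0based_halfopen"))
        if len(comp) == 0:
            raise TableFormatError(f"{source}: no .bed files found")
        return comp

    if not os.path.exists(source):
        raise FileNotFoundError(source)
    by_tf: dict[str, list[GenomicInterval]] = {}
    for lineno, fields in enumerate(_split_rows(source), start=1):
        if not fields:
            continue
        if len(fields) < 4:
            raise TableFormatError(
                f"{source}:{lineno}: expected 4 columns (tf, chrom, start, end)"
            )
        tf, chrom, s_tok, e_tok = fields[:4]
        if lineno == 1 and not _is_number(s_tok):
            continue
        try:
            by_tf.setdefault(tf, []).append(
                GenomicInterval(chrom, int(float(s_tok)), int(float(e_tok)))
            )
        except TableFormatError as exc:
            raise TableFormatError(f"{source}:{lineno}: {exc}") from exc
    for tf, peaks in by_tf.items():
        comp.add(PeakSet(factor=tf, peaks=peaks))
    if len(comp) == 0:
        raise TableFormatError(f"{source}: empty compendium")
    return comp


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path: str, control_genotype: str | None = None) -> PhenotypeTable:
    """Read a CSV/TSV of (genotype, replicate, body length in microns)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    lowered = {c.strip().lower(): c for c in df.columns}
    try:
        gcol = next(lowered[k] for k in ("genotype", "strain", "group") if k in lowered)
        lcol = next(
            lowered[k]
            for k in ("length_um", "length", "body_length", "body length (um)")
            if k in lowered
        )
    except StopIteration:
        raise TableFormatError(
            f"{path}: need a genotype column and a body-length column"
        ) from None
    rcol = next(
        (lowered[k] for k in ("replicate", "rep", "worm", "animal") if k in lowered),
        None,
    )
    records = []
    for idx, row in df.iterrows():
        rep = str(row[rcol]) if rcol is not None else str(idx)
        try:
            records.append(
                PhenotypeRecord(str(row[gcol]), rep, float(row[lcol]))
            )
        except (TypeError, ValueError) as exc:
            raise TableFormatError(f"{path}: row {int(idx) + 2}: {exc}") from exc
    table = PhenotypeTable(records=records)
    if control_genotype is not None and control_genotype not in table.genotypes():
        raise TableFormatError(
            f"{path}: control genotype {control_genotype!r} absent"
        )
    return table


# ---------------------------------------------------------------------------
# run report


def write_run_report(report: Mapping, path: str) -> None:
    """Serialize the pipeline run report (all decision flags echoed) as JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
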