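"""Readers and writers for the tab-separated pipeline tables.

Every writer emits '#'-prefixed header lines carrying the config fingerprint
and seed so a result file is traceable to the run that produced it. Readers
skip those lines. Genomic coordinates are 1-based inclusive in report tables
and 0-based half-open in BED exports.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .datatypes import (
    ExpressionMatrix,
    GeneAnnotation,
    ProbeTable,
    RegionSummary,
    SampleMetadata,
    normalize_chromosome,
)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report-style), unlike banker's rounding."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def _header_lines(config: PipelineConfig | None) -> list[str]:
    if config is None:
        return []
    return [f"# {config.fingerprint()}", f"# seed={config.seed}"]


def _write_tsv(df: pd.DataFrame, path: str | Path, config: PipelineConfig | None,
               index: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def write_table(df: pd.DataFrame, path: str | Path,
                config: PipelineConfig | None = None, index: bool = False) -> None:
    """Write any result table with the standard config/seed header."""
    _write_tsv(df, path, config, index=index)


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except ValueError as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc


# ---------------------------------------------------------------- probe table

def read_probe_table(path: str | Path) -> ProbeTable:
    """Read a probe-level log2-ratio table (probe_id, chrom, start, end, samples)."""
    df = _read_table(path)
    rename = {"chrom": "chromosome"}
    df = df.rename(columns=rename)
    missing = [c for c in ProbeTable.META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    sample_cols = [c for c in df.columns if c not in ProbeTable.META_COLS]
    for col in sample_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based incl. header
            raise ValueError(
                f"{path}: non-numeric ratio in column {col!r} at data row {row}")
        df[col] = numeric
    return ProbeTable(df)


def write_probe_table(table: ProbeTable, path: str | Path,
                      config: PipelineConfig | None = None) -> None:
    df = table.frame.rename(columns={"chromosome": "chrom"})
    _write_tsv(df, path, config)


# ---------------------------------------------------------- expression matrix

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = _read_table(path)
    if "gene_symbol" not in df.columns:
        raise ValueError(f"{path}: missing required column 'gene_symbol'")
    return ExpressionMatrix(df.set_index("gene_symbol"))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            config: PipelineConfig | None = None) -> None:
    _write_tsv(matrix.frame, path, config, index=True)


# ----------------------------------------------------------------- annotation

def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read gene intervals from a header-ed TSV or a 6-column BED file.

    BED input (no header, chrom/start/end/name/score/strand) uses 0-based
    half-open coordinates; they are converted to 1-based inclusive.
    """
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            first = fh.readline()
    if "gene_symbol" in first:
        df = _read_table(path)
        return GeneAnnotation(df)
    bed = _read_table(path, header=None)
    if bed.shape[1] < 4:
        raise ValueError(f"{path}: BED annotation needs at least 4 columns")
    bed = bed.iloc[:, :6]
    bed.columns = ["chromosome", "start", "end", "gene_symbol", "score", "strand"][: bed.shape[1]]
    if "strand" not in bed.columns:
        bed["strand"] = "+"
    df = pd.DataFrame({
        "gene_symbol": bed["gene_symbol"],
        "chromosome": bed["chromosome"].map(normalize_chromosome),
        "start": bed["start"].astype(int) + 1,  # BED is 0-based half-open
        "end": bed["end"].astype(int),
        "strand": bed["strand"],
    })
    return GeneAnnotation(df)


def write_annotation(annotation: GeneAnnotation, path: str | Path,
                     config: PipelineConfig | None = None) -> None:
    cols = ["gene_symbol", "chromosome", "start", "end", "strand"]
    _write_tsv(annotation.frame[cols], path, config)


# ------------------------------------------------------------------- metadata

def read_metadata(path: str | Path) -> SampleMetadata:
    df = _read_table(path)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path,
                   config: PipelineConfig | None = None) -> None:
    _write_tsv(metadata.frame, path, config)


def validate_cohort(probe_table: ProbeTable, expression: ExpressionMatrix,
                    metadata: SampleMetadata) -> None:
    """Cross-check identifiers between the loaded tables.

    Expression samples must exist in metadata; metadata samples must have a
    ratio column. Raises with the full offender list.
    """
    metadata.validate_against(probe_table)
    orphans = sorted(set(expression.samples) - set(metadata.samples))
    if orphans:
        raise ValueError(
            f"expression samples absent from metadata: {orphans}")


# -------------------------------------------------------------------- regions

def regions_frame(regions: list[RegionSummary]) -> pd.DataFrame:
    """Report table of regions, 1-based inclusive coordinates."""
    rows = [{
        "direction": r.direction, "chromosome": r.chromosome,
        "start_bp": r.start_bp, "end_bp": r.end_bp, "size_mb": f"{r.size_mb:.2f}",
        "count": r.count, "percent": r.percent,
        "frequency": f"{r.count} ({r.percent}%)",
        "target_genes": ",".join(r.target_genes) if r.target_genes else "-",
    } for r in regions]
    return pd.DataFrame(rows, columns=["direction", "chromosome", "start_bp",
                                       "end_bp", "size_mb", "count", "percent",
                                       "frequency", "target_genes"])


def write_regions(regions: list[RegionSummary], path: str | Path,
                  config: PipelineConfig | None = None) -> None:
    """Write regions as BED (0-based half-open); score column = sample count."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        for i, r in enumerate(regions):
            sign = "+" if r.direction == "gain" else "-"
            name = f"{sign}region{i + 1}"
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{name}"
                     f"\t{r.count}\t{r.percent}\n")


def read_regions(path: str | Path, n_samples: int) -> list[RegionSummary]:
    """Read back a region BED written by :func:`write_regions`."""
    from .recurrence import region_size_mb

    regions: list[RegionSummary] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start0, end, name, count, percent = line.rstrip("\n").split("\t")
            direction = "gain" if name.startswith("+") else "loss"
            start_bp, end_bp = int(start0) + 1, int(end)
            regions.append(RegionSummary(
                direction=direction, chromosome=normalize_chromosome(chrom),
                start_bp=start_bp, end_bp=end_bp,
                size_mb=region_size_mb(start_bp, end_bp),
                count=int(count), percent=int(percent), n_samples=n_samples))
    return regions


def write_regions_report(regions: list[RegionSummary], path: str | Path,
                         config: PipelineConfig | None = None) -> None:
    _write_tsv(regions_frame(regions), path, config)
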