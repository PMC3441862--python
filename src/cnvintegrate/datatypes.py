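"""Core data containers for the pipeline.

The tabular types are thin wrappers around :class:`pandas.DataFrame` that
validate their invariants on construction and pin down the coordinate
conventions: genomic intervals are held 1-based inclusive internally (the
convention of vendor CGH report tables) and converted to 0-based half-open
only on BED export.
Chromosome names are normalised to bare "1".."22", "X", "Y".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KARYOTYPE_ORDER: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_KARYOTYPE_RANK = {c: i for i, c in enumerate(KARYOTYPE_ORDER)}

HISTOLOGY_VALUES = ("PD", "MD", "M-PD")
T_STAGES = ("T1", "T2", "T3", "T4")
N_STAGES = ("N0", "N1", "N2", "N3")
M_STAGES = ("M0", "M1")


def normalize_chromosome(name: str) -> str:
    """Strip an optional 'chr' prefix and validate against the karyotype."""
    bare = str(name)
    if bare.lower().startswith("chr"):
        bare = bare[3:]
    if bare not in _KARYOTYPE_RANK:
        raise ValueError(f"unknown chromosome name: {name!r}")
    return bare


def karyotype_rank(chromosome: str) -> int:
    """Total order on chromosomes: 1..22 then X then Y."""
    return _KARYOTYPE_RANK[normalize_chromosome(chromosome)]


def karyotype_sort(df: pd.DataFrame, chrom_col: str = "chromosome",
                   start_col: str = "start") -> pd.DataFrame:
    """Return *df* sorted by (karyotype order, start); stable and idempotent."""
    rank = df[chrom_col].map(karyotype_rank)
    order = np.lexsort((df[start_col].to_numpy(), rank.to_numpy()))
    return df.iloc[order].reset_index(drop=True)


@dataclass
class ProbeTable:
    """Genome-ordered aCGH probes with per-sample tumor/normal log2 ratios.

    ``frame`` columns: probe_id, chromosome, start, end, then one numeric
    column of log2(tumor/normal) per sample pair.
    """

    frame: pd.DataFrame

    META_COLS = ("probe_id", "chromosome", "start", "end")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.META_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        df = df.copy()
        df["chromosome"] = df["chromosome"].map(normalize_chromosome)
        if df["probe_id"].duplicated().any():
            dups = df.loc[df["probe_id"].duplicated(), "probe_id"].head(3).tolist()
            raise ValueError(f"duplicate probe_ids: {dups}")
        if (df["start"] > df["end"]).any():
            raise ValueError("probe intervals must satisfy start <= end")
        samples = [c for c in df.columns if c not in self.META_COLS]
        if len(set(samples)) != len(samples):
            raise ValueError("sample column names must be unique")
        ratios = df[samples].to_numpy(dtype=float)
        if samples and not np.isfinite(ratios).all():
            raise ValueError("all log2 ratios must be finite")
        df[samples] = ratios
        self.frame = karyotype_sort(df)

    @property
    def samples(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.META_COLS]

    @property
    def n_probes(self) -> int:
        return len(self.frame)

    def ratios(self) -> np.ndarray:
        """(n_probes, n_samples) float matrix in table order."""
        return self.frame[self.samples].to_numpy(dtype=float)

    def drop_chromosomes(self, names: tuple[str, ...] = ("Y",)) -> "ProbeTable":
        bare = {normalize_chromosome(n) for n in names}
        keep = ~self.frame["chromosome"].isin(bare)
        return ProbeTable(self.frame.loc[keep].reset_index(drop=True))

    def chromosomes(self) -> list[str]:
        """Chromosomes present, in karyotype order."""
        seen = self.frame["chromosome"].unique().tolist()
        return sorted(seen, key=karyotype_rank)


@dataclass
class ExpressionMatrix:
    """Gene-level log2 expression with paired tumor ('T') / normal ('N') columns.

    ``frame`` is indexed by gene_symbol; columns are e.g. "s01T", "s01N".
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.name != "gene_symbol":
            if "gene_symbol" in df.columns:
                df = df.set_index("gene_symbol")
            else:
                df = df.copy()
                df.index.name = "gene_symbol"
        if df.index.duplicated().any():
            raise ValueError("gene symbols must be unique")
        if not np.isfinite(df.to_numpy(dtype=float)).all():
            raise ValueError("expression signals must be finite")
        t_samples = {c[:-1] for c in df.columns if c.endswith("T")}
        n_samples = {c[:-1] for c in df.columns if c.endswith("N")}
        bad = [c for c in df.columns if not (c.endswith("T") or c.endswith("N"))]
        if bad:
            raise ValueError(f"expression columns must end in T or N: {bad}")
        if t_samples != n_samples:
            odd = sorted(t_samples ^ n_samples)
            raise ValueError(f"samples missing a T or N column: {odd}")
        self.frame = df.astype(float)

    @property
    def samples(self) -> list[str]:
        return sorted({c[:-1] for c in self.frame.columns})

    @property
    def genes(self) -> list[str]:
        return self.frame.index.tolist()

    def tumor(self) -> pd.DataFrame:
        """Tumor log2 signals, columns renamed to bare sample ids."""
        cols = [s + "T" for s in self.samples]
        return self.frame[cols].rename(columns=dict(zip(cols, self.samples)))

    def normal(self) -> pd.DataFrame:
        cols = [s + "N" for s in self.samples]
        return self.frame[cols].rename(columns=dict(zip(cols, self.samples)))

    def tn_log2_ratio(self) -> pd.DataFrame:
        """Per-sample tumor minus normal log2 signal (the expression ratio)."""
        return self.tumor() - self.normal()


@dataclass
class GeneAnnotation:
    """One genomic interval per gene symbol (longest span wins on duplicates)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = ["gene_symbol", "chromosome", "start", "end"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if "strand" not in df.columns:
            df["strand"] = "+"
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValueError("strand must be '+' or '-'")
        df["chromosome"] = df["chromosome"].map(normalize_chromosome)
        if (df["start"] >= df["end"]).any():
            raise ValueError("gene intervals must satisfy start < end")
        if df["gene_symbol"].duplicated().any():
            df["_span"] = df["end"] - df["start"]
            df = (df.sort_values("_span", ascending=False)
                    .drop_duplicates("gene_symbol")
                    .drop(columns="_span"))
        self.frame = karyotype_sort(df)

    @property
    def genes(self) -> list[str]:
        return self.frame["gene_symbol"].tolist()


@dataclass
class SampleMetadata:
    """Clinical annotations: TNM stage, histology and SRCC flag per sample."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = ["sample_id", "t_stage", "n_stage", "m_stage", "histology"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if "srcc_flag" not in df.columns:
            df["srcc_flag"] = False
        df["srcc_flag"] = df["srcc_flag"].astype(bool)
        if df["sample_id"].duplicated().any():
            raise ValueError("sample_id values must be unique")
        for col, allowed in (("t_stage", T_STAGES), ("n_stage", N_STAGES),
                             ("m_stage", M_STAGES), ("histology", HISTOLOGY_VALUES)):
            bad = df.loc[~df[col].isin(allowed), col].unique().tolist()
            if bad:
                raise ValueError(f"invalid {col} values {bad}; allowed: {allowed}")
        self.frame = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def validate_against(self, probe_table: ProbeTable) -> None:
        """Every metadata sample must have a ratio column; offenders listed."""
        missing = sorted(set(self.samples) - set(probe_table.samples))
        if missing:
            raise ValueError(f"metadata samples absent from probe table: {missing}")


@dataclass
class SegmentCall:
    """One contiguous aberration call in one sample."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_probes: int
    mean_log2: float
    score: float
    # probe indices within the per-chromosome probe array (inclusive)
    first_probe: int = -1
    last_probe: int = -1

    @property
    def direction(self) -> str:
        return "gain" if self.mean_log2 > 0 else "loss"


@dataclass
class RegionSummary:
    """A recurrent region or minimal common region with frequency labels."""

    direction: str  # "gain" | "loss"
    chromosome: str
    start_bp: int
    end_bp: int
    size_mb: float
    count: int
    percent: int
    n_samples: int
    first_probe: int = -1
    last_probe: int = -1
    target_genes: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        sign = "+" if self.direction == "gain" else "-"
        return f"{sign}{self.chromosome}:{self.start_bp}-{self.end_bp}"


def segment_calls_frame(calls: list[SegmentCall]) -> pd.DataFrame:
    """Tabulate SegmentCalls (one row per call) for reporting."""
    rows = [{
        "sample_id": c.sample_id, "chromosome": c.chromosome,
        "start_bp": c.start_bp, "end_bp": c.end_bp, "n_probes": c.n_probes,
        "mean_log2": c.mean_log2, "score": c.score, "direction": c.direction,
    } for c in calls]
    return pd.DataFrame(rows, columns=["sample_id", "chromosome", "start_bp",
                                       "end_bp", "n_probes", "mean_log2",
                                       "score", "direction"])
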