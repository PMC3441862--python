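"""Synthetic paired tumor/normal cohort with known injected CNVs and
dosage-driven expression.

The generator emulates the statistical structure of a small gastric-cancer
aCGH + expression study: ~27 paired samples, evenly tiled probes on a few
chromosomes, gain/loss segments shared by sample subsets whose carrier
fractions span the non-recurrent to highly recurrent range (~10-80%), one
segment linked to a histology class to create a subtype-differential region,
and gene expression that tracks gene dosage with Gaussian log2 noise. A
global centering offset is added to every raw ratio so the centralization
step is exercised. All randomness flows from a single seed through
``numpy.random.SeedSequence`` spawning (one child stream per concern), so a
fixed seed reproduces the cohort bit-for-bit.

What it deliberately does not model: tumor purity and subclonality, probe
GC / response biases, array summarization from raw intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ExpressionMatrix,
    GeneAnnotation,
    ProbeTable,
    SampleMetadata,
)


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes for the simulated measurements."""

    probe_sigma: float = 0.2      # s.d. of probe log2 ratios
    expr_sigma: float = 0.3       # s.d. of expression log2 noise
    centering_offset: float = 0.1  # global raw-ratio shift

    def __post_init__(self) -> None:
        if self.probe_sigma <= 0 or self.expr_sigma <= 0:
            raise ValueError("noise sigmas must be positive")


@dataclass(frozen=True)
class SegmentSpec:
    """One CNV to inject: where, which direction, how strong, who carries it.

    ``carrier_fraction`` applies to the whole cohort, or — when
    ``linked_histology`` is set — within that histology class only (samples
    outside the class never carry the segment).
    """

    chromosome: str
    start_bp: int
    end_bp: int
    direction: str  # "gain" | "loss"
    shift: float = 0.8  # |mean log2 shift| in carriers
    carrier_fraction: float = 0.5
    linked_histology: str | None = None


@dataclass
class InjectedSegment:
    """A realised injected CNV with its carrier sample set."""

    chromosome: str
    start_bp: int
    end_bp: int
    direction: str
    shift: float
    carriers: list[str]

    def carrier_fraction(self, n_samples: int) -> float:
        return len(self.carriers) / n_samples


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for parameter-recovery checks."""

    injected_segments: list[InjectedSegment]
    dosage_genes: list[tuple[str, float]]  # (gene_symbol, dosage coefficient)
    null_genes: list[str]

    def to_yaml(self, path: str) -> None:
        payload = {
            "injected_segments": [{
                "chromosome": s.chromosome, "start_bp": s.start_bp,
                "end_bp": s.end_bp, "direction": s.direction,
                "shift": s.shift, "carriers": s.carriers,
            } for s in self.injected_segments],
            "dosage_genes": [{"gene_symbol": g, "coefficient": c}
                             for g, c in self.dosage_genes],
            "null_genes": self.null_genes,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


# --------------------------------------------------------- study-scale spec

CHROM_LENGTH_BP = 100_000_000
DEFAULT_CHROMOSOMES = ("1", "2", "3", "4")
PROBE_LENGTH_BP = 60
GENE_LENGTH_BP = 150_000


def default_truth_spec() -> list[SegmentSpec]:
    """Injected segments emulating the study's aberration landscape.

    The carrier counts reproduce the reported recurrence spectrum of a
    27-sample gastric cohort — 15 recurrent gains (19, 17, 12, 11, 11, 10,
    10, 8x6, 7x3 carriers of 27, i.e. 26-70%) and 5 recurrent losses
    (9, 9, 8, 8, 7 carriers) — compressed onto four 100-Mb chromosomes,
    plus sub-recurrent segments near 10-15% so the non-recurrent tail
    exists, and one gain confined to the MD histology class (the
    subtype-classifying region analogue). The dominant 30-Mb gain on
    chromosome 1 plays the role of the high-frequency 8q gain; the 15-Mb
    gain on chromosome 2 that of 20q.
    """

    def mb(x: float) -> int:
        return int(x * 1_000_000)

    # same-direction segments on a chromosome are kept >= 10 Mb apart so
    # that, at the simulated probe density, inter-region gaps stay
    # proportional to the real array's (where recurrent regions are
    # separated by thousands of probes and co-carried neighbours are not
    # bridged by a single call)
    segs = [
        # chromosome 1: the 8q-analogue block plus mid-frequency structure
        ("1", 10, 40, "gain", 19 / 27), ("1", 52, 57, "gain", 12 / 27),
        ("1", 69, 72, "gain", 8 / 27), ("1", 80, 90, "loss", 9 / 27),
        ("1", 94, 96, "gain", 4 / 27),
        # chromosome 2: the 20q-analogue block
        ("2", 5, 20, "gain", 17 / 27), ("2", 32, 37, "gain", 11 / 27),
        ("2", 49, 52, "gain", 8 / 27), ("2", 62, 72, "loss", 9 / 27),
        ("2", 84, 87, "gain", 7 / 27),
        # chromosome 3
        ("3", 5, 15, "gain", 11 / 27), ("3", 27, 35, "gain", 10 / 27),
        ("3", 47, 50, "gain", 8 / 27), ("3", 60, 68, "loss", 8 / 27),
        ("3", 80, 85, "gain", 9 / 27), ("3", 92, 94, "loss", 3 / 27),
        # chromosome 4: the subtype-linked region is added separately below
        ("4", 26, 36, "gain", 10 / 27), ("4", 48, 53, "gain", 8 / 27),
        ("4", 65, 68, "loss", 8 / 27), ("4", 80, 82, "gain", 7 / 27),
        ("4", 92, 96, "loss", 7 / 27),
    ]
    out = [SegmentSpec(c, mb(a) + 1, mb(b), d, 0.8, f)
           for c, a, b, d, f in segs]
    out.append(SegmentSpec("4", mb(10) + 1, mb(14), "gain", 0.8, 0.8,
                           linked_histology="MD"))
    return out


def default_metadata(n_samples: int = 27) -> SampleMetadata:
    """Clinical labels matching the study composition at n=27: 12 PD (2 with
    partial SRCC), 11 MD, 4 M-PD; T and N stages split roughly in half;
    6 metastatic samples."""
    sample_ids = [f"s{i + 1:02d}" for i in range(n_samples)]
    histology, srcc = [], []
    for i in range(n_samples):
        frac = i / n_samples
        if frac < 12 / 27:
            histology.append("PD")
        elif frac < 23 / 27:
            histology.append("MD")
        else:
            histology.append("M-PD")
        srcc.append(histology[-1] == "PD" and sum(srcc) < 2 and i >= 10)
    t_stage = [("T1", "T2", "T3", "T4")[i % 4] for i in range(n_samples)]
    n_stage = [("N0", "N1", "N0", "N2")[i % 4] for i in range(n_samples)]
    n_m1 = max(round(n_samples * 6 / 27), 1)  # 6 metastatic at n=27
    m1_every = max(n_samples // n_m1, 1)
    m_stage = ["M1" if (i % m1_every == 0 and i // m1_every < n_m1) else "M0"
               for i in range(n_samples)]
    return SampleMetadata(pd.DataFrame({
        "sample_id": sample_ids, "t_stage": t_stage, "n_stage": n_stage,
        "m_stage": m_stage, "histology": histology, "srcc_flag": srcc,
    }))


def make_annotation(chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES,
                    n_genes_per_chrom: int = 125,
                    chrom_length: int = CHROM_LENGTH_BP) -> GeneAnnotation:
    """Evenly spaced gene intervals across the simulated chromosomes."""
    rows = []
    spacing = chrom_length // n_genes_per_chrom
    for chrom in chromosomes:
        for i in range(n_genes_per_chrom):
            start = i * spacing + 1
            rows.append({"gene_symbol": f"G{chrom}_{i + 1:03d}",
                         "chromosome": chrom, "start": start,
                         "end": start + GENE_LENGTH_BP - 1,
                         "strand": "+" if i % 2 == 0 else "-"})
    return GeneAnnotation(pd.DataFrame(rows))


def _probe_frame(chromosomes: tuple[str, ...], n_probes_per_chrom: int,
                 chrom_length: int) -> pd.DataFrame:
    rows = []
    spacing = chrom_length // n_probes_per_chrom
    for chrom in chromosomes:
        for i in range(n_probes_per_chrom):
            start = i * spacing + 1
            rows.append({"probe_id": f"P{chrom}_{i + 1:05d}", "chromosome": chrom,
                         "start": start, "end": start + PROBE_LENGTH_BP - 1})
    return pd.DataFrame(rows)


def _draw_carriers(spec: SegmentSpec, metadata: SampleMetadata,
                   rng: np.random.Generator) -> list[str]:
    samples = metadata.samples
    if spec.linked_histology is not None:
        pool = metadata.frame.loc[
            metadata.frame["histology"] == spec.linked_histology,
            "sample_id"].tolist()
    else:
        pool = list(samples)
    k = int(round(spec.carrier_fraction * len(pool)))
    k = min(max(k, 0), len(pool))
    chosen = rng.choice(len(pool), size=k, replace=False)
    return sorted(pool[int(i)] for i in chosen)


def simulate_cohort(n_samples: int = 27,
                    n_probes_per_chrom: int = 2_000,
                    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES,
                    chrom_length: int = CHROM_LENGTH_BP,
                    annotation: GeneAnnotation | None = None,
                    segments: list[SegmentSpec] | None = None,
                    noise: NoiseModel = NoiseModel(),
                    metadata: SampleMetadata | None = None,
                    dosage_coefficient: float = 1.0,
                    n_expression_pairs: int = 25,
                    expr_baseline_range: tuple[float, float] = (5.0, 11.0),
                    unexpressed_fraction: float = 0.05,
                    seed: int = 0,
                    ) -> tuple[ProbeTable, ExpressionMatrix, SampleMetadata,
                               SyntheticTruth]:
    """Simulate a paired tumor/normal cohort with known CNV and dosage truth.

    Carrier samples of a segment receive probe log2 ratios
    ``Normal(+-shift, probe_sigma)`` inside it; everything else is
    ``Normal(0, probe_sigma)``; the centering offset is then added globally.
    Every gene lying fully inside an injected segment is a dosage gene whose
    tumor expression is ``baseline + coefficient * true_copy_log2 + noise``;
    all other genes are nulls. Expression is generated for the first
    ``n_expression_pairs`` samples (arrays are typically available for a
    subset of the aCGH cohort). A small fraction of genes gets a baseline
    below the expression-signal cutoff so the present-call filter has work
    to do.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if metadata is None:
        metadata = default_metadata(n_samples)
    if len(metadata.samples) != n_samples:
        raise ValueError("metadata size disagrees with n_samples")
    if annotation is None:
        annotation = make_annotation(chromosomes, chrom_length=chrom_length)
    if segments is None:
        segments = default_truth_spec()
    for s in segments:
        if s.chromosome not in chromosomes or s.end_bp > chrom_length:
            raise ValueError(f"segment outside simulated chromosomes: {s}")

    ss = np.random.SeedSequence(seed)
    rng_carriers, rng_probe, rng_expr = (np.random.default_rng(c)
                                         for c in ss.spawn(3))

    samples = metadata.samples
    probes = _probe_frame(chromosomes, n_probes_per_chrom, chrom_length)
    n_probes = len(probes)
    p_chrom = probes["chromosome"].to_numpy()
    p_start = probes["start"].to_numpy()

    injected: list[InjectedSegment] = []
    for spec in segments:
        carriers = _draw_carriers(spec, metadata, rng_carriers)
        injected.append(InjectedSegment(
            chromosome=spec.chromosome, start_bp=spec.start_bp,
            end_bp=spec.end_bp, direction=spec.direction, shift=spec.shift,
            carriers=carriers))

    # true per-probe, per-sample mean shift
    shift_matrix = np.zeros((n_probes, n_samples))
    sample_pos = {s: j for j, s in enumerate(samples)}
    for seg in injected:
        mask = ((p_chrom == seg.chromosome) & (p_start >= seg.start_bp)
                & (p_start <= seg.end_bp))
        signed = seg.shift if seg.direction == "gain" else -seg.shift
        for s in seg.carriers:
            shift_matrix[mask, sample_pos[s]] += signed

    ratios = (shift_matrix
              + rng_probe.normal(0.0, noise.probe_sigma, (n_probes, n_samples))
              + noise.centering_offset)
    probe_frame = pd.concat(
        [probes, pd.DataFrame(ratios, columns=samples)], axis=1)
    probe_table = ProbeTable(probe_frame)

    # --- expression -------------------------------------------------------
    genes = annotation.frame.reset_index(drop=True)
    n_genes = len(genes)
    # gene x sample true copy log2: the summed shift of segments fully
    # covering the gene
    gene_cnv = np.zeros((n_genes, n_samples))
    dosage: list[tuple[str, float]] = []
    for i, g in genes.iterrows():
        covering = [seg for seg in injected
                    if seg.chromosome == g["chromosome"]
                    and seg.start_bp <= g["start"] and seg.end_bp >= g["end"]]
        if not covering:
            continue
        dosage.append((g["gene_symbol"], dosage_coefficient))
        for seg in covering:
            signed = seg.shift if seg.direction == "gain" else -seg.shift
            for s in seg.carriers:
                gene_cnv[i, sample_pos[s]] += signed
    dosage_names = {g for g, _ in dosage}
    null_genes = [g for g in genes["gene_symbol"] if g not in dosage_names]

    expr_samples = samples[:n_expression_pairs]
    expr_idx = [sample_pos[s] for s in expr_samples]
    lo, hi = expr_baseline_range
    baseline = rng_expr.uniform(lo, hi, n_genes)
    n_low = int(round(unexpressed_fraction * n_genes))
    if n_low:
        low_genes = rng_expr.choice(n_genes, size=n_low, replace=False)
        baseline[low_genes] = rng_expr.uniform(2.0, 3.5, n_low)
    # nulls have all-zero gene_cnv rows, so tumor = baseline + noise there
    tumor = (baseline[:, None]
             + dosage_coefficient * gene_cnv[:, expr_idx]
             + rng_expr.normal(0.0, noise.expr_sigma,
                               (n_genes, len(expr_samples))))
    normal = (baseline[:, None]
              + rng_expr.normal(0.0, noise.expr_sigma,
                                (n_genes, len(expr_samples))))
    cols = {}
    for j, s in enumerate(expr_samples):
        cols[s + "T"] = tumor[:, j]
        cols[s + "N"] = normal[:, j]
    expr_frame = pd.DataFrame(cols, index=pd.Index(genes["gene_symbol"],
                                                   name="gene_symbol"))
    expression = ExpressionMatrix(expr_frame)

    truth = SyntheticTruth(injected_segments=injected, dosage_genes=dosage,
                           null_genes=null_genes)
    return probe_table, expression, metadata, truth


def simulate_null_cohort(n_samples: int, n_probes: int,
                         noise: NoiseModel = NoiseModel(),
                         chromosome: str = "1",
                         chrom_length: int = CHROM_LENGTH_BP,
                         seed: int = 0) -> ProbeTable:
    """Pure-noise paired cohort (no injected segments), for false-positive
    rate estimation of the caller and the region scan."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    probes = _probe_frame((chromosome,), n_probes, chrom_length)
    samples = [f"s{i + 1:02d}" for i in range(n_samples)]
    ratios = rng.normal(0.0, noise.probe_sigma, (n_probes, n_samples)) \
        + noise.centering_offset
    frame = pd.concat([probes, pd.DataFrame(ratios, columns=samples)], axis=1)
    return ProbeTable(frame)
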