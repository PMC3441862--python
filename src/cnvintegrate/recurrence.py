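"""Genome-wide aberration frequencies, recurrent regions and minimal common regions.

Gains and losses are treated fully independently. A region is *recurrent*
when a maximal run of consecutive probes each carries the aberration in at
least ``ceil(recurrence_fraction * n_samples)`` samples. Within each
recurrent run, the *minimal common region* (MCR) is the sub-run where the
carrier count attains its maximum — the smallest interval shared by the most
samples; a run may contain several disjoint MCRs at the same peak count.

Frequencies are reported as ``count (percent)`` with nearest-integer percent,
sizes in Mb to two decimals computed from Mb-rounded endpoints.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datatypes import ProbeTable, RegionSummary, karyotype_rank
from .io import round_half_up


def frequency_percent(count: int, n_samples: int) -> int:
    """Nearest-integer percentage, half rounded up (19/27 -> 70)."""
    return int(round_half_up(100.0 * count / n_samples))


def recurrence_threshold(recurrence_fraction: float, n_samples: int) -> int:
    """Minimum carrier count for recurrence: ceil(fraction * n)."""
    return math.ceil(recurrence_fraction * n_samples)


def region_size_mb(start_bp: int, end_bp: int) -> float:
    """Region size in Mb at report precision.

    Endpoints are first rounded to 0.01 Mb (as printed in report tables) and
    the size is their difference, so printed bounds and printed sizes agree.
    """
    start_mb = round_half_up(start_bp / 1e6, 2)
    end_mb = round_half_up(end_bp / 1e6, 2)
    return round_half_up(end_mb - start_mb, 2)


def frequency_profile(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-probe gain/loss carrier counts from a rasterized call matrix.

    ``calls`` is the probe x sample int matrix from
    :func:`cnvintegrate.segmentation.call_matrix`.
    """
    values = calls.to_numpy()
    return pd.DataFrame({
        "gain_count": (values == 1).sum(axis=1),
        "loss_count": (values == -1).sum(axis=1),
    }, index=calls.index)


def _runs_at_least(counts: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Maximal runs (half-open index intervals) where counts >= k."""
    above = counts >= k
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(above))
    return list(zip(starts, stops))


def _summarize_run(table: ProbeTable, chrom_idx: np.ndarray, run: tuple[int, int],
                   direction: str, count: int, n_samples: int) -> RegionSummary:
    first = int(chrom_idx[run[0]])
    last = int(chrom_idx[run[1] - 1])
    start_bp = int(table.frame["start"].iloc[first])
    end_bp = int(table.frame["end"].iloc[last])
    return RegionSummary(
        direction=direction,
        chromosome=str(table.frame["chromosome"].iloc[first]),
        start_bp=start_bp, end_bp=end_bp,
        size_mb=region_size_mb(start_bp, end_bp),
        count=count, percent=frequency_percent(count, n_samples),
        n_samples=n_samples, first_probe=first, last_probe=last)


def recurrent_regions(table: ProbeTable, profile: pd.DataFrame,
                      recurrence_fraction: float, n_samples: int
                      ) -> list[RegionSummary]:
    """Maximal runs of probes with direction-specific carrier count >= threshold.

    The reported count of a run is its maximum probe-level carrier count
    (the frequency at which the aberration is most shared within the region).
    """
    table = table.drop_chromosomes(("Y",))
    if len(profile) != table.n_probes:
        raise ValueError("profile and probe table lengths differ")
    k = recurrence_threshold(recurrence_fraction, n_samples)
    chroms = table.frame["chromosome"].to_numpy()
    out: list[RegionSummary] = []
    for chrom in table.chromosomes():
        chrom_idx = np.flatnonzero(chroms == chrom)
        for direction, col in (("gain", "gain_count"), ("loss", "loss_count")):
            counts = profile[col].to_numpy()[chrom_idx]
            for run in _runs_at_least(counts, k):
                peak = int(counts[run[0]:run[1]].max())
                out.append(_summarize_run(table, chrom_idx, run, direction,
                                          peak, n_samples))
    out.sort(key=lambda r: (karyotype_rank(r.chromosome), r.start_bp, r.direction))
    return out


def minimal_common_regions(table: ProbeTable, profile: pd.DataFrame,
                           recurrence_fraction: float, n_samples: int
                           ) -> list[RegionSummary]:
    """MCRs: within each recurrent run, the sub-run(s) at the peak carrier count."""
    table = table.drop_chromosomes(("Y",))
    k = recurrence_threshold(recurrence_fraction, n_samples)
    chroms = table.frame["chromosome"].to_numpy()
    out: list[RegionSummary] = []
    for chrom in table.chromosomes():
        chrom_idx = np.flatnonzero(chroms == chrom)
        for direction, col in (("gain", "gain_count"), ("loss", "loss_count")):
            counts = profile[col].to_numpy()[chrom_idx]
            for run_start, run_stop in _runs_at_least(counts, k):
                window = counts[run_start:run_stop]
                peak = int(window.max())
                for sub in _runs_at_least(window, peak):
                    run = (run_start + sub[0], run_start + sub[1])
                    out.append(_summarize_run(table, chrom_idx, run, direction,
                                              peak, n_samples))
    out.sort(key=lambda r: (karyotype_rank(r.chromosome), r.start_bp, r.direction))
    return out


def annotate_target_genes(region: RegionSummary, dosage_results: pd.DataFrame,
                          target_fc_cutoff: float = 2.0) -> RegionSummary:
    """Attach target genes: dosage FC >= cutoff in gains, <= 1/cutoff in losses.

    ``dosage_results`` is the gene-level integration table (needs columns
    gene_symbol, chromosome, start, end, fc).
    """
    required = {"gene_symbol", "chromosome", "start", "end", "fc"}
    if not required.issubset(dosage_results.columns):
        raise ValueError("integration results required before target-gene annotation")
    df = dosage_results
    inside = ((df["chromosome"] == region.chromosome)
              & (df["end"] >= region.start_bp) & (df["start"] <= region.end_bp))
    sub = df.loc[inside].dropna(subset=["fc"])
    if region.direction == "gain":
        hits = sub.loc[sub["fc"] >= target_fc_cutoff, "gene_symbol"]
    else:
        hits = sub.loc[sub["fc"] <= 1.0 / target_fc_cutoff, "gene_symbol"]
    region.target_genes = hits.tolist()
    return region
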