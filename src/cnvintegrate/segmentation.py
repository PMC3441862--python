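"""Per-sample aberration detection from probe log2 ratios.

The pipeline mirrors how commercial aCGH callers process a two-colour array:

1. *Centralization* — re-centre each sample's log2 ratio distribution so the
   dominant copy-neutral population sits at zero (histogram mode with
   parabolic refinement).
2. *Noise estimation* — a robust derivative-based spread estimate
   ``sigma = median(|r[i+1] - r[i]|) / (0.6745 * sqrt(2))`` over adjacent
   same-chromosome probes, insensitive to the aberrations themselves.
3. *Segmentation* — recursive maximal-scoring-interval search: the interval
   score ``S(I) = |mean(r over I)| * sqrt(|I|) / sigma`` is the mean deviation
   in noise-s.d. units scaled by the square root of the probe count; the
   best-scoring interval with ``S >= adm_threshold`` is called and the search
   recurses on both flanks.
4. *Filters* — minimum probe count, a minimum |mean log2| amplitude floor
   that suppresses shallow near-zero calls, and a cap on calls per sample.

Chromosome Y is excluded before calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import ProbeTable, SegmentCall

_MAD_TO_SIGMA = 0.6745  # Phi^-1(0.75): MAD -> s.d. for Gaussian noise
_SIGMA_FLOOR = 1e-8


@dataclass(frozen=True)
class NoiseEstimate:
    """Robust per-sample probe-to-probe spread of log2 ratios."""

    sigma_hat: float

    def __post_init__(self) -> None:
        if not self.sigma_hat > 0:
            raise ValueError("sigma_hat must be positive")


def centralize(ratios: np.ndarray, bin_width: float = 0.01) -> tuple[np.ndarray, float]:
    """Centre one sample's log2 ratios on the dominant copy-neutral mode.

    The offset is the mode of a fixed-width histogram (default bin 0.01),
    refined by fitting a parabola through the modal bin and its neighbours.
    Returns ``(centered_ratios, offset)``.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("cannot centralize an empty ratio vector")
    if ratios.size < 100:
        warnings.warn("fewer than 100 probes: centralization mode estimate is noisy",
                      stacklevel=2)
    lo, hi = ratios.min(), ratios.max()
    if hi - lo < bin_width:  # effectively constant input
        offset = float(np.median(ratios))
        return ratios - offset, offset
    edges = np.arange(lo, hi + 2 * bin_width, bin_width)
    counts, edges = np.histogram(ratios, bins=edges)
    k = int(np.argmax(counts))
    centre = 0.5 * (edges[k] + edges[k + 1])
    if 0 < k < len(counts) - 1:
        y0, y1, y2 = counts[k - 1], counts[k], counts[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            # vertex of the parabola through the three bin counts
            shift = 0.5 * (y0 - y2) / denom
            centre += np.clip(shift, -0.5, 0.5) * bin_width
    offset = float(centre)
    return ratios - offset, offset


def estimate_noise(centered: np.ndarray, chromosomes: np.ndarray) -> NoiseEstimate:
    """Derivative-based spread: median |adjacent difference| within chromosomes.

    The first difference of the ratio track cancels any piecewise-constant
    copy-number signal, so the estimate reflects probe noise alone; dividing
    by ``0.6745 * sqrt(2)`` calibrates the median absolute difference of two
    independent Gaussians back to the per-probe s.d.
    """
    centered = np.asarray(centered, dtype=float)
    chromosomes = np.asarray(chromosomes)
    diffs = np.abs(np.diff(centered))
    same_chrom = chromosomes[1:] == chromosomes[:-1]
    diffs = diffs[same_chrom]
    if diffs.size == 0:
        raise ValueError("need at least 2 probes on some chromosome to estimate noise")
    sigma = float(np.median(diffs) / (_MAD_TO_SIGMA * np.sqrt(2.0)))
    return NoiseEstimate(sigma_hat=max(sigma, _SIGMA_FLOOR))


def best_scoring_interval(ratios: np.ndarray, sigma: float
                          ) -> tuple[int, int, float]:
    """Highest-scoring interval of ``ratios``; ties -> leftmost, then shortest.

    Returns ``(start, stop, score)`` with a half-open probe-index interval.
    Score of [i, j) is ``|prefix[j] - prefix[i]| / sqrt(j - i) / sigma``.
    """
    r = np.asarray(ratios, dtype=float)
    n = r.size
    prefix = np.concatenate(([0.0], np.cumsum(r)))
    best_score, best_start, best_len = -1.0, 0, 1
    for length in range(1, n + 1):  # ascending: shorter wins exact ties
        sums = np.abs(prefix[length:] - prefix[:-length])
        k = int(np.argmax(sums))  # leftmost among equal sums
        score = sums[k] / np.sqrt(length) / sigma
        if score > best_score and not np.isclose(score, best_score, rtol=0, atol=1e-12):
            best_score, best_start, best_len = score, k, length
        elif np.isclose(score, best_score, rtol=0, atol=1e-12) and k < best_start:
            best_score, best_start, best_len = score, k, length
    return best_start, best_start + best_len, best_score


def _recurse_intervals(r: np.ndarray, offset: int, sigma: float, threshold: float,
                       out: list[tuple[int, int, float]]) -> None:
    if r.size == 0:
        return
    start, stop, score = best_scoring_interval(r, sigma)
    if score < threshold:
        return
    out.append((offset + start, offset + stop, score))
    _recurse_intervals(r[:start], offset, sigma, threshold, out)
    _recurse_intervals(r[stop:], offset + stop, sigma, threshold, out)


def segment_sample(centered: np.ndarray, chromosomes: np.ndarray,
                   starts: np.ndarray, ends: np.ndarray,
                   noise: NoiseEstimate, config: PipelineConfig,
                   sample_id: str = "sample") -> list[SegmentCall]:
    """Segment one sample's centred ratio track into aberration calls.

    Probes must be in genome order; each chromosome is searched independently
    and the aberration filters (min probes, amplitude floor, region cap) are
    applied across the whole sample afterwards.
    """
    centered = np.asarray(centered, dtype=float)
    chromosomes = np.asarray(chromosomes)
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    order_ok = np.all(np.diff(starts)[chromosomes[1:] == chromosomes[:-1]] >= 0)
    if not order_ok:
        raise ValueError("probes must be sorted by genomic position within chromosomes")

    calls: list[SegmentCall] = []
    for chrom in pd.unique(chromosomes):
        if chrom == "Y":
            continue
        mask = chromosomes == chrom
        idx = np.flatnonzero(mask)
        r = centered[idx]
        found: list[tuple[int, int, float]] = []
        _recurse_intervals(r, 0, noise.sigma_hat, config.adm_threshold, found)
        for start, stop, score in found:
            mean_log2 = float(r[start:stop].mean())
            n_probes = stop - start
            if n_probes < config.min_probes:
                continue
            if abs(mean_log2) < config.min_abs_mean:
                continue
            first, last = idx[start], idx[stop - 1]
            calls.append(SegmentCall(
                sample_id=sample_id, chromosome=str(chrom),
                start_bp=int(starts[first]), end_bp=int(ends[last]),
                n_probes=n_probes, mean_log2=mean_log2, score=float(score),
                first_probe=int(first), last_probe=int(last)))
    calls.sort(key=lambda c: -c.score)
    calls = calls[: config.max_regions]
    calls.sort(key=lambda c: (c.first_probe,))
    return calls


def segment_cohort(table: ProbeTable, config: PipelineConfig
                   ) -> dict[str, list[SegmentCall]]:
    """Centralize, estimate noise and segment every sample of a cohort.

    Chromosome Y is dropped before calling; returns calls per sample id.
    """
    table = table.drop_chromosomes(("Y",))
    chroms = table.frame["chromosome"].to_numpy()
    starts = table.frame["start"].to_numpy()
    ends = table.frame["end"].to_numpy()
    out: dict[str, list[SegmentCall]] = {}
    for sample in table.samples:
        raw = table.frame[sample].to_numpy(dtype=float)
        centered, _ = centralize(raw)
        noise = estimate_noise(centered, chroms)
        out[sample] = segment_sample(centered, chroms, starts, ends, noise,
                                     config, sample_id=sample)
    return out


def call_matrix(table: ProbeTable, calls: dict[str, list[SegmentCall]]
                ) -> pd.DataFrame:
    """Rasterize segment calls onto probes: +1 gain, -1 loss, 0 neutral.

    Indexed by probe_id with one int8 column per sample; probes on
    chromosomes excluded from calling stay neutral.
    """
    table = table.drop_chromosomes(("Y",))
    n = table.n_probes
    chroms = table.frame["chromosome"].to_numpy()
    starts = table.frame["start"].to_numpy()
    mat = np.zeros((n, len(table.samples)), dtype=np.int8)
    for j, sample in enumerate(table.samples):
        for call in calls.get(sample, []):
            on_chrom = chroms == call.chromosome
            covered = on_chrom & (starts >= call.start_bp) & (starts <= call.end_bp)
            mat[covered, j] = 1 if call.direction == "gain" else -1
    return pd.DataFrame(mat, index=table.frame["probe_id"], columns=table.samples)
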