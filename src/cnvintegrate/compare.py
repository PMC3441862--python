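"""Region-wise Fisher exact scans for copy-number differences between
clinical groups (histology PD vs MD, tumor stage T1-2 vs T3-4, nodal stage
N0 vs N1-3).

Each region contributes a 2 groups x 3 states (gain / neutral / loss) table
of sample counts; the two-sided conditional exact p-value is computed by full
enumeration of all tables with the observed margins, summing the
hypergeometric probabilities of every table no more probable than the
observed one. Chromosomes X and Y are excluded (sex-linked dosage would bias
the counts), samples with partial signet-ring histology are excluded, and a
region is only tested when at least a configurable fraction (default 25%) of
one group carries classifying gains or losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .datatypes import RegionSummary, SampleMetadata

_STATE_GAIN, _STATE_NEUTRAL, _STATE_LOSS = 1, 0, -1


@dataclass
class GroupContrast:
    """Two disjoint sample groups plus the samples excluded from both."""

    name: str
    group_a: list[str]
    group_b: list[str]
    excluded: dict[str, str] = field(default_factory=dict)  # sample -> reason

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("contrast groups must be disjoint")
        if not self.group_a or not self.group_b:
            raise ValueError(f"contrast {self.name!r} has an empty group")


@dataclass
class RegionComparison:
    region: RegionSummary
    counts: np.ndarray  # 2x3: rows group_a/group_b, cols gain/neutral/loss
    p_value: float
    fdr: float = float("nan")
    significant: bool = False


def build_contrasts(metadata: SampleMetadata) -> list[GroupContrast]:
    """The three clinical contrasts, with exclusion bookkeeping.

    Samples flagged as partial signet-ring cell carcinoma (SRCC) are removed
    from every contrast; mixed-histology (M-PD) samples are additionally
    excluded from the PD-vs-MD comparison.
    """
    df = metadata.frame
    srcc = dict.fromkeys(df.loc[df["srcc_flag"], "sample_id"],
                         "partial signet-ring cell carcinoma")
    usable = df.loc[~df["srcc_flag"]]

    contrasts: list[GroupContrast] = []

    pd_ids = usable.loc[usable["histology"] == "PD", "sample_id"].tolist()
    md_ids = usable.loc[usable["histology"] == "MD", "sample_id"].tolist()
    mpd = dict.fromkeys(
        usable.loc[usable["histology"] == "M-PD", "sample_id"],
        "mixed histology (M-PD)")
    contrasts.append(GroupContrast("PD-vs-MD", pd_ids, md_ids,
                                   excluded={**srcc, **mpd}))

    early = usable.loc[usable["t_stage"].isin(["T1", "T2"]), "sample_id"].tolist()
    late = usable.loc[usable["t_stage"].isin(["T3", "T4"]), "sample_id"].tolist()
    contrasts.append(GroupContrast("T12-vs-T34", early, late, excluded=dict(srcc)))

    n0 = usable.loc[usable["n_stage"] == "N0", "sample_id"].tolist()
    npos = usable.loc[usable["n_stage"].isin(["N1", "N2", "N3"]),
                      "sample_id"].tolist()
    contrasts.append(GroupContrast("N0-vs-N13", n0, npos, excluded=dict(srcc)))
    return contrasts


def region_sample_states(region: RegionSummary, calls: pd.DataFrame,
                         probe_table_frame: pd.DataFrame,
                         overlap_fraction: float = 0.5) -> pd.Series:
    """Per-sample region state in {+1 gain, 0 neutral, -1 loss}.

    A sample counts as gained (lost) when calls of that direction cover at
    least ``overlap_fraction`` of the region's probes.
    """
    chroms = probe_table_frame["chromosome"].to_numpy()
    starts = probe_table_frame["start"].to_numpy()
    if len(probe_table_frame) != len(calls):
        raise ValueError("call matrix must align row-for-row with the probe table")
    in_region = ((chroms == region.chromosome)
                 & (starts >= region.start_bp) & (starts <= region.end_bp))
    sub = calls.iloc[np.flatnonzero(in_region)]
    if sub.empty:
        return pd.Series(_STATE_NEUTRAL, index=calls.columns, dtype=np.int8)
    vals = sub.to_numpy()
    gain_frac = (vals == 1).mean(axis=0)
    loss_frac = (vals == -1).mean(axis=0)
    states = np.zeros(vals.shape[1], dtype=np.int8)
    states[gain_frac >= overlap_fraction] = _STATE_GAIN
    states[loss_frac >= overlap_fraction] = _STATE_LOSS
    return pd.Series(states, index=calls.columns)


def region_table(states: pd.Series, contrast: GroupContrast) -> np.ndarray:
    """2x3 counts (gain, neutral, loss) per group from per-sample states."""
    table = np.zeros((2, 3), dtype=int)
    for row, group in enumerate((contrast.group_a, contrast.group_b)):
        sub = states.loc[group]
        table[row] = [(sub == _STATE_GAIN).sum(), (sub == _STATE_NEUTRAL).sum(),
                      (sub == _STATE_LOSS).sum()]
    return table


def fisher_exact_rxc(counts: np.ndarray) -> float:
    """Two-sided conditional exact p for a 2x3 (or 2xc) contingency table.

    Enumerates every table with the observed margins and sums the
    multivariate-hypergeometric probabilities of all tables whose probability
    does not exceed that of the observed table. Degenerate margins give p=1.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or counts.shape[0] != 2:
        raise ValueError("expected a 2xc table")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    n = counts.sum()
    if n == 0 or (row == 0).any() or (col[col > 0].size <= 1):
        return 1.0

    log_const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)

    def log_prob(top: np.ndarray) -> float:
        bottom = col - top
        return float(log_const - gammaln(top + 1).sum() - gammaln(bottom + 1).sum())

    lp_obs = log_prob(counts[0])
    r1 = row[0]
    total = 0.0
    c = col
    tol = 1e-9  # ties in probability count as "as extreme"
    for a in range(max(0, r1 - c[1] - c[2]), min(r1, c[0]) + 1):
        for b in range(max(0, r1 - a - c[2]), min(r1 - a, c[1]) + 1):
            top = np.array([a, b, r1 - a - b])
            lp = log_prob(top)
            if lp <= lp_obs + tol:
                total += np.exp(lp)
    return float(min(total, 1.0))


def scan_regions(regions: list[RegionSummary], calls: pd.DataFrame,
                 probe_table_frame: pd.DataFrame, contrast: GroupContrast,
                 config: PipelineConfig) -> list[RegionComparison]:
    """Fisher-scan regions for group differences in copy-number state.

    Regions on X/Y are skipped; regions where no group reaches the
    classifying-fraction of gains or losses are skipped before testing.
    The ``significant`` flag uses the raw p < alpha rule; Benjamini-Hochberg
    FDR across the tested regions is reported alongside.
    """
    results: list[RegionComparison] = []
    sizes = np.array([len(contrast.group_a), len(contrast.group_b)], dtype=float)
    for region in regions:
        if region.chromosome in ("X", "Y"):
            continue
        states = region_sample_states(region, calls, probe_table_frame,
                                      config.region_overlap_fraction)
        table = region_table(states, contrast)
        class_frac = np.maximum(table[:, 0], table[:, 2]) / sizes
        if class_frac.max() < config.classifying_fraction:
            continue
        p = fisher_exact_rxc(table)
        results.append(RegionComparison(region=region, counts=table, p_value=p))
    if results:
        pvals = [r.p_value for r in results]
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, fdr):
            r.fdr = float(q)
            r.significant = r.p_value < config.alpha
    return results


def comparisons_frame(results: list[RegionComparison]) -> pd.DataFrame:
    rows = [{
        "chromosome": r.region.chromosome, "start_bp": r.region.start_bp,
        "end_bp": r.region.end_bp, "direction": r.region.direction,
        "a_gain": r.counts[0, 0], "a_neutral": r.counts[0, 1],
        "a_loss": r.counts[0, 2], "b_gain": r.counts[1, 0],
        "b_neutral": r.counts[1, 1], "b_loss": r.counts[1, 2],
        "p_value": r.p_value, "fdr": r.fdr, "significant": r.significant,
    } for r in results]
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp",
                                       "direction", "a_gain", "a_neutral",
                                       "a_loss", "b_gain", "b_neutral",
                                       "b_loss", "p_value", "fdr",
                                       "significant"])
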