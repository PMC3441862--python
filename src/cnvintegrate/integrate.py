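"""Gene-level integration of copy number and expression.

Only genes inside recurrent aberration regions are analysed; gains and
losses are treated separately. For each gene:

* the gene-level copy ratio per sample is the mean log2 ratio of the aCGH
  probes overlapping the gene (genes touching no probe are flagged and
  excluded);
* a sample is CNV-positive when that ratio exceeds the 1.5-fold bound
  (|log2| >= 0.585) in the region's direction;
* the dosage fold change FC is the ratio of median *linear* tumor expression
  in CNV-positive vs CNV-negative samples, with selection flags at 1.3-fold
  and 2-fold (reciprocal bounds for losses);
* the Pearson correlation between the gene's copy log2 ratio and its
  tumor-minus-normal expression log2 ratio is tested via the t-transform
  ``t = r * sqrt(n-2) / sqrt(1-r^2)`` and Benjamini-Hochberg adjusted across
  the analysed genes.

A per-region two-sample t-test (tumor vs matched normal signals) supports
the differential screen used for dense gained regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .datatypes import ExpressionMatrix, GeneAnnotation, ProbeTable, RegionSummary


def gene_copy_ratio(table: ProbeTable, annotation: GeneAnnotation) -> pd.DataFrame:
    """Mean probe log2 ratio per gene and sample.

    Overlap is any base-pair intersection on 1-based inclusive intervals.
    Genes overlapping no probe get NaN rows (the "lack of aCGH data" flag)
    and are excluded from downstream dosage analysis.
    """
    probes = table.frame
    ratios = table.ratios()
    out = np.full((len(annotation.frame), len(table.samples)), np.nan)
    chrom_groups = {c: np.flatnonzero(probes["chromosome"].to_numpy() == c)
                    for c in table.chromosomes()}
    p_start = probes["start"].to_numpy()
    p_end = probes["end"].to_numpy()
    for i, gene in annotation.frame.reset_index(drop=True).iterrows():
        idx = chrom_groups.get(gene["chromosome"])
        if idx is None:
            continue
        hit = idx[(p_end[idx] >= gene["start"]) & (p_start[idx] <= gene["end"])]
        if hit.size:
            out[i] = ratios[hit].mean(axis=0)
    return pd.DataFrame(out, index=annotation.frame["gene_symbol"],
                        columns=table.samples)


def classify_cnv(gene_log2: pd.Series, direction: str,
                 cnv_call_log2: float = 0.585) -> pd.Series:
    """CNV-positive booleans per sample, inclusive at the threshold."""
    if direction == "gain":
        return gene_log2 >= cnv_call_log2
    if direction == "loss":
        return gene_log2 <= -cnv_call_log2
    raise ValueError(f"direction must be gain or loss, got {direction!r}")


def expression_filter(expression: ExpressionMatrix,
                      expr_signal_cutoff: float = 3.9) -> ExpressionMatrix:
    """Drop unexpressed genes: mean log2 signal across all arrays must exceed
    the cutoff (strictly)."""
    means = expression.frame.mean(axis=1)
    return ExpressionMatrix(expression.frame.loc[means > expr_signal_cutoff])


def dosage_fc(tumor_log2: pd.Series, cnv_positive: pd.Series, direction: str,
              fc_cutoff: float = 1.3, target_fc_cutoff: float = 2.0
              ) -> tuple[float, bool, bool]:
    """Fold change of median linear tumor expression, CNV+ over CNV-.

    Returns ``(fc, selected_at_fc_cutoff, selected_at_target_cutoff)``;
    ``fc`` is NaN when either group is empty. Selection is inclusive at the
    cutoff, with reciprocal bounds for loss regions.
    """
    linear = np.power(2.0, tumor_log2)
    pos = linear[cnv_positive.reindex(tumor_log2.index, fill_value=False)]
    neg = linear[~cnv_positive.reindex(tumor_log2.index, fill_value=False)]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan"), False, False
    fc = float(np.median(pos) / np.median(neg))
    if direction == "gain":
        return fc, fc >= fc_cutoff, fc >= target_fc_cutoff
    return fc, fc <= 1.0 / fc_cutoff, fc <= 1.0 / target_fc_cutoff


def dosage_correlation(gene_log2: np.ndarray, expr_log2_ratio: np.ndarray
                       ) -> tuple[float, float]:
    """Pearson r between copy and expression log2 ratios, with two-sided p
    from the exact t-transform. Returns (nan, nan) on degenerate input."""
    x = np.asarray(gene_log2, dtype=float)
    y = np.asarray(expr_log2_ratio, dtype=float)
    if x.size != y.size or x.size < 3:
        return float("nan"), float("nan")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def differential_ttest(tumor: pd.DataFrame, normal: pd.DataFrame) -> pd.DataFrame:
    """Equal-variance two-sample t-test, tumor vs normal arrays, per gene.

    Genes with zero pooled variance get p=1 when the means agree and p=0
    otherwise.
    """
    genes = tumor.index
    t_vals = np.empty(len(genes))
    p_vals = np.empty(len(genes))
    for i, g in enumerate(genes):
        a = tumor.loc[g].to_numpy(dtype=float)
        b = normal.loc[g].to_numpy(dtype=float)
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            equal = np.isclose(a.mean(), b.mean())
            t_vals[i], p_vals[i] = 0.0 if equal else np.inf, 1.0 if equal else 0.0
            continue
        t_vals[i], p_vals[i] = stats.ttest_ind(a, b, equal_var=True)
    return pd.DataFrame({"t": t_vals, "p_value": p_vals}, index=genes)


def _gene_regions(annotation: GeneAnnotation, regions: list[RegionSummary]
                  ) -> pd.DataFrame:
    """Assign each gene the first recurrent region it intersects (if any)."""
    genes = annotation.frame.reset_index(drop=True)
    region_name = np.array([None] * len(genes), dtype=object)
    direction = np.array([None] * len(genes), dtype=object)
    for r in regions:
        hit = ((genes["chromosome"] == r.chromosome)
               & (genes["end"] >= r.start_bp) & (genes["start"] <= r.end_bp)
               & pd.isna(region_name))
        region_name[hit.to_numpy()] = r.name
        direction[hit.to_numpy()] = r.direction
    out = genes[["gene_symbol", "chromosome", "start", "end"]].copy()
    out["region"] = region_name
    out["direction"] = direction
    return out


def integrate_cohort(table: ProbeTable, expression: ExpressionMatrix,
                     annotation: GeneAnnotation, regions: list[RegionSummary],
                     config: PipelineConfig) -> pd.DataFrame:
    """Full gene-level dosage table for genes in recurrent regions.

    Columns mirror a supplementary-style report: mean normal/tumor signal,
    FC, mean aCGH log2 in CNV+ cases, CNV+ frequency, Pearson r, p, FDR and
    the selection flags. Samples are the intersection of the aCGH and
    expression cohorts.
    """
    expression = expression_filter(expression, config.expr_signal_cutoff)
    samples = [s for s in expression.samples if s in table.samples]
    if not samples:
        raise ValueError("no samples shared between probe table and expression")
    copy_ratio = gene_copy_ratio(table, annotation)
    gene_map = _gene_regions(annotation, regions)
    tumor = expression.tumor()[samples]
    normal = expression.normal()[samples]
    tn_ratio = expression.tn_log2_ratio()[samples]

    rows = []
    for _, g in gene_map.iterrows():
        gene = g["gene_symbol"]
        if g["region"] is None or gene not in expression.frame.index:
            continue
        log2_cnv = copy_ratio.loc[gene, samples]
        if log2_cnv.isna().any():
            rows.append({"gene_symbol": gene, "region": g["region"],
                         "chromosome": g["chromosome"], "start": g["start"],
                         "end": g["end"], "direction": g["direction"],
                         "lack_acgh_data": True})
            continue
        direction = g["direction"]
        cnv_pos = classify_cnv(log2_cnv, direction, config.cnv_call_log2)
        fc, sel13, sel20 = dosage_fc(tumor.loc[gene], cnv_pos, direction,
                                     config.fc_cutoff, config.target_fc_cutoff)
        r, p = dosage_correlation(log2_cnv.to_numpy(),
                                  tn_ratio.loc[gene].to_numpy())
        acgh_pos_mean = (float(log2_cnv[cnv_pos].mean()) if cnv_pos.any()
                         else float("nan"))
        rows.append({
            "gene_symbol": gene, "region": g["region"],
            "chromosome": g["chromosome"], "start": g["start"], "end": g["end"],
            "direction": direction, "lack_acgh_data": False,
            "normal_mean": float(normal.loc[gene].mean()),
            "tumor_mean": float(tumor.loc[gene].mean()),
            "fc": fc, "acgh_log2_cnv_pos": acgh_pos_mean,
            "n_cnv_pos": int(cnv_pos.sum()),
            "pearson_r": r, "p_value": p,
            "selected_1p3": sel13, "selected_2fold": sel20,
        })
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    tested = result["p_value"].notna() if "p_value" in result else pd.Series(dtype=bool)
    result["fdr"] = np.nan
    result["significant_correlation"] = False
    if tested.any():
        _, q, _, _ = multipletests(result.loc[tested, "p_value"], method="fdr_bh")
        result.loc[tested, "fdr"] = q
        result.loc[tested, "significant_correlation"] = (
            result.loc[tested, "p_value"] < config.alpha)
    return result


def percent_significant(n_significant: int, n_tested: int) -> float:
    """Reporting arithmetic: share of tested genes with significant
    correlation, one decimal (e.g. 133 of 163 -> 81.6)."""
    from .io import round_half_up

    return round_half_up(100.0 * n_significant / n_tested, 1)
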