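"""Relative quantification of validation genes by the 2^-ddCt method.

Each reaction is run in triplicate and normalised to the ACTB internal
control: dCt = mean(target Ct) - mean(reference Ct) within a sample;
ddCt = dCt(tumor) - dCt(matched normal calibrator); RQ = 2^-ddCt. Perfect
doubling per cycle is assumed (no efficiency correction). Replicate spread
above 0.5 cycles attaches a quality warning but does not drop the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .integrate import dosage_correlation

REPLICATE_SD_LIMIT = 0.5  # cycles


@dataclass
class CtRecord:
    sample_id: str
    gene_symbol: str
    ct_replicates: tuple[float, float, float]
    reference_ct_replicates: tuple[float, float, float]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, reps in (("target", self.ct_replicates),
                           ("reference", self.reference_ct_replicates)):
            if len(reps) != 3:
                raise ValueError(f"{name} Ct must have exactly 3 replicates")
            if not all(0 < c < 45 for c in reps):
                raise ValueError(f"{name} Ct values must lie in (0, 45) cycles")
            if float(np.std(reps, ddof=1)) > REPLICATE_SD_LIMIT:
                self.warnings.append(
                    f"{name} replicate s.d. exceeds {REPLICATE_SD_LIMIT} cycles")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.ct_replicates)
                     - np.mean(self.reference_ct_replicates))


def relative_quantity(target: CtRecord, calibrator: CtRecord) -> float:
    """RQ = 2^-(dCt_target - dCt_calibrator) for a tumor/normal pair."""
    if target.gene_symbol != calibrator.gene_symbol:
        raise ValueError("target and calibrator must assay the same gene")
    ddct = target.delta_ct - calibrator.delta_ct
    return float(2.0 ** (-ddct))


def rq_table(tumor_records: list[CtRecord], normal_records: list[CtRecord]
             ) -> pd.DataFrame:
    """Per (gene, sample) RQ values using the matched normal as calibrator."""
    normals = {(r.gene_symbol, r.sample_id): r for r in normal_records}
    rows = []
    for rec in tumor_records:
        key = (rec.gene_symbol, rec.sample_id)
        if key not in normals:
            raise ValueError(f"no matched normal Ct record for {key}")
        rq = relative_quantity(rec, normals[key])
        rows.append({"gene_symbol": rec.gene_symbol, "sample_id": rec.sample_id,
                     "rq": rq, "log2_rq": float(np.log2(rq)),
                     "qc_warnings": "; ".join(rec.warnings + normals[key].warnings)})
    return pd.DataFrame(rows)


def validation_correlation(rq: pd.DataFrame, gene_log2_cnv: pd.DataFrame
                           ) -> pd.DataFrame:
    """Pearson r between log2(RQ) and gene-level copy log2 ratio, per gene.

    Genes with fewer than 3 assayed samples are skipped; BH FDR is computed
    across the tested genes. ``gene_log2_cnv`` is indexed by gene with one
    column per sample (as produced by ``integrate.gene_copy_ratio``).
    """
    rows = []
    for gene, sub in rq.groupby("gene_symbol"):
        if gene not in gene_log2_cnv.index:
            continue
        samples = [s for s in sub["sample_id"] if s in gene_log2_cnv.columns]
        if len(samples) < 3:
            continue
        sub = sub.set_index("sample_id").loc[samples]
        x = gene_log2_cnv.loc[gene, samples].to_numpy(dtype=float)
        y = sub["log2_rq"].to_numpy(dtype=float)
        r, p = dosage_correlation(x, y)
        rows.append({"gene_symbol": gene, "n": len(samples),
                     "pearson_r": r, "p_value": p})
    out = pd.DataFrame(rows, columns=["gene_symbol", "n", "pearson_r", "p_value"])
    out["fdr"] = np.nan
    tested = out["p_value"].notna()
    if tested.any():
        _, q, _, _ = multipletests(out.loc[tested, "p_value"], method="fdr_bh")
        out.loc[tested, "fdr"] = q
    return out
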