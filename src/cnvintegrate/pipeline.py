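"""End-to-end orchestration: segmentation -> recurrence -> subtype scan ->
integration -> clustering, over one cohort."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cluster as _cluster
from . import compare as _compare
from . import integrate as _integrate
from . import recurrence as _recurrence
from . import segmentation as _segmentation
from .config import PipelineConfig
from .datatypes import (
    ExpressionMatrix,
    GeneAnnotation,
    ProbeTable,
    RegionSummary,
    SampleMetadata,
    SegmentCall,
)


@dataclass
class PipelineResult:
    calls: dict[str, list[SegmentCall]]
    call_matrix: pd.DataFrame
    frequency_profile: pd.DataFrame
    recurrent_regions: list[RegionSummary]
    mcrs: list[RegionSummary]
    comparisons: dict[str, list[_compare.RegionComparison]]
    dosage: pd.DataFrame
    clustering: _cluster.ClusterResult | None


def run_pipeline(probe_table: ProbeTable, expression: ExpressionMatrix,
                 metadata: SampleMetadata, annotation: GeneAnnotation,
                 config: PipelineConfig) -> PipelineResult:
    """Run every analysis stage on a loaded cohort."""
    n_samples = len(probe_table.samples)
    calls = _segmentation.segment_cohort(probe_table, config)
    cm = _segmentation.call_matrix(probe_table, calls)
    table_no_y = probe_table.drop_chromosomes(("Y",))
    profile = _recurrence.frequency_profile(cm)
    regions = _recurrence.recurrent_regions(
        table_no_y, profile, config.recurrence_fraction, n_samples)
    mcrs = _recurrence.minimal_common_regions(
        table_no_y, profile, config.recurrence_fraction, n_samples)

    comparisons = {}
    for contrast in _compare.build_contrasts(metadata):
        comparisons[contrast.name] = _compare.scan_regions(
            regions, cm, table_no_y.frame, contrast, config)

    dosage = _integrate.integrate_cohort(probe_table, expression, annotation,
                                         regions, config)
    for region in mcrs + regions:
        if not dosage.empty and "fc" in dosage.columns:
            _recurrence.annotate_target_genes(region, dosage,
                                              config.target_fc_cutoff)

    clustering = None
    if not dosage.empty and "selected_1p3" in dosage.columns:
        selected = dosage.loc[dosage["selected_1p3"] == True,  # noqa: E712
                              "gene_symbol"].tolist()
        if len(selected) >= 2:
            kept = _integrate.expression_filter(
                expression, config.expr_signal_cutoff)
            matrix = kept.frame.loc[[g for g in selected
                                     if g in kept.frame.index]]
            # median-centre each gene across arrays (heatmap-display
            # convention) before the two-way clustering
            centred = matrix.sub(matrix.median(axis=1), axis=0)
            tissue = pd.Series({c: c[-1] for c in centred.columns})
            if centred.shape[0] >= 2 and centred.shape[1] >= 2:
                clustering = _cluster.two_way_cluster(centred, tissue)

    return PipelineResult(
        calls=calls, call_matrix=cm, frequency_profile=profile,
        recurrent_regions=regions, mcrs=mcrs, comparisons=comparisons,
        dosage=dosage, clustering=clustering)
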