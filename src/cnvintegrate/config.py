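"""Pipeline configuration shared by every analysis stage.

All thresholds live in one place so that a run is fully described by a
config + seed pair, and so that every output file can carry the same
fingerprint in its header.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and options governing the whole pipeline.

    Attributes
    ----------
    adm_threshold : float
        Minimum interval score ``|mean| * sqrt(n_probes) / sigma`` for an
        aberration call.
    min_probes : int
        Minimum number of probes in a surviving aberration region.
    min_abs_mean : float
        Minimum absolute mean log2 ratio of a region (0.5 corresponds to a
        1.4-fold copy-number change); suppresses shallow near-zero calls.
    max_regions : int
        Cap on aberration regions per sample; the top-scoring calls are kept.
    recurrence_fraction : float
        Fraction of samples required for an aberration to count as recurrent.
    fc_cutoff : float
        Expression fold-change cutoff for dosage-gene selection.
    target_fc_cutoff : float
        Stricter fold-change cutoff used to nominate target genes of a region.
    cnv_call_log2 : float
        Per-gene |log2 ratio| at which a sample counts as CNV-positive
        (0.585 corresponds to a 1.5-fold change).
    expr_signal_cutoff : float
        Mean log2 expression signal below which a gene is considered
        unexpressed and dropped.
    alpha : float
        Raw significance level for the Fisher scan and correlation tests.
    ttest_alpha : float
        Significance level for the per-region tumor/normal t-test screen.
    classifying_fraction : float
        Minimum fraction of one group that must carry classifying gains or
        losses for a region to enter the Fisher scan.
    region_overlap_fraction : float
        Fraction of a region a call must cover for the sample to count as
        gained/lost in that region.
    seed : int
        Seed recorded in every output header.
    """

    adm_threshold: float = 4.0
    min_probes: int = 2
    min_abs_mean: float = 0.5
    max_regions: int = 10_000
    recurrence_fraction: float = 0.25
    fc_cutoff: float = 1.3
    target_fc_cutoff: float = 2.0
    cnv_call_log2: float = 0.585
    expr_signal_cutoff: float = 3.9
    alpha: float = 0.05
    ttest_alpha: float = 1e-4
    classifying_fraction: float = 0.25
    region_overlap_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "adm_threshold",
            "min_probes",
            "min_abs_mean",
            "max_regions",
            "fc_cutoff",
            "target_fc_cutoff",
            "cnv_call_log2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.recurrence_fraction <= 1):
            raise ValueError("recurrence_fraction must lie in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    def fingerprint(self) -> str:
        """One-line summary written into '#' header lines of every output."""
        fields = dataclasses.asdict(self)
        body = " ".join(f"{k}={v}" for k, v in sorted(fields.items()))
        return f"cnvintegrate-config {body}"

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


DEFAULT_CONFIG = PipelineConfig()
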