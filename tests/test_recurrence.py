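"""Frequency profiles, recurrent-region runs, MCR extraction and target genes."""

import numpy as np
import pandas as pd
import pytest

from cnvintegrate.datatypes import ProbeTable, RegionSummary
from cnvintegrate.recurrence import (
    annotate_target_genes,
    frequency_percent,
    frequency_profile,
    minimal_common_regions,
    recurrence_threshold,
    recurrent_regions,
    region_size_mb,
)


def make_table(n_probes: int, n_samples: int, chrom: str = "1") -> ProbeTable:
    frame = pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n_probes)],
        "chromosome": chrom,
        "start": np.arange(n_probes) * 1000 + 1,
        "end": np.arange(n_probes) * 1000 + 60,
    })
    for j in range(n_samples):
        frame[f"s{j:02d}"] = 0.0
    return ProbeTable(frame)


def calls_df(mat: np.ndarray, table: ProbeTable) -> pd.DataFrame:
    return pd.DataFrame(mat.astype(np.int8), index=table.frame["probe_id"],
                        columns=table.samples)


def brute_force_mcr(mat: np.ndarray, k: int) -> list[tuple[int, int, int]]:
    """Independent oracle: for gains, the maximal-count sub-runs of each
    >=k run, by direct scanning. Returns (first, last, count) triples."""
    counts = (mat == 1).sum(axis=1)
    out = []
    i, n = 0, len(counts)
    while i < n:
        if counts[i] < k:
            i += 1
            continue
        j = i
        while j + 1 < n and counts[j + 1] >= k:
            j += 1
        peak = counts[i:j + 1].max()
        a = i
        while a <= j:
            if counts[a] == peak:
                b = a
                while b + 1 <= j and counts[b + 1] == peak:
                    b += 1
                out.append((a, b, int(peak)))
                a = b + 1
            else:
                a += 1
        i = j + 1
    return out


class TestFrequencyArithmetic:
    @pytest.mark.parametrize("count,n,expected", [
        (19, 27, 70), (17, 27, 63), (9, 27, 33), (7, 27, 26), (12, 27, 44),
        (11, 27, 41), (10, 27, 37), (8, 27, 30),
    ])
    def test_percent_labels_match_published_convention(self, count, n, expected):
        assert frequency_percent(count, n) == expected

    def test_recurrence_threshold_for_quarter_of_27(self):
        assert recurrence_threshold(0.25, 27) == 7

    @pytest.mark.parametrize("start_mb,end_mb,expected", [
        (47.86, 146.27, 98.41), (63.35, 73.62, 10.27), (53.84, 57.47, 3.63),
    ])
    def test_mcr_size_arithmetic(self, start_mb, end_mb, expected):
        assert region_size_mb(round(start_mb * 1e6), round(end_mb * 1e6)) == expected


class TestFrequencyProfile:
    def test_all_neutral_gives_zero_profile(self):
        table = make_table(10, 3)
        profile = frequency_profile(calls_df(np.zeros((10, 3)), table))
        assert (profile == 0).all().all()

    def test_19_of_27_gain_counts(self):
        table = make_table(5, 27)
        mat = np.zeros((5, 27))
        mat[2, :19] = 1
        profile = frequency_profile(calls_df(mat, table))
        assert profile["gain_count"].tolist() == [0, 0, 19, 0, 0]
        assert frequency_percent(19, 27) == 70

    def test_profile_conserves_column_totals(self):
        rng = np.random.default_rng(2)
        table = make_table(40, 6)
        mat = rng.choice([-1, 0, 1], size=(40, 6), p=[0.2, 0.6, 0.2])
        profile = frequency_profile(calls_df(mat, table))
        assert profile["gain_count"].sum() == (mat == 1).sum()
        assert profile["loss_count"].sum() == (mat == -1).sum()


class TestRecurrentRegions:
    def test_run_at_exact_threshold_reports_26_percent(self):
        table = make_table(20, 27)
        mat = np.zeros((20, 27))
        mat[5:8, :7] = 1  # exactly k=7 carriers
        profile = frequency_profile(calls_df(mat, table))
        regions = recurrent_regions(table, profile, 0.25, 27)
        assert len(regions) == 1
        assert regions[0].count == 7
        assert regions[0].percent == 26

    def test_below_threshold_is_empty(self):
        table = make_table(20, 27)
        mat = np.zeros((20, 27))
        mat[:, :6] = 1  # 6 < ceil(0.25*27)=7 everywhere
        profile = frequency_profile(calls_df(mat, table))
        assert recurrent_regions(table, profile, 0.25, 27) == []

    def test_runs_split_by_subthreshold_probe(self):
        table = make_table(20, 8)
        mat = np.zeros((20, 8))
        mat[3:6, :4] = 1
        mat[7:10, :4] = 1  # probe 6 stays below k=2
        profile = frequency_profile(calls_df(mat, table))
        regions = recurrent_regions(table, profile, 0.25, 8)
        assert len(regions) == 2
        assert [(r.first_probe, r.last_probe) for r in regions] == [(3, 5), (7, 9)]

    def test_invariant_to_sample_column_order(self):
        rng = np.random.default_rng(6)
        table = make_table(50, 10)
        mat = rng.choice([0, 1], size=(50, 10), p=[0.6, 0.4])
        profile1 = frequency_profile(calls_df(mat, table))
        perm = rng.permutation(10)
        profile2 = frequency_profile(calls_df(mat[:, perm], table))
        r1 = recurrent_regions(table, profile1, 0.25, 10)
        r2 = recurrent_regions(table, profile2, 0.25, 10)
        assert [(r.start_bp, r.end_bp, r.count) for r in r1] == \
            [(r.start_bp, r.end_bp, r.count) for r in r2]


class TestMinimalCommonRegions:
    def test_nested_calls_yield_shared_core(self):
        # one sample spans probes 1-99, nine others span 40-60: with k=7 the
        # MCR is the 40-60 core at count 10
        table = make_table(100, 10)
        mat = np.zeros((100, 10))
        mat[1:100, 0] = 1
        mat[40:61, 1:10] = 1
        profile = frequency_profile(calls_df(mat, table))
        mcrs = minimal_common_regions(table, profile, 0.25, 10)
        assert len(mcrs) == 1
        assert (mcrs[0].first_probe, mcrs[0].last_probe) == (40, 60)
        assert mcrs[0].count == 10

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            table = make_table(60, 9)
            mat = (rng.random((60, 9)) < 0.35).astype(int)
            profile = frequency_profile(calls_df(mat, table))
            k = recurrence_threshold(0.25, 9)
            mcrs = minimal_common_regions(table, profile, 0.25, 9)
            gains = [(m.first_probe, m.last_probe, m.count)
                     for m in mcrs if m.direction == "gain"]
            assert gains == brute_force_mcr(mat, k)

    def test_every_mcr_contained_in_one_recurrent_region(self, pipeline_result):
        regions = pipeline_result.recurrent_regions
        for m in pipeline_result.mcrs:
            hosts = [r for r in regions
                     if r.direction == m.direction
                     and r.chromosome == m.chromosome
                     and r.start_bp <= m.start_bp and r.end_bp >= m.end_bp]
            assert len(hosts) == 1
            assert m.count == hosts[0].count  # region count is its peak


class TestTargetGenes:
    def _region(self, direction="gain"):
        return RegionSummary(direction=direction, chromosome="1",
                             start_bp=1000, end_bp=9000,
                             size_mb=region_size_mb(1000, 9000),
                             count=7, percent=26, n_samples=27)

    def _dosage(self, fcs, inside=True):
        start = 2000 if inside else 50_000
        return pd.DataFrame({
            "gene_symbol": [f"G{i}" for i in range(len(fcs))],
            "chromosome": "1", "start": start, "end": start + 100,
            "fc": fcs})

    def test_no_overlapping_genes_gives_empty_list(self):
        region = annotate_target_genes(self._region(), self._dosage([3.0], inside=False))
        assert region.target_genes == []

    def test_two_fold_threshold_inclusive_for_gains(self):
        region = annotate_target_genes(self._region(), self._dosage([2.1, 1.9, 2.0]))
        assert region.target_genes == ["G0", "G2"]

    def test_reciprocal_threshold_for_losses(self):
        region = annotate_target_genes(self._region("loss"),
                                       self._dosage([0.45, 0.6, 2.2]))
        assert region.target_genes == ["G0"]

    def test_dependency_error_without_integration_columns(self):
        with pytest.raises(ValueError, match="integration"):
            annotate_target_genes(self._region(), pd.DataFrame({"gene_symbol": []}))
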