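"""Fisher exact r x c enumeration, contrast construction and the region scan."""

import itertools
from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as fisher_2x2

from cnvintegrate import PipelineConfig
from cnvintegrate.compare import (
    GroupContrast,
    build_contrasts,
    fisher_exact_rxc,
    region_sample_states,
    region_table,
    scan_regions,
)
from cnvintegrate.datatypes import RegionSummary
from cnvintegrate.simulate import default_metadata


def oracle_fisher_p(table) -> float:
    """Independent exact-rational enumeration of the two-sided conditional p."""
    table = np.asarray(table, dtype=int)
    r, c, n = table.sum(1), table.sum(0), table.sum()

    def prob(t) -> Fraction:
        num = Fraction(1)
        for x in list(r) + list(c):
            num *= factorial(int(x))
        den = Fraction(factorial(int(n)))
        for x in np.ravel(t):
            den *= factorial(int(x))
        return num / den

    p_obs = prob(table)
    total = Fraction(0)
    for top in itertools.product(*(range(int(x) + 1) for x in c)):
        if sum(top) != r[0]:
            continue
        t = np.array([top, c - np.array(top)])
        if (t < 0).any():
            continue
        pr = prob(t)
        if pr <= p_obs:
            total += pr
    return float(total)


class TestFisherExactRxC:
    def test_identical_rows_give_p_one(self):
        assert fisher_exact_rxc(np.array([[2, 2, 2], [2, 2, 2]])) == 1.0

    def test_fully_separated_table_frozen_oracle_value(self):
        # enumeration over all margin-preserving tables gives exactly 1/126
        p = fisher_exact_rxc(np.array([[5, 0, 0], [0, 5, 0]]))
        assert p == pytest.approx(1 / 126, rel=1e-9)

    def test_embedded_2x2_matches_closed_form(self):
        # [[3,0],[0,3]] has classical two-sided p = 0.1
        p = fisher_exact_rxc(np.array([[3, 0, 0], [0, 3, 0]]))
        assert p == pytest.approx(0.1, rel=1e-9)
        assert p == pytest.approx(fisher_2x2([[3, 0], [0, 3]])[1], rel=1e-6)

    def test_agrees_with_enumeration_oracle_on_small_tables(self):
        rng = np.random.default_rng(19)
        for _ in range(40):
            n = int(rng.integers(2, 21))
            flat = rng.multinomial(n, np.full(6, 1 / 6))
            table = flat.reshape(2, 3)
            if (table.sum(1) == 0).any():
                continue
            assert fisher_exact_rxc(table) == pytest.approx(
                oracle_fisher_p(table), abs=1e-9)

    def test_invariant_under_row_swap_and_column_permutation(self):
        rng = np.random.default_rng(23)
        table = rng.multinomial(15, np.full(6, 1 / 6)).reshape(2, 3)
        p = fisher_exact_rxc(table)
        assert fisher_exact_rxc(table[::-1]) == pytest.approx(p, abs=1e-12)
        for perm in itertools.permutations(range(3)):
            assert fisher_exact_rxc(table[:, perm]) == pytest.approx(p, abs=1e-12)

    def test_degenerate_margins_give_p_one(self):
        assert fisher_exact_rxc(np.array([[0, 0, 0], [1, 2, 3]])) == 1.0
        assert fisher_exact_rxc(np.array([[0, 4, 0], [0, 5, 0]])) == 1.0


class TestContrasts:
    def test_srcc_exclusion_reproduces_group_sizes(self):
        """12 PD with 2 partial-SRCC and 11 MD -> PD group of 10 vs MD of 11."""
        meta = default_metadata(27)
        contrasts = {c.name: c for c in build_contrasts(meta)}
        pd_md = contrasts["PD-vs-MD"]
        assert len(pd_md.group_a) == 10
        assert len(pd_md.group_b) == 11
        assert sum("signet-ring" in reason
                   for reason in pd_md.excluded.values()) == 2

    def test_all_samples_in_one_stage_rejected(self):
        frame = default_metadata(8).frame.copy()
        frame["t_stage"] = "T1"
        from cnvintegrate.datatypes import SampleMetadata
        with pytest.raises(ValueError, match="empty group"):
            build_contrasts(SampleMetadata(frame))

    def test_groups_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            GroupContrast("bad", ["s1", "s2"], ["s2", "s3"])


class TestRegionTable:
    def _states(self, values, samples):
        return pd.Series(values, index=samples, dtype=np.int8)

    def test_all_neutral_counts(self):
        states = self._states([0] * 6, [f"s{i}" for i in range(6)])
        contrast = GroupContrast("x", ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert region_table(states, contrast).tolist() == [[0, 3, 0], [0, 3, 0]]

    def test_separated_groups_counts(self):
        samples = [f"s{i}" for i in range(10)]
        states = self._states([1] * 5 + [0] * 5, samples)
        contrast = GroupContrast("x", samples[:5], samples[5:])
        assert region_table(states, contrast).tolist() == [[5, 0, 0], [0, 5, 0]]

    def test_counts_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(12)]
        vals = rng.choice([-1, 0, 1], 12)
        contrast = GroupContrast("x", samples[:6], samples[6:])
        t1 = region_table(self._states(vals, samples), contrast)
        perm = rng.permutation(12)
        t2 = region_table(self._states(vals[perm],
                                       [samples[i] for i in perm]), contrast)
        assert (t1 == t2).all()


class TestScan:
    def _fixture(self, states_by_sample, n_probes=10):
        """A one-region fixture with prescribed per-sample states."""
        samples = list(states_by_sample)
        frame = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(n_probes)],
            "chromosome": "1",
            "start": np.arange(n_probes) * 1000 + 1,
            "end": np.arange(n_probes) * 1000 + 60,
        })
        calls = pd.DataFrame(
            {s: np.full(n_probes, v, dtype=np.int8)
             for s, v in states_by_sample.items()})
        region = RegionSummary(direction="gain", chromosome="1", start_bp=1,
                               end_bp=n_probes * 1000, size_mb=0.01,
                               count=5, percent=50, n_samples=len(samples))
        return frame, calls, region

    def test_differential_region_flagged(self):
        # 8 of 10 group-A samples gained, none of group B: strong association
        states = {f"a{i}": 1 if i < 8 else 0 for i in range(10)}
        states.update({f"b{i}": 0 for i in range(10)})
        frame, calls, region = self._fixture(states)
        contrast = GroupContrast("x", [f"a{i}" for i in range(10)],
                                 [f"b{i}" for i in range(10)])
        results = scan_regions([region], calls, frame, contrast,
                               PipelineConfig())
        assert len(results) == 1
        assert results[0].significant
        assert results[0].p_value < 0.001

    def test_low_frequency_region_skipped_before_testing(self):
        # gains in only 10% of both classes fail the 25% classifying rule
        states = {f"a{i}": 1 if i == 0 else 0 for i in range(10)}
        states.update({f"b{i}": 1 if i == 0 else 0 for i in range(10)})
        frame, calls, region = self._fixture(states)
        contrast = GroupContrast("x", [f"a{i}" for i in range(10)],
                                 [f"b{i}" for i in range(10)])
        assert scan_regions([region], calls, frame, contrast,
                            PipelineConfig()) == []

    def test_x_and_y_regions_skipped(self):
        states = {f"a{i}": 1 for i in range(4)}
        states.update({f"b{i}": 0 for i in range(4)})
        frame, calls, region = self._fixture(states)
        region.chromosome = "X"
        contrast = GroupContrast("x", [f"a{i}" for i in range(4)],
                                 [f"b{i}" for i in range(4)])
        frame_x = frame.assign(chromosome="X")
        assert scan_regions([region], calls, frame_x, contrast,
                            PipelineConfig()) == []

    def test_half_overlap_rule_for_region_state(self):
        # calls covering 50% of the region's probes count; 40% does not
        n = 10
        frame = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(n)], "chromosome": "1",
            "start": np.arange(n) * 1000 + 1, "end": np.arange(n) * 1000 + 60})
        calls = pd.DataFrame({
            "s1": np.array([1] * 5 + [0] * 5, dtype=np.int8),
            "s2": np.array([1] * 4 + [0] * 6, dtype=np.int8)})
        region = RegionSummary(direction="gain", chromosome="1", start_bp=1,
                               end_bp=n * 1000, size_mb=0.01, count=1,
                               percent=50, n_samples=2)
        states = region_sample_states(region, calls, frame, 0.5)
        assert states["s1"] == 1
        assert states["s2"] == 0


def test_null_type_one_error_calibrated():
    """Empirical rejection rate of the 2x3 exact test at alpha=0.05 under a
    group-independent state distribution stays within [0.03, 0.07]."""
    rng = np.random.default_rng(2027)
    probs = (0.3, 0.5, 0.2)  # mid-range recurrent-region call rates
    rejections = 0
    n_rep = 600
    for _ in range(n_rep):
        table = np.array([rng.multinomial(13, probs),
                          rng.multinomial(14, probs)])
        rejections += fisher_exact_rxc(table) < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07
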