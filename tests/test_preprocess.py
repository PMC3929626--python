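"""Background correction, GC centering, quantile normalization,
summarization and the expression floors."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import make_probe_matrix, make_summary
from exonscreen.preprocess import (EXON, GENE, background_correct,
                                   filter_low_expression, gc_adjust,
                                   quantile_normalize, summarize_probesets)


def quantile_normalize_oracle(x: np.ndarray) -> np.ndarray:
    """Hand-executed rank-mean algorithm (tie-free inputs only)."""
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = np.argsort(np.argsort(x[:, j]))
        out[:, j] = target[ranks]
    return out


class TestBackgroundCorrect:
    def test_sigma_zero_limit_subtracts_mean(self):
        # E[s|o] -> o - mu as sigma -> 0+
        m = make_probe_matrix(np.full((2, 2), 100.0))
        out = background_correct(m, bg_mean=40.0, bg_sd=1e-12, signal_rate=0.01)
        assert np.allclose(out.values.to_numpy(), 60.0)

    def test_zero_background_is_identity(self):
        vals = np.array([[10.0, 20.0], [30.0, 40.0]])
        m = make_probe_matrix(vals)
        out = background_correct(m, bg_mean=0.0, bg_sd=1e-12, signal_rate=0.01)
        assert np.allclose(out.values.to_numpy(), vals)

    def test_monotone_and_strictly_positive(self, rng):
        o = np.sort(rng.uniform(0, 500, size=200))
        m = make_probe_matrix(o[:, None])
        out = background_correct(m, bg_mean=50.0, bg_sd=15.0, signal_rate=1 / 200)
        c = out.values.to_numpy().ravel()
        assert (c > 0).all()
        assert (np.diff(c) >= -1e-9).all()

    def test_estimated_parameters_recover_background_scale(self, rng):
        # background-only probes pin the mode; signal probes sit above it
        bg = rng.normal(60, 8, size=4000).clip(min=0)
        signal = 60 + rng.exponential(300, size=2000)
        m = make_probe_matrix(np.concatenate([bg, signal])[:, None])
        out = background_correct(m)
        corrected = out.values.to_numpy().ravel()
        # background-only probes collapse toward zero, signal survives
        assert np.median(corrected[:4000]) < 30
        assert np.median(corrected[4000:]) > 150

    def test_invalid_parameters_rejected(self):
        m = make_probe_matrix(np.ones((2, 2)))
        with pytest.raises(ValueError):
            background_correct(m, 10.0, -1.0, 0.1)
        with pytest.raises(ValueError):
            background_correct(m, 10.0, 1.0, -0.1)


class TestGcAdjust:
    def test_single_bin_is_identity(self, rng):
        vals = rng.uniform(10, 100, size=(20, 3))
        m = make_probe_matrix(vals, probe_gc=rng.uniform(0.2, 0.8, 20))
        out = gc_adjust(m, n_bins=1)
        assert np.allclose(out.values.to_numpy(), vals)

    def test_offset_bins_get_equal_medians(self):
        # low-GC probes sit exactly 1 log2 unit below high-GC probes
        low = 2.0 ** np.linspace(5, 6, 50)
        high = 2.0 ** (np.linspace(5, 6, 50) + 1.0)
        vals = np.concatenate([low, high])[:, None]
        gc = np.array([0.3] * 50 + [0.7] * 50)
        m = make_probe_matrix(vals, probe_gc=gc)
        out = gc_adjust(m, n_bins=2)
        logv = np.log2(out.values.to_numpy().ravel())
        assert np.median(logv[:50]) == pytest.approx(np.median(logv[50:]))

    def test_missing_gc_is_noop_with_warning(self, caplog, rng):
        vals = rng.uniform(10, 100, size=(10, 2))
        m = make_probe_matrix(vals)
        with caplog.at_level(logging.WARNING, logger="exonscreen"):
            out = gc_adjust(m, n_bins=10)
        assert np.allclose(out.values.to_numpy(), vals)
        assert any("gc_adjust skipped" in r.message for r in caplog.records)


class TestQuantileNormalize:
    def test_two_by_two_hand_example(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = quantile_normalize(x)
        assert np.allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_unchanged(self):
        x = np.tile(np.array([[5.0], [1.0], [9.0]]), (1, 4))
        assert np.allclose(quantile_normalize(x), x)

    def test_ties_receive_mean_of_target_quantiles(self):
        x = np.array([[1.0, 1.0], [1.0, 2.0], [2.0, 3.0]])
        out = quantile_normalize(x)
        # target = [1, 1.5, 2.5]; the tied pair in column 1 spans ranks 0,1
        assert np.allclose(out[:, 0], [1.25, 1.25, 2.5])
        assert np.allclose(out[:, 1], [1.0, 1.5, 2.5])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.ones((5, 1)))

    @settings(deadline=None, max_examples=25)
    @given(arrays(np.float64, (11, 4), unique=True,
                  elements=st.floats(0, 1e6, allow_nan=False)))
    def test_distributions_identical_and_idempotent(self, x):
        # tie-free inputs: with ties the tied entries share mean target
        # values, so per-sample distributions legitimately differ
        out = quantile_normalize(x)
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, x.shape[1]):
            assert np.allclose(sorted_cols[:, j], sorted_cols[:, 0])
        assert np.allclose(quantile_normalize(out), out)

    def test_matches_rank_mean_oracle(self, rng):
        x = rng.uniform(0, 100, size=(50, 8))  # continuous: no ties
        assert np.allclose(quantile_normalize(x), quantile_normalize_oracle(x))


class TestSummarizeProbesets:
    def test_mean_of_log2_probes(self):
        m = make_probe_matrix(np.array([[8.0], [32.0]]), probes_per_set=2)
        s = summarize_probesets(m)
        assert s.values.iloc[0, 0] == pytest.approx(4.0)  # mean(log2 8, log2 32)

    def test_single_probe_probeset_identity(self):
        m = make_probe_matrix(np.array([[16.0]]), probes_per_set=1)
        s = summarize_probesets(m)
        assert s.values.iloc[0, 0] == pytest.approx(4.0)

    def test_matches_brute_force_mean(self, rng):
        vals = rng.uniform(1, 1000, size=(25, 3))
        m = make_probe_matrix(vals, probes_per_set=5)
        s = summarize_probesets(m)
        for i in range(5):
            expected = np.log2(vals[5 * i: 5 * i + 5]).mean(axis=0)
            assert np.allclose(s.values.loc[f"ps{i}"].to_numpy(), expected)


class TestFilterLowExpression:
    def test_gene_below_linear_floor_removed(self):
        s = make_summary(
            {"g1": list(np.log2([10, 20, 30, 20])), "g2": [6.0] * 4},
            kinds={"g1": GENE, "g2": GENE})
        kept, removed = filter_low_expression(s)
        assert removed == ["g1"]  # mean linear 20 < 25
        assert list(kept.values.index) == ["g2"]

    def test_exon_below_log2_floor_removed(self):
        s = make_summary({"e1": [2.9] * 4, "e2": [3.1] * 4},
                         kinds={"e1": EXON, "e2": EXON})
        kept, removed = filter_low_expression(s)
        assert removed == ["e1"]

    def test_all_above_floors_unchanged(self):
        s = make_summary({"g": [7.0] * 3, "e": [5.0] * 3},
                         kinds={"g": GENE, "e": EXON})
        kept, removed = filter_low_expression(s)
        assert removed == []
        assert kept.values.equals(s.values)

    def test_min_aggregation_option(self):
        # one bad array sinks the feature under "min" but not under "mean"
        s = make_summary({"g": list(np.log2([10, 100, 100, 100]))},
                         kinds={"g": GENE})
        _, removed_mean = filter_low_expression(s, aggregate="mean")
        _, removed_min = filter_low_expression(s, aggregate="min")
        assert removed_mean == [] and removed_min == ["g"]
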