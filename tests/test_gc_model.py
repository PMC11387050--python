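"""Core model: normalization, binning, LOESS, scores, classification."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panelgc.gc_model import (
    BiasClass,
    BiasCurve,
    DEFAULT_THRESHOLDS,
    ScoreStatus,
    Thresholds,
    bin_by_gc,
    classify_bias,
    fit_bias_curve,
    gc_percentile,
    normalize_depths,
    relative_fold_change,
    score_auc,
    score_bias,
    score_sample,
)
from panelgc.io_formats import DepthTable, ProbeInterval, ProbeSet


def depth_table(values, chrom="chr1", start=0):
    """Single-block DepthTable from a flat vector."""
    v = np.asarray(values)
    return DepthTable({chrom: [(start, start + len(v), v)]})


class TestNormalization:
    def test_mean_depth_maps_to_one(self):
        profile = normalize_depths(depth_table([7] * 50), "s")
        np.testing.assert_allclose(profile.values(), 1.0)

    def test_zero_depth_maps_to_zero(self):
        profile = normalize_depths(depth_table([0, 4]), "s")
        assert profile.values()[0] == 0.0

    def test_two_position_example(self):
        profile = normalize_depths(depth_table([1, 3]), "s")  # mean 2
        np.testing.assert_allclose(
            profile.values(), [math.log2(1.5), math.log2(2.5)]
        )

    def test_no_coverage_flagged(self):
        profile = normalize_depths(depth_table([0, 0, 0]), "s")
        assert profile.no_coverage
        assert (profile.values() == 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_depths(depth_table([]), "s")

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=300)
        .filter(lambda v: sum(v) > 0)
    )
    def test_conservation_of_normalizer(self, depths):
        """Mean of back-transformed normalized depths is exactly 1."""
        profile = normalize_depths(depth_table(depths), "s")
        back = 2.0 ** profile.values() - 1.0
        assert back.mean() == pytest.approx(1.0, abs=1e-9)


class TestBinning:
    @pytest.mark.parametrize("gc,pct", [(0.0, 0), (0.345, 35), (0.5, 50), (0.995, 100),
                                        (0.125, 13)])
    def test_percentile_rounds_half_up(self, gc, pct):
        assert gc_percentile(gc) == pct

    def _profile_and_probes(self, per_probe_values, gcs):
        blocks, intervals, pos = [], [], 0
        for vals in per_probe_values:
            intervals.append(ProbeInterval("chr1", pos, pos + len(vals)))
            blocks.append((pos, pos + len(vals), np.asarray(vals, dtype=float)))
            pos += len(vals) + 10
        probes = ProbeSet(intervals, np.asarray(gcs))
        table = DepthTable({"chr1": blocks})
        # values are already on the normalized scale for these tests
        from panelgc.gc_model import DepthProfile
        return DepthProfile("s", table, 1.0), probes

    def test_median_of_medians_resists_outliers(self):
        profile, probes = self._profile_and_probes(
            [[0.2] * 3, [1.0] * 3, [9.9] * 3], [0.40, 0.40, 0.40]
        )
        table = bin_by_gc(profile, probes)
        assert table.loc[40, "median_of_medians"] == pytest.approx(1.0)
        assert table.loc[40, "n_probes"] == 3

    def test_probe_median_of_positions(self):
        profile, probes = self._profile_and_probes([[0, 0, 5]], [0.30])
        assert bin_by_gc(profile, probes).loc[30, "median_of_medians"] == 0.0

    def test_each_probe_contributes_once(self):
        profile, probes = self._profile_and_probes(
            [[1.0] * 2] * 5, [0.2, 0.2, 0.5, 0.7, 0.7]
        )
        table = bin_by_gc(profile, probes)
        assert table["n_probes"].sum() == 5
        assert set(table.index) == {20, 50, 70}

    def test_nan_gc_probes_skipped(self):
        profile, probes = self._profile_and_probes(
            [[1.0], [2.0]], [0.4, float("nan")]
        )
        assert bin_by_gc(profile, probes)["n_probes"].sum() == 1


def make_table(percentiles, values):
    return pd.DataFrame(
        {"median_of_medians": values, "n_probes": 1},
        index=pd.Index(percentiles, name="percentile"),
    )


class TestLoess:
    def test_reproduces_constant(self):
        table = make_table(range(10, 91), [0.8] * 81)
        curve = fit_bias_curve(table)
        np.testing.assert_allclose(curve.predict(np.arange(10, 91)), 0.8, atol=1e-12)

    def test_reproduces_line(self):
        x = np.arange(10, 91)
        table = make_table(x, 0.01 * x + 0.3)
        curve = fit_bias_curve(table)
        np.testing.assert_allclose(
            curve.predict(x), 0.01 * x + 0.3, atol=1e-9
        )

    def test_reproduces_quadratic(self):
        """Degree-2 local fits are exact on globally quadratic data, whatever
        the span — a closed-form oracle for the smoother's degree."""
        x = np.arange(0, 101)
        y = 1.0 - 1e-4 * (x - 50) ** 2
        curve = fit_bias_curve(make_table(x, y))
        np.testing.assert_allclose(curve.predict(x), y, atol=1e-9)

    def test_too_few_percentiles_is_hard_error(self):
        table = make_table(range(5), [1.0] * 5)
        with pytest.raises(ValueError, match="5 occupied"):
            fit_bias_curve(table)

    def test_domain_recorded(self):
        table = make_table(range(30, 71), [1.0] * 41)
        assert fit_bias_curve(table).domain == (30, 70)


class TestScoreBias:
    def flat_curve(self, lo, hi, value):
        return fit_bias_curve(make_table(range(lo, hi + 1), [value] * (hi - lo + 1)))

    def test_symmetric_anchors_score_one(self):
        b25, b75, s = score_bias(self.flat_curve(10, 90, 1.0))
        assert b25 == pytest.approx(1.0, abs=1e-12)
        assert b75 == pytest.approx(1.0, abs=1e-12)
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_twofold_gc_ratio(self):
        assert relative_fold_change(1.0, math.log2(3)) == pytest.approx(
            math.log2(3), abs=1e-12  # 2^b75-1 = 2 is twice 2^b25-1 = 1
        )

    def test_twofold_at_ratio(self):
        assert relative_fold_change(math.log2(3), 1.0) == pytest.approx(
            math.log2(1.5), abs=1e-12
        )

    def test_identity_b75_25(self):
        # the defining identity holds for arbitrary anchors
        b25, b75 = 0.7, 1.9
        expect = math.log2((2**b75 - 1) / (2**b25 - 1) + 1)
        assert relative_fold_change(b25, b75) == pytest.approx(expect, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(0.01, 3.0), st.floats(0.01, 3.0), st.floats(0.01, 0.5)
    )
    def test_monotonicity(self, b25, b75, eps):
        """Score strictly increases in b75 and strictly decreases in b25."""
        s = relative_fold_change(b25, b75)
        assert relative_fold_change(b25, b75 + eps) > s
        assert relative_fold_change(b25 + eps, b75) < s

    def test_sentinels_for_nonpositive_linear_depth(self):
        assert relative_fold_change(0.0, 1.0) == math.inf
        assert relative_fold_change(-0.5, 1.0) == math.inf
        assert relative_fold_change(1.0, 0.0) == 0.0

    def test_anchor_clamped_within_margin(self):
        curve = self.flat_curve(27, 77, 0.9)  # anchors 25/75 within 2 of domain
        b25, b75, s = score_bias(curve)
        assert b25 == pytest.approx(0.9) and b75 == pytest.approx(0.9)
        assert s == pytest.approx(1.0)

    def test_anchor_too_far_outside_domain_unscorable(self):
        curve = self.flat_curve(30, 70, 0.9)
        b25, b75, s = score_bias(curve)
        assert b25 is None and s is None

    def test_invalid_anchor_order(self):
        with pytest.raises(ValueError):
            score_bias(self.flat_curve(10, 90, 1.0), at_anchor=75, gc_anchor=25)


class TestScoreAuc:
    def test_constant_curve_full_domain(self):
        curve = fit_bias_curve(make_table(range(0, 101), [0.7] * 101))
        assert score_auc(curve) == pytest.approx(0.7, abs=1e-9)  # 51c - 50c

    def test_even_curve_about_fifty_cancels(self):
        x = np.arange(0, 101)
        curve = fit_bias_curve(make_table(x, 1e-4 * (x - 50) ** 2))
        assert score_auc(curve) == pytest.approx(0.0, abs=1e-9)

    def test_increasing_curve_positive(self):
        x = np.arange(0, 101)
        curve = fit_bias_curve(make_table(x, 0.01 * x))
        assert score_auc(curve) > 0

    def test_one_sided_domain_undefined(self):
        curve = fit_bias_curve(make_table(range(55, 91), [1.0] * 36))
        assert score_auc(curve) is None


class TestClassification:
    T = DEFAULT_THRESHOLDS

    @pytest.mark.parametrize(
        "b25,b75,b75_25,expected",
        [
            (0.9, 0.9, 1.60, BiasClass.GC_BIAS_FAIL),       # relative GC fail
            (1.40, 0.9, 1.0, BiasClass.AT_BIAS_FAIL),       # absolute AT fail alone
            (1.0, 1.0, 1.0, BiasClass.NO_BIAS),
            (0.9, 0.8, 0.70, BiasClass.AT_BIAS_WARN),
            (0.9, 1.0, 1.40, BiasClass.GC_BIAS_WARN),
            (0.9, 1.35, 1.2, BiasClass.GC_BIAS_FAIL),       # absolute GC fail alone
            # boundaries use the printed comparators (>= / <=)
            (0.9, 0.9, math.log2(3), BiasClass.GC_BIAS_FAIL),
            (0.9, 0.9, math.log2(2.5), BiasClass.GC_BIAS_WARN),
            (0.9, 0.9, DEFAULT_THRESHOLDS.rel_warn_lo, BiasClass.AT_BIAS_WARN),
            (0.9, 0.9, math.log2(1.5), BiasClass.AT_BIAS_FAIL),
        ],
    )
    def test_rule_table(self, b25, b75, b75_25, expected):
        cls, _ = classify_bias(b25, b75, b75_25, self.T)
        assert cls == expected

    def test_bidirectional_anomaly_tiebreak(self):
        cls, notes = classify_bias(1.4, 1.4, 1.1, self.T)
        assert cls == BiasClass.GC_BIAS_FAIL and any("bidirectional" in n for n in notes)
        cls, notes = classify_bias(1.4, 1.4, 0.9, self.T)
        assert cls == BiasClass.AT_BIAS_FAIL and notes

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-1, 3), st.floats(-1, 3), st.floats(0, 4))
    def test_total_function(self, b25, b75, b75_25):
        cls, _ = classify_bias(b25, b75, b75_25, self.T)
        assert isinstance(cls, BiasClass)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            Thresholds(rel_fail_hi=0.5)


class TestFullSamplePipeline:
    def _uniform_sample(self, probes, depth_by_probe):
        blocks = []
        for probe, d in zip(probes, depth_by_probe):
            blocks.append((probe.start, probe.end, np.full(len(probe), d)))
        return DepthTable({"chr1": blocks})

    def _probes(self, gcs, length=20):
        intervals, pos = [], 0
        for _ in gcs:
            intervals.append(ProbeInterval("chr1", pos, pos + length))
            pos += length + 5
        return ProbeSet(intervals, np.asarray(gcs, dtype=float))

    def test_scale_invariance(self):
        """Multiplying all raw depths by a constant changes nothing."""
        gcs = np.linspace(0.10, 0.90, 40)
        depths = np.where(gcs < 0.5, 10, 20)
        probes = self._probes(gcs)
        s1, _ = score_sample(self._uniform_sample(probes, depths), probes, "a")
        s2, _ = score_sample(self._uniform_sample(probes, depths * 13), probes, "a")
        assert s1.b75_25 == pytest.approx(s2.b75_25, abs=1e-12)
        assert s1.b25 == pytest.approx(s2.b25, abs=1e-12)
        assert s1.bias_class == s2.bias_class

    @pytest.mark.parametrize("r", [1.0, 1.5, 2.0, 3.0])
    def test_oracle_equivalence_on_noiseless_step(self, r):
        """Closed form: step depths with GC:AT ratio r give b75/25 = log2(r+1)."""
        gcs = np.round(np.linspace(0.10, 0.90, 81), 2)  # every percentile occupied
        probes = self._probes(gcs)
        depths = np.where(gcs < 0.5, 100.0, 100.0 * r)
        scores, _ = score_sample(self._uniform_sample(probes, depths), probes, "a")
        assert scores.b75_25 == pytest.approx(math.log2(r + 1), abs=1e-3)

    def test_mirror_symmetry(self):
        """Swapping AT- and GC-side depth patterns maps ratio r to 1/r."""
        gcs = np.round(np.linspace(0.10, 0.90, 81), 2)
        probes = self._probes(gcs)
        r = 2.0
        hi = np.where(gcs < 0.5, 100.0, 100.0 * r)
        lo = np.where(gcs < 0.5, 100.0 * r, 100.0)
        s_hi, _ = score_sample(self._uniform_sample(probes, hi), probes, "a")
        s_lo, _ = score_sample(self._uniform_sample(probes, lo), probes, "a")
        assert s_hi.b75_25 == pytest.approx(math.log2(r + 1), abs=1e-3)
        assert s_lo.b75_25 == pytest.approx(math.log2(1 / r + 1), abs=1e-3)

    def test_zero_coverage_sample_status(self):
        gcs = np.linspace(0.10, 0.90, 20)
        probes = self._probes(gcs)
        scores, curve = score_sample(
            self._uniform_sample(probes, np.zeros(20)), probes, "a"
        )
        assert scores.status == ScoreStatus.NO_COVERAGE
        assert scores.bias_class is None and scores.b75_25 is None
        assert curve is None
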