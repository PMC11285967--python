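import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from entrokal.entropy import (
    EntropyParams,
    TemplateMatchCounts,
    approximate_entropy,
    cp_variance,
    sample_entropy,
    sampen_variance,
    template_match_counts,
    windowed_entropy_series,
)
from entrokal.errors import EmptySeriesError, ParameterError, WindowTooShortError
from entrokal.signals import SignalRecord

from conftest import brute_apen, brute_match_counts, brute_sampen


class TestTemplateMatchCounts:
    def test_periodic_sequence_every_match_extends(self):
        # period-3 data: every matching 2-template extends to a 3-template
        window = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1], dtype=float)
        counts = template_match_counts(window, m=2, r=0.5)
        assert counts.b_count == counts.a_count > 0
        assert counts.cp == 1.0

    def test_monotone_window_has_no_matches(self):
        window = np.arange(20, dtype=float)
        counts = template_match_counts(window, m=2, r=0.5)
        assert counts.b_count == 0

    def test_matches_bruteforce_including_overlaps(self, rng):
        for _ in range(40):
            n = int(rng.integers(10, 41))
            m = int(rng.integers(1, 4))
            x = rng.normal(size=n)
            r = float(rng.uniform(0.1, 1.0))
            got = template_match_counts(x, m, r)
            B, A, KB, KA = brute_match_counts(x, m, r)
            assert (got.b_count, got.a_count, got.k_b, got.k_a) == (B, A, KB, KA)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            template_match_counts(np.arange(10.0), m=2, r=0.0)
        with pytest.raises(WindowTooShortError):
            template_match_counts(np.arange(3.0), m=2, r=0.5)

    def test_counts_invariants_enforced(self):
        with pytest.raises(ParameterError):
            TemplateMatchCounts(b_count=1, a_count=2)


class TestSampleEntropy:
    def test_constant_window_is_undefined(self):
        res = sample_entropy(np.ones(50))
        assert not res.defined and math.isnan(res.value)

    def test_periodic_window_gives_zero(self):
        window = np.tile([1.0, 2.0, 3.0], 10)
        res = sample_entropy(window, m=2, r=0.5)
        assert res.value == 0.0 and res.cp == 1.0

    def test_matches_bruteforce(self, rng):
        for _ in range(50):
            n = int(rng.integers(12, 61))
            x = rng.normal(size=n)
            r = 0.2 * x.std(ddof=1)
            got = sample_entropy(x, m=2, r=r)
            expected = brute_sampen(x, 2, r)
            if expected is None:
                assert not got.defined
            else:
                assert got.value == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_when_defined(self, rng):
        for _ in range(50):
            x = rng.normal(size=80)
            res = sample_entropy(x, m=2, c=0.25)
            if res.defined:
                assert res.value >= 0.0

    @given(alpha=st.floats(0.1, 50).filter(lambda a: a != 0), seed=st.integers(0, 100))
    def test_scale_invariance(self, alpha, seed):
        # r = c*sigma makes SampEn invariant under amplitude scaling
        x = np.random.default_rng(seed).normal(size=120)
        a = sample_entropy(x, m=2, c=0.2)
        b = sample_entropy(alpha * x, m=2, c=0.2)
        assert a.value == pytest.approx(b.value, rel=1e-9) or (
            not a.defined and not b.defined
        )

    def test_cp_nondecreasing_in_tolerance(self, rng):
        x = rng.normal(size=100)
        tolerances = np.linspace(0.05, 1.5, 12) * x.std(ddof=1)
        cps = [template_match_counts(x, 2, t).cp for t in tolerances]
        cps = [c for c in cps if not math.isnan(c)]
        assert all(a <= b + 1e-12 for a, b in zip(cps, cps[1:]))


class TestApproximateEntropy:
    def test_constant_window_with_absolute_tolerance(self):
        assert approximate_entropy(np.ones(30), m=2, r=0.5) == pytest.approx(0.0)

    def test_constant_window_with_relative_tolerance_undefined(self):
        assert math.isnan(approximate_entropy(np.ones(30), m=2))

    def test_matches_bruteforce(self, rng):
        for _ in range(50):
            n = int(rng.integers(12, 41))
            x = rng.normal(size=n)
            r = 0.25 * x.std(ddof=1)
            assert approximate_entropy(x, 2, r) == pytest.approx(
                brute_apen(x, 2, r), rel=1e-10
            )

    def test_self_match_bias_below_sampen(self, rng):
        # ApEn's self-matches bias it below SampEn on i.i.d. data
        diffs = []
        for _ in range(30):
            x = rng.normal(size=300)
            se = sample_entropy(x, m=2, c=0.15)
            ae = approximate_entropy(x, m=2, c=0.15)
            if se.defined:
                diffs.append(se.value - ae)
        assert np.mean(diffs) > 0


class TestCpVariance:
    def test_binomial_term_only(self):
        counts = TemplateMatchCounts(b_count=100, a_count=50, k_b=0, k_a=0)
        assert cp_variance(counts) == pytest.approx(0.25 / 100)

    def test_cp_one_collapses_to_overlap_difference(self):
        counts = TemplateMatchCounts(b_count=40, a_count=40, k_b=11, k_a=17)
        assert cp_variance(counts) == pytest.approx((17 - 11) / 40**2)

    def test_undefined_when_no_matches(self):
        assert math.isnan(cp_variance(TemplateMatchCounts(b_count=0, a_count=0)))

    def test_delta_method_scaling(self):
        counts = TemplateMatchCounts(b_count=100, a_count=50, k_b=0, k_a=0)
        assert sampen_variance(counts) == pytest.approx(cp_variance(counts) / 0.25)


class TestWindowedSeries:
    def test_window_count_and_tail_discard(self):
        sig = SignalRecord(np.random.default_rng(0).normal(size=1234), fs=100.0)
        series = windowed_entropy_series(sig, EntropyParams(L=500))
        assert series.n_windows == 2
        assert series.window_length == 500

    def test_window_length_derived_from_rate(self):
        sig = SignalRecord(np.random.default_rng(0).normal(size=3000), fs=256.0)
        series = windowed_entropy_series(sig, EntropyParams(L=None))
        assert series.window_length == 1280
        assert series.n_windows == 2

    def test_signal_shorter_than_window_errors(self):
        sig = SignalRecord(np.zeros(499), fs=100.0)
        with pytest.raises(EmptySeriesError):
            windowed_entropy_series(sig, EntropyParams(L=500))

    def test_undefined_windows_flagged_not_imputed(self):
        values = np.concatenate([np.zeros(500), np.random.default_rng(1).normal(size=500)])
        series = windowed_entropy_series(SignalRecord(values, fs=100.0), EntropyParams(L=500))
        assert not series.defined[0] and series.defined[1]

    def test_variance_attached_for_sampen(self, rng):
        sig = SignalRecord(rng.normal(size=600), fs=100.0)
        series = windowed_entropy_series(
            sig, EntropyParams(L=200), with_variance=True
        )
        assert series.variances is not None
        assert np.isfinite(series.variances).all()
        assert (series.variances > 0).all()

    def test_frame_schema(self, rng):
        sig = SignalRecord(rng.normal(size=1000), fs=100.0)
        df = windowed_entropy_series(sig, EntropyParams(L=500)).to_frame()
        assert list(df.columns) == ["window_index", "t_start", "entropy", "cp", "cp_variance"]
        assert df["t_start"].tolist() == [0.0, 5.0]
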