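"""Logistic annoyance models: evaluation, fitting, %HA bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from parloud import annoyance as ann
from parloud.annoyance import (
    LogisticParams,
    bin_by_loudness,
    fit_logistic,
    indoor_level,
    logistic,
    long_term_pct_ha,
    pct_highly_annoyed,
    short_term_annoyance,
)


class TestLogistic:
    def test_midpoint_is_half_maximum(self):
        p = LogisticParams(L=10.0, k=0.1, x0=20.0)
        assert logistic(20.0, p) == pytest.approx(5.0)

    def test_limit_is_maximum(self):
        p = LogisticParams(L=10.0, k=0.1, x0=20.0)
        assert logistic(1e6, p) == pytest.approx(10.0)

    @given(
        L=st.floats(1.0, 100.0),
        b=st.floats(0.85, 0.99),
        a=st.floats(0.01, 1.0),
        x=st.floats(0.0, 80.0),
    )
    def test_reparameterizations_agree(self, L, b, a, x):
        p = LogisticParams.from_reciprocal(L, a, b)
        reciprocal = 1.0 / (1.0 / L + a * b**x)
        assert logistic(x, p) == pytest.approx(reciprocal, rel=1e-12)
        assert p.a == pytest.approx(a, rel=1e-12)
        assert p.b == pytest.approx(b, rel=1e-12)

    def test_nonpositive_maximum_rejected(self):
        with pytest.raises(ValueError):
            LogisticParams(L=-1.0, k=0.1, x0=0.0)


class TestFittedCurves:
    def test_short_term_at_zero_loudness(self):
        # 1 / (0.1 + 0.463)
        assert short_term_annoyance(0.0) == pytest.approx(1.0 / 0.563, rel=1e-9)

    def test_short_term_saturates_at_ten(self):
        assert short_term_annoyance(1e5) == pytest.approx(10.0, rel=1e-6)

    def test_short_term_strictly_increasing(self):
        grid = np.linspace(0.0, 60.0, 200)
        vals = short_term_annoyance(grid)
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals <= 10.0)

    def test_long_term_at_zero_loudness_nonzero(self):
        # residents are annoyed even at zero loudness: 1/0.053
        assert long_term_pct_ha(0.0) == pytest.approx(18.87, abs=0.01)

    def test_long_term_at_twenty_sones(self):
        assert long_term_pct_ha(20.0) == pytest.approx(30.0, abs=0.1)

    def test_long_term_saturates_at_hundred(self):
        assert long_term_pct_ha(1e5) == pytest.approx(100.0, rel=1e-6)

    def test_negative_loudness_rejected(self):
        with pytest.raises(ValueError):
            short_term_annoyance(-1.0)
        with pytest.raises(ValueError):
            long_term_pct_ha(-1.0)


class TestFitLogistic:
    def test_noiseless_recovery(self):
        xs = np.arange(0.0, 61.0, 2.0)
        truth = LogisticParams.from_reciprocal(9.5, 0.4, 0.94)
        ys = logistic(xs, truth)
        m = fit_logistic(xs, ys, scale_max=10.0)
        assert m.params.L == pytest.approx(truth.L, rel=1e-6)
        assert m.params.b == pytest.approx(truth.b, rel=1e-6)
        assert m.params.a == pytest.approx(truth.a, rel=1e-6)
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_response_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_logistic(np.arange(10.0), np.full(10, 5.0))

    def test_too_few_distinct_x_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([1.0, 1.0, 2.0, 2.0], [1.0, 1.1, 2.0, 2.1])

    @pytest.mark.parametrize("b_true,sd", [(0.90, 0.3), (0.95, 0.5), (0.99, 0.2)])
    def test_parameter_recovery_under_noise(self, b_true, sd):
        # median recovered base over 100 seeded replicates within 0.01
        xs = np.arange(0.0, 61.0, 2.0)
        truth = LogisticParams.from_reciprocal(10.0, 0.463, b_true)
        clean = logistic(xs, truth)
        bs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ys = np.clip(clean + rng.normal(0.0, sd, xs.size), 1e-3, 10.0 - 1e-3)
            bs.append(fit_logistic(xs, ys, scale_max=10.0).params.b)
        assert abs(np.median(bs) - b_true) <= 0.01


class TestPctHighlyAnnoyed:
    def test_simple_counts(self):
        assert pct_highly_annoyed([8, 9, 10, 0]) == 75.0
        assert pct_highly_annoyed([7] * 12) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pct_highly_annoyed([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pct_highly_annoyed([11])

    def test_bernoulli_sampling_consistency(self):
        rng = np.random.default_rng(5)
        p = 0.3
        ratings = np.where(rng.random(10000) < p, 9, 2)
        assert pct_highly_annoyed(ratings) == pytest.approx(100 * p, abs=1.0)


class TestBinning:
    def test_nine_groups_for_0_to_45_sones(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "loudness_sone": rng.uniform(0.0, 44.9, 500),
                "highly_annoyed": rng.random(500) < 0.3,
            }
        )
        bins = bin_by_loudness(df)
        assert len(bins) == 9
        np.testing.assert_allclose(
            bins.upper_sone.to_numpy() - bins.lower_sone.to_numpy(), 5.0
        )

    def test_single_record_lands_in_its_bin(self):
        df = pd.DataFrame({"loudness_sone": [12.0], "highly_annoyed": [True]})
        bins = bin_by_loudness(df)
        assert len(bins) == 1
        assert bins.lower_sone[0] == 10.0 and bins.upper_sone[0] == 15.0

    def test_negative_loudness_rejected(self):
        df = pd.DataFrame({"loudness_sone": [-1.0], "highly_annoyed": [False]})
        with pytest.raises(ValueError):
            bin_by_loudness(df)

    def test_binned_pct_ha_tracks_generating_curve(self):
        rng = np.random.default_rng(11)
        loud = rng.uniform(0.0, 45.0, 20000)
        p = long_term_pct_ha(loud) / 100.0
        df = pd.DataFrame(
            {"loudness_sone": loud, "highly_annoyed": rng.random(loud.size) < p}
        )
        bins = bin_by_loudness(df)
        for row in bins.itertuples():
            expected = long_term_pct_ha(row.midpoint_sone)
            sigma = 100 * np.sqrt(expected / 100 * (1 - expected / 100) / row.n)
            assert abs(row.pct_ha - expected) < 4 * sigma + 1.0


class TestIndoorLevel:
    @pytest.mark.parametrize(
        "outdoor,source,expected",
        [(70.0, "aircraft", 55.0), (70.0, "road", 54.2), (0.0, "aircraft", -15.0)],
    )
    def test_corrections(self, outdoor, source, expected):
        assert indoor_level(outdoor, source) == pytest.approx(expected)

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            indoor_level(70.0, "railway")
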