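import numpy as np
import pandas as pd
import pytest

from opichatter.corpus import ClassLabel
from opichatter.geotemporal import (
    RegionRateTable,
    attach_metrics,
    correlate,
    monthly_series,
    quantile_bins,
    read_reference_metrics,
    region_rates,
    threshold_filter,
)

A, I, U, E = ClassLabel.A, ClassLabel.I, ClassLabel.U, ClassLabel.E


class TestMonthlySeries:
    def test_direct_count(self, posts_factory):
        posts = [
            posts_factory(0, "a", A, ts="2013-02-10T00:00:00+00:00"),
            posts_factory(1, "b", U, ts="2013-02-15T00:00:00+00:00"),
            posts_factory(2, "c", U, ts="2013-02-20T00:00:00+00:00"),
        ]
        series = monthly_series(posts)
        assert series.frequency("2013-02", A) == 1
        assert series.proportion("2013-02", A) == pytest.approx(1 / 3)

    def test_empty_month_flagged(self, posts_factory):
        posts = [
            posts_factory(0, "a", A, ts="2013-01-10T00:00:00+00:00"),
            posts_factory(1, "b", U, ts="2013-03-10T00:00:00+00:00"),
        ]
        series = monthly_series(posts)
        feb = pd.Period("2013-02", "M")
        assert feb in series.undefined_months
        assert series.frequency("2013-02", A) == 0
        assert np.isnan(series.proportion("2013-02", A))

    def test_chronological_order(self, posts_factory):
        posts = [
            posts_factory(0, "a", A, ts="2013-05-01T00:00:00+00:00"),
            posts_factory(1, "b", A, ts="2012-11-01T00:00:00+00:00"),
        ]
        series = monthly_series(posts)
        assert list(series.table.index) == sorted(series.table.index)

    def test_frequencies_sum_to_monthly_total(self, posts_factory):
        rng = np.random.default_rng(0)
        labels = [A, I, U, E]
        posts = [
            posts_factory(
                i, "t", labels[rng.integers(0, 4)],
                ts=f"2013-{rng.integers(1, 13):02d}-05T00:00:00+00:00",
            )
            for i in range(200)
        ]
        series = monthly_series(posts)
        freq_cols = [c for c in series.table.columns if c.startswith("freq_")]
        assert (series.table[freq_cols].sum(axis=1) == series.table["total"]).all()

    def test_generator_proportion_recovery(self):
        from opichatter.synthetic import GeneratorConfig, gen_corpus

        prev = 0.05
        cfg = GeneratorConfig(
            n_posts=6000,
            prevalences=_dist(prev),
            seed=11,
        )
        series = monthly_series(gen_corpus(cfg))
        props = series.table["prop_A"].dropna()
        se = np.sqrt(prev * (1 - prev) / (cfg.n_posts / len(props)))
        assert abs(props.mean() - prev) < 2 * se


def _dist(p_a):
    from opichatter.corpus import ClassDistribution

    rest = 1.0 - p_a
    return ClassDistribution({A: p_a, I: rest * 0.25, U: rest * 0.70, E: rest * 0.05})


class TestRegionRates:
    def test_per_post_ratio(self, posts_factory):
        posts = [
            posts_factory(i, "t", A if i < 5 else U, region="X") for i in range(100)
        ]
        table = region_rates(posts, mode="per_post")
        assert table.table.loc["X", "abuse_rate"] == pytest.approx(0.05)

    def test_per_capita_scaling(self, posts_factory):
        posts = [posts_factory(i, "t", A, region="X") for i in range(5)]
        table = region_rates(posts, {"X": 50_000}, mode="per_capita")
        assert table.table.loc["X", "abuse_rate"] == pytest.approx(10.0)

    def test_two_region_hand_tally(self, posts_factory):
        posts = (
            [posts_factory(i, "t", A, region="X") for i in range(2)]
            + [posts_factory(10 + i, "t", U, region="X") for i in range(6)]
            + [posts_factory(20 + i, "t", A, region="Y") for i in range(1)]
            + [posts_factory(30 + i, "t", I, region="Y") for i in range(3)]
        )
        table = region_rates(posts, mode="per_post")
        assert table.table.loc["X", "n_posts"] == 8
        assert table.table.loc["X", "n_abuse"] == 2
        assert table.table.loc["X", "abuse_rate"] == pytest.approx(2 / 8)
        assert table.table.loc["Y", "abuse_rate"] == pytest.approx(1 / 4)

    def test_unknown_region_per_capita_lists_ids(self, posts_factory):
        posts = [posts_factory(0, "t", A, region="ZZ")]
        with pytest.raises(ValueError, match="ZZ"):
            region_rates(posts, {"X": 1000}, mode="per_capita")

    def test_zero_post_region_flagged(self, posts_factory):
        posts = [posts_factory(0, "t", A, region="X")]
        table = region_rates(posts, {"X": 100, "Y": 100}, mode="per_post")
        assert bool(table.table.loc["Y", "no_posts"])
        assert np.isnan(table.table.loc["Y", "abuse_rate"])

    def test_abuse_conservation(self, posts_factory):
        rng = np.random.default_rng(1)
        labels = [A, I, U, E]
        posts = [
            posts_factory(i, "t", labels[rng.integers(0, 4)],
                          region=f"R{rng.integers(0, 7)}")
            for i in range(300)
        ]
        table = region_rates(posts, mode="per_post")
        total_abuse = sum(p.gold_label == A for p in posts)
        assert table.table["n_abuse"].sum() == total_abuse

    def test_bad_mode(self, posts_factory):
        with pytest.raises(ValueError):
            region_rates([posts_factory(0, "t", A)], mode="per_area")


class TestCorrelate:
    def test_affine_identity(self):
        x = np.arange(1.0, 11.0)
        res = correlate(x, 2 * x + 1)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_hand_computed_example(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        res = correlate(x, y)
        # closed-form: cov=10/.. r = 10/sqrt(10*14.8); spearman d^2 sum = 4
        assert res.pearson_r == pytest.approx(10 / np.sqrt(10 * 14.8), abs=1e-12)
        assert res.spearman_rho == pytest.approx(1 - 6 * 4 / (5 * 24), abs=1e-12)
        assert res.n == 5

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(20), rng.random(20)
        a, b = correlate(x, y), correlate(y, x)
        assert a.pearson_r == pytest.approx(b.pearson_r)
        assert a.spearman_rho == pytest.approx(b.spearman_rho)

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(30), rng.random(30)
        base = correlate(x, y).spearman_rho
        assert correlate(np.exp(3 * x), y).spearman_rho == pytest.approx(base)
        assert correlate(x, y**3).spearman_rho == pytest.approx(base)

    def test_zero_variance_flagged(self):
        res = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined
        assert np.isnan(res.pearson_r)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])


def _rate_table(deaths, rates=None):
    n = len(deaths)
    df = pd.DataFrame(
        {
            "n_posts": [100] * n,
            "n_abuse": [5] * n,
            "abuse_rate": rates if rates is not None else [0.05] * n,
            "death_count": deaths,
            "reference_metric": np.linspace(0, 1, n),
        },
        index=[f"R{i}" for i in range(n)],
    )
    return RegionRateTable(df)


class TestThresholdFilter:
    def test_zero_threshold_identity(self):
        table = _rate_table([10, 60, 120, 40, 200])
        assert len(threshold_filter(table, 0)) == 5

    def test_count_filter(self):
        table = _rate_table([10, 60, 120, 40, 200])
        assert len(threshold_filter(table, 50)) == 3

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError, match="every region"):
            threshold_filter(_rate_table([1, 2, 3]), 1000)

    def test_missing_death_count_rejected(self):
        table = _rate_table([1, 2, 3])
        table.table = table.table.drop(columns=["death_count"])
        with pytest.raises(ValueError, match="death_count"):
            threshold_filter(table, 10)

    def test_correlation_improves_with_threshold(self):
        """Heteroscedastic noise: high-death regions carry cleaner rates, so
        raising the threshold increases correlation."""
        rng = np.random.default_rng(8)
        n = 120
        signal = rng.random(n)
        deaths = np.round(10 + 290 * signal).astype(int)
        noise_scale = np.where(deaths >= 150, 0.02, 0.6)
        rates = signal + rng.normal(0, noise_scale)
        df = pd.DataFrame(
            {
                "n_posts": 100,
                "n_abuse": 5,
                "abuse_rate": rates,
                "death_count": deaths,
                "reference_metric": signal,
            },
            index=[f"R{i}" for i in range(n)],
        )
        table = RegionRateTable(df)
        rs = []
        for thresh in (0, 150):
            sub = threshold_filter(table, thresh)
            rs.append(
                correlate(sub.table["abuse_rate"], sub.table["reference_metric"]).pearson_r
            )
        assert rs[1] > rs[0]


class TestMetricsIO:
    def test_read_and_attach(self, tmp_path, posts_factory):
        path = tmp_path / "metrics.csv"
        path.write_text(
            "region_id,population,metric_name,metric_value,death_count\n"
            "X,1000,deaths,3.5,60\nY,2000,deaths,1.5,20\n"
        )
        metrics = read_reference_metrics(path)
        posts = [posts_factory(i, "t", A if i % 2 else U, region="X") for i in range(10)]
        table = attach_metrics(region_rates(posts, mode="per_post"), metrics)
        assert table.table.loc["X", "reference_metric"] == pytest.approx(3.5)
        assert table.table.loc["X", "death_count"] == 60

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "metrics.csv"
        path.write_text("region_id,population\nX,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_reference_metrics(path)

    def test_quantile_bins(self):
        bins = quantile_bins(np.arange(25), n_bins=5)
        assert sorted(set(bins)) == [0, 1, 2, 3, 4]
        assert (np.bincount(bins) == 5).all()
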