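"""Geotemporal aggregation of classified posts and correlation against
reference health metrics (e.g. county overdose death rates, survey
percentages)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import ClassLabel, LABELS, Post

__all__ = [
    "MonthlySeries",
    "RegionRateTable",
    "CorrelationResult",
    "monthly_series",
    "region_rates",
    "correlate",
    "threshold_filter",
    "read_reference_metrics",
]


@dataclass
class MonthlySeries:
    """Per calendar month: class frequencies and proportions of the monthly
    total.  Months without posts carry zero frequencies and NaN proportions
    (flagged in ``undefined_months``)."""

    table: pd.DataFrame  # index: month Periods; columns: freq_<c>, prop_<c>, total
    undefined_months: list = field(default_factory=list)

    def frequency(self, month: str, label: ClassLabel) -> int:
        return int(self.table.loc[pd.Period(month, "M"), f"freq_{label.value}"])

    def proportion(self, month: str, label: ClassLabel) -> float:
        return float(self.table.loc[pd.Period(month, "M"), f"prop_{label.value}"])


def monthly_series(
    posts: Sequence[Post], classes: Optional[set] = None
) -> MonthlySeries:
    """Bucket labeled posts by calendar month (UTC).

    ``classes`` restricts the reported per-class columns (default: all four);
    proportions are relative to *all* posts that month.
    """
    if classes is None:
        classes = set(LABELS)
    classes = {c if isinstance(c, ClassLabel) else ClassLabel(str(c)) for c in classes}
    if not posts:
        raise ValueError("no posts to aggregate")
    months = pd.PeriodIndex(
        [pd.Period(p.timestamp.strftime("%Y-%m"), "M") for p in posts], freq="M"
    )
    labels = [p.gold_label for p in posts]
    full_range = pd.period_range(months.min(), months.max(), freq="M")
    df = pd.DataFrame(index=full_range)
    totals = pd.Series(1, index=months).groupby(level=0).count()
    df["total"] = totals.reindex(full_range, fill_value=0)
    for lab in sorted(classes, key=lambda l: l.value):
        hits = pd.Series(
            [1 if l == lab else 0 for l in labels], index=months
        ).groupby(level=0).sum()
        df[f"freq_{lab.value}"] = hits.reindex(full_range, fill_value=0).astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            df[f"prop_{lab.value}"] = np.where(
                df["total"] > 0, df[f"freq_{lab.value}"] / df["total"], np.nan
            )
    undefined = list(df.index[df["total"] == 0])
    return MonthlySeries(df, undefined)


@dataclass
class RegionRateTable:
    """Per-region post counts, abuse counts, rates and reference metrics."""

    table: pd.DataFrame  # index region_id; columns n_posts, n_abuse, abuse_rate,
    #                      population, reference_metric, death_count
    mode: str = "per_post"

    def __len__(self) -> int:
        return len(self.table)

    @property
    def regions(self) -> list[str]:
        return list(self.table.index)


def region_rates(
    posts: Sequence[Post],
    populations: Optional[Mapping[str, float]] = None,
    mode: str = "per_post",
    abuse_label: ClassLabel = ClassLabel.A,
) -> RegionRateTable:
    """Aggregate abuse-indicating post rates per region.

    ``per_post``: rate = abuse posts / all posts in the region (robust to
    regional user-base size; the default).  ``per_capita``: abuse posts per
    100,000 population, requiring every region in ``populations``.
    """
    if mode not in ("per_post", "per_capita"):
        raise ValueError(f"unknown mode {mode!r}")
    if not posts:
        raise ValueError("no posts to aggregate")
    rows: dict[str, dict] = {}
    for p in posts:
        rec = rows.setdefault(p.region_id, {"n_posts": 0, "n_abuse": 0})
        rec["n_posts"] += 1
        if p.gold_label == abuse_label:
            rec["n_abuse"] += 1
    if populations is not None:
        for rid in populations:
            rows.setdefault(rid, {"n_posts": 0, "n_abuse": 0})
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "region_id"
    if mode == "per_capita":
        if populations is None:
            raise ValueError("per_capita mode requires populations")
        unknown = sorted(set(df.index) - set(populations))
        if unknown:
            raise ValueError(f"regions missing from populations: {unknown}")
        pops = pd.Series(populations, dtype=float).reindex(df.index)
        if (pops <= 0).any():
            raise ValueError("populations must be positive in per_capita mode")
        df["population"] = pops
        df["abuse_rate"] = df["n_abuse"] / df["population"] * 100_000.0
    else:
        if populations is not None:
            df["population"] = pd.Series(populations, dtype=float).reindex(df.index)
        with np.errstate(invalid="ignore", divide="ignore"):
            df["abuse_rate"] = np.where(
                df["n_posts"] > 0, df["n_abuse"] / df["n_posts"].replace(0, 1), np.nan
            )
    df["no_posts"] = df["n_posts"] == 0
    return RegionRateTable(df, mode)


@dataclass
class CorrelationResult:
    pearson_r: float
    p_pearson: float
    spearman_rho: float
    p_spearman: float
    n: int
    defined: bool = True

    def as_row(self, measure: str) -> dict:
        return {
            "measure": measure,
            "pearson_r": round(self.pearson_r, 3) if self.defined else "",
            "p_pearson": round(self.p_pearson, 4) if self.defined else "",
            "spearman_rho": round(self.spearman_rho, 3) if self.defined else "",
            "p_spearman": round(self.p_spearman, 4) if self.defined else "",
            "n": self.n,
        }


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson (on values) and Spearman (average-rank ties) correlation with
    two-tailed t-approximation p-values.  Zero variance in either vector
    yields a flagged, undefined result."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need n >= 3 for defined p-values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, int(x.size), False)
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(
        float(pr.statistic),
        float(pr.pvalue),
        float(sr.statistic),
        float(sr.pvalue),
        int(x.size),
    )


def threshold_filter(table: RegionRateTable, min_deaths: int) -> RegionRateTable:
    """Retain regions whose death count meets ``min_deaths`` (so correlations
    can be recomputed on higher-signal subsets)."""
    if "death_count" not in table.table.columns:
        raise ValueError("table has no death_count column")
    kept = table.table[table.table["death_count"] >= min_deaths]
    if kept.empty:
        raise ValueError(f"min_deaths={min_deaths} removes every region")
    return RegionRateTable(kept.copy(), table.mode)


def read_reference_metrics(path: str | Path) -> pd.DataFrame:
    """CSV with columns region_id, population, metric_name, metric_value and
    optional death_count; indexed by region_id."""
    df = pd.read_csv(path, dtype={"region_id": str})
    required = {"region_id", "population", "metric_name", "metric_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df.set_index("region_id")


def attach_metrics(table: RegionRateTable, metrics: pd.DataFrame) -> RegionRateTable:
    df = table.table.join(
        metrics[[c for c in ("metric_value", "death_count", "population") if c in metrics.columns]],
        how="inner",
        rsuffix="_ref",
    )
    df = df.rename(columns={"metric_value": "reference_metric"})
    return RegionRateTable(df, table.mode)


def quantile_bins(values: Sequence[float], n_bins: int = 5) -> np.ndarray:
    """Quantile bin index (0..n_bins-1) per value, for heat-map shading."""
    s = pd.Series(values, dtype=float)
    return pd.qcut(s.rank(method="first"), n_bins, labels=False).to_numpy()


def plot_choropleth(table: RegionRateTable, out_path: str | Path, n_bins: int = 5):
    """Optional thin rendering layer: one shaded cell per region, ordered by
    region id — a schematic stand-in for a true shapefile choropleth."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.table.dropna(subset=["abuse_rate"])
    bins = quantile_bins(df["abuse_rate"], n_bins)
    ncols = int(math.ceil(math.sqrt(len(df))))
    fig, ax = plt.subplots(figsize=(8, 8))
    cmap = plt.get_cmap("OrRd", n_bins)
    for i, (rid, _row) in enumerate(df.iterrows()):
        r, c = divmod(i, ncols)
        ax.add_patch(plt.Rectangle((c, -r), 0.95, 0.95, color=cmap(int(bins[i]))))
        ax.text(c + 0.5, -r + 0.5, str(rid), ha="center", va="center", fontsize=6)
    ax.set_xlim(-0.5, ncols + 0.5)
    ax.set_ylim(-(len(df) // ncols + 1.5), 1.5)
    ax.axis("off")
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
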