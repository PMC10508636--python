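"""Bias and power quantification for ascertained vs. unascertained fits.

Implements the study-level metrics: flipped-verdict fractions between fit
tables (rejected under ascertainment but accepted on all sites, and vice
versa), residual-SE / R-squared of Z-score trends, percentile classifiers
against thinned-replicate null distributions, and power against sets of
incorrect graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FitTable:
    """WR/LL per topology for one SNP set."""

    label: str
    table: pd.DataFrame  # columns: topology, wr, ll

    @classmethod
    def from_fits(cls, label: str, topology_ids, fits) -> "FitTable":
        return cls(label, pd.DataFrame({
            "topology": list(topology_ids),
            "wr": [f.wr for f in fits],
            "ll": [f.ll for f in fits],
        }))

    def aligned(self, other: "FitTable") -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        m = self.table.merge(other.table, on="topology", suffixes=("_a", "_b"))
        if m.empty:
            raise ValueError("fit tables share no topologies")
        return (m["wr_a"].to_numpy(), m["wr_b"].to_numpy(),
                m["ll_a"].to_numpy(), m["ll_b"].to_numpy())


def flipped_fractions(all_sites: FitTable, ascertained: FitTable,
                      threshold: float = 3.0) -> tuple[float, float]:
    """(bias fraction, power fraction) of verdict flips at a WR threshold.

    Bias fraction: topologies rejected under ascertainment (WR > threshold)
    but accepted on all sites (WR < threshold) — the probability proxy for
    rejecting a true model.  Power fraction: the converse flips.
    """
    wr_all, wr_asc, _, _ = all_sites.aligned(ascertained)
    n = len(wr_all)
    bias = np.sum((wr_asc > threshold) & (wr_all < threshold)) / n
    power = np.sum((wr_asc < threshold) & (wr_all > threshold)) / n
    return float(bias), float(power)


def trend_dispersion(x, y, zero_intercept: bool = False,
                     z_cap: float | None = None):
    """OLS trend of ascertained on unascertained values and its dispersion.

    Returns (residual SE, R^2, slope, intercept).  ``z_cap`` optionally
    drops points with |x| >= z_cap before fitting (the |Z| < 15 restriction
    used for f4 Z-score panels); ``zero_intercept`` forces the line through
    the origin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if z_cap is not None:
        keep = np.abs(x) < z_cap
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: zero variance")
    if zero_intercept:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        p = 1
    else:
        slope, intercept = np.polyfit(x, y, 1)
        p = 2
    resid = y - (slope * x + intercept)
    rss = float(np.sum(resid ** 2))
    residual_se = float(np.sqrt(rss / (x.size - p)))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return residual_se, r2, float(slope), float(intercept)


@dataclass
class ThinnedNull:
    """Null distribution of a metric across random site subsamples."""

    metric: str
    values: np.ndarray
    seeds: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.values)

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.values, q))


def classify_bias(metric_value: float, null: ThinnedNull, side: str = "upper",
                  percentile: float = 2.5) -> str:
    """"biased" iff the metric lies beyond the null percentile (strict).

    ``side="upper"`` flags values above the (100 - percentile)-th percentile
    (metrics that grow with bias, e.g. residual SE or flip fractions);
    ``side="lower"`` flags values below the percentile-th percentile (e.g.
    R^2).  The strict-inequality convention at the threshold is deliberate
    and documented.
    """
    if null.n == 0:
        raise ValueError("empty null distribution")
    if 100.0 / null.n > percentile:
        raise ValueError(
            f"null of {null.n} replicates cannot resolve the {percentile} percentile")
    if side == "upper":
        thr = null.percentile(100.0 - percentile)
        return "biased" if metric_value > thr else "unbiased"
    if side == "lower":
        thr = null.percentile(percentile)
        return "biased" if metric_value < thr else "unbiased"
    raise ValueError(f"unknown side: {side}")


@dataclass
class BiasReport:
    """Summary of one ascertainment scheme against the all-sites baseline."""

    scheme: str
    bias_fraction: float
    power_fraction: float
    r2_wr: float
    r2_ll: float
    residual_se_wr: float
    verdict: str | None = None
    null_percentile: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("scheme", "bias_fraction", "power_fraction", "r2_wr",
                 "r2_ll", "residual_se_wr", "verdict", "null_percentile")}


def bias_report(all_sites: FitTable, ascertained: FitTable,
                threshold: float = 3.0,
                null: ThinnedNull | None = None,
                null_side: str = "upper",
                null_percentile: float = 2.5,
                top_k: int | None = None) -> BiasReport:
    """Full comparison of one ascertained fit table with the baseline.

    ``top_k`` restricts to the K best-fitting topologies by baseline LL
    before computing correlation metrics (the "5,000 best-fitting graphs"
    pre-selection).
    """
    base = all_sites
    if top_k is not None:
        keep = base.table.nsmallest(top_k, "ll")["topology"]
        base = FitTable(base.label, base.table[base.table["topology"].isin(keep)])
        ascertained = FitTable(ascertained.label,
                               ascertained.table[ascertained.table["topology"].isin(keep)])
    bias, power = flipped_fractions(base, ascertained, threshold)
    wr_a, wr_b, ll_a, ll_b = base.aligned(ascertained)
    res_se, r2_wr, _, _ = trend_dispersion(wr_a, wr_b)
    _, r2_ll, _, _ = trend_dispersion(ll_a, ll_b)
    verdict = None
    if null is not None:
        verdict = classify_bias(bias, null, side=null_side,
                                percentile=null_percentile)
    return BiasReport(scheme=ascertained.label, bias_fraction=bias,
                      power_fraction=power, r2_wr=r2_wr, r2_ll=r2_ll,
                      residual_se_wr=res_se, verdict=verdict,
                      null_percentile=null_percentile if null else None)


def power_vs_incorrect(all_sites: FitTable, ascertained: FitTable,
                       threshold: float = 3.0) -> tuple[float, float]:
    """Power summary over a set of incorrect graphs.

    Returns (median WR difference ascertained - all sites, proportion of
    incorrect graphs rejected on all sites but accepted under
    ascertainment).  A negative median difference means ascertainment makes
    wrong graphs look better than they are.
    """
    wr_all, wr_asc, _, _ = all_sites.aligned(ascertained)
    if len(wr_all) == 0:
        raise ValueError("empty fit tables")
    delta = float(np.median(wr_asc - wr_all))
    flips = float(np.mean((wr_all > threshold) & (wr_asc < threshold)))
    return delta, flips


def scatter_export(x, y, path, xlabel: str = "all sites",
                   ylabel: str = "ascertained") -> None:
    """Minimal scatter plot export (diagnostics, not publication styling)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(np.asarray(x), np.asarray(y), s=6, alpha=0.5)
    lim = max(np.max(np.abs(x)), np.max(np.abs(y))) * 1.05
    ax.plot([-lim, lim], [-lim, lim], lw=0.5, color="grey")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
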