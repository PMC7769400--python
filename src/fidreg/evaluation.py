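"""Statistical comparison of registration methods against the gold standard.

Per-setup accuracy metrics are paired by construction (every method is
scored on the same setups), so methods are compared to the point-match
baseline with the Wilcoxon signed-rank test, the standard nonparametric
choice when the error distributions are non-Gaussian and the sample per
site is small (tens of setups).  Significance is judged per comparison at
``alpha = 0.05``; no multiple-testing correction is applied across axes
and methods (a caveat, not an endorsement — see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateSampleError, InvalidArgumentError, MissingBaselineError

__all__ = [
    "WilcoxonResult",
    "ComparisonTable",
    "wilcoxon_signed_rank",
    "summarize",
    "export_distributions",
]

#: Largest sample for which the exact signed-rank null is enumerated.
EXACT_N_MAX = 12


@dataclass(frozen=True)
class WilcoxonResult:
    """Outcome of a two-sided Wilcoxon signed-rank test."""

    statistic: float  # smaller of the positive/negative rank sums
    p_value: float
    n_effective: int  # pairs remaining after zero-difference removal
    significant: bool


def wilcoxon_signed_rank(x, y=None, alpha: float = 0.05, zero_method: str = "wilcox") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    With one argument, tests the differences against zero; with two,
    tests ``x - y``.  Zero differences are discarded before ranking
    (classic Wilcoxon); pass ``zero_method="pratt"`` to keep them in the
    ranking.  The exact null distribution is enumerated for
    ``n_effective <= 12`` tie-free samples; larger (or tied) samples use
    the normal approximation with tie and continuity corrections.

    Raises
    ------
    DegenerateSampleError
        If every difference is zero (the test is undefined).
    InvalidArgumentError
        If fewer than 5 non-zero pairs remain.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if y is not None and len(x) != len(np.asarray(y)):
        raise InvalidArgumentError("paired samples must have equal length")
    if np.all(d == 0):
        raise DegenerateSampleError("all paired differences are zero; the signed-rank test is undefined")
    nz = d[d != 0]
    n_eff = len(nz)
    if n_eff < 5:
        raise InvalidArgumentError(f"need >= 5 non-zero paired differences, got {n_eff}")
    ranks_tied = len(np.unique(np.abs(nz))) < n_eff
    use_exact = n_eff <= EXACT_N_MAX and not ranks_tied and (zero_method == "wilcox" or not np.any(d == 0))
    res = stats.wilcoxon(
        d,
        zero_method=zero_method,
        correction=True,
        alternative="two-sided",
        method="exact" if use_exact else "approx",
    )
    p = float(res.pvalue)
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=p,
        n_effective=n_eff,
        significant=bool(p < alpha),
    )


@dataclass(frozen=True)
class ComparisonTable:
    """Summary statistics per (site, method, metric) plus p-values vs baseline.

    ``table`` holds mean, sample (n-1) standard deviation and count;
    ``p_values`` holds the Wilcoxon comparison of each method against the
    baseline: paired on per-setup values for scalar metrics, and — for
    the isocenter residuals, which are already method-minus-baseline
    differences — a signed-rank test of the components against zero.
    """

    table: pd.DataFrame
    p_values: pd.DataFrame
    alpha: float
    baseline: str


def summarize(report: pd.DataFrame, alpha: float = 0.05, baseline: str = "PM") -> ComparisonTable:
    """Aggregate a tidy experiment report into a comparison table.

    Expects the columns produced by
    :func:`fidreg.phantom_sim.run_experiment`; rows may arrive in any
    order (the result is order-invariant).
    """
    if report is None or len(report) == 0:
        raise InvalidArgumentError("empty experiment report")
    required = {"site", "setup", "method", "metric", "axis", "value"}
    missing = required - set(report.columns)
    if missing:
        raise InvalidArgumentError(f"report missing columns: {sorted(missing)}")
    if baseline not in set(report["method"]):
        raise MissingBaselineError(f"no rows for baseline method {baseline!r}")
    df = report.copy()
    df["axis"] = df["axis"].fillna("")
    summary = (
        df.groupby(["site", "method", "metric", "axis"], as_index=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .sort_values(["site", "method", "metric", "axis"])
        .reset_index(drop=True)
    )
    pvals: list[dict] = []
    for site, site_df in df.groupby("site"):
        base = site_df[(site_df["method"] == baseline)]
        for method in sorted(set(site_df["method"]) - {baseline}):
            mdf = site_df[site_df["method"] == method]
            for (metric, axis), sel in mdf.groupby(["metric", "axis"]):
                sel = sel.sort_values("setup")
                try:
                    if metric.startswith("ire_"):
                        if axis == "mag":
                            continue  # magnitudes are one-sided by construction
                        res = wilcoxon_signed_rank(sel["value"].to_numpy(), alpha=alpha)
                    else:
                        bsel = base[base["metric"] == metric].sort_values("setup")
                        if len(bsel) != len(sel):
                            continue
                        res = wilcoxon_signed_rank(
                            sel["value"].to_numpy(), bsel["value"].to_numpy(), alpha=alpha
                        )
                except DegenerateSampleError:
                    continue
                pvals.append(
                    {"site": site, "method": method, "metric": metric, "axis": axis,
                     "p_value": res.p_value, "n_effective": res.n_effective,
                     "significant": res.significant}
                )
    p_df = pd.DataFrame(
        pvals, columns=["site", "method", "metric", "axis", "p_value", "n_effective", "significant"]
    ).sort_values(["site", "method", "metric", "axis"]).reset_index(drop=True)
    return ComparisonTable(table=summary, p_values=p_df, alpha=alpha, baseline=baseline)


def export_distributions(report: pd.DataFrame, bins: int = 20) -> pd.DataFrame:
    """Density-normalized histograms per (site, method, metric, axis).

    Each group's bin heights integrate to 1 (sum of width x height), the
    natural scaling for overlaying error distributions measured with
    different numbers of observations.  Returns a tidy table with columns
    site, method, metric, axis, bin_left, bin_right, density.
    """
    if bins < 2:
        raise InvalidArgumentError(f"bins must be >= 2, got {bins}")
    if report is None or len(report) == 0:
        warnings.warn("export_distributions: empty selection, returning empty table")
        return pd.DataFrame(
            columns=["site", "method", "metric", "axis", "bin_left", "bin_right", "density"]
        )
    df = report.copy()
    df["axis"] = df["axis"].fillna("")
    out: list[dict] = []
    for (site, method, metric, axis), sel in df.groupby(["site", "method", "metric", "axis"]):
        values = sel["value"].to_numpy(dtype=float)
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:  # single-valued group: one occupied unit-density bin
            width = max(abs(lo) * 1e-6, 1e-9)
            edges = np.linspace(lo - width / 2, lo + width / 2, bins + 1)
        else:
            edges = np.linspace(lo, hi, bins + 1)
        density, edges = np.histogram(values, bins=edges, density=True)
        for left, right, dens in zip(edges[:-1], edges[1:], density):
            out.append(
                {"site": site, "method": method, "metric": metric, "axis": axis,
                 "bin_left": float(left), "bin_right": float(right), "density": float(dens)}
            )
    return pd.DataFrame(out)
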