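"""Super-plot summaries, volume fractions and group comparisons.

The super-plot convention reports every individual measurement, the
per-tomogram (replicate) means, and an overall summary; the overall mean and
s.d. here are computed across all item values (the printed n's accompany the
overall means), with the per-tomogram means and their s.d. also emitted so
either convention is recoverable.

The Mann-Whitney U test is exact by full enumeration of rank arrangements
(mid-ranks for ties) for combined n <= 25, matching the small per-tomogram
group sizes of tomography studies; larger samples fall back to the normal
approximation with a flag.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError

__all__ = [
    "MeasurementTable",
    "SuperPlotSummary",
    "superplot",
    "volume_fractions",
    "MannWhitneyResult",
    "mann_whitney_exact",
    "defect_frequency_compare",
    "plot_superplot",
]

TABLE_COLUMNS = ["value", "unit", "item_id", "group_id", "region", "genotype", "metric"]

REGIONS = ("axon", "C-domain", "T-zone", "P-domain", "filopodia")

# overlap resolution priority for volume fractions (first wins)
MASK_PRIORITY = ["microtubule", "actin", "membrane", "ribosome"]


def MeasurementTable(rows: list[dict] | pd.DataFrame) -> pd.DataFrame:
    """Long-format measurement table with the canonical columns.

    One row per measured item: value, unit, item_id, group_id (tomogram),
    region, genotype, metric.  Raises on missing value/group/metric fields
    or inconsistent units within a metric.
    """
    df = pd.DataFrame(rows)
    for col in TABLE_COLUMNS:
        if col not in df.columns:
            if col in ("region", "genotype", "unit"):
                df[col] = ""
            else:
                raise ValidationError(f"measurement table missing column {col!r}")
    if df["value"].isna().any() or (df["metric"] == "").any():
        raise ValidationError("missing value/metric entries in measurement table")
    for metric, sub in df.groupby("metric"):
        if sub["unit"].nunique() > 1:
            raise ValidationError(f"inconsistent units within metric {metric!r}")
    return df[TABLE_COLUMNS]


@dataclass
class SuperPlotSummary:
    """Per-item values, per-tomogram means and overall summary for one metric."""

    metric: str
    values: np.ndarray
    group_means: dict[str, float]
    overall_mean: float
    overall_sd: float
    overall_median: float
    n_items: int
    n_groups: int
    group_mean_sd: float = float("nan")  # s.d. across tomogram means


def superplot(table: pd.DataFrame, metric: str) -> SuperPlotSummary:
    """Summarize one metric of a measurement table, super-plot style."""
    sub = table[table["metric"] == metric]
    if len(sub) == 0:
        raise ValidationError(f"unknown metric {metric!r}")
    values = sub["value"].to_numpy(dtype=float)
    gm = sub.groupby("group_id")["value"].mean()
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    gsd = float(gm.std(ddof=1)) if len(gm) > 1 else 0.0
    return SuperPlotSummary(
        metric=metric,
        values=values,
        group_means=gm.to_dict(),
        overall_mean=float(np.mean(values)),
        overall_sd=sd,
        overall_median=float(np.median(values)),
        n_items=len(values),
        n_groups=len(gm),
        group_mean_sd=gsd,
    )


def volume_fractions(masks: dict[str, np.ndarray],
                     priority: list[str] | None = None) -> dict[str, float]:
    """Per-feature segmentation volume as a percentage of all features.

    Masks must share one grid; overlapping voxels are resolved by the
    priority order (first listed wins) with a warning.  Percentages sum to
    100 over the features present.
    """
    import warnings

    if not masks:
        raise ValidationError("no masks given")
    shapes = {m.shape for m in masks.values()}
    if len(shapes) != 1:
        raise ValidationError("all masks must share one grid")
    order = list(priority) if priority else [k for k in MASK_PRIORITY if k in masks]
    order += [k for k in masks if k not in order]
    claimed = np.zeros(next(iter(shapes)), dtype=bool)
    counts: dict[str, int] = {}
    overlapped = False
    for name in order:
        m = masks[name].astype(bool)
        if np.any(m & claimed):
            overlapped = True
            m = m & ~claimed
        counts[name] = int(m.sum())
        claimed |= m
    if overlapped:
        warnings.warn("overlapping masks resolved by priority order", stacklevel=2)
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("all masks empty: fractions undefined")
    return {k: 100.0 * v / total for k, v in counts.items()}


@dataclass
class MannWhitneyResult:
    U: float
    p: float
    exact: bool
    n_a: int
    n_b: int


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def mann_whitney_exact(group_a, group_b, max_exact_n: int = 25) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with exact enumeration p-value.

    The p-value enumerates all C(n, n_a) assignments of the pooled mid-ranks
    and counts arrangements whose U deviates from the null mean n_a*n_b/2 at
    least as much as observed (ties handled by mid-ranks).  For combined
    n > ``max_exact_n`` a normal approximation (tie-corrected) is used and
    flagged via ``exact=False``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    ranks = _midranks(np.concatenate([a, b]))
    R_a = float(ranks[:n_a].sum())
    U_obs = R_a - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    if n <= max_exact_n:
        dev = abs(U_obs - mu) - 1e-9
        const = n_a * (n_a + 1) / 2.0
        hits = 0
        total = 0
        for comb in itertools.combinations(ranks, n_a):
            U = sum(comb) - const
            total += 1
            if abs(U - mu) >= dev:
                hits += 1
        p = hits / total
        return MannWhitneyResult(U=float(U_obs), p=float(p), exact=True,
                                 n_a=n_a, n_b=n_b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(U=float(U_obs), p=float(res.pvalue), exact=False,
                             n_a=n_a, n_b=n_b)


def _tukey_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Boolean mask of extreme outliers by the Tukey fence Q3 + k*IQR.

    Quartiles use the 'nearest' rule so that with the few tomograms typical
    of these comparisons the fence is set by observed values rather than
    interpolation toward the extreme; a degenerate zero IQR flags nothing.
    """
    q1, q3 = np.percentile(values, [25, 75], method="nearest")
    iqr = q3 - q1
    if iqr <= 0:
        return np.zeros(len(values), dtype=bool)
    return values > q3 + k * iqr


def defect_frequency_compare(wt, ko, outlier_policy: str = "tukey3",
                             ) -> dict:
    """WT-vs-KO comparison of per-tomogram defect frequencies.

    Runs the exact Mann-Whitney test on all tomograms and again with
    extreme outliers (beyond Q3 + 3*IQR within each arm) removed, reporting
    both p-values and the rule applied.  Requires >= 3 tomograms per arm.
    """
    wt = np.asarray(wt, dtype=float)
    ko = np.asarray(ko, dtype=float)
    if len(wt) < 3 or len(ko) < 3:
        raise ValidationError("need >= 3 tomograms per arm")
    if outlier_policy != "tukey3":
        raise ValidationError(f"unknown outlier policy {outlier_policy!r}")
    full = mann_whitney_exact(wt, ko)
    out_wt = _tukey_outliers(wt)
    out_ko = _tukey_outliers(ko)
    wt_trim, ko_trim = wt[~out_wt], ko[~out_ko]
    if len(wt_trim) == 0 or len(ko_trim) == 0:
        trimmed = full
    else:
        trimmed = mann_whitney_exact(wt_trim, ko_trim)
    return {
        "p_all": full.p,
        "U_all": full.U,
        "p_outliers_removed": trimmed.p,
        "U_outliers_removed": trimmed.U,
        "outliers_wt": wt[out_wt].tolist(),
        "outliers_ko": ko[out_ko].tolist(),
        "outlier_rule": "value > Q3 + 3*IQR within arm",
        "n_wt": len(wt),
        "n_ko": len(ko),
    }


def plot_superplot(table: pd.DataFrame, metric: str, path: str) -> None:
    """Write a super-plot image: items small, tomogram means large, mean line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = superplot(table, metric)
    sub = table[table["metric"] == metric]
    fig, ax = plt.subplots(figsize=(4, 4))
    groups = list(summary.group_means)
    cmap = plt.get_cmap("tab10")
    rng = np.random.default_rng(0)
    for gi, g in enumerate(groups):
        vals = sub[sub["group_id"] == g]["value"].to_numpy()
        x = gi + rng.uniform(-0.15, 0.15, len(vals))
        ax.scatter(x, vals, s=12, color=cmap(gi % 10), alpha=0.6)
        ax.scatter([gi], [summary.group_means[g]], s=120, color=cmap(gi % 10),
                   edgecolor="k", zorder=3)
    ax.axhline(summary.overall_mean, color="k", lw=1.5)
    unit = sub["unit"].iloc[0]
    ax.set_ylabel(f"{metric} ({unit})" if unit else metric)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels(groups, rotation=45, ha="right", fontsize=7)
    ax.set_title(f"{metric}: {summary.overall_mean:.2f} +- {summary.overall_sd:.2f}"
                 f" (n={summary.n_items})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
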