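"""Normalization and rank-based statistics on c-Fos count tables.

Counts are normalized per region to the pooled mean of both conditions,
expressed as a percentage: ``100 * value / pooled_mean(region)``, so the
grand mean of every region is exactly 100.  Conditions are compared per
region with exact Mann-Whitney tests, and expression is related to
behavior with per-region Spearman correlations (exact permutation p at the
study's sample sizes).  Because every test downstream of normalization is
rank-based, the normalization is cosmetic for inference — it only puts the
group comparison on an interpretable percentage scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exact import mannwhitney_exact, spearman_exact
from .tables import BehaviorTable, CountTable

__all__ = [
    "RegionComparison",
    "normalize_counts",
    "region_group_comparison",
    "brain_behavior_correlation",
]


@dataclass(frozen=True)
class RegionComparison:
    """Mann-Whitney comparison of one region between conditions."""

    region: str
    u_statistic: float
    p_raw: float
    p_adjusted: float | None
    median_a: float
    median_b: float

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "u_statistic": self.u_statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "median_a": self.median_a,
            "median_b": self.median_b,
        }


def _check_same_regions(a: CountTable, b: CountTable) -> list[str]:
    if a.regions != b.regions:
        raise ValueError(
            f"region sets differ between conditions: {a.regions} vs "
            f"{b.regions}")
    return a.regions


def normalize_counts(table_a: CountTable, table_b: CountTable
                     ) -> tuple[CountTable, CountTable]:
    """Per-region percentage normalization to the pooled two-group mean.

    Each cell becomes ``100 * value / mean(region over all subjects of
    both conditions)``; with equal group sizes this equals normalizing to
    the mean of the two group means.  The grand mean per region of the
    combined output is 100 by construction.
    """
    regions = _check_same_regions(table_a, table_b)
    pooled = np.concatenate([table_a.values(), table_b.values()], axis=0)
    pooled_mean = pooled.mean(axis=0)
    zero = [r for r, m in zip(regions, pooled_mean) if m <= 0]
    if zero:
        raise ValueError(f"regions with pooled mean 0: {zero}")
    out = []
    for t in (table_a, table_b):
        df = t.data.astype(float) / pooled_mean * 100.0
        out.append(CountTable(condition=t.condition, data=df))
    return out[0], out[1]


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def region_group_comparison(norm_a: CountTable, norm_b: CountTable,
                            adjust: str | None = None
                            ) -> list[RegionComparison]:
    """Per-region Mann-Whitney tests between the two conditions.

    Exact enumeration p for groups of at most 8 per side, tie-corrected
    normal approximation otherwise.  ``adjust='bh'`` adds a
    Benjamini-Hochberg column; the default reports raw p only.
    """
    regions = _check_same_regions(norm_a, norm_b)
    va, vb = norm_a.values(), norm_b.values()
    if min(va.shape[0], vb.shape[0]) < 3:
        raise ValueError("need n >= 3 subjects per group")
    rows = []
    for j, region in enumerate(regions):
        u, p = mannwhitney_exact(va[:, j], vb[:, j])
        rows.append((region, u, p,
                     float(np.median(va[:, j])), float(np.median(vb[:, j]))))
    if adjust is None:
        adjusted = [None] * len(rows)
    elif adjust == "bh":
        adjusted = [float(v) for v in
                    benjamini_hochberg([r[2] for r in rows])]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return [
        RegionComparison(region=r, u_statistic=float(u), p_raw=float(p),
                         p_adjusted=adj, median_a=ma, median_b=mb)
        for (r, u, p, ma, mb), adj in zip(rows, adjusted)
    ]


def brain_behavior_correlation(behavior: BehaviorTable, counts: CountTable
                               ) -> pd.DataFrame:
    """Spearman correlation of D2 with each region's c-Fos counts.

    Subjects are aligned by label between the two tables.  Returns a
    DataFrame indexed by region with columns ``rho``, ``p_value`` and
    ``n``; a constant count column yields NaN (correlation undefined).
    """
    if set(behavior.subjects) != set(counts.subjects):
        raise ValueError(
            "behavior and count tables cover different subjects: "
            f"{sorted(set(behavior.subjects) ^ set(counts.subjects))}")
    d2 = behavior.data.loc[counts.data.index, "d2"].to_numpy(float)
    if d2.size < 4:
        raise ValueError("need n >= 4 subjects for correlation")
    rows = {}
    for region in counts.regions:
        x = counts.data[region].to_numpy(float)
        rho, p = spearman_exact(d2, x)
        rows[region] = {"rho": rho, "p_value": p, "n": int(d2.size)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "region"
    return out


def rank_transform(table: CountTable) -> CountTable:
    """Column-wise mid-rank transform (diagnostic; rank statistics are
    invariant under it)."""
    ranked = table.data.apply(lambda c: stats.rankdata(c), axis=0)
    ranked = pd.DataFrame(ranked, index=table.data.index,
                          columns=table.data.columns, dtype=float)
    return CountTable(condition=table.condition, data=ranked)
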