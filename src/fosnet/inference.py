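"""Resampling inference on global network metrics.

Two resampling schemes, kept deliberately distinct:

* **Bootstrap** — subjects are resampled with replacement (same n) and the
  whole estimation chain (Spearman matrix, thresholding, global metrics)
  is recomputed per replicate, giving a sampling distribution of
  transitivity and global efficiency around the observed network.
* **Shuffled null** — the off-diagonal upper-triangle (rho, p) pairs of
  the observed correlation matrix are permuted uniformly at random and
  mirrored, keeping the unit diagonal fixed, then re-thresholded.  Every
  replicate preserves symmetry, the diagonal, the off-diagonal value
  multiset, and (because p travels with rho) the thresholded edge count;
  what it destroys is the *placement* of edges, so it asks whether the
  observed metric depends on where the significant correlations sit, not
  on how many there are.

Observed metrics are compared against the null with the add-one empirical
p-value (1 + #{null >= obs}) / (1 + N), and between conditions with a
two-sided Wilcoxon rank-sum test on the two bootstrap distributions —
which treats resamples as independent observations and is therefore
anticonservative; it is implemented as published practice for this
analysis family, with the caveat documented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exact import spearman_matrix_exact
from .metrics import GlobalMetrics, global_metrics_from_weights
from .tables import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "MetricDistribution",
    "ChanceTest",
    "ComparisonResult",
    "bootstrap_metrics",
    "shuffle_correlation_matrix",
    "shuffled_null",
    "metric_vs_chance",
    "compare_conditions",
]

GLOBAL_METRIC_NAMES = ("transitivity", "global_efficiency")


@dataclass(frozen=True)
class MetricDistribution:
    """B resampled values of one named global metric."""

    metric_name: str
    source: str  # "bootstrap" | "shuffled_null"
    values: tuple[float, ...] = field(repr=False)
    B: int
    seed: int
    observed: float

    def __post_init__(self) -> None:
        if len(self.values) != self.B:
            raise ValueError("length of values must equal B")
        if self.source not in ("bootstrap", "shuffled_null"):
            raise ValueError(f"unknown source {self.source!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def to_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "source": self.source,
            "B": self.B,
            "seed": self.seed,
            "observed": self.observed,
            "values": [float(v) for v in self.values],
        }


@dataclass(frozen=True)
class ChanceTest:
    """Empirical comparison of an observed metric against its null."""

    metric_name: str
    observed: float
    empirical_p: float
    direction: str

    def to_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "observed": self.observed,
            "empirical_p": self.empirical_p,
            "direction": self.direction,
        }


@dataclass(frozen=True)
class ComparisonResult:
    """Between-condition Wilcoxon rank-sum comparison of one metric."""

    metric_name: str
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    greater: str  # label of the condition with the larger median

    def to_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "median_a": self.median_a,
            "median_b": self.median_b,
            "greater": self.greater,
        }


def _metrics_of_matrices(rho: np.ndarray, p: np.ndarray, alpha: float
                         ) -> GlobalMetrics:
    """Threshold matrices and compute global metrics on the result."""
    n = rho.shape[0]
    sig = np.zeros_like(rho, dtype=bool)
    finite = np.isfinite(p)
    sig[finite] = p[finite] < alpha
    np.fill_diagonal(sig, False)
    w = np.where(sig, np.abs(rho), 0.0)
    iu, ju = np.triu_indices(n, k=1)
    pos = int(((rho[iu, ju] >= 0) & sig[iu, ju]).sum())
    neg = int(((rho[iu, ju] < 0) & sig[iu, ju]).sum())
    return global_metrics_from_weights(w, pos, neg)


def bootstrap_metrics(table: CountTable, B: int = 100, alpha: float = 0.05,
                      seed: int = 0) -> list[MetricDistribution]:
    """Subject-level bootstrap of transitivity and global efficiency.

    Each of the B replicates resamples the animals with replacement,
    recomputes the exact Spearman matrix, re-thresholds at alpha, and
    recomputes both global metrics.  Replicates in which a region's
    resampled counts are constant simply drop that region's correlations
    (NaN rho cannot form edges); such events are logged.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    data = table.values()
    n = data.shape[0]
    observed = _observed_global_metrics(table, alpha)
    values = {name: [] for name in GLOBAL_METRIC_NAMES}
    n_constant_events = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        rho, p = spearman_matrix_exact(data[idx])
        if np.isnan(np.diag(rho)).any():
            n_constant_events += 1
        gm = _metrics_of_matrices(rho, p, alpha)
        values["transitivity"].append(gm.transitivity)
        values["global_efficiency"].append(gm.global_efficiency)
    if n_constant_events:
        logger.info("bootstrap %s: %d replicates had a constant region "
                    "column (region dropped for that replicate)",
                    table.condition, n_constant_events)
    return [
        MetricDistribution(
            metric_name=name, source="bootstrap",
            values=tuple(float(v) for v in values[name]), B=B, seed=seed,
            observed=(observed.transitivity if name == "transitivity"
                      else observed.global_efficiency))
        for name in GLOBAL_METRIC_NAMES
    ]


def _observed_global_metrics(table: CountTable, alpha: float) -> GlobalMetrics:
    rho, p = spearman_matrix_exact(table.values())
    return _metrics_of_matrices(rho, p, alpha)


def shuffle_correlation_matrix(rho_v: np.ndarray, p_v: np.ndarray,
                               rng: np.random.Generator
                               ) -> tuple[np.ndarray, np.ndarray]:
    """One diagonal-preserving shuffle replicate of (rho, p).

    Applies a single uniform permutation to the off-diagonal upper-triangle
    (rho, p) pairs and mirrors it, leaving the unit diagonal in place; the
    off-diagonal value multiset is preserved exactly.
    """
    m = rho_v.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    perm = rng.permutation(iu.size)
    r_new = np.eye(m)
    p_new = np.zeros((m, m))
    r_new[iu, ju] = r_new[ju, iu] = rho_v[iu, ju][perm]
    p_new[iu, ju] = p_new[ju, iu] = p_v[iu, ju][perm]
    return r_new, p_new


def shuffled_null(rho: pd.DataFrame, p: pd.DataFrame, alpha: float = 0.05,
                  N: int = 100, seed: int = 0) -> list[MetricDistribution]:
    """Diagonal-preserving shuffled null for the global metrics.

    Each replicate applies one uniform random permutation to the
    off-diagonal upper-triangle (rho, p) pairs, mirrors it to the lower
    triangle, re-thresholds at alpha and recomputes the metrics.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    rho_v = np.asarray(rho, dtype=float)
    p_v = np.asarray(p, dtype=float)
    if rho_v.shape != p_v.shape or rho_v.shape[0] != rho_v.shape[1]:
        raise ValueError("rho and p must be square and congruent")
    observed = _metrics_of_matrices(rho_v, p_v, alpha)
    values = {name: [] for name in GLOBAL_METRIC_NAMES}
    for _ in range(N):
        r_new, p_new = shuffle_correlation_matrix(rho_v, p_v, rng)
        gm = _metrics_of_matrices(r_new, p_new, alpha)
        values["transitivity"].append(gm.transitivity)
        values["global_efficiency"].append(gm.global_efficiency)
    return [
        MetricDistribution(
            metric_name=name, source="shuffled_null",
            values=tuple(float(v) for v in values[name]), B=N, seed=seed,
            observed=(observed.transitivity if name == "transitivity"
                      else observed.global_efficiency))
        for name in GLOBAL_METRIC_NAMES
    ]


def metric_vs_chance(observed: float, null: MetricDistribution,
                     direction: str = "greater") -> ChanceTest:
    """Add-one empirical p of the observed metric against its null.

    direction='greater': p = (1 + #{null >= observed}) / (1 + N); 'less'
    mirrors it; 'two_sided' doubles the smaller of the two (capped at 1).
    """
    vals = null.as_array()
    if vals.size == 0:
        raise ValueError("empty null distribution")
    n_ge = int((vals >= observed - 1e-12).sum())
    n_le = int((vals <= observed + 1e-12).sum())
    p_greater = (1 + n_ge) / (1 + vals.size)
    p_less = (1 + n_le) / (1 + vals.size)
    if direction == "greater":
        p = p_greater
    elif direction == "less":
        p = p_less
    elif direction == "two_sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return ChanceTest(metric_name=null.metric_name, observed=float(observed),
                      empirical_p=float(p), direction=direction)


def compare_conditions(dist_a: MetricDistribution, dist_b: MetricDistribution,
                       label_a: str = "A", label_b: str = "B"
                       ) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum between two bootstrap distributions."""
    if dist_a.metric_name != dist_b.metric_name:
        raise ValueError(
            f"metric mismatch: {dist_a.metric_name} vs {dist_b.metric_name}")
    a = dist_a.as_array()
    b = dist_b.as_array()
    stat, p = stats.ranksums(a, b)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    greater = label_a if med_a > med_b else label_b
    if med_a == med_b:
        greater = "tie"
    return ComparisonResult(
        metric_name=dist_a.metric_name, statistic=float(stat),
        p_value=float(p), median_a=med_a, median_b=med_b, greater=greater)
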