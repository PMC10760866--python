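"""The Q histone-mark similarity statistic and its summaries.

Q(i1, i2) = |log10(signal_i1 / signal_i2)| measures how dissimilar the
aggregate level of a histone modification is between two loci: Q = 0 for
identical signals and grows as the signals diverge.  Q is symmetric and
invariant to common rescaling of the two signals.  Pairs where either
signal is zero (or negative) have no defined Q; they are flagged with NaN,
excluded from summaries and counted.

The module also provides the derived summaries used to detect
diffusion-induced patterns: per-bin medians of Q against a grouping
variable (lattice distance or Hi-C spatial proximity), ordinary
least-squares slopes of those medians, a "chance" median from randomly
drawn within-class pairs (ignoring proximity), and the delta-delta
statistic (MedianQ_LL - MedianQ_EE) - (chance_LL - chance_EE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "q_similarity",
    "assign_bins",
    "equal_count_edges",
    "median_q_by_bin",
    "regression_slope",
    "slope_bootstrap_ci",
    "chance_median_q",
    "delta_delta",
    "QSummary",
]


def q_similarity(signal1, signal2):
    """|log10(signal1/signal2)|; NaN where either signal is not positive.

    Accepts scalars or arrays (broadcast).  NaN marks an undefined pair --
    callers exclude and count such pairs rather than raising.
    """
    s1 = np.asarray(signal1, dtype=float)
    s2 = np.asarray(signal2, dtype=float)
    valid = (s1 > 0) & (s2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.abs(np.log10(s1 / s2))
    q = np.where(valid, q, np.nan)
    if q.ndim == 0:
        return float(q)
    return q


def assign_bins(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per value for right-open bins [lo, hi), last bin closed.

    Values outside [edges[0], edges[-1]] get index -1.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing, length >= 2")
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = len(edges) - 2
    idx[(values < edges[0]) | (values > edges[-1])] = -1
    return idx


def equal_count_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin edges holding roughly equal numbers of observations."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to bin")
    edges = np.quantile(values, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        # Degenerate (constant) grouping variable: one catch-all bin.
        edges = np.array([edges[0], edges[0] + 1.0])
    return edges


def median_q_by_bin(pairs: pd.DataFrame, group_col: str, edges: np.ndarray,
                    q_col: str = "Q", class_col: str | None = "pair_class"):
    """Per-bin median Q (and counts) for each class of pairs.

    Pairs with undefined (NaN) Q are excluded.  Returns a DataFrame with
    one row per (class, bin): bin index, left/right edge, center, median Q,
    and count; empty bins appear with count 0 and NaN median.  Raises if no
    pair has a defined Q.
    """
    retained = pairs[np.isfinite(pairs[q_col].to_numpy(float))].copy()
    if retained.empty:
        raise ValueError("all pairs have undefined Q")
    edges = np.asarray(edges, dtype=float)
    retained["_bin"] = assign_bins(retained[group_col].to_numpy(float), edges)
    retained = retained[retained["_bin"] >= 0]
    classes = [None] if class_col is None else sorted(retained[class_col].unique())
    rows = []
    for cls in classes:
        sub = retained if cls is None else retained[retained[class_col] == cls]
        for b in range(len(edges) - 1):
            q = sub.loc[sub["_bin"] == b, q_col].to_numpy(float)
            rows.append(
                {
                    "pair_class": cls,
                    "bin": b,
                    "left": edges[b],
                    "right": edges[b + 1],
                    "center": 0.5 * (edges[b] + edges[b + 1]),
                    "median_q": float(np.median(q)) if q.size else np.nan,
                    "count": int(q.size),
                }
            )
    return pd.DataFrame(rows)


def regression_slope(centers, medians):
    """OLS fit of per-bin medians on bin centers.

    Returns ``(slope, intercept, stderr)``.  NaN medians (empty bins) are
    dropped; fewer than 2 remaining points is an error.
    """
    x = np.asarray(centers, dtype=float)
    y = np.asarray(medians, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("need at least 2 bins with defined medians")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.stderr)


def slope_bootstrap_ci(pairs: pd.DataFrame, group_col: str, edges: np.ndarray,
                       rng: np.random.Generator, q_col: str = "Q",
                       n_boot: int = 200, level: float = 0.95):
    """Bootstrap CI for the slope of median Q against the grouping variable.

    Resamples pairs with replacement, recomputes binned medians and the
    OLS slope.  Returns ``(slope, ci_low, ci_high)``; resamples where the
    slope is undefined (too few non-empty bins) are skipped.
    """
    retained = pairs[np.isfinite(pairs[q_col].to_numpy(float))]
    g = retained[group_col].to_numpy(float)
    q = retained[q_col].to_numpy(float)
    bins = assign_bins(g, edges)
    keep = bins >= 0
    g, q, bins = g[keep], q[keep], bins[keep]
    centers = 0.5 * (np.asarray(edges[:-1]) + np.asarray(edges[1:]))

    def binned_slope(b, qv):
        med = np.array(
            [np.median(qv[b == i]) if np.any(b == i) else np.nan
             for i in range(len(centers))]
        )
        return regression_slope(centers, med)[0]

    point = binned_slope(bins, q)
    draws = []
    n = len(q)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            draws.append(binned_slope(bins[idx], q[idx]))
        except ValueError:
            continue
    if not draws:
        raise ValueError("no bootstrap resample produced a defined slope")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(point), float(lo), float(hi)


def chance_median_q(signals, rng: np.random.Generator, n_draws: int = 10000):
    """Median Q over randomly drawn pairs of loci from one class.

    Draws ``n_draws`` unordered pairs of *distinct* loci uniformly (with
    replacement across draws) from the positive-signal loci and returns the
    median Q -- the similarity expected from the class's signal
    distribution alone, with no proximity information.
    """
    s = np.asarray(signals, dtype=float)
    s = s[s > 0]
    if s.size < 2:
        raise ValueError("need at least 2 loci with positive signal")
    i = rng.integers(0, s.size, size=n_draws)
    j = rng.integers(0, s.size - 1, size=n_draws)
    j[j >= i] += 1  # uniform over distinct partners
    return float(np.median(np.abs(np.log10(s[i] / s[j]))))


def delta_delta(median_ll, median_ee, chance_ll: float, chance_ee: float):
    """Per-bin (MedianQ_LL - MedianQ_EE) - (chance_LL - chance_EE).

    Positive values at low spatial proximity are the diffusion signature:
    the late-late excess dissimilarity beyond what the two classes' signal
    distributions alone would produce.
    """
    ll = np.asarray(median_ll, dtype=float)
    ee = np.asarray(median_ee, dtype=float)
    if ll.shape != ee.shape:
        raise ValueError("per-bin median arrays must be aligned")
    return (ll - ee) - (float(chance_ll) - float(chance_ee))


@dataclass
class QSummary:
    """Binned-median summary of Q for one mark (EE vs LL classes)."""

    bin_edges: np.ndarray
    medians: pd.DataFrame                     # output of median_q_by_bin
    chance: dict                              # class -> chance median
    slopes: dict                              # class -> (slope, intercept, stderr)
    delta_delta: np.ndarray
    n_dropped: int = 0
    extras: dict = field(default_factory=dict)

    def median_series(self, pair_class: str) -> np.ndarray:
        sub = self.medians[self.medians["pair_class"] == pair_class]
        return sub.sort_values("bin")["median_q"].to_numpy(float)

    def to_frame(self) -> pd.DataFrame:
        df = self.medians.copy()
        df["chance"] = df["pair_class"].map(self.chance)
        df["slope"] = df["pair_class"].map({c: s[0] for c, s in self.slopes.items()})
        df["slope_stderr"] = df["pair_class"].map({c: s[2] for c, s in self.slopes.items()})
        dd = pd.Series(self.delta_delta, index=range(len(self.delta_delta)))
        df["delta_delta"] = df["bin"].map(dd)
        df["n_dropped"] = self.n_dropped
        return df
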