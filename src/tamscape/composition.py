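"""Regional composition tables and 2x2 contingency statistics.

Each cell-type or activation-state row is compared between tumour core and
periphery with a Yates-continuity-corrected Pearson chi-squared test on the
2x2 table (state vs not-state, core vs periphery).  The Mann-Whitney test
used for ligand/receptor density comparisons lives here too: exact
permutation enumeration for small samples, normal approximation with tie
correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

REGIONS = ("core", "periphery")


@dataclass
class ContingencyResult:
    table: np.ndarray  # 2x2
    chi2: float
    p: float
    yates: bool
    proportions: tuple  # (a/(a+b), c/(c+d)) — row-wise first-column proportions


def chisq_2x2(a: int, b: int, c: int, d: int, yates: bool = True) -> ContingencyResult:
    """Pearson chi-squared on the 2x2 table [[a, b], [c, d]] with 1 df.

    With ``yates`` the absolute deviation |O - E| is reduced by 0.5 and
    clamped at zero before squaring (continuity correction).
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in contingency table")
    expected = np.outer(row, col) / total
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    p = float(chi2_dist.sf(stat, df=1)) if stat > 0 else 1.0
    props = (a / row[0] if row[0] else np.nan, c / row[1] if row[1] else np.nan)
    return ContingencyResult(obs.astype(int), stat, p, yates, props)


def composition_table(states, regions, state_order=None) -> pd.DataFrame:
    """Counts and percentages per state x region with per-state chi-squared p.

    Mirrors the published table layout: one row per state with the overall
    count (% of all cells), the core count (% of core cells), the periphery
    count (% of periphery cells), and the Yates chi-squared p-value for the
    2x2 comparison state-vs-rest between regions.
    """
    states = np.asarray(states, dtype=object)
    regions = np.asarray(regions, dtype=object)
    if len(states) != len(regions):
        raise ValueError("states and regions must align")
    unknown = set(regions) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown region labels {sorted(unknown)}; expected {REGIONS}")
    n_core = int((regions == "core").sum())
    n_peri = int((regions == "periphery").sum())
    order = state_order if state_order is not None else list(pd.unique(states))
    rows = []
    for s in order:
        in_s = states == s
        a = int((in_s & (regions == "core")).sum())
        c = int((in_s & (regions == "periphery")).sum())
        if n_core > 0 and n_peri > 0 and 0 < a + c < n_core + n_peri:
            res = chisq_2x2(a, n_core - a, c, n_peri - c)
        else:  # single-region input or degenerate margin: no comparison
            res = ContingencyResult(
                np.array([[a, n_core - a], [c, n_peri - c]]), np.nan, np.nan,
                True, (np.nan, np.nan),
            )
        rows.append(
            {
                "state": s,
                "all_n": a + c,
                "all_pct": round((a + c) / (n_core + n_peri) * 100),
                "core_n": a,
                "core_pct": round(a / n_core * 100) if n_core else np.nan,
                "periphery_n": c,
                "periphery_pct": round(c / n_peri * 100) if n_peri else np.nan,
                "chi2": res.chi2,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows).set_index("state")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x vs y using midranks."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank(method="average").values
    n = len(x)
    return float(ranks[:n].sum() - n * (n + 1) / 2)


def mannwhitney(x, y) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact permutation enumeration of U when n + m <= 12 (two-sided via
    P(|U - nm/2| >= |u - nm/2|)); otherwise the normal approximation with
    tie correction.  All values tied across both samples -> p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    u = _u_statistic(x, y)
    center = n * m / 2.0
    if n + m <= 12:
        dev = abs(u - center)
        count = 0
        total = 0
        idx = range(n + m)
        for comb in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - center) >= dev - 1e-12:
                count += 1
        return count / total
    # normal approximation, tie-corrected variance
    N = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    var = n * m / 12.0 * (N + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u - center) - 0.5) / np.sqrt(var)  # continuity correction
    return float(2 * norm.sf(max(z, 0.0)))
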