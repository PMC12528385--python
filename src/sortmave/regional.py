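"""Regional comparison of variant scores between assays.

Different assays have different score ranges, so scores are first transformed
to quantile ranks with the empirical cumulative distribution function (ECDF;
average ranks divided by n, ties sharing the average).  The two assays are
then aligned by exact (position, substitution) match, and a one-sided
Wilcoxon signed-rank test is applied in a 15-residue sliding window (step 1),
asking whether assay A's normalised scores are lower (more deleterious) than
assay B's in that window.  Windows with fewer than five matched variant pairs
are not tested; zero differences are dropped (Wilcoxon's original treatment,
with Pratt's as an option).  p-values are reported alongside -log10(p), and
windows are indexed by their centre residue.

The signed-rank p-value uses the exact null distribution (dynamic programme
over all 2^n sign assignments, valid with ties) for up to 25 non-zero pairs,
and the Normal approximation with tie correction and continuity correction
above that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "ecdf_normalize",
    "signed_rank_test",
    "sliding_window_test",
    "significant_intervals",
]

EXACT_LIMIT = 25


def ecdf_normalize(scores) -> np.ndarray:
    """Quantile ranks in (0, 1]: average rank of each score divided by n.

    Order-preserving and invariant to monotone transforms of the input.
    NaNs propagate as NaN and do not contribute to n.
    """
    scores = np.asarray(scores, dtype=float)
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValueError("ECDF normalisation needs at least one finite score")
    out = np.full(scores.shape, np.nan)
    vals = scores[finite]
    out[finite] = rankdata(vals, method="average") / vals.size
    return out


def _exact_p(ranks: np.ndarray, w_pos: float, alternative: str) -> float:
    """Exact signed-rank p-value by DP over all sign assignments.

    Works with tied (average, i.e. half-integer) ranks by doubling them to
    integers; the null assigns each |difference| a positive sign with
    probability 1/2 independently.
    """
    doubled = np.rint(ranks * 2).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(np.rint(w_pos * 2))
    if alternative == "less":
        return float(pmf[: w2 + 1].sum())
    return float(pmf[w2:].sum())


def _approx_p(d: np.ndarray, ranks: np.ndarray, w_pos: float, alternative: str) -> float:
    n = d.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on the |d| ranks
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    sd = np.sqrt(var)
    if sd == 0:
        return 1.0
    if alternative == "less":
        z = (w_pos - mean + 0.5) / sd
        return float(norm.cdf(z))
    z = (w_pos - mean - 0.5) / sd
    return float(norm.sf(z))


def signed_rank_test(
    diffs,
    alternative: Literal["less", "greater"] = "less",
    zero_method: Literal["wilcox", "pratt"] = "wilcox",
    exact_limit: int = EXACT_LIMIT,
) -> tuple[float, int]:
    """One-sided Wilcoxon signed-rank test on paired differences.

    ``alternative="less"`` tests whether the differences are negative (the
    first member of each pair lower).  Returns ``(p_value, n_used)`` where
    ``n_used`` counts the non-zero differences entering the statistic.
    Raises ``ValueError`` when no non-zero differences remain.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    if zero_method == "wilcox":
        d = d[d != 0]
        if d.size == 0:
            raise ValueError("all differences are zero")
        ranks = rankdata(np.abs(d), method="average")
    elif zero_method == "pratt":
        if d.size == 0 or np.all(d == 0):
            raise ValueError("all differences are zero")
        ranks = rankdata(np.abs(d), method="average")
        ranks = ranks[d != 0]
        d = d[d != 0]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    w_pos = float(ranks[d > 0].sum())
    if d.size <= exact_limit and zero_method == "wilcox":
        p = _exact_p(ranks, w_pos, alternative)
    else:
        p = _approx_p(d, ranks, w_pos, alternative)
    return min(p, 1.0), int(d.size)


@dataclass(frozen=True)
class WindowResult:
    center_position: int
    n_pairs: int
    p_value: float
    neg_log10_p: float
    direction: str


def align_assays(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """ECDF-normalise two variant score tables and pair them on
    (position, substitution).  Returns columns ``position, ecdf_a, ecdf_b``."""
    a = table_a.dropna(subset=["score"]).copy()
    b = table_b.dropna(subset=["score"]).copy()
    a["ecdf"] = ecdf_normalize(a["score"])
    b["ecdf"] = ecdf_normalize(b["score"])
    keys = ["position", "wt_aa", "alt_aa"]
    merged = a[keys + ["ecdf"]].merge(
        b[keys + ["ecdf"]], on=keys, suffixes=("_a", "_b")
    )
    return merged.rename(columns={"ecdf_a": "ecdf_a", "ecdf_b": "ecdf_b"})


def sliding_window_test(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    region=None,
    window: int = 15,
    min_variants: int = 5,
    alternative: Literal["less", "greater"] = "less",
    zero_method: Literal["wilcox", "pratt"] = "wilcox",
) -> pd.DataFrame:
    """Sliding-window one-sided signed-rank comparison of two assays.

    Tables need ``position, wt_aa, alt_aa, score`` columns.  Windows of
    ``window`` residues slide one residue at a time over ``region`` (default:
    the span of matched positions); a window is tested only if it holds at
    least ``min_variants`` matched pairs, and omitted if every difference is
    zero.  Output columns: ``center, n_pairs, p, neg_log10_p, direction``.
    """
    paired = align_assays(table_a, table_b)
    if paired.empty:
        return pd.DataFrame(
            columns=["center", "n_pairs", "p", "neg_log10_p", "direction"]
        )
    if region is None:
        lo, hi = int(paired["position"].min()), int(paired["position"].max())
    else:
        lo, hi = region.start_pos, region.end_pos
    if window > hi - lo + 1:
        raise ValueError("window longer than the region")
    direction = "A_lower" if alternative == "less" else "A_higher"
    half = window // 2
    diffs = paired["ecdf_a"] - paired["ecdf_b"]
    pos = paired["position"].to_numpy()
    records = []
    for start in range(lo, hi - window + 2):
        center = start + half  # centre residue of an odd-width window
        in_win = (pos >= start) & (pos <= start + window - 1)
        n_matched = int(in_win.sum())
        if n_matched < min_variants:
            continue
        d = diffs[in_win].to_numpy()
        if np.all(d == 0):
            continue
        p, _ = signed_rank_test(d, alternative, zero_method)
        records.append(
            {
                "center": center,
                "n_pairs": n_matched,
                "p": p,
                "neg_log10_p": -np.log10(p),
                "direction": direction,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["center", "n_pairs", "p", "neg_log10_p", "direction"]
    )


def significant_intervals(results: pd.DataFrame, alpha: float = 0.05) -> list[tuple[int, int]]:
    """Maximal runs of consecutive window centres with p < alpha."""
    sig = results.loc[results["p"] < alpha, "center"].astype(int).sort_values().to_numpy()
    intervals: list[tuple[int, int]] = []
    for c in sig:
        if intervals and c == intervals[-1][1] + 1:
            intervals[-1] = (intervals[-1][0], c)
        else:
            intervals.append((c, c))
    return intervals
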