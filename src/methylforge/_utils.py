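"""Small shared helpers: interval arithmetic and multiple-testing adjustment."""

from __future__ import annotations

import numpy as np
import pandas as pd


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values), monotone in rank."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.clip(q, 0.0, 1.0)
    return out


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent half-open intervals (single chromosome)."""
    if len(starts) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    order = np.argsort(starts, kind="mergesort")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s), np.array(out_e)


def overlap_any(starts_a, ends_a, starts_b, ends_b) -> np.ndarray:
    """Boolean per A interval: overlaps >=1 B interval (half-open, one chromosome).

    B intervals are merged internally, so the test is a pair of searchsorted
    calls rather than a quadratic scan.
    """
    starts_a = np.asarray(starts_a)
    ends_a = np.asarray(ends_a)
    if len(starts_b) == 0 or len(starts_a) == 0:
        return np.zeros(len(starts_a), dtype=bool)
    mb_s, mb_e = merge_intervals(np.asarray(starts_b), np.asarray(ends_b))
    # A overlaps some merged B iff there is a B with b.start < a.end and b.end > a.start
    idx = np.searchsorted(mb_s, ends_a, side="left")  # number of B starting before a.end
    prev_end = np.where(idx > 0, mb_e[np.maximum(idx - 1, 0)], -1)
    return (idx > 0) & (prev_end > starts_a)


def intersection_length(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    return max(0, min(end_a, end_b) - max(start_a, start_b))


def require_columns(df: pd.DataFrame, cols, what: str = "table") -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")
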