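"""Cytosine-level and read-level methylation quantification.

The central container is the *call table*: a pandas DataFrame with columns
``chrom, pos, strand, context, m, total`` holding one cytosine per row
(0-based positions, ``m`` methylated read count, ``total`` read coverage).
Per-molecule information is carried by :class:`ReadMethylationRecord`.

Weighted methylation level of a region is the coverage-weighted mean:
sum of methylated counts divided by sum of total counts over the region's
cytosines — not the mean of per-site levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MethylationCall:
    """A single cytosine's methylation evidence."""

    chrom: str
    pos: int  # 0-based
    strand: str  # '+' or '-'
    context: str  # CG | CHG | CHH
    m: int
    total: int

    def __post_init__(self):
        if not (0 <= self.m <= self.total):
            raise ValueError(f"require 0 <= methylated <= total, got {self.m}/{self.total}")


@dataclass
class ReadMethylationRecord:
    """One sequenced molecule's linked CpG calls.

    positions are strictly increasing 0-based coordinates within
    ``[start, end)``; calls are 'M' (methylated) or 'U'.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    positions: np.ndarray
    calls: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls)
        if len(self.positions) and (
            np.any(np.diff(self.positions) <= 0)
            or self.positions[0] < self.start
            or self.positions[-1] >= self.end
        ):
            raise ValueError(f"read {self.read_id}: call positions must be strictly increasing within the span")

    @property
    def n_cpgs(self) -> int:
        return len(self.positions)

    @property
    def frac_methylated(self) -> float:
        return float(np.mean(self.calls == "M")) if len(self.calls) else float("nan")


@dataclass(frozen=True)
class NonConversionEstimate:
    """Bisulfite non-conversion rate from an unmethylated spike-in genome."""

    rate: float
    n_calls: int
    ci_low: float
    ci_high: float


def collapse_strands(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge symmetric CpG calls into one unit per CpG dinucleotide.

    A plus-strand CG call at position p and the minus-strand call at p+1
    report the same CpG; their counts are summed and assigned to p.  Calls in
    CH context (and strandless CG calls, strand '.') pass through unchanged.
    Total counts are conserved exactly.
    """
    if calls.empty:
        return calls.copy()
    cg = (calls["context"] == "CG") & calls["strand"].isin(["+", "-"])
    cg_calls = calls.loc[cg]
    rest = calls.loc[~cg]
    unit_pos = np.where(cg_calls["strand"] == "-", cg_calls["pos"] - 1, cg_calls["pos"])
    merged = (
        cg_calls.assign(pos=unit_pos, strand="+")
        .groupby(["chrom", "pos"], as_index=False, sort=True)
        .agg(strand=("strand", "first"), context=("context", "first"),
             m=("m", "sum"), total=("total", "sum"))
    )
    out = pd.concat([merged, rest], ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)


def weighted_methylation(
    calls: pd.DataFrame,
    interval: tuple[str, int, int] | None = None,
    min_coverage: int = 1,
) -> float:
    """Weighted mean methylation over an interval's cytosines.

    Σ methylated / Σ total over sites with coverage >= ``min_coverage``.
    Returns ``nan`` when no qualifying site exists — "no data" is distinct
    from "unmethylated".

    Parameters
    ----------
    calls : call table (any context mix; filter beforehand if needed)
    interval : (chrom, start, end) half-open, or None for all calls
    min_coverage : per-site coverage floor (>=1)
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    sub = calls
    if interval is not None:
        chrom, start, end = interval
        sub = calls.loc[
            (calls["chrom"] == chrom) & (calls["pos"] >= start) & (calls["pos"] < end)
        ]
    sub = sub.loc[sub["total"] >= min_coverage]
    tot = int(sub["total"].sum())
    if tot == 0:
        return float("nan")
    return float(sub["m"].sum() / tot)


def weighted_methylation_by_region(
    calls: pd.DataFrame, regions: pd.DataFrame, min_coverage: int = 1
) -> np.ndarray:
    """Vectorised weighted level per region (rows of ``regions``: chrom,start,end).

    Returns an array aligned to ``regions`` with nan for uncovered regions.
    """
    ok = calls.loc[calls["total"] >= min_coverage]
    out = np.full(len(regions), np.nan)
    for chrom, grp in ok.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        m = grp["m"].to_numpy()[order]
        t = grp["total"].to_numpy()[order]
        cm = np.concatenate([[0], np.cumsum(m)])
        ct = np.concatenate([[0], np.cumsum(t)])
        mask = (regions["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        lo = np.searchsorted(pos, regions.loc[mask, "start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, regions.loc[mask, "end"].to_numpy(), side="left")
        tt = ct[hi] - ct[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(tt > 0, (cm[hi] - cm[lo]) / np.where(tt > 0, tt, 1), np.nan)
        out[mask] = vals
    return out


def estimate_nonconversion(calls: pd.DataFrame, spike_contig: str) -> NonConversionEstimate:
    """Non-conversion rate from an unmethylated spike contig (e.g. lambda).

    Rate = methylated / total over every spike cytosine, with a Wilson 95%
    confidence interval.
    """
    spike = calls.loc[calls["chrom"] == spike_contig]
    n = int(spike["total"].sum())
    if n == 0:
        raise ValueError(f"spike contig {spike_contig!r} absent or uncovered")
    k = int(spike["m"].sum())
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return NonConversionEstimate(rate=k / n, n_calls=n, ci_low=float(lo), ci_high=float(hi))


DEFAULT_BINS = (0.0, 1.0)  # f == 0 -> unmethylated, f == 1 -> full, else intermediate


def classify_read(
    record: ReadMethylationRecord,
    min_cpgs: int = 5,
    bins: tuple[float, float] = DEFAULT_BINS,
) -> str:
    """Classify one molecule by its per-read mCG fraction.

    Reads spanning fewer than ``min_cpgs`` CpGs are ``excluded``.  With the
    default strict bins a read is ``unmethylated`` at fraction 0, ``full`` at
    fraction 1 and ``intermediate`` otherwise; ``bins=(lo, hi)`` relaxes this
    to f <= lo / f >= hi.
    """
    if record.n_cpgs < min_cpgs:
        return "excluded"
    f = record.frac_methylated
    lo, hi = bins
    if f <= lo:
        return "unmethylated"
    if f >= hi:
        return "full"
    return "intermediate"


def read_class_profile(
    records,
    regions: pd.DataFrame,
    min_overlap_frac: float = 0.8,
    min_cpgs: int = 5,
    bins: tuple[float, float] = DEFAULT_BINS,
) -> pd.Series:
    """Class proportions over reads anchored to a region set.

    A read is retained when the overlap between its span and the region set,
    divided by the *read* length, is >= ``min_overlap_frac``, and it spans at
    least ``min_cpgs`` CpGs.  Returns proportions over
    {unmethylated, intermediate, full} summing to 1, or an all-nan Series
    when no read qualifies.
    """
    if regions.empty:
        raise ValueError("region set is empty")
    by_chrom = {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in regions.groupby("chrom", sort=False)
    }
    counts = {"unmethylated": 0, "intermediate": 0, "full": 0}
    n_kept = 0
    for r in records:
        if r.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[r.chrom]
        inter = np.clip(np.minimum(ends, r.end) - np.maximum(starts, r.start), 0, None).sum()
        if r.end <= r.start or inter / (r.end - r.start) < min_overlap_frac:
            continue
        cls = classify_read(r, min_cpgs=min_cpgs, bins=bins)
        if cls == "excluded":
            continue
        counts[cls] += 1
        n_kept += 1
    if n_kept == 0:
        logger.warning("read_class_profile: no read passed the overlap/CpG filters")
        return pd.Series({k: np.nan for k in counts}, name="proportion")
    return pd.Series({k: v / n_kept for k, v in counts.items()}, name="proportion")


def calls_from_records(records, chrom_order=None) -> pd.DataFrame:
    """Tally per-position CpG calls from read records (independent of any
    aggregation done at simulation time)."""
    tally: dict[tuple[str, int], list[int]] = {}
    for r in records:
        for p, c in zip(r.positions, r.calls):
            key = (r.chrom, int(p))
            if key not in tally:
                tally[key] = [0, 0]
            tally[key][1] += 1
            if c == "M":
                tally[key][0] += 1
    rows = [
        (chrom, pos, "+", "CG", m, t) for (chrom, pos), (m, t) in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "m", "total"])
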