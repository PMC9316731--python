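"""Methylation within immunoprecipitated chromatin, differential
accessibility at regions, and hmC comparison across region classes.

``methylation_in_peaks`` asks the ChIP-bisulfite question directly: over a
peak set, does the IP-selected molecule population carry more (or less)
methylation than the bulk methylome?  Peaks are quantified by weighted mCG
in both call sets and compared peak-by-peak (paired signed-rank by default;
a one-sided rank-sum is available for cross-condition contrasts).

Differential accessibility is a stand-in pipeline — median-of-ratios
normalization, two-sample t on log2 counts, BH — classifying regions as
gain / loss / none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust
from .core import weighted_methylation_by_region
from .expression import median_of_ratios

logger = logging.getLogger(__name__)


@dataclass
class PeakMethylationReport:
    table: pd.DataFrame          # per-peak bulk / ip levels (+ difference)
    median_bulk: float
    median_ip: float
    median_difference: float     # ip - bulk
    statistic: float
    pvalue: float
    test: str
    n_peaks: int


def methylation_in_peaks(
    bulk_calls: pd.DataFrame,
    ip_calls: pd.DataFrame,
    peaks: pd.DataFrame,
    min_coverage: int = 1,
    paired: bool = True,
    alternative: str = "two-sided",
) -> PeakMethylationReport:
    """Weighted mCG per peak in bulk vs IP-selected call sets.

    Peaks with no qualifying coverage in either set are dropped from the
    pairing (logged).  ``paired=True`` uses the Wilcoxon signed-rank test on
    per-peak differences; otherwise a rank-sum test on the two level sets.
    """
    if peaks.empty:
        raise ValueError("peak set is empty")
    bulk = weighted_methylation_by_region(bulk_calls, peaks, min_coverage=min_coverage)
    ip = weighted_methylation_by_region(ip_calls, peaks, min_coverage=min_coverage)
    tab = peaks[["chrom", "start", "end"]].copy()
    tab["bulk"] = bulk
    tab["ip"] = ip
    ok = ~(np.isnan(bulk) | np.isnan(ip))
    dropped = int((~ok).sum())
    if dropped:
        logger.info("methylation_in_peaks: dropped %d uncovered peak(s)", dropped)
    tab = tab.loc[ok].reset_index(drop=True)
    tab["difference"] = tab["ip"] - tab["bulk"]
    if tab.empty:
        raise ValueError("no peak covered in both call sets")
    if paired:
        diffs = tab["difference"].to_numpy()
        if np.allclose(diffs, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(diffs, alternative=alternative)
        test = "wilcoxon-signed-rank"
    else:
        stat, p = stats.mannwhitneyu(tab["ip"], tab["bulk"], alternative=alternative)
        test = "rank-sum"
    return PeakMethylationReport(
        table=tab,
        median_bulk=float(tab["bulk"].median()),
        median_ip=float(tab["ip"].median()),
        median_difference=float(tab["difference"].median()),
        statistic=float(stat), pvalue=float(p), test=test, n_peaks=len(tab),
    )


def accessibility_change_at_regions(
    counts: pd.DataFrame,
    groups: dict,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential accessibility classes (gain / loss / none) per region.

    ``counts`` is region x sample; ``groups`` maps sample -> one of exactly
    two labels (the second label sorted is the treatment; log2FC is
    treatment - reference).  Regions that are all-zero everywhere are
    flagged and classified none.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    sa = [s for s in counts.columns if groups.get(s) == labels[0]]
    sb = [s for s in counts.columns if groups.get(s) == labels[1]]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs >= 2 replicates")
    sf = median_of_ratios(counts.loc[(counts > 0).all(axis=1)] if (counts > 0).all(axis=1).any() else counts + 1)
    norm = counts / sf
    la = np.log2(norm[sa].to_numpy() + 1.0)
    lb = np.log2(norm[sb].to_numpy() + 1.0)
    allzero = (counts[sa + sb].to_numpy() == 0).all(axis=1)
    t, p = stats.ttest_ind(lb, la, axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = bh_adjust(p)
    lfc = lb.mean(axis=1) - la.mean(axis=1)
    cls = np.where((fdr < alpha) & (lfc > 0), "gain",
                   np.where((fdr < alpha) & (lfc < 0), "loss", "none"))
    cls[allzero] = "none"
    if allzero.any():
        logger.info("accessibility_change_at_regions: %d all-zero region(s) flagged", int(allzero.sum()))
    out = pd.DataFrame({
        "region": counts.index,
        "log2FC": lfc,
        "FDR": fdr,
        "change_class": cls,
        "all_zero": allzero,
    })
    return out.reset_index(drop=True)


@dataclass
class HmcComparison:
    levels: dict                 # class -> per-region weighted hmC levels
    medians: pd.Series
    tests: pd.DataFrame          # lower, higher, statistic, pvalue, n_lower, n_higher


def hmc_by_region_class(
    hmc_calls: pd.DataFrame,
    region_sets: dict,
    min_coverage: int = 1,
    contrasts: list | None = None,
) -> HmcComparison:
    """Weighted hmC levels per region class with one-sided location tests.

    ``contrasts`` is a list of (lower, higher) class-name pairs; each is
    tested with a one-sided two-sample t (H1: mean level of ``lower`` <
    mean level of ``higher``).  By default every non-DMR class is tested
    against every DMR class (names containing "DMR" but not "non").
    Degenerate tests (zero variance in both groups) are flagged with nan p.
    """
    nonempty = {k: v for k, v in region_sets.items() if v is not None and len(v)}
    if len(nonempty) < 2:
        raise ValueError("need >= 2 non-empty region classes")
    levels = {}
    for name, regions in nonempty.items():
        vals = weighted_methylation_by_region(hmc_calls, regions, min_coverage=min_coverage)
        levels[name] = vals[~np.isnan(vals)]
    medians = pd.Series({k: (float(np.median(v)) if len(v) else np.nan) for k, v in levels.items()})
    if contrasts is None:
        dmr_classes = [k for k in nonempty if "dmr" in k.lower() and not k.lower().startswith("non")]
        non_classes = [k for k in nonempty if k not in dmr_classes]
        contrasts = [(lo, hi) for lo in non_classes for hi in dmr_classes]
    rows = []
    for lo, hi in contrasts:
        if lo not in levels or hi not in levels or len(levels[lo]) < 2 or len(levels[hi]) < 2:
            logger.warning("hmc_by_region_class: contrast (%s, %s) skipped (empty class)", lo, hi)
            continue
        a, b = levels[lo], levels[hi]
        if np.var(a) == 0 and np.var(b) == 0:
            rows.append((lo, hi, np.nan, np.nan, len(a), len(b)))
            logger.warning("hmc_by_region_class: degenerate contrast (%s, %s) flagged", lo, hi)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative="less")
        rows.append((lo, hi, float(t), float(p), len(a), len(b)))
    tests = pd.DataFrame(rows, columns=["lower", "higher", "statistic", "pvalue", "n_lower", "n_higher"])
    return HmcComparison(levels=levels, medians=medians, tests=tests)
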