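"""Count normalization, spike-in global-shift control, and the joint
promoter-methylation x transcriptional-response classification.

Normalization is median-of-ratios (the standard scaling approach): each
sample's size factor is the median, over genes with positive counts in every
sample, of that sample's count divided by the gene's geometric mean across
samples.  Spike-in rows (label prefix "ERCC-") can be excluded from factor
estimation; the spike-fraction shift test always works on raw counts, since
the fraction of a library is scale-invariant.

Differential expression itself is a documented stand-in (two-sample t on
log2 normalized counts with BH adjustment); externally computed DE tables
can be supplied instead wherever one is consumed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust

logger = logging.getLogger(__name__)

SPIKE_PREFIX = "ERCC-"


@dataclass
class CountMatrix:
    """Gene x sample integer counts with sample->condition mapping."""

    counts: pd.DataFrame
    conditions: dict
    size_factors: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    @property
    def spike_mask(self) -> np.ndarray:
        return self.counts.index.astype(str).str.startswith(SPIKE_PREFIX)

    @property
    def gene_counts(self) -> pd.DataFrame:
        return self.counts.loc[~self.spike_mask]

    @property
    def spike_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.spike_mask]

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("call normalize_counts first")
        return self.counts / self.size_factors

    def samples_of(self, condition: str) -> list:
        return [s for s, c in self.conditions.items() if c == condition and s in self.counts.columns]


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors. Requires >= 1 gene positive in all samples."""
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has positive counts in every sample")
    logref = np.log(arr[allpos]).mean(axis=1)
    sf = np.exp(np.median(np.log(arr[allpos]) - logref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(
    cm: CountMatrix,
    exclude_spikes: bool = True,
    min_expressed_frac: float = 0.5,
    basis: str | None = None,
) -> CountMatrix:
    """Filter very lowly expressed genes and compute size factors.

    The low-count filter keeps genes with >0 counts in at least
    ``ceil(min_expressed_frac * n_samples)`` samples — a fixed-sample-count
    low-expression rule rescaled proportionally to the matrix at hand.  Spike rows are
    kept regardless.

    ``basis`` selects the rows used for size-factor estimation: "genes"
    (default; standard scaling, valid when most genes are unchanged),
    "spikes" (fixed-amount spike-ins — robust when a large asymmetric
    fraction of genes responds), or "all".  ``exclude_spikes=False`` is a
    shorthand for basis="all".
    """
    counts = cm.counts
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    if basis is None:
        basis = "genes" if exclude_spikes else "all"
    n_needed = math.ceil(min_expressed_frac * counts.shape[1])
    spike = cm.spike_mask
    expressed = (counts > 0).sum(axis=1) >= n_needed
    keep = expressed.to_numpy() | np.asarray(spike)
    filtered = counts.loc[keep]
    spike_f = filtered.index.astype(str).str.startswith(SPIKE_PREFIX)
    if basis == "genes":
        rows = filtered.loc[~spike_f]
    elif basis == "spikes":
        if not spike_f.any():
            raise ValueError("basis='spikes' but no ERCC- rows present")
        rows = filtered.loc[spike_f]
    elif basis == "all":
        rows = filtered
    else:
        raise ValueError(f"unknown basis {basis!r}")
    sf = median_of_ratios(rows)
    return CountMatrix(counts=filtered, conditions=dict(cm.conditions), size_factors=sf)


@dataclass
class SpikeShiftResult:
    """Per-sample spike fractions and the two-group rank-sum comparison."""

    fractions: pd.Series
    groups: dict
    statistic: float
    pvalue: float
    alpha: float
    verdict: str  # 'shift' | 'no-shift'


def spikein_shift_test(cm: CountMatrix, groups: dict | None = None, alpha: float = 0.05) -> SpikeShiftResult:
    """Wilcoxon rank-sum test of spike-in library fractions between two groups.

    ``groups`` maps sample -> group label (defaults to the matrix's condition
    map, which must then have exactly two conditions).  Fractions are
    computed on raw counts: spike total / library total per sample.
    """
    groups = dict(groups or cm.conditions)
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    if not cm.spike_mask.any():
        raise ValueError("no spike-in rows (ERCC- prefix) present")
    frac = cm.spike_counts.sum(axis=0) / cm.counts.sum(axis=0)
    a = frac[[s for s in cm.samples if groups.get(s) == labels[0]]]
    b = frac[[s for s in cm.samples if groups.get(s) == labels[1]]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return SpikeShiftResult(
        fractions=frac, groups=groups, statistic=float(stat), pvalue=float(p),
        alpha=alpha, verdict="shift" if p < alpha else "no-shift",
    )


def differential_expression(cm: CountMatrix, cond_base: str, cond_treat: str,
                            pseudocount: float = 1.0) -> pd.DataFrame:
    """Stand-in DE test: two-sample t on log2 normalized counts, BH-adjusted.

    Returns gene, log2FC (treat - base), pvalue, FDR, baseMean and
    per-condition normalized means (mean_<condition> columns).  Spike rows
    are excluded.  This deliberately does not reproduce a negative-binomial
    GLM; it exists so synthetic DE tables can be derived from simulated
    counts.
    """
    norm = cm.normalized()
    norm = norm.loc[~norm.index.astype(str).str.startswith(SPIKE_PREFIX)]
    sa = cm.samples_of(cond_base)
    sb = cm.samples_of(cond_treat)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 replicates per condition")
    la = np.log2(norm[sa].to_numpy() + pseudocount)
    lb = np.log2(norm[sb].to_numpy() + pseudocount)
    t, p = stats.ttest_ind(lb, la, axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    out = pd.DataFrame({
        "gene": norm.index,
        "log2FC": lb.mean(axis=1) - la.mean(axis=1),
        "pvalue": p,
        "FDR": bh_adjust(p),
        "baseMean": norm[sa + sb].mean(axis=1).to_numpy(),
        f"mean_{cond_base}": norm[sa].mean(axis=1).to_numpy(),
        f"mean_{cond_treat}": norm[sb].mean(axis=1).to_numpy(),
    })
    return out.reset_index(drop=True)


@dataclass
class ResponseTable:
    """Promoter-DMR genes joined to their transcriptional response class."""

    table: pd.DataFrame       # gene, dmr_stat, log2FC, FDR, class
    proportions: pd.Series    # over {down, not-DE, up}, sums to 1
    n_genes: int


def build_response_table(
    promoter_dmrs: pd.DataFrame,
    de_table: pd.DataFrame,
    fdr: float = 0.05,
    min_expression: float = 50.0,
    exclude_genes=None,
) -> ResponseTable:
    """Classify promoter-DMR genes by expression change.

    ``promoter_dmrs`` needs columns gene and a DMR statistic (``delta`` or
    ``dmr_stat``).  Genes are kept when some condition-mean normalized count
    (mean_* columns, else baseMean) reaches ``min_expression``; classes are
    down (FDR < fdr, log2FC < 0), up (FDR < fdr, log2FC > 0), not-DE
    otherwise.  ``exclude_genes`` drops e.g. genes responsive in the
    catalytically dead control.
    """
    stat_col = "dmr_stat" if "dmr_stat" in promoter_dmrs.columns else "delta"
    pd_genes = promoter_dmrs[["gene", stat_col]].rename(columns={stat_col: "dmr_stat"})
    pd_genes = pd_genes.loc[pd_genes["gene"] != ""].drop_duplicates("gene")
    joined = pd_genes.merge(de_table, on="gene", how="left", validate="one_to_one")
    missing = joined["log2FC"].isna()
    if missing.any():
        logger.warning("build_response_table: %d promoter-DMR gene(s) missing from the DE table; dropped",
                       int(missing.sum()))
        joined = joined.loc[~missing]
    if exclude_genes:
        joined = joined.loc[~joined["gene"].isin(set(exclude_genes))]
    mean_cols = [c for c in joined.columns if c.startswith("mean_")]
    expr = joined[mean_cols].max(axis=1) if mean_cols else joined["baseMean"]
    joined = joined.loc[expr >= min_expression].reset_index(drop=True)
    sig = joined["FDR"] < fdr
    cls = np.where(sig & (joined["log2FC"] < 0), "down",
                   np.where(sig & (joined["log2FC"] > 0), "up", "not-DE"))
    joined["class"] = cls
    if len(joined):
        props = joined["class"].value_counts(normalize=True).reindex(
            ["down", "not-DE", "up"], fill_value=0.0)
    else:
        props = pd.Series(np.nan, index=["down", "not-DE", "up"])
    return ResponseTable(table=joined, proportions=props, n_genes=len(joined))


@dataclass
class TrendResult:
    rho: float
    pvalue: float
    curve: pd.DataFrame  # x (DMR statistic), y (smoothed log2FC)
    defined: bool = True


def methylation_expression_trend(
    response: ResponseTable | pd.DataFrame,
    span: float = 0.75,
) -> TrendResult:
    """Rank correlation and local-regression trend of log2FC vs DMR statistic.

    The smoother is a tricube-weighted local linear fit (lowess) with
    ``span`` as the fraction of points in each window.
    """
    df = response.table if isinstance(response, ResponseTable) else response
    df = df.dropna(subset=["dmr_stat", "log2FC"])
    if len(df) < 10:
        raise ValueError("need >= 10 genes with defined statistic and log2FC")
    x = df["dmr_stat"].to_numpy(dtype=float)
    y = df["log2FC"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        logger.warning("methylation_expression_trend: constant DMR statistic; correlation undefined")
        return TrendResult(rho=float("nan"), pvalue=float("nan"),
                           curve=pd.DataFrame({"x": [], "y": []}), defined=False)
    rho, p = stats.spearmanr(x, y)
    from statsmodels.nonparametric.smoothers_lowess import lowess

    smoothed = lowess(y, x, frac=span, return_sorted=True)
    curve = pd.DataFrame({"x": smoothed[:, 0], "y": smoothed[:, 1]})
    return TrendResult(rho=float(rho), pvalue=float(p), curve=curve)
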