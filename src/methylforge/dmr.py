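"""Differentially methylated region detection, filtering and classification.

The detector is a documented stand-in for dmrseq, not a reimplementation of
its transformed-coefficient GLS model: candidate windows of CpGs are scored
by the difference of pooled weighted mCG between conditions, merged into
candidate regions, and assigned empirical p-values against a genome-wide
null pool built by re-running the same candidate detection on
replicate-label permutations.  The dmrseq defaults are kept: 500 bp windows,
500 bp merge gap, 20 permutations, and 2 replicates per condition as the
minimum design.

Downstream rules follow the induction/withdrawal study design exactly:

* DMR filter: q-value < 0.05 and |weighted mCG difference| >= 20%;
* promoter-DMRs: the stringent q < 0.01 subset overlapping -2000/+200 bp of
  any TSS (strand-aware; a -2000/+500 window is available by flag);
* retention after withdrawal: retain-DMRs have <10% mCG in noDox, >10% in
  Dox and DoxWD-7d and at least twice the noDox level in DoxWD-7d;
  loss-DMRs have <10% in noDox and DoxWD-7d but >10% in Dox.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import bh_adjust, overlap_any
from .core import collapse_strands

logger = logging.getLogger(__name__)

DMR_COLUMNS = ["chrom", "start", "end", "n_cpgs", "meth_a", "meth_b", "delta", "p", "q"]


def _pooled_cpg_table(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Strand-collapse each replicate's CG calls and align on CpG units.

    Returns a long table chrom, pos and per-replicate m_i / t_i columns
    (missing coverage = 0).
    """
    pieces = []
    for i, rep in enumerate(replicates):
        cg = rep.loc[rep["context"] == "CG"]
        cg = collapse_strands(cg)
        pieces.append(cg[["chrom", "pos", "m", "total"]].rename(
            columns={"m": f"m_{i}", "total": f"t_{i}"}))
    out = pieces[0]
    for piece in pieces[1:]:
        out = out.merge(piece, on=["chrom", "pos"], how="outer")
    return out.fillna(0).sort_values(["chrom", "pos"], ignore_index=True)


def _window_stats(pos, M, T, labels_a, window_span, max_gap, min_cpgs):
    """Candidate windows on one chromosome.

    pos : CpG unit positions (sorted); M, T : (n_reps, n_cpgs) count arrays.
    Returns arrays (start_idx, end_idx, delta, meth_a, meth_b) for windows of
    >= min_cpgs CpGs spanning <= window_span bp, tiled with 50% overlap
    within max_gap-delimited segments.
    """
    mA = M[labels_a].sum(axis=0)
    tA = T[labels_a].sum(axis=0)
    mB = M[~labels_a].sum(axis=0)
    tB = T[~labels_a].sum(axis=0)
    cmA, ctA = np.concatenate([[0], np.cumsum(mA)]), np.concatenate([[0], np.cumsum(tA)])
    cmB, ctB = np.concatenate([[0], np.cumsum(mB)]), np.concatenate([[0], np.cumsum(tB)])

    seg_breaks = np.flatnonzero(np.diff(pos) > max_gap)
    seg_starts = np.concatenate([[0], seg_breaks + 1])
    seg_ends = np.concatenate([seg_breaks + 1, [pos.size]])

    lo_list, hi_list = [], []
    step = max(window_span // 2, 1)
    for s0, s1 in zip(seg_starts, seg_ends):
        if s1 - s0 < min_cpgs:
            continue
        anchor = pos[s0]
        last = pos[s1 - 1]
        w = anchor
        while w <= last:
            lo = np.searchsorted(pos[s0:s1], w) + s0
            hi = np.searchsorted(pos[s0:s1], w + window_span) + s0
            if hi - lo >= min_cpgs:
                lo_list.append(lo)
                hi_list.append(hi)
            w += step
    if not lo_list:
        return (np.array([], dtype=int),) * 2 + (np.array([]),) * 3
    lo_arr = np.array(lo_list)
    hi_arr = np.array(hi_list)
    keep = np.ones(lo_arr.size, dtype=bool)  # drop duplicate windows
    if lo_arr.size > 1:
        dup = (np.diff(lo_arr) == 0) & (np.diff(hi_arr) == 0)
        keep[1:][dup] = False
    lo_arr, hi_arr = lo_arr[keep], hi_arr[keep]

    with np.errstate(invalid="ignore", divide="ignore"):
        wa = (cmA[hi_arr] - cmA[lo_arr]) / np.maximum(ctA[hi_arr] - ctA[lo_arr], 1)
        wb = (cmB[hi_arr] - cmB[lo_arr]) / np.maximum(ctB[hi_arr] - ctB[lo_arr], 1)
    covered = ((ctA[hi_arr] - ctA[lo_arr]) > 0) & ((ctB[hi_arr] - ctB[lo_arr]) > 0)
    return lo_arr[covered], hi_arr[covered], (wa - wb)[covered], wa[covered], wb[covered]


def _candidate_regions(pos, M, T, labels_a, window_span, max_gap, min_cpgs, candidate_delta):
    """Merge same-sign significant-looking windows into candidate regions.

    Returns (list of (start_idx, end_idx, delta, wa, wb), all window |delta|).
    """
    lo, hi, delta, wa, wb = _window_stats(pos, M, T, labels_a, window_span, max_gap, min_cpgs)
    if lo.size == 0:
        return [], np.array([])
    all_stats = np.abs(delta)
    sig = np.abs(delta) >= candidate_delta
    if not sig.any():
        return [], all_stats
    regions = []
    lo_s, hi_s, d_s = lo[sig], hi[sig], delta[sig]
    order = np.argsort(lo_s, kind="mergesort")
    for i in order:
        l, h, d = int(lo_s[i]), int(hi_s[i]), float(d_s[i])
        if regions:
            pl, ph, pd_ = regions[-1]
            gap = pos[l] - pos[ph - 1] if l >= ph else 0
            if gap <= max_gap and np.sign(d) == np.sign(pd_):
                regions[-1] = (pl, max(ph, h), pd_)
                continue
        regions.append((l, h, d))
    # trim merged extents to CpGs carrying sign-consistent signal, then
    # recompute stats over the trimmed extents
    mAp = M[labels_a].sum(axis=0)
    tAp = T[labels_a].sum(axis=0)
    mBp = M[~labels_a].sum(axis=0)
    tBp = T[~labels_a].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        site_diff = mAp / np.maximum(tAp, 1) - mBp / np.maximum(tBp, 1)
    cmA, ctA = np.concatenate([[0], np.cumsum(mAp)]), np.concatenate([[0], np.cumsum(tAp)])
    cmB, ctB = np.concatenate([[0], np.cumsum(mBp)]), np.concatenate([[0], np.cumsum(tBp)])
    out = []
    n_sites = pos.size
    for l, h, d in regions:
        sgn = np.sign(d)
        # grow over adjacent sign-consistent CpGs (tiled windows need not
        # align with the true edge), then shrink past edge CpGs without signal
        while l > 0 and sgn * site_diff[l - 1] >= candidate_delta and pos[l] - pos[l - 1] <= max_gap:
            l -= 1
        while h < n_sites and sgn * site_diff[h] >= candidate_delta and pos[h] - pos[h - 1] <= max_gap:
            h += 1
        # an edge CpG only anchors the boundary when at least one of its two
        # inward neighbours also carries signal (isolated noisy CpGs in the
        # flanking background would otherwise freeze the trim too early)
        def _anchored(i, step):
            if sgn * site_diff[i] < candidate_delta:
                return False
            nbrs = [i + step, i + 2 * step]
            nbrs = [j for j in nbrs if l <= j < h]
            return not nbrs or any(sgn * site_diff[j] >= candidate_delta for j in nbrs)

        while h - l > min_cpgs and not _anchored(l, +1):
            l += 1
        while h - l > min_cpgs and not _anchored(h - 1, -1):
            h -= 1
        ta, tb = ctA[h] - ctA[l], ctB[h] - ctB[l]
        wa_r = (cmA[h] - cmA[l]) / max(ta, 1)
        wb_r = (cmB[h] - cmB[l]) / max(tb, 1)
        out.append((l, h, wa_r - wb_r, wa_r, wb_r))
    return out, all_stats


def detect_dmrs(
    calls_a: list[pd.DataFrame],
    calls_b: list[pd.DataFrame],
    window_span: int = 500,
    max_gap: int = 500,
    min_cpgs: int = 5,
    n_perms: int = 20,
    seed: int = 0,
    candidate_delta: float = 0.1,
) -> pd.DataFrame:
    """Detect candidate DMRs between two conditions (A - B difference).

    ``calls_a`` / ``calls_b`` are per-replicate call tables (>= 2 each).
    Returns a DataFrame with columns chrom, start, end, n_cpgs, meth_a,
    meth_b, delta, p, q sorted by q then position.
    """
    if len(calls_a) < 2 or len(calls_b) < 2:
        raise ValueError("need >= 2 replicate call sets per condition")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    nA, nB = len(calls_a), len(calls_b)
    table = _pooled_cpg_table(list(calls_a) + list(calls_b))
    m_cols = [f"m_{i}" for i in range(nA + nB)]
    t_cols = [f"t_{i}" for i in range(nA + nB)]
    obs_labels = np.zeros(nA + nB, dtype=bool)
    obs_labels[:nA] = True

    # distinct balanced relabelings (identity first, |delta|-symmetric dedup)
    combos = []
    seen = set()
    for combo in itertools.combinations(range(nA + nB), nA):
        key = frozenset(combo)
        comp = frozenset(set(range(nA + nB)) - set(combo))
        if nA == nB and comp in seen:
            continue
        seen.add(key)
        combos.append(combo)
    identity = tuple(range(nA))
    null_combos = [c for c in combos if c != identity]
    rng = np.random.default_rng(seed)
    if len(null_combos) > n_perms:
        pick = rng.choice(len(null_combos), size=n_perms, replace=False)
        null_combos = [null_combos[i] for i in np.sort(pick)]

    obs_rows = []
    null_pool = []
    for chrom, grp in table.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        M = grp[m_cols].to_numpy().T.astype(np.int64)
        T = grp[t_cols].to_numpy().T.astype(np.int64)
        regions, _ = _candidate_regions(pos, M, T, obs_labels, window_span, max_gap,
                                        min_cpgs, candidate_delta)
        for l, h, d, wa, wb in regions:
            obs_rows.append((chrom, int(pos[l]), int(pos[h - 1]) + 2, int(h - l), wa, wb, d))
        # genome-wide null pool: every window statistic under every
        # replicate-label permutation (dmrseq-style pooling — a per-region
        # permutation with 2v2 replicates could never reach p < 0.05)
        for combo in null_combos:
            lab = np.zeros(nA + nB, dtype=bool)
            lab[list(combo)] = True
            _, _, perm_delta, _, _ = _window_stats(pos, M, T, lab, window_span, max_gap, min_cpgs)
            null_pool.append(np.abs(perm_delta))

    if not obs_rows:
        return pd.DataFrame(columns=DMR_COLUMNS)
    null_arr = np.sort(np.concatenate(null_pool)) if null_pool else np.array([])
    obs = pd.DataFrame(obs_rows, columns=["chrom", "start", "end", "n_cpgs",
                                          "meth_a", "meth_b", "delta"])
    n_null = null_arr.size
    ge = n_null - np.searchsorted(null_arr, np.abs(obs["delta"].to_numpy()), side="left")
    obs["p"] = (1.0 + ge) / (1.0 + n_null)
    obs["q"] = bh_adjust(obs["p"].to_numpy())
    return obs.sort_values(["q", "chrom", "start"], ignore_index=True)


def filter_dmrs(dmrs: pd.DataFrame, q_max: float = 0.05, min_delta: float = 0.20) -> pd.DataFrame:
    """Apply the standard DMR filter: q < q_max and |delta| >= min_delta."""
    keep = (dmrs["q"] < q_max) & (dmrs["delta"].abs() >= min_delta)
    return dmrs.loc[keep].reset_index(drop=True)


def promoter_windows(tss: pd.DataFrame, window: tuple[int, int] = (-2000, 200)) -> pd.DataFrame:
    """Strand-aware promoter windows around TSSs (upstream negative)."""
    up, down = window
    plus = tss["strand"] == "+"
    start = np.where(plus, tss["pos"] + up, tss["pos"] - down)
    end = np.where(plus, tss["pos"] + down, tss["pos"] - up)
    return pd.DataFrame({"chrom": tss["chrom"], "start": start, "end": end,
                         "gene": tss.get("gene", pd.Series(["."] * len(tss)))})


def assign_genomic_class(
    dmrs: pd.DataFrame,
    tss: pd.DataFrame,
    promoter_window: tuple[int, int] = (-2000, 200),
    distal_min_tss_dist: int = 2000,
    promoter_q_max: float = 0.01,
) -> pd.DataFrame:
    """Add a ``genomic_class`` column: promoter / distal / other.

    Promoter-DMRs are the stringent subset (q < promoter_q_max) overlapping a
    strand-aware promoter window; DMRs whose nearest TSS is farther than
    ``distal_min_tss_dist`` are distal; the rest are other.  A ``gene``
    column records the overlapped promoter's gene (first by position).
    """
    if tss.empty:
        raise ValueError("tss_list is empty")
    out = dmrs.reset_index(drop=True).copy()
    wins = promoter_windows(tss, promoter_window)
    cls = np.full(len(out), "other", dtype=object)
    gene = np.full(len(out), "", dtype=object)
    tss_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in tss.groupby("chrom")}
    for i, r in out.iterrows():
        s, e = int(r["start"]), int(r["end"])
        ts = tss_by_chrom.get(r["chrom"], np.array([]))
        if ts.size:
            j = np.searchsorted(ts, s)
            cands = []
            if j > 0:
                cands.append(s - ts[j - 1])
            if j < ts.size:
                cands.append(max(0, ts[j] - (e - 1)))
            dist = min(cands)
        else:
            dist = np.iinfo(np.int64).max
        w = wins.loc[wins["chrom"] == r["chrom"]]
        ov = (w["start"].to_numpy() < e) & (w["end"].to_numpy() > s)
        if ov.any() and r["q"] < promoter_q_max:
            cls[i] = "promoter"
            gene[i] = w["gene"].to_numpy()[np.flatnonzero(ov)[0]]
        elif dist > distal_min_tss_dist:
            cls[i] = "distal"
    out["genomic_class"] = cls
    out["gene"] = gene
    return out


def classify_retention(nodox: float, dox: float, doxwd7: float) -> str:
    """Retention class of one DMR from its three condition levels.

    retain : noDox < 10%, Dox > 10%, DoxWD-7d > 10% and >= 2x noDox
    loss   : noDox < 10%, Dox > 10%, DoxWD-7d < 10%
    """
    levels = (nodox, dox, doxwd7)
    if any(l is None or (isinstance(l, float) and np.isnan(l)) for l in levels):
        logger.info("classify_retention: undefined level -> unclassified")
        return "unclassified"
    if nodox < 0.10 and dox > 0.10:
        if doxwd7 > 0.10 and doxwd7 >= 2 * nodox:
            return "retain"
        if doxwd7 < 0.10:
            return "loss"
    return "unclassified"


def classify_retention_table(dmrs: pd.DataFrame, col_nodox="meth_nodox",
                             col_dox="meth_dox", col_wd7="meth_doxwd7") -> pd.DataFrame:
    out = dmrs.copy()
    out["retention_class"] = [
        classify_retention(a, b, c)
        for a, b, c in zip(out[col_nodox], out[col_dox], out[col_wd7])
    ]
    return out


def call_umrs(calls: pd.DataFrame, max_mcg: float = 0.10, min_cpgs: int = 10) -> pd.DataFrame:
    """Simplified unmethylated-region caller.

    Maximal runs of consecutive CpG units each with level <= max_mcg and
    containing >= min_cpgs CpGs; interval spans first to last CpG (the +2
    covers the final CpG dinucleotide).  Calls must be strand-collapsed.
    """
    rows = []
    cg = calls.loc[(calls["context"] == "CG") & (calls["total"] > 0)]
    for chrom, grp in cg.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        level = grp["m"].to_numpy() / grp["total"].to_numpy()
        pos = grp["pos"].to_numpy()
        low = level <= max_mcg
        edges = np.flatnonzero(np.diff(np.concatenate([[0], low.view(np.int8), [0]])))
        for a, b in zip(edges[::2], edges[1::2]):
            if b - a >= min_cpgs:
                mean_m = float(np.mean(level[a:b]))
                rows.append((chrom, int(pos[a]), int(pos[b - 1]) + 2, int(b - a), mean_m))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpgs", "mean_mcg"])


def umr_overlap_fraction(dmr: tuple[str, int, int], umrs: pd.DataFrame) -> float:
    """|DMR ∩ UMR| / |UMR| for the best-overlapping UMR (0 if none).

    Ties are broken by largest intersection, then leftmost UMR.
    """
    chrom, start, end = dmr
    sub = umrs.loc[umrs["chrom"] == chrom]
    if sub.empty:
        return 0.0
    inter = np.clip(np.minimum(sub["end"], end) - np.maximum(sub["start"], start), 0, None)
    if inter.max() == 0:
        return 0.0
    best = sub.loc[inter == inter.max()].sort_values("start").iloc[0]
    return float(inter.max() / (best["end"] - best["start"]))


def region_overlap_permutation_test(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    genome_bounds: dict,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[int, float]:
    """Permutation test of region-set overlap (regioneR style).

    Observed statistic: number of A regions overlapping >= 1 B region.  The
    null re-places each A region uniformly on its own chromosome (length
    preserved) ``n_perm`` times; p = (1 + #{perm >= obs}) / (n_perm + 1),
    so the minimum attainable p is 1/(n_perm + 1).
    """
    if set_a.empty or set_b.empty:
        raise ValueError("both region sets must be non-empty")
    for df, label in ((set_a, "A"), (set_b, "B")):
        for _, r in df.iterrows():
            L = genome_bounds.get(r["chrom"])
            if L is None or r["end"] > L or r["start"] < 0:
                raise ValueError(f"region set {label}: {r['chrom']}:{r['start']}-{r['end']} outside genome bounds")
            if r["end"] - r["start"] > L:
                raise ValueError(f"region longer than chromosome {r['chrom']}")
    rng = np.random.default_rng(seed)

    b_by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy())
                  for c, g in set_b.groupby("chrom", sort=False)}

    def count_overlaps(a_df) -> int:
        tot = 0
        for c, g in a_df.groupby("chrom", sort=False):
            if c not in b_by_chrom:
                continue
            bs, be = b_by_chrom[c]
            tot += int(overlap_any(g["start"].to_numpy(), g["end"].to_numpy(), bs, be).sum())
        return tot

    observed = count_overlaps(set_a)
    a_chrom = set_a["chrom"].to_numpy()
    a_len = (set_a["end"] - set_a["start"]).to_numpy()
    ge = 0
    for _ in range(n_perm):
        starts = np.empty(len(set_a), dtype=np.int64)
        for c in np.unique(a_chrom):
            mask = a_chrom == c
            L = genome_bounds[c]
            starts[mask] = rng.integers(0, L - a_len[mask] + 1)
        perm = pd.DataFrame({"chrom": a_chrom, "start": starts, "end": starts + a_len})
        if count_overlaps(perm) >= observed:
            ge += 1
    p = (1 + ge) / (n_perm + 1)
    return observed, p
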