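import numpy as np
import pandas as pd
import pytest

import methylforge as mf
from methylforge.core import collapse_strands
from methylforge.periodicity import (
    AnchorProfile, aggregate_profile, ch_context_preference,
    difference_profile, estimate_period,
)
from methylforge.sim.sequencing import simulate_reads_and_calls


BINS = np.arange(-1000, 1000, 10) + 5.0


def _profile(values, coverage=None):
    return AnchorProfile("test", 10, 1000, BINS, np.asarray(values, float),
                         coverage if coverage is not None else np.full(BINS.size, 100.0), 10)


def test_flat_signal_gives_flat_profile():
    calls = pd.DataFrame({"chrom": "chr1", "pos": np.arange(0, 20_000, 40),
                          "strand": "+", "context": "CG", "m": 5, "total": 10})
    anchors = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [5_000, 9_000, 13_000],
                            "strand": ["+", "-", "+"]})
    prof = aggregate_profile(calls, anchors, flank=1000, bin_size=50)
    assert prof.defined
    assert np.nanmax(np.abs(prof.values - 0.5)) < 1e-12
    assert len(prof.values) == 2 * 1000 // 50


def test_profile_matches_pooled_count_oracle():
    rng = np.random.default_rng(3)
    calls = pd.DataFrame({"chrom": "chr1", "pos": np.sort(rng.choice(50_000, 3_000, replace=False)),
                          "strand": "+", "context": "CG",
                          "total": rng.integers(1, 40, 3_000)})
    calls["m"] = rng.binomial(calls["total"], 0.3)
    anchors = pd.DataFrame({"chrom": "chr1",
                            "pos": rng.integers(2_000, 48_000, 100), "strand": "+"})
    flank, bs = 1_000, 100
    prof = aggregate_profile(calls, anchors, flank=flank, bin_size=bs, strand_flip=False)
    m_or = np.zeros(2 * flank // bs)
    t_or = np.zeros_like(m_or)
    for _, a in anchors.iterrows():
        sub = calls[(calls.pos >= a.pos - flank) & (calls.pos < a.pos + flank)]
        b = ((sub.pos - a.pos + flank) // bs).astype(int)
        for bi, m, t in zip(b, sub.m, sub.total):
            m_or[bi] += m
            t_or[bi] += t
    expect = np.where(t_or > 0, m_or / np.maximum(t_or, 1), np.nan)
    assert np.allclose(prof.coverage, t_or)
    assert np.allclose(prof.values, expect, equal_nan=True)


def test_profile_anchor_order_invariance():
    rng = np.random.default_rng(4)
    calls = pd.DataFrame({"chrom": "chr1", "pos": np.arange(0, 30_000, 60),
                          "strand": "+", "context": "CG",
                          "total": rng.integers(1, 30, 500)})
    calls["m"] = rng.binomial(calls["total"], 0.5)
    anchors = pd.DataFrame({"chrom": "chr1", "pos": [5_000, 10_000, 20_000], "strand": "+"})
    a = aggregate_profile(calls, anchors, 1000, 50)
    b = aggregate_profile(calls, anchors.iloc[::-1], 1000, 50)
    assert np.allclose(a.values, b.values, equal_nan=True)


def test_strand_flip_mirrors_minus_anchors():
    calls = pd.DataFrame({"chrom": "chr1", "pos": np.arange(4_000, 6_000, 10),
                          "strand": "+", "context": "CG", "total": 10})
    calls["m"] = (calls["pos"] > 5_000).astype(int) * 10  # step up right of 5000
    plus = aggregate_profile(calls, pd.DataFrame({"chrom": ["chr1"], "pos": [5_000], "strand": ["+"]}),
                             500, 50)
    minus = aggregate_profile(calls, pd.DataFrame({"chrom": ["chr1"], "pos": [5_000], "strand": ["-"]}),
                              500, 50)
    assert np.allclose(plus.values, minus.values[::-1], equal_nan=True)


@pytest.mark.parametrize("period", [160, 190, 220])
def test_period_recovery_noiseless(period):
    v = 0.3 + 0.1 * np.cos(2 * np.pi * BINS / period)
    est = estimate_period(_profile(v), n_perm=199, seed=1)
    assert abs(est.period - period) <= 10
    assert est.pvalue < 0.01
    assert abs(est.phase) <= 10  # cosine peak at the anchor


def test_period_flat_profile_not_significant():
    rng = np.random.default_rng(0)
    n_ok = 0
    for s in range(40):
        v = 0.3 + rng.normal(0, 0.02, BINS.size)
        est = estimate_period(_profile(v), n_perm=99, seed=100 + s)
        n_ok += est.pvalue >= 0.05
    assert n_ok >= 33  # ~calibrated; detailed check in the acceptance suite


def test_period_flank_too_small_raises():
    prof = AnchorProfile("t", 10, 200, np.arange(-200, 200, 10) + 5.0,
                         np.zeros(40), np.ones(40), 1)
    with pytest.raises(ValueError, match="flank"):
        estimate_period(prof, period_range=(120, 300))


def test_simulated_protection_sets_profile_period(small_ref):
    """Hard nucleosome protection at 200 bp spacing imprints a 200 bp period
    on the mCG-gain profile, and the mCH profile shares it (the CpH channel
    mirrors the CpG deposition pattern)."""
    p = mf.KineticParams(nucleosome_protection=0.0, nucleosome_spacing=200,
                         p_gain_cg=0.8, p_gain_ch_base=0.08)
    truth = mf.simulate_methylomes(small_ref, p, conditions=("noDox", "Dox"),
                                   n_molecules=150, seed=4)
    _, calls = simulate_reads_and_calls(truth, depth=30, seed=5, with_records=False)
    anchors = small_ref.motif_centers().rename(columns={"center": "pos"})[["chrom", "pos", "strand"]]
    prof = {}
    for ctx_name, keep_cg in (("mCG", True), ("mCH", False)):
        parts = {}
        for cond in ("Dox", "noDox"):
            c = calls[cond]
            sub = c[c["context"] == "CG"] if keep_cg else c[c["context"] != "CG"]
            if keep_cg:
                sub = collapse_strands(sub)
            parts[cond] = aggregate_profile(sub, anchors, flank=1000, bin_size=10,
                                            channel=ctx_name)
        prof[ctx_name] = difference_profile(parts["Dox"], parts["noDox"])
    est_cg = estimate_period(prof["mCG"], n_perm=199, seed=6)
    est_ch = estimate_period(prof["mCH"], n_perm=199, seed=7)
    assert abs(est_cg.period - 200) <= 10 and est_cg.pvalue < 0.05
    assert abs(est_ch.period - est_cg.period) <= 10


def test_ch_context_uniform_enrichment_one(small_ref):
    sites = small_ref.sites
    ch = (~sites.is_cg) & (~sites.is_spike) & (sites.strand == "+")
    idx = np.flatnonzero(ch)[:2_000]
    calls = pd.DataFrame({
        "chrom": np.array(sites.chrom_names, dtype=object)[sites.chrom_index[idx]],
        "pos": sites.pos[idx], "strand": "+", "context": sites.context[idx],
        "m": 3, "total": 10})
    tab = ch_context_preference(calls, small_ref.all_sequences)
    assert np.allclose(tab["enrichment"], 1.0)


def test_ch_context_weighted_mean_is_one(small_ref):
    rng = np.random.default_rng(9)
    sites = small_ref.sites
    ch = (~sites.is_cg) & (~sites.is_spike)
    idx = np.flatnonzero(ch)
    idx = rng.choice(idx, 3_000, replace=False)
    tot = rng.integers(1, 40, idx.size)
    calls = pd.DataFrame({
        "chrom": np.array(sites.chrom_names, dtype=object)[sites.chrom_index[idx]],
        "pos": sites.pos[idx], "strand": sites.strand[idx],
        "context": sites.context[idx],
        "m": rng.binomial(tot, 0.1), "total": tot})
    tab = ch_context_preference(calls, small_ref.all_sequences)
    w = (tab["enrichment"] * tab["total"]).sum() / tab["total"].sum()
    assert w == pytest.approx(1.0, abs=1e-6)


def test_ch_context_empty_flagged(small_ref):
    empty = pd.DataFrame(columns=["chrom", "pos", "strand", "context", "m", "total"])
    tab = ch_context_preference(empty, small_ref.all_sequences)
    assert tab.empty
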