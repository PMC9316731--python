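import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methylforge as mf
from methylforge import io
from methylforge.core import (
    ReadMethylationRecord, classify_read, collapse_strands,
    estimate_nonconversion, read_class_profile, weighted_methylation,
    weighted_methylation_by_region,
)

from conftest import make_call_table


# ----------------------------------------------------------------- I/O ----

def test_cgmap_positions_are_one_based_on_disk(tmp_path):
    calls = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "strand": ["+"],
                          "context": ["CG"], "m": [3], "total": [5]})
    path = tmp_path / "x.cgmap"
    io.write_cgmap(calls, path)
    line = path.read_text().splitlines()[0].split("\t")
    assert line[2] == "101"
    back = io.read_calls(path, "cgmap")
    assert back.loc[0, "pos"] == 100


@pytest.mark.parametrize("dialect", ["cgmap", "bedgraph"])
def test_roundtrip_identity(tmp_path, dialect):
    rng = np.random.default_rng(0)
    calls = make_call_table(rng, n=300)
    path = tmp_path / f"x.{dialect}"
    if dialect == "cgmap":
        io.write_cgmap(calls, path)
    else:
        io.write_bedgraph_counts(calls, path)
    back = io.read_calls(path, dialect)
    for col in ["chrom", "pos", "m", "total"]:
        assert np.array_equal(back[col].to_numpy(), calls[col].to_numpy())


def test_empty_file_gives_empty_table(tmp_path):
    path = tmp_path / "empty.cgmap"
    path.write_text("")
    out = io.read_calls(path, "cgmap")
    assert out.empty and list(out.columns) == io.CALL_COLUMNS


def test_malformed_line_reports_line_number(tmp_path):
    path = tmp_path / "bad.cgmap"
    path.write_text("chr1\tC\t101\tCG\tCG\t0.5\t3\t5\nchr1\tC\toops\n")
    with pytest.raises(ValueError, match=":2"):
        io.read_calls(path, "cgmap")
    path.write_text("chr1\tC\t101\tXX\tCG\t0.5\t3\t5\n")
    with pytest.raises(ValueError, match="context"):
        io.read_calls(path, "cgmap")


def test_read_record_roundtrip(tmp_path):
    recs = [ReadMethylationRecord("r1", "chr1", 0, 150, np.array([5, 30, 60]),
                                  np.array(["M", "U", "M"]))]
    path = tmp_path / "reads.tsv"
    io.write_read_records(recs, path)
    back = io.read_read_records(path)
    assert back[0].read_id == "r1"
    assert np.array_equal(back[0].positions, recs[0].positions)
    assert np.array_equal(back[0].calls, recs[0].calls)


# ----------------------------------------------------- strand collapse ----

def test_collapse_merges_symmetric_cpg():
    calls = pd.DataFrame({
        "chrom": ["chr1", "chr1"], "pos": [100, 101], "strand": ["+", "-"],
        "context": ["CG", "CG"], "m": [3, 2], "total": [5, 5]})
    out = collapse_strands(calls)
    assert len(out) == 1
    assert out.loc[0, ["pos", "m", "total"]].tolist() == [100, 5, 10]


def test_collapse_plus_only_unchanged():
    calls = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10, 30, 50],
                          "strand": "+", "context": "CG",
                          "m": [1, 2, 3], "total": [4, 5, 6]})
    out = collapse_strands(calls)
    assert np.array_equal(out["m"].to_numpy(), calls["m"].to_numpy())


def test_collapse_passes_ch_through(small_ref):
    calls = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [10, 11],
                          "strand": ["+", "-"], "context": ["CHH", "CHG"],
                          "m": [1, 1], "total": [2, 2]})
    out = collapse_strands(calls)
    assert len(out) == 2


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_collapse_conserves_total_counts(seed):
    rng = np.random.default_rng(seed)
    n = 400
    pos = rng.integers(0, 10_000, n)
    calls = pd.DataFrame({
        "chrom": rng.choice(["chr1", "chr2"], n), "pos": pos,
        "strand": rng.choice(["+", "-"], n),
        "context": rng.choice(["CG", "CHG", "CHH"], n, p=[0.5, 0.25, 0.25]),
        "total": rng.integers(1, 50, n)})
    calls["m"] = rng.binomial(calls["total"], 0.4)
    out = collapse_strands(calls)
    assert out["total"].sum() == calls["total"].sum()
    assert out["m"].sum() == calls["m"].sum()


# ------------------------------------------------ weighted methylation ----

def test_weighted_is_count_ratio_not_mean_of_levels():
    calls = pd.DataFrame({"chrom": "chr1", "pos": [10, 20], "strand": "+",
                          "context": "CG", "m": [3, 7], "total": [10, 10]})
    assert weighted_methylation(calls, ("chr1", 0, 100)) == 0.5
    skew = pd.DataFrame({"chrom": "chr1", "pos": [10, 20], "strand": "+",
                         "context": "CG", "m": [0, 10], "total": [100, 10]})
    assert weighted_methylation(skew, ("chr1", 0, 100)) == pytest.approx(10 / 110)


def test_weighted_undefined_is_nan_not_zero():
    calls = pd.DataFrame({"chrom": "chr1", "pos": [10], "strand": "+",
                          "context": "CG", "m": [0], "total": [5]})
    assert np.isnan(weighted_methylation(calls, ("chr1", 100, 200)))
    assert np.isnan(weighted_methylation(calls, ("chr1", 0, 100), min_coverage=10))


def test_weighted_matches_bruteforce_oracle():
    rng = np.random.default_rng(1)
    calls = make_call_table(rng, n=500)
    regions = pd.DataFrame({
        "chrom": "chr1",
        "start": rng.integers(0, 45_000, 300)})
    regions["end"] = regions["start"] + rng.integers(100, 5_000, 300)
    vec = weighted_methylation_by_region(calls, regions, min_coverage=5)
    for i, r in regions.iterrows():
        sub = calls[(calls.pos >= r.start) & (calls.pos < r.end) & (calls.total >= 5)]
        expect = sub.m.sum() / sub.total.sum() if sub.total.sum() else np.nan
        scalar = weighted_methylation(calls, ("chr1", r.start, r.end), min_coverage=5)
        if np.isnan(expect):
            assert np.isnan(vec[i]) and np.isnan(scalar)
        else:
            assert vec[i] == expect == scalar


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_weighted_invariant_to_order_and_splitting(seed):
    rng = np.random.default_rng(seed)
    calls = make_call_table(rng, n=100, span=1_000)
    full = weighted_methylation(calls, ("chr1", 0, 1_000))
    shuffled = calls.sample(frac=1.0, random_state=1)
    assert weighted_methylation(shuffled, ("chr1", 0, 1_000)) == full
    # split interval, pool counts
    cut = 500
    parts = []
    for lo, hi in [(0, cut), (cut, 1_000)]:
        sub = calls[(calls.pos >= lo) & (calls.pos < hi)]
        parts.append((sub.m.sum(), sub.total.sum()))
    pooled = sum(p[0] for p in parts) / sum(p[1] for p in parts)
    assert pooled == pytest.approx(full, abs=1e-15)


# ------------------------------------------------------ non-conversion ----

def test_nonconversion_estimate_binomial():
    rng = np.random.default_rng(2)
    n = 100_000
    m = rng.binomial(n, 0.01)
    calls = pd.DataFrame({"chrom": ["lambda_spike"], "pos": [0], "strand": "+",
                          "context": "CG", "m": [m], "total": [n]})
    est = estimate_nonconversion(calls, "lambda_spike")
    assert 0.008 < est.rate < 0.012
    assert est.ci_low <= est.rate <= est.ci_high


def test_nonconversion_zero_has_zero_lower_bound():
    calls = pd.DataFrame({"chrom": ["lambda_spike"], "pos": [0], "strand": "+",
                          "context": "CG", "m": [0], "total": [500]})
    est = estimate_nonconversion(calls, "lambda_spike")
    assert est.rate == 0.0 and est.ci_low < 1e-12


def test_nonconversion_missing_spike_raises():
    calls = pd.DataFrame({"chrom": ["chr1"], "pos": [0], "strand": "+",
                          "context": "CG", "m": [0], "total": [5]})
    with pytest.raises(ValueError, match="spike"):
        estimate_nonconversion(calls, "lambda_spike")


# -------------------------------------------------- per-read analysis ----

def _read(calls_str, start=0):
    positions = np.arange(start + 5, start + 5 + 8 * len(calls_str), 8)
    return ReadMethylationRecord("r", "chr1", start, start + 150,
                                 positions, np.array(list(calls_str)))


@pytest.mark.parametrize("calls_str,expected", [
    ("MMMMM", "full"),
    ("UUUUUU", "unmethylated"),
    ("MUUUU", "intermediate"),
    ("MMMM", "excluded"),   # only 4 CpGs: below the >=5 rule
])
def test_classify_read(calls_str, expected):
    assert classify_read(_read(calls_str)) == expected


def test_classify_read_configurable_bins():
    r = _read("M" + "U" * 9)  # 10% methylated
    assert classify_read(r, bins=(0.1, 0.9)) == "unmethylated"
    assert classify_read(r) == "intermediate"


def test_profile_excludes_reads_below_overlap_fraction():
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [300]})
    inside = _read("UUUUU", start=60)          # fully inside
    partial = ReadMethylationRecord("p", "chr1", 0, 100,
                                    np.arange(55, 100, 8), np.array(["U"] * 6))
    props = read_class_profile([inside, partial], regions, min_overlap_frac=0.8)
    assert props["unmethylated"] == 1.0  # only the 100%-overlap read counts
    props2 = read_class_profile([inside, partial], regions, min_overlap_frac=0.4)
    assert props2.sum() == pytest.approx(1.0)


def test_profile_proportions_sum_to_one_or_flagged():
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000]})
    reads = [_read("MMMMM", start=i * 200) for i in range(4)]
    props = read_class_profile(reads, regions)
    assert props.sum() == pytest.approx(1.0, abs=1e-12)
    none = read_class_profile([], regions)
    assert none.isna().all()
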