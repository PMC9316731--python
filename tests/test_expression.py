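import numpy as np
import pandas as pd
import pytest

import methylforge as mf
from methylforge.expression import (
    CountMatrix, build_response_table, differential_expression,
    median_of_ratios, methylation_expression_trend, normalize_counts,
    spikein_shift_test,
)
from methylforge.sim.expression import simulate_expression_counts


def _classes(n, mix, seed, mag=1.0):
    r = np.random.default_rng(seed)
    cls = r.choice(["repressed", "insensitive", "activated"], size=n, p=mix)
    lfc = np.where(cls == "repressed", -mag, np.where(cls == "activated", mag, 0.0))
    return pd.DataFrame({"gene": [f"g{i}" for i in range(n)],
                         "class": cls, "true_log2fc": lfc})


# ------------------------------------------------------- simulation ----

def test_insensitive_genes_have_zero_fold_change():
    gc = _classes(100, [0, 1, 0], 1)
    cm, tt = simulate_expression_counts(gene_classes=gc, n_replicates=3, seed=2,
                                        nb_dispersion=0.02)
    assert (tt["true_log2fc"] == 0).all()
    a = cm.gene_counts[cm.samples_of("noDox")].mean(axis=1)
    b = cm.gene_counts[cm.samples_of("Dox")].mean(axis=1)
    ratio = (b.sum() / a.sum())
    assert ratio == pytest.approx(1.0, abs=0.05)


def test_repressed_genes_halve():
    gc = _classes(400, [1, 0, 0], 3)
    cm, _ = simulate_expression_counts(gene_classes=gc, n_replicates=4, seed=4,
                                       nb_dispersion=0.05)
    a = cm.gene_counts[cm.samples_of("noDox")].to_numpy().mean(axis=1)
    b = cm.gene_counts[cm.samples_of("Dox")].to_numpy().mean(axis=1)
    ratio = b.sum() / a.sum()
    se = np.std(b / np.maximum(a, 1)) / np.sqrt(len(a))
    assert abs(ratio - 0.5) < 3 * se + 0.01


def test_fixed_spikes_double_fraction_under_halved_mrna():
    gc = _classes(300, [0, 1, 0], 5)
    cm1, _ = simulate_expression_counts(gene_classes=gc, n_replicates=4, seed=6,
                                        nb_dispersion=0.02, ercc_fraction=0.02)
    cm2, _ = simulate_expression_counts(gene_classes=gc, n_replicates=4, seed=6,
                                        nb_dispersion=0.02, ercc_fraction=0.02,
                                        global_scale={"Dox": 0.5})
    def frac(cm, cond):
        s = cm.samples_of(cond)
        return cm.spike_counts[s].sum().sum() / cm.counts[s].sum().sum()
    f_no = frac(cm2, "noDox")
    f_dox = frac(cm2, "Dox")
    # spike fraction of the library: s/(s+g); halving g nearly doubles it
    expect = f_no / (0.5 + 0.5 * f_no * 2)
    assert f_dox / f_no == pytest.approx(expect / f_no, rel=0.05)
    assert f_dox > 1.8 * f_no
    assert frac(cm1, "Dox") == pytest.approx(f_no, rel=0.1)


def test_simulation_input_validation(small_ref):
    gc = _classes(10, [0, 1, 0], 0)
    with pytest.raises(ValueError, match="nb_dispersion"):
        simulate_expression_counts(gene_classes=gc, nb_dispersion=0.0)
    with pytest.raises(ValueError, match="ercc_fraction"):
        simulate_expression_counts(gene_classes=gc, ercc_fraction=1.5)
    with pytest.raises(ValueError, match="n_replicates"):
        simulate_expression_counts(gene_classes=gc, n_replicates=1)


def test_spike_rows_are_92_labeled(small_ref):
    gc = _classes(50, [0, 1, 0], 0)
    cm, _ = simulate_expression_counts(gene_classes=gc, seed=1)
    assert int(cm.spike_mask.sum()) == 92
    assert cm.spike_counts.index.str.startswith("ERCC-").all()


# ----------------------------------------------------- normalization ----

def test_size_factors_track_scaling():
    rng = np.random.default_rng(7)
    base = rng.poisson(100, 300) + 1
    counts = pd.DataFrame({"A": base, "B": 2 * base},
                          index=[f"g{i}" for i in range(300)])
    cm = CountMatrix(counts=counts, conditions={"A": "x", "B": "y"})
    out = normalize_counts(cm)
    sf = out.size_factors
    assert sf["B"] / sf["A"] == pytest.approx(2.0)
    norm = out.normalized()
    assert np.allclose(norm["A"], norm["B"])


def test_median_of_ratios_matches_bruteforce_oracle():
    rng = np.random.default_rng(8)
    counts = pd.DataFrame(rng.negative_binomial(10, 0.05, (400, 6)) + 1,
                          columns=list("abcdef"))
    sf = median_of_ratios(counts)
    logref = np.log(counts.to_numpy()).mean(axis=1)
    for j, col in enumerate(counts.columns):
        expect = np.exp(np.median(np.log(counts[col].to_numpy()) - logref))
        assert sf[col] == pytest.approx(expect, rel=1e-12)


def test_scale_equivariance():
    rng = np.random.default_rng(9)
    counts = pd.DataFrame(rng.poisson(50, (200, 4)) + 1, columns=list("abcd"))
    cm = CountMatrix(counts=counts, conditions={})
    sf1 = normalize_counts(cm).size_factors
    counts2 = counts.copy()
    counts2["c"] = counts2["c"] * 3
    sf2 = normalize_counts(CountMatrix(counts=counts2, conditions={})).size_factors
    # equivariance holds up to a common rescaling of all factors
    assert (sf2["c"] / sf2["a"]) / (sf1["c"] / sf1["a"]) == pytest.approx(3.0, rel=1e-9)
    assert sf2["b"] / sf2["a"] == pytest.approx(sf1["b"] / sf1["a"], rel=1e-9)


def test_low_count_filter_scales_with_samples():
    counts = pd.DataFrame(np.ones((5, 8), dtype=int) * 10,
                          index=[f"g{i}" for i in range(5)],
                          columns=[f"s{i}" for i in range(8)])
    counts.iloc[0, :5] = 0  # expressed in only 3 of 8 samples
    cm = CountMatrix(counts=counts, conditions={})
    out = normalize_counts(cm)
    assert "g0" not in out.counts.index
    assert len(out.counts) == 4


def test_all_zero_sample_rejected():
    counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]}, index=["g1", "g2"])
    with pytest.raises(ValueError, match="all-zero"):
        normalize_counts(CountMatrix(counts=counts, conditions={}))


# -------------------------------------------------- spike shift test ----

def test_identical_fractions_no_shift():
    counts = pd.DataFrame(
        {"a": [100, 10], "b": [100, 10], "c": [100, 10], "d": [100, 10]},
        index=["g1", "ERCC-1"])
    cm = CountMatrix(counts=counts, conditions={"a": "x", "b": "x", "c": "y", "d": "y"})
    res = spikein_shift_test(cm)
    assert res.pvalue == 1.0 and res.verdict == "no-shift"
    assert np.allclose(res.fractions, 10 / 110)


def test_spike_test_needs_two_reps_and_spikes():
    counts = pd.DataFrame({"a": [1], "b": [2], "c": [3]}, index=["ERCC-1"])
    cm = CountMatrix(counts=counts, conditions={"a": "x", "b": "y", "c": "y"})
    with pytest.raises(ValueError, match="replicates"):
        spikein_shift_test(cm)
    counts2 = pd.DataFrame(np.ones((2, 4), dtype=int), columns=list("abcd"),
                           index=["g1", "g2"])
    cm2 = CountMatrix(counts=counts2, conditions=dict(zip("abcd", "xxyy")))
    with pytest.raises(ValueError, match="spike"):
        spikein_shift_test(cm2)


# ------------------------------------------------- response table ----

def test_response_classes_by_fdr_and_sign():
    prom = pd.DataFrame({"gene": ["g1", "g2", "g3", "g4"], "delta": [0.4] * 4})
    de = pd.DataFrame({
        "gene": ["g1", "g2", "g3", "g4"],
        "log2FC": [-1.2, 0.8, 0.3, -2.0],
        "FDR": [0.03, 0.01, 0.5, 0.2],
        "baseMean": [500.0, 500.0, 500.0, 40.0],
    })
    resp = build_response_table(prom, de)
    t = resp.table.set_index("gene")
    assert t.loc["g1", "class"] == "down"
    assert t.loc["g2", "class"] == "up"
    assert t.loc["g3", "class"] == "not-DE"
    assert "g4" not in t.index  # below the >50 normalized counts rule
    assert resp.proportions.sum() == pytest.approx(1.0)


def test_response_exclude_genes():
    prom = pd.DataFrame({"gene": ["g1", "g2"], "delta": [0.4, 0.4]})
    de = pd.DataFrame({"gene": ["g1", "g2"], "log2FC": [-1, -1],
                       "FDR": [0.01, 0.01], "baseMean": [100.0, 100.0]})
    resp = build_response_table(prom, de, exclude_genes={"g2"})
    assert list(resp.table["gene"]) == ["g1"]


def test_response_recovery_from_simulation():
    gc = _classes(500, [0.4, 0.4, 0.2], 11)
    cm, tt = simulate_expression_counts(gene_classes=gc, n_replicates=4, seed=12,
                                        nb_dispersion=0.02, base_mean_median=500)
    de = differential_expression(normalize_counts(cm, basis="spikes"), "noDox", "Dox")
    resp = build_response_table(pd.DataFrame({"gene": gc["gene"], "delta": 0.5}), de)
    truthmap = tt.set_index("gene")["class"].map(
        {"repressed": "down", "insensitive": "not-DE", "activated": "up"})
    acc = (resp.table["class"].to_numpy()
           == truthmap.loc[resp.table["gene"]].to_numpy()).mean()
    assert acc >= 0.95


# ------------------------------------------------------- trend ----

def test_trend_perfect_anticorrelation():
    df = pd.DataFrame({"dmr_stat": np.linspace(0, 1, 50)})
    df["log2FC"] = -df["dmr_stat"]
    res = methylation_expression_trend(df)
    assert res.rho == pytest.approx(-1.0)


def test_trend_smoother_exact_on_linear_input():
    x = np.linspace(0, 1, 100)
    df = pd.DataFrame({"dmr_stat": x, "log2FC": 2 * x - 1})
    res = methylation_expression_trend(df)
    interior = (res.curve["x"] > 0.2) & (res.curve["x"] < 0.8)
    assert np.allclose(res.curve.loc[interior, "y"],
                       2 * res.curve.loc[interior, "x"] - 1, atol=1e-6)


def test_trend_constant_statistic_flagged():
    df = pd.DataFrame({"dmr_stat": np.ones(20), "log2FC": np.arange(20.0)})
    res = methylation_expression_trend(df)
    assert not res.defined and np.isnan(res.rho)


def test_trend_requires_ten_genes():
    df = pd.DataFrame({"dmr_stat": np.arange(5.0), "log2FC": np.arange(5.0)})
    with pytest.raises(ValueError, match=">= 10"):
        methylation_expression_trend(df)
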