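"""End-to-end orchestration of a synthetic experiment and its analysis.

``simulate_experiment`` writes a complete miniature experiment to disk
(reference FASTA, feature BEDs, per-condition replicate CGmap files, read
records, count matrix, truth JSON); ``run_pipeline`` runs every downstream
stage on it and writes deterministic TSV/JSON reports.  Both are seeded:
the same seed and configuration produce byte-identical output trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, dmr as dmr_mod, io, periodicity as per_mod
from . import chromatin as chrom_mod, expression as expr_mod
from .sim import (
    KineticParams, ReferenceConfig, simulate_expression_counts,
    simulate_methylomes, simulate_reference,
)
from .sim.sequencing import replicate_call_sets, simulate_reads_and_calls

FLOAT_FMT = "%.6g"


@dataclass
class ExperimentConfig:
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    params: KineticParams = field(default_factory=KineticParams)
    conditions: tuple = ("noDox", "Dox", "DoxWD-7d", "Dox-mut")
    n_molecules: int = 100
    depth: float = 30.0
    n_replicates: int = 2
    frag_len: int = 150
    n_expr_genes: int = 300
    n_expr_replicates: int = 4

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = json.load(fh)
        ref = ReferenceConfig(**raw.pop("reference", {}))
        par = KineticParams(**raw.pop("params", {}))
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(reference=ref, params=par, **raw)


def _write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def simulate_experiment(cfg: ExperimentConfig, outdir, seed: int = 0):
    """Simulate and write a full experiment; returns (truth, artifacts dict)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = simulate_reference(cfg.reference, seed=seed)
    truth = simulate_methylomes(ref, cfg.params, conditions=cfg.conditions,
                                n_molecules=cfg.n_molecules, seed=seed + 1)
    reps = replicate_call_sets(truth, depth=cfg.depth, n_replicates=cfg.n_replicates,
                               frag_len=cfg.frag_len, seed=seed + 2)
    records, _ = simulate_reads_and_calls(truth, depth=cfg.depth, frag_len=cfg.frag_len,
                                          seed=seed + 3, conditions=["Dox"])
    _, tab_calls = simulate_reads_and_calls(truth, depth=cfg.depth, frag_len=cfg.frag_len,
                                            seed=seed + 4, channel="tab", with_records=False)
    cm, expr_truth = simulate_expression_counts(
        truth, n_genes=cfg.n_expr_genes, n_replicates=cfg.n_expr_replicates, seed=seed + 5)

    io.write_fasta(ref.all_sequences, outdir / "reference.fa")
    io.write_bed6(ref.cgi.assign(name="CGI", score=0, strand="."), outdir / "cgi.bed")
    io.write_bed6(ref.tss.assign(start=ref.tss["pos"], end=ref.tss["pos"] + 1,
                                 name=ref.tss["gene"], score=0),
                  outdir / "tss.bed")
    io.write_bed6(ref.motif_sites.assign(end=ref.motif_sites["start"] + 12,
                                         name="motif", score=ref.motif_sites["affinity"]),
                  outdir / "motif_sites.bed")
    for cond, rep_list in reps.items():
        for i, calls in enumerate(rep_list, start=1):
            io.write_cgmap(calls, outdir / f"calls_{cond}_rep{i}.cgmap")
    for cond, df in tab_calls.items():
        io.write_cgmap(df, outdir / f"tabseq_{cond}.cgmap")
    io.write_read_records(records["Dox"], outdir / "reads_Dox.tsv")
    io.write_counts(cm.counts, outdir / "counts.tsv")
    _write_tsv(expr_truth, outdir / "expression_truth.tsv")
    io.write_json(truth.summary(), outdir / "truth.json")
    return truth, {"reps": reps, "records": records, "tab_calls": tab_calls,
                   "counts": cm, "expr_truth": expr_truth}


def run_pipeline(cfg: ExperimentConfig, outdir, seed: int = 0) -> dict:
    """Simulate an experiment and run every analysis stage over it.

    Writes reports under ``outdir`` and returns the headline numbers as a
    flat dict (also written to ``pipeline_summary.json``).
    """
    outdir = Path(outdir)
    truth, art = simulate_experiment(cfg, outdir, seed=seed)
    ref = truth.ref
    reps = art["reps"]
    summary: dict = {"seed": seed}

    # --- non-conversion from the unmethylated spike
    pooled_dox = _pool(reps["Dox"])
    nc = core.estimate_nonconversion(pooled_dox, "lambda_spike")
    summary["nonconversion_rate"] = nc.rate
    summary["nonconversion_n_calls"] = nc.n_calls

    # --- DMRs Dox vs noDox
    dmrs = dmr_mod.detect_dmrs(reps["Dox"], reps["noDox"], seed=seed + 10)
    kept = dmr_mod.filter_dmrs(dmrs)
    kept = dmr_mod.assign_genomic_class(kept, ref.tss)
    # per-condition levels + retention where a withdrawal condition exists
    pooled = {}
    for c, r in reps.items():
        all_calls = _pool(r)
        pooled[c] = core.collapse_strands(all_calls.loc[all_calls["context"] == "CG"])
    for cond in ("noDox", "Dox", "DoxWD-7d"):
        if cond in pooled:
            col = {"noDox": "meth_nodox", "Dox": "meth_dox", "DoxWD-7d": "meth_doxwd7"}[cond]
            kept[col] = core.weighted_methylation_by_region(pooled[cond], kept)
    if {"meth_nodox", "meth_dox", "meth_doxwd7"} <= set(kept.columns):
        kept = dmr_mod.classify_retention_table(kept)
        vc = kept["retention_class"].value_counts()
        summary["n_retain_dmrs"] = int(vc.get("retain", 0))
        summary["n_loss_dmrs"] = int(vc.get("loss", 0))
    _write_tsv(kept, outdir / "dmrs.tsv")
    summary["n_dmrs"] = len(kept)
    summary["n_promoter_dmrs"] = int((kept["genomic_class"] == "promoter").sum())

    umrs = dmr_mod.call_umrs(pooled["noDox"])
    _write_tsv(umrs, outdir / "umrs_noDox.tsv")
    summary["n_umrs"] = len(umrs)

    # --- overlap of DMRs with planted motif target regions
    if len(kept):
        obs, p_ov = dmr_mod.region_overlap_permutation_test(
            kept[["chrom", "start", "end"]], truth.target_regions,
            ref.chrom_lengths, n_perm=100, seed=seed + 11)
        summary["dmr_motif_overlap_count"] = obs
        summary["dmr_motif_overlap_p"] = p_ov

    # --- nucleosome-phased deposition
    anchors = ref.motif_centers().rename(columns={"center": "pos"})[["chrom", "pos", "strand"]]
    prof_dox = per_mod.aggregate_profile(pooled["Dox"], anchors, flank=1000, bin_size=10)
    prof_nodox = per_mod.aggregate_profile(pooled["noDox"], anchors, flank=1000, bin_size=10)
    gain = per_mod.difference_profile(prof_dox, prof_nodox, channel="mCG_gain")
    est = per_mod.estimate_period(gain, n_perm=500, seed=seed + 12)
    _write_tsv(pd.DataFrame({"bin_center": gain.bin_centers, "value": gain.values,
                             "coverage": gain.coverage}), outdir / "gain_profile.tsv")
    summary["period_bp"] = est.period
    summary["period_p"] = est.pvalue

    ch_dox = _pool(reps["Dox"])
    ctx = per_mod.ch_context_preference(ch_dox, ref.all_sequences)
    _write_tsv(ctx.head(50), outdir / "ch_context.tsv")
    if len(ctx):
        summary["top_ch_context"] = str(ctx.iloc[0]["context"])
        summary["top_ch_enrichment"] = float(ctx.iloc[0]["enrichment"])

    # --- expression
    cm = expr_mod.normalize_counts(art["counts"])
    shift = expr_mod.spikein_shift_test(cm, {s: c for s, c in cm.conditions.items()})
    summary["spike_shift_p"] = shift.pvalue
    summary["spike_shift_verdict"] = shift.verdict
    de = expr_mod.differential_expression(cm, "noDox", "Dox")
    _write_tsv(de, outdir / "de_table.tsv")
    prom = kept.loc[kept["genomic_class"] == "promoter", ["gene", "delta"]]
    if len(prom) >= 1:
        resp = expr_mod.build_response_table(prom, de)
        _write_tsv(resp.table, outdir / "response_table.tsv")
        for k, v in resp.proportions.items():
            summary[f"response_prop_{k}"] = float(v)
        if resp.n_genes >= 10:
            trend = expr_mod.methylation_expression_trend(resp)
            summary["trend_spearman_rho"] = trend.rho
            summary["trend_spearman_p"] = trend.pvalue

    # --- hmC by region class (TAB channel)
    tab = art["tab_calls"]
    if "DoxWD-7d" in tab and len(kept) and "retention_class" in kept.columns:
        sets = {
            "loss-DMR": kept.loc[kept["retention_class"] == "loss"],
            "retain-DMR": kept.loc[kept["retention_class"] == "retain"],
            "non-DMR promoter": dmr_mod.promoter_windows(ref.tss),
        }
        try:
            hmc = chrom_mod.hmc_by_region_class(tab["DoxWD-7d"], sets)
            _write_tsv(hmc.tests, outdir / "hmc_tests.tsv")
            summary["hmc_median_loss_dmr"] = float(hmc.medians.get("loss-DMR", np.nan))
        except ValueError:
            pass

    io.write_json(summary, outdir / "pipeline_summary.json")
    return summary


def _pool(replicates) -> pd.DataFrame:
    """Sum call counts across replicate call tables."""
    cat = pd.concat(replicates, ignore_index=True)
    return (cat.groupby(["chrom", "pos", "strand", "context"], as_index=False, sort=True)
            .agg(m=("m", "sum"), total=("total", "sum")))
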