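"""Expression count simulation with ERCC-style spike-in rows.

Counts are negative-binomial with per-gene base means spanning orders of
magnitude.  Gene means respond to condition through each gene's true log2
fold change (from the methylome ground truth) and through a per-condition
global mRNA-per-cell scale factor; spike-in rows model a fixed absolute
amount of exogenous RNA per cell, so their expected counts do NOT follow the
global scale — which is exactly what makes them a control for global shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_ERCC = 92


def simulate_expression_counts(
    truth=None,
    n_genes: int | None = None,
    n_replicates: int = 4,
    nb_dispersion: float = 0.05,
    ercc_fraction: float = 0.02,
    global_scale: dict | None = None,
    conditions=("noDox", "Dox"),
    seed: int = 0,
    gene_classes: pd.DataFrame | None = None,
    base_mean_median: float = 200.0,
    base_mean_log_sigma: float = 1.2,
):
    """Simulate a gene x sample count matrix plus its DE truth table.

    ``gene_classes`` (columns gene, class, true_log2fc) overrides the classes
    carried by ``truth`` — plumbing for focused tests.  Fold changes apply in
    the "Dox" condition; noDox / Dox-mut stay at baseline.

    Returns ``(CountMatrix, truth_table)``.
    """
    from ..expression import CountMatrix  # local import to avoid a cycle

    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    if not (0.0 < ercc_fraction < 1.0):
        raise ValueError("ercc_fraction must be in (0, 1)")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 per condition")

    if gene_classes is None:
        if truth is None:
            raise ValueError("need a SimulationTruth or an explicit gene_classes table")
        gene_classes = truth.gene_classes[["gene", "class", "true_log2fc"]].copy()
    gene_classes = gene_classes.reset_index(drop=True)

    rng = np.random.default_rng(seed)
    if n_genes is not None:
        if n_genes < len(gene_classes):
            keep = rng.choice(len(gene_classes), size=n_genes, replace=False)
            gene_classes = gene_classes.iloc[np.sort(keep)].reset_index(drop=True)
        elif n_genes > len(gene_classes):
            extra = pd.DataFrame({
                "gene": [f"bg{i + 1:05d}" for i in range(n_genes - len(gene_classes))],
                "class": "insensitive",
                "true_log2fc": 0.0,
            })
            gene_classes = pd.concat([gene_classes, extra], ignore_index=True)

    genes = gene_classes["gene"].to_numpy()
    lfc = gene_classes["true_log2fc"].to_numpy(dtype=float)
    n = len(genes)
    base = rng.lognormal(mean=np.log(base_mean_median), sigma=base_mean_log_sigma, size=n)

    scale = {c: 1.0 for c in conditions}
    if truth is not None:
        scale.update({c: v for c, v in truth.global_scale.items() if c in scale})
    if global_scale:
        scale.update(global_scale)

    # spike means: log-uniform over 4 orders of magnitude, fixed across conditions,
    # scaled so spikes are ercc_fraction of the baseline library
    spike_raw = 10.0 ** rng.uniform(0, 4, size=N_ERCC)
    spike_means = spike_raw * (ercc_fraction / (1 - ercc_fraction)) * base.sum() / spike_raw.sum()
    spike_names = [f"ERCC-{i + 1:05d}" for i in range(N_ERCC)]

    r = 1.0 / nb_dispersion
    cols, data = [], []
    for cond in conditions:
        eff = np.where(_is_induced(cond), 2.0 ** lfc, 1.0)
        mu_gene = base * eff * scale[cond]
        for rep in range(1, n_replicates + 1):
            mu = np.concatenate([mu_gene, spike_means])
            p = r / (r + mu)
            data.append(rng.negative_binomial(r, p))
            cols.append(f"{cond}_rep{rep}")
    counts = pd.DataFrame(
        np.column_stack(data), index=list(genes) + spike_names, columns=cols
    )
    counts.index.name = "gene"
    condition_map = {f"{c}_rep{r}": c for c in conditions for r in range(1, n_replicates + 1)}

    truth_table = gene_classes.copy()
    truth_table["base_mean"] = base
    cm = CountMatrix(counts=counts, conditions=condition_map)
    return cm, truth_table


def _is_induced(cond: str) -> bool:
    """Conditions in which methylation-driven fold changes apply."""
    return cond == "Dox"
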