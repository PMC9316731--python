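import numpy as np
import pandas as pd
import pytest

import methylforge as mf
from methylforge.sim.methylome import STATE_MC, STATE_U


def make_call_table(rng, n=200, chrom="chr1", span=50_000, context="CG",
                    level=None, coverage=30):
    """Random single-strand call table with independent binomial counts."""
    pos = np.sort(rng.choice(span, size=n, replace=False))
    if level is None:
        level = rng.uniform(0, 1, n)
    elif np.isscalar(level):
        level = np.full(n, float(level))
    tot = rng.poisson(coverage, n) + 1
    m = rng.binomial(tot, level)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+",
                         "context": context, "m": m, "total": tot})


def two_population_truth(ref, frac_full=0.5, n_molecules=100, condition="Dox",
                         params=None):
    """SimulationTruth whose molecules are entirely methylated or entirely
    unmethylated at every CpG (spike truth preserved) — the ground truth the
    per-read classifier should recover exactly at zero non-conversion."""
    params = params or mf.KineticParams(epsilon_nonconv=0.0)
    truth = mf.simulate_methylomes(ref, params, conditions=(condition,),
                                   n_molecules=n_molecules, seed=0)
    sites = ref.sites
    st = truth.states[condition]
    n_full = int(round(frac_full * n_molecules))
    st[:, ~sites.is_spike] = STATE_U
    st[:n_full, sites.is_cg & ~sites.is_spike] = STATE_MC
    return truth, n_full


@pytest.fixture(scope="session")
def small_ref():
    return mf.simulate_reference(seed=11)


@pytest.fixture(scope="session")
def sparse_ref_config():
    """Well-separated promoter targets, used for detection calibration."""
    return mf.ReferenceConfig(
        chrom_sizes={"chr1": 60_000, "chr2": 40_000}, n_cgi=12, n_tss=12,
        n_motif_sites=10, promoter_motif_frac=0.8, min_feature_gap=2_500)


@pytest.fixture(scope="session")
def induced_truth(small_ref):
    """Default-parameter experiment with all five conditions."""
    return mf.simulate_methylomes(small_ref, n_molecules=100, seed=12)
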