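"""Bisulfite read emission and call aggregation.

Reads are emitted directly as per-molecule call records (alignment is not
modelled): each read derives from exactly one molecule, covers a contiguous
``frag_len`` window, and reports the molecule's state at every cytosine site
it spans.  The only error layer is bisulfite non-conversion: an unconverted
(unmethylated) cytosine is misread as methylated with probability
``epsilon_nonconv``.

Channels
--------
wgbs : mC and hmC both read as methylated (standard bisulfite chemistry).
tab  : TAB-seq — only hmC is protected and reads as methylated; mC converts.

Spike contigs are sequenced at a coverage set by their mass fraction of the
library (default 0.5% w/w relative to the main genome, the lambda spike
design), which at miniature genome scale yields a usable number of spike
calls.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..core import ReadMethylationRecord
from .methylome import SimulationTruth, STATE_MC, STATE_HMC

logger = logging.getLogger(__name__)


def simulate_reads_and_calls(
    truth: SimulationTruth,
    depth: float = 30.0,
    frag_len: int = 150,
    seed: int = 0,
    conditions=None,
    channel: str = "wgbs",
    spike_mass_fraction: float = 0.005,
    with_records: bool = True,
    epsilon: float | None = None,
):
    """Emit reads and aggregate calls for each condition.

    Parameters
    ----------
    depth : mean per-site coverage on the main genome
    frag_len : fragment (read) length in bp
    channel : "wgbs" or "tab"
    spike_mass_fraction : spike DNA mass relative to main-genome mass
    with_records : also build per-read CpG call records (CG context only)
    epsilon : override the truth's bisulfite non-conversion rate

    Returns
    -------
    (records, calls) : dict condition -> list[ReadMethylationRecord],
                       dict condition -> call table DataFrame
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if channel not in ("wgbs", "tab"):
        raise ValueError(f"unknown channel {channel!r}")
    eps = truth.params.epsilon_nonconv if epsilon is None else epsilon
    conditions = list(conditions or truth.states)
    sites = truth.sites
    ref = truth.ref
    if frag_len < 20:
        raise ValueError("frag_len too short to span sites")

    main_len = ref.main_genome_length
    spike_len = sum(len(s) for s in ref.spike_sequences.values())
    lengths = {**ref.chrom_lengths, **{k: len(v) for k, v in ref.spike_sequences.items()}}

    rng_root = np.random.SeedSequence(seed)
    cond_rngs = {c: np.random.default_rng(s) for c, s in zip(conditions, rng_root.spawn(len(conditions)))}

    all_records: dict[str, list] = {}
    all_calls: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        if cond not in truth.states:
            raise ValueError(f"condition {cond!r} has no simulated methylome")
        rng = cond_rngs[cond]
        states = truth.states[cond]
        n_mol = states.shape[0]
        m_tally = np.zeros(sites.n_sites, dtype=np.int64)
        t_tally = np.zeros(sites.n_sites, dtype=np.int64)
        records: list[ReadMethylationRecord] = []

        for name in sites.chrom_names:
            L = lengths[name]
            is_spike = name in ref.spike_sequences
            if is_spike:
                cov = depth * spike_mass_fraction * main_len / max(spike_len, 1)
            else:
                cov = depth
            # fragments may overhang contig ends (clipped), so expected
            # coverage is uniform at cov across the whole contig
            n_reads = int(round(cov * (L + frag_len - 1) / frag_len))
            if n_reads == 0:
                logger.warning("simulate_reads_and_calls: depth %.3g yields zero reads on %s", cov, name)
                continue
            pos_c, idx_c = sites.by_chrom[name]
            raw = rng.integers(-frag_len + 1, L, size=n_reads)
            starts = np.maximum(raw, 0)
            ends = np.minimum(raw + frag_len, L)
            mols = rng.integers(0, n_mol, size=n_reads)
            lo = np.searchsorted(pos_c, starts, side="left")
            hi = np.searchsorted(pos_c, ends, side="left")
            lens = hi - lo
            total = int(lens.sum())
            if total == 0:
                continue
            base = np.repeat(lo, lens)
            within = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
            site_local = base + within
            site_global = idx_c[site_local]
            mol_per_call = np.repeat(mols, lens)
            st = states[mol_per_call, site_global]
            if channel == "wgbs":
                obs = st >= STATE_MC
                unconverted_pool = st == 0
            else:
                obs = st == STATE_HMC
                unconverted_pool = st != STATE_HMC
            flip = unconverted_pool & (rng.random(total) < eps)
            obs = obs | flip
            np.add.at(t_tally, site_global, 1)
            np.add.at(m_tally, site_global, obs)

            if with_records:
                cg_mask = sites.is_cg[site_global]
                read_idx = np.repeat(np.arange(n_reads), lens)[cg_mask]
                pos_cg = sites.pos[site_global[cg_mask]]
                obs_cg = obs[cg_mask]
                bounds = np.searchsorted(read_idx, np.arange(n_reads + 1))
                for i in range(n_reads):
                    a, b = bounds[i], bounds[i + 1]
                    if a == b:
                        continue
                    records.append(ReadMethylationRecord(
                        read_id=f"{cond}:{name}:{i}",
                        chrom=name,
                        start=int(starts[i]),
                        end=int(ends[i]),
                        positions=pos_cg[a:b],
                        calls=np.where(obs_cg[a:b], "M", "U"),
                    ))

        covered = t_tally > 0
        chrom_arr = np.array(sites.chrom_names, dtype=object)[sites.chrom_index[covered]]
        calls = pd.DataFrame({
            "chrom": chrom_arr,
            "pos": sites.pos[covered],
            "strand": sites.strand[covered],
            "context": sites.context[covered],
            "m": m_tally[covered],
            "total": t_tally[covered],
        })
        all_records[cond] = records
        all_calls[cond] = calls
    return all_records, all_calls


def replicate_call_sets(truth, depth, n_replicates=2, frag_len=150, seed=0,
                        conditions=None, channel="wgbs", with_records=False):
    """Independent read draws as sequencing replicates.

    Returns dict condition -> list of call tables (one per replicate).
    Each replicate is a fresh sampling of molecules and fragments, emulating
    library replicates drawn from the same cell population.
    """
    reps: dict[str, list[pd.DataFrame]] = {}
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    for r in range(n_replicates):
        _, calls = simulate_reads_and_calls(
            truth, depth=depth, frag_len=frag_len, seed=child[r],
            conditions=conditions, channel=channel, with_records=with_records,
        )
        for cond, df in calls.items():
            reps.setdefault(cond, []).append(df)
    return reps
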