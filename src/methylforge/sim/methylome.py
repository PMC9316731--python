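"""Molecule-level methylome forward model.

Each condition holds ``n_molecules`` whole-genome DNA molecules; every
cytosine site of every molecule is in one of three states (unmethylated, mC,
hmC).  The model layers:

* a baseline methylome — CpGs mostly methylated outside CpG islands, CGIs
  essentially unmethylated, negligible CpH methylation;
* induced deposition around planted motif sites (Dox), scaled by motif
  affinity, suppressed inside nucleosome footprints phased around each motif,
  and context-weighted in the CpH channel (TxCAC-class preference);
* post-withdrawal kinetics — per cell division a methylated CpG is retained
  with probability ``p_maintain`` (passive dilution otherwise) or oxidised to
  hmC with probability ``k_tet``; hmC resolves to unmethylated on the
  following division.  With ``k_tet = 0`` the expected mCG frequency after
  ``d`` divisions is ``m0 * p_maintain**d``.

Spike contigs carry fixed truth: the lambda-like contig is fully
unmethylated, the pUC19-like contig fully hydroxymethylated.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .reference import ReferenceSet, SiteTable

STATE_U, STATE_MC, STATE_HMC = 0, 1, 2
CONDITIONS = ("noDox", "Dox", "DoxWD-3d", "DoxWD-7d", "Dox-mut")
_WITHDRAWAL_DAYS = {"DoxWD-3d": 3.0, "DoxWD-7d": 7.0}


@dataclass
class KineticParams:
    """Deposition / maintenance / demethylation parameters.

    All probabilities are per CpG (or per CpH) per event; ``ch_context_multiplier``
    maps IUPAC-wildcard 5-mer patterns centered on the cytosine ('N' matches
    anything; 3-mer keys are padded to 'NN' + key) to rate multipliers.
    """

    p_gain_cg: float = 0.7
    p_gain_ch_base: float = 0.02
    ch_context_multiplier: dict = field(default_factory=lambda: {"TNCAC": 5.0})
    nucleosome_protection: float = 0.25   # deposition multiplier inside a footprint
    nucleosome_footprint: int = 147
    nucleosome_spacing: int = 190
    gain_radius: int = 1_000              # motif influence half-width, bp
    p_maintain: float = 0.8
    k_tet: float = 0.02
    divisions_per_day: float = 1.0
    epsilon_nonconv: float = 0.005
    baseline_mcg: float = 0.8             # CpG methylation outside CGIs
    cgi_mcg: float = 0.01                 # CpG methylation inside CGIs
    baseline_mch: float = 0.002

    def __post_init__(self):
        for name in ("p_gain_cg", "p_gain_ch_base", "nucleosome_protection",
                     "p_maintain", "k_tet", "epsilon_nonconv",
                     "baseline_mcg", "cgi_mcg", "baseline_mch"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nucleosome_spacing <= 0:
            raise ValueError("nucleosome_spacing must be positive")
        if any(m < 0 for m in self.ch_context_multiplier.values()):
            raise ValueError("context multipliers must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment."""

    ref: ReferenceSet
    params: KineticParams
    conditions: list
    n_molecules: int
    states: dict                 # condition -> uint8 array (n_molecules, n_sites)
    dyads: pd.DataFrame          # chrom, pos (nucleosome dyad centers, post-binding)
    target_regions: pd.DataFrame  # chrom, start, end, designed_delta, n_cpgs
    gene_classes: pd.DataFrame   # gene, class, true_log2fc, targeted
    global_scale: dict           # condition -> true mRNA-per-cell scale factor
    seed: int

    @property
    def sites(self) -> SiteTable:
        return self.ref.sites

    def mc_frequency(self, condition: str, include_hmc: bool = True) -> np.ndarray:
        """Per-site fraction of molecules methylated (hmC counts as mC in the
        bisulfite channel unless ``include_hmc`` is False)."""
        st = self.states[condition]
        if include_hmc:
            return np.mean(st >= STATE_MC, axis=0)
        return np.mean(st == STATE_MC, axis=0)

    def summary(self) -> dict:
        """JSON-serialisable digest (configuration + designed truth, no
        molecule matrices)."""
        return {
            "seed": self.seed,
            "n_molecules": self.n_molecules,
            "conditions": list(self.conditions),
            "params": asdict(self.params),
            "global_scale": self.global_scale,
            "target_regions": self.target_regions.to_dict(orient="list"),
            "gene_classes": self.gene_classes.to_dict(orient="list"),
            "dyads": self.dyads.to_dict(orient="list"),
            "spike_truth": self.ref.spike_truth,
        }


def context_multipliers(sites: SiteTable, table: dict) -> np.ndarray:
    """Per-site CpH rate multiplier from wildcard 5-mer patterns.

    Patterns shorter than 5 are right-aligned on (C + downstream), padded with
    'N'.  The first matching pattern wins (insertion order); unmatched sites
    get multiplier 1.
    """
    mult = np.ones(sites.n_sites)
    assigned = np.zeros(sites.n_sites, dtype=bool)
    for pat, m in table.items():
        pat = pat.upper()
        if len(pat) == 3:
            pat = "NN" + pat
        if len(pat) != 5 or pat[2] != "C":
            raise ValueError(f"context pattern {pat!r} must be 5 bp (or 3 bp) with C at the methylated position")
        rx = pat.replace("N", "?")
        hit = np.array([fnmatch.fnmatch(p, rx) for p in sites.penta]) & ~assigned
        mult[hit] = m
        assigned |= hit
    return mult


def phased_dyads(ref: ReferenceSet, params: KineticParams, n_per_side: int | None = None) -> pd.DataFrame:
    """Nucleosome dyads phased symmetrically around each motif site.

    The bound motif sits in a linker; the first dyads are half a repeat length
    away on either side, then every ``nucleosome_spacing`` bp out to the motif
    influence radius.
    """
    if n_per_side is None:
        n_per_side = max(1, int(np.ceil(params.gain_radius / params.nucleosome_spacing)) + 1)
    rows = []
    for _, m in ref.motif_centers().iterrows():
        for k in range(n_per_side):
            off = int(round(params.nucleosome_spacing * (k + 0.5)))
            rows.append((m.chrom, int(m.center - off)))
            rows.append((m.chrom, int(m.center + off)))
    return pd.DataFrame(rows, columns=["chrom", "pos"]).drop_duplicates().sort_values(
        ["chrom", "pos"], ignore_index=True)


def _site_gain_probability(ref: ReferenceSet, params: KineticParams,
                           dyads: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(per-site deposition probability, per-site protection multiplier)."""
    sites = ref.sites
    exposure = np.zeros(sites.n_sites)
    centers = ref.motif_centers()
    for ci, name in enumerate(sites.chrom_names):
        mask = sites.chrom_index == ci
        if not mask.any():
            continue
        sub = centers.loc[centers["chrom"] == name]
        if sub.empty:
            continue
        pos = sites.pos[mask]
        expo = np.zeros(pos.size)
        for c, a in zip(sub["center"], sub["affinity"]):
            expo = np.maximum(expo, a * (np.abs(pos - c) <= params.gain_radius))
        exposure[mask] = expo
    exposure[sites.is_spike] = 0.0

    prot = np.ones(sites.n_sites)
    half = params.nucleosome_footprint // 2
    for ci, name in enumerate(sites.chrom_names):
        mask = sites.chrom_index == ci
        d = dyads.loc[dyads["chrom"] == name, "pos"].to_numpy()
        if not mask.any() or d.size == 0:
            continue
        pos = sites.pos[mask]
        d = np.sort(d)
        j = np.searchsorted(d, pos)
        dist = np.full(pos.size, np.iinfo(np.int64).max, dtype=np.int64)
        left_ok = j > 0
        dist[left_ok] = np.abs(pos[left_ok] - d[j[left_ok] - 1])
        right_ok = j < d.size
        dist[right_ok] = np.minimum(dist[right_ok], np.abs(pos[right_ok] - d[j[right_ok]]))
        prot_mask = np.zeros(sites.n_sites, dtype=bool)
        prot_mask[np.flatnonzero(mask)[dist <= half]] = True
        prot[prot_mask] = params.nucleosome_protection

    mult = context_multipliers(sites, params.ch_context_multiplier)
    base_rate = np.where(sites.is_cg, params.p_gain_cg,
                         np.minimum(1.0, params.p_gain_ch_base * mult))
    return np.clip(base_rate * exposure * prot, 0.0, 1.0), prot


def _baseline_probability(sites: SiteTable, params: KineticParams) -> np.ndarray:
    p = np.where(sites.is_cg,
                 np.where(sites.in_cgi, params.cgi_mcg, params.baseline_mcg),
                 params.baseline_mch)
    p = p.copy()
    p[sites.is_spike] = 0.0
    return p


def _spike_states(sites: SiteTable, ref: ReferenceSet, state: np.ndarray) -> None:
    """Overwrite spike-contig sites with their fixed truth (in place)."""
    for name, truth in ref.spike_truth.items():
        ci = sites.chrom_names.index(name)
        mask = sites.chrom_index == ci
        state[:, mask] = STATE_HMC if truth == "hydroxymethylated" else STATE_U


def _divide(state: np.ndarray, params: KineticParams, rng: np.random.Generator,
            frozen: np.ndarray) -> None:
    """One cell division, in place.  ``frozen`` sites (spikes) never change."""
    flat = state.ravel()
    nz = np.flatnonzero(flat)
    nz = nz[~frozen.ravel()[nz]]
    if nz.size == 0:
        return
    vals = flat[nz]
    u = rng.random(nz.size)
    is_h = vals == STATE_HMC
    is_m = vals == STATE_MC
    new = np.empty_like(vals)
    new[is_h] = STATE_U  # hmC resolves after one division
    ox = is_m & (u < params.k_tet)
    keep = is_m & ~ox & (rng.random(nz.size) < params.p_maintain)
    new[is_m] = STATE_U
    new[ox] = STATE_HMC
    new[keep] = STATE_MC
    flat[nz] = new


def simulate_methylomes(
    ref: ReferenceSet,
    params: KineticParams | None = None,
    conditions=CONDITIONS,
    n_molecules: int = 100,
    seed: int = 0,
    class_mix: tuple[float, float, float] = (0.52, 0.40, 0.08),
    effect_log2fc: float = 1.5,
    global_scale: dict | None = None,
    target_half_width: int | None = None,
) -> SimulationTruth:
    """Simulate molecule-level methylomes for the requested conditions.

    ``class_mix`` gives the (repressed, insensitive, activated) probabilities
    for genes whose promoter overlaps an induced target region; all other
    genes are insensitive.  Withdrawal conditions are derived from the *same*
    Dox molecules by iterating the division kinetics.
    """
    params = params or KineticParams()
    unknown = [c for c in conditions if c not in CONDITIONS]
    if unknown:
        raise ValueError(f"unknown condition label(s) {unknown}; expected subset of {CONDITIONS}")
    if n_molecules < 2:
        raise ValueError("n_molecules must be >= 2")

    sites = ref.sites
    ss = np.random.SeedSequence(seed)
    children = {name: np.random.default_rng(s)
                for name, s in zip(("base", "gain", "wd", "genes"), ss.spawn(4))}

    dyads = phased_dyads(ref, params)
    p_gain, _prot = _site_gain_probability(ref, params, dyads)
    p_base = _baseline_probability(sites, params)
    frozen = np.broadcast_to(sites.is_spike, (n_molecules, sites.n_sites))

    states: dict[str, np.ndarray] = {}
    need_dox = any(c in ("Dox", "DoxWD-3d", "DoxWD-7d") for c in conditions)

    for cond in ("noDox", "Dox-mut"):
        if cond in conditions:
            st = (children["base"].random((n_molecules, sites.n_sites)) < p_base).astype(np.uint8)
            _spike_states(sites, ref, st)
            states[cond] = st

    if need_dox:
        rng_g = children["gain"]
        dox = (rng_g.random((n_molecules, sites.n_sites)) < p_base).astype(np.uint8)
        gained = rng_g.random((n_molecules, sites.n_sites)) < p_gain
        dox = np.maximum(dox, gained.astype(np.uint8))
        _spike_states(sites, ref, dox)
        if "Dox" in conditions:
            states["Dox"] = dox
        rng_w = children["wd"]
        for cond, days in _WITHDRAWAL_DAYS.items():
            if cond not in conditions:
                continue
            d = int(round(days * params.divisions_per_day))
            st = dox.copy()
            for _ in range(d):
                _divide(st, params, rng_w, frozen)
            _spike_states(sites, ref, st)
            states[cond] = st

    # --- designed target regions: the full motif influence footprint,
    # overlapping footprints merged (nearby motifs act as one region)
    half = target_half_width if target_half_width is not None else params.gain_radius
    centers = ref.motif_centers()
    cg_plus = sites.is_cg & (sites.strand == "+")
    t_rows = []
    for chrom, grp in centers.groupby("chrom", sort=True):
        from .._utils import merge_intervals

        chrom_len = ref.chrom_lengths[chrom]
        starts, ends = merge_intervals(
            np.clip(grp["center"].to_numpy() - half, 0, chrom_len),
            np.clip(grp["center"].to_numpy() + half, 0, chrom_len))
        ci = sites.chrom_names.index(chrom)
        on_chrom = sites.chrom_index == ci
        for lo, hi in zip(starts, ends):
            in_reg = on_chrom & (sites.pos >= lo) & (sites.pos < hi)
            reg_cg = in_reg & sites.is_cg
            if not np.any(reg_cg):
                t_rows.append((chrom, int(lo), int(hi), 0.0, 0))
                continue
            site_delta = p_gain * (1.0 - p_base)
            # the designed DMR is the span of CpGs with a substantial
            # per-site expected difference, not the whole influence radius
            strong = reg_cg & (site_delta >= 0.2)
            if np.any(strong):
                # contiguous clusters of strongly affected CpGs are the
                # designed DMRs; clusters closer than ~1 kb (a window plus a
                # merge gap at the default analysis scale) act as one region
                sidx = np.flatnonzero(strong)
                spos = sites.pos[sidx]
                breaks = np.flatnonzero(np.diff(spos) > 1000)
                c_starts = np.concatenate([[0], breaks + 1])
                c_ends = np.concatenate([breaks + 1, [spos.size]])
                for a, b in zip(c_starts, c_ends):
                    sel = sidx[a:b]
                    designed = float(np.mean(site_delta[sel]))
                    n_cpg_units = int(np.sum(cg_plus[sel]))
                    t_rows.append((chrom, int(spos[a]), int(spos[b - 1]) + 2,
                                   designed, n_cpg_units))
            else:
                designed = float(np.mean(site_delta[reg_cg]))
                n_cpg_units = int(np.sum(reg_cg & cg_plus))
                t_rows.append((chrom, int(lo), int(hi), designed, n_cpg_units))
    target_regions = pd.DataFrame(
        t_rows, columns=["chrom", "start", "end", "designed_delta", "n_cpgs"]
    ).sort_values(["chrom", "start"], ignore_index=True)

    # --- gene response classes tied to promoter methylation truth
    rng_gene = children["genes"]
    classes, lfcs, targeted_flags = [], [], []
    tr_by_chrom = {c: g[["start", "end", "designed_delta"]].to_numpy()
                   for c, g in target_regions.groupby("chrom")}
    for _, t in ref.tss.iterrows():
        if t.strand == "+":
            win = (t.pos - 2000, t.pos + 200)
        else:
            win = (t.pos - 200, t.pos + 2000)
        regs = tr_by_chrom.get(t.chrom)
        targeted = regs is not None and bool(
            np.any((regs[:, 0] < win[1]) & (regs[:, 1] > win[0]) & (regs[:, 2] >= 0.1))
        )
        if targeted:
            cls = ("repressed", "insensitive", "activated")[
                int(rng_gene.choice(3, p=np.asarray(class_mix) / np.sum(class_mix)))
            ]
        else:
            cls = "insensitive"
        lfc = {"repressed": -effect_log2fc, "insensitive": 0.0, "activated": effect_log2fc}[cls]
        classes.append(cls)
        lfcs.append(lfc)
        targeted_flags.append(targeted)
    gene_classes = ref.tss[["gene", "chrom", "pos", "strand"]].copy()
    gene_classes["class"] = classes
    gene_classes["true_log2fc"] = lfcs
    gene_classes["targeted"] = targeted_flags

    return SimulationTruth(
        ref=ref,
        params=params,
        conditions=list(conditions),
        n_molecules=n_molecules,
        states=states,
        dyads=dyads,
        target_regions=target_regions,
        gene_classes=gene_classes,
        global_scale=global_scale or {c: 1.0 for c in conditions},
        seed=seed,
    )
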