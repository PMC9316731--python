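"""Synthetic reference genome with planted regulatory features.

The emitted genome is a miniature caricature of a mammalian methylome
substrate: a CpG-depleted background, CpG-island (CGI) promoters, a planted
zinc-finger consensus motif (exact or degenerate copies, promoter-proximal
and distal), and spike-in contigs carrying known methylation truth — an
unmethylated lambda-like contig for non-conversion estimation and a fully
hydroxymethylated pUC19-like contig for the hmC protection control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

MOTIF_CONSENSUS = "CCCTCCTCCCCC"

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReferenceConfig:
    """Sizes and feature counts for :func:`simulate_reference`."""

    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 60_000, "chr2": 40_000})
    n_tss: int = 24
    n_cgi: int = 24
    n_motif_sites: int = 30
    cgi_len: int = 600
    promoter_motif_frac: float = 0.5  # fraction of motifs planted in CGI promoters
    degenerate_frac: float = 0.2      # fraction of motifs carrying one mismatch
    lambda_spike_len: int = 4_000
    puc19_spike_len: int = 2_000
    min_feature_gap: int = 400
    distal_margin: int = 2_500        # distal motifs at least this far from any TSS


@dataclass
class SiteTable:
    """All cytosine sites of a reference, both strands, flattened.

    Arrays are aligned; sites are sorted by (chromosome, position).  ``penta``
    is the strand-oriented 5-mer centered on the cytosine (reverse-complemented
    for minus-strand sites), ``tri`` its last three bases (C + 2 downstream).
    """

    chrom_names: list
    chrom_index: np.ndarray  # int per site
    pos: np.ndarray
    strand: np.ndarray       # '+' / '-'
    context: np.ndarray      # 'CG' / 'CHG' / 'CHH'
    penta: np.ndarray        # '<U5'
    in_cgi: np.ndarray       # bool
    is_spike: np.ndarray     # bool

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @cached_property
    def tri(self) -> np.ndarray:
        return np.array([p[2:] for p in self.penta])

    @cached_property
    def is_cg(self) -> np.ndarray:
        return self.context == "CG"

    def chrom_of(self) -> np.ndarray:
        return np.array(self.chrom_names, dtype=object)[self.chrom_index]

    @cached_property
    def by_chrom(self) -> dict:
        """chrom -> (positions ascending, global site indices)."""
        out = {}
        for ci, name in enumerate(self.chrom_names):
            idx = np.flatnonzero(self.chrom_index == ci)
            out[name] = (self.pos[idx], idx)
        return out


@dataclass
class ReferenceSet:
    """Reference sequences plus planted feature annotations."""

    sequences: dict           # main chromosomes, name -> str
    spike_sequences: dict     # spike contigs, name -> str
    spike_truth: dict         # spike name -> 'unmethylated' | 'hydroxymethylated'
    tss: pd.DataFrame         # chrom, pos, strand, gene
    cgi: pd.DataFrame         # chrom, start, end
    motif_sites: pd.DataFrame  # chrom, start, strand, affinity, exact
    config: ReferenceConfig
    seed: int

    @property
    def chrom_lengths(self) -> dict:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def all_sequences(self) -> dict:
        return {**self.sequences, **self.spike_sequences}

    @property
    def main_genome_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @cached_property
    def sites(self) -> SiteTable:
        return _build_site_table(self)

    def motif_centers(self) -> pd.DataFrame:
        half = len(MOTIF_CONSENSUS) // 2
        df = self.motif_sites.copy()
        df["center"] = df["start"] + half
        return df


def _random_seq(rng: np.random.Generator, n: int, probs) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def _deplete_cpg(seq: np.ndarray, rng: np.random.Generator, keep: float = 0.15) -> None:
    """Mutate the G of most CpG dinucleotides in place (background depletion)."""
    is_c = seq[:-1] == b"C"
    is_g = seq[1:] == b"G"
    cg = np.flatnonzero(is_c & is_g)
    kill = cg[rng.random(cg.size) > keep] + 1
    seq[kill] = rng.choice(np.frombuffer(b"AT", dtype="S1"), size=kill.size)


def _cgi_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    """GC-rich, CpG-retaining island sequence."""
    return _random_seq(rng, n, [0.15, 0.35, 0.35, 0.15])


def simulate_reference(config: ReferenceConfig | None = None, seed: int = 0, **overrides) -> ReferenceSet:
    """Generate a seeded reference genome with planted features.

    Any :class:`ReferenceConfig` field may be overridden by keyword.  Raises
    ``ValueError`` naming the violated constraint when the requested features
    cannot be packed into the genome.
    """
    cfg = config or ReferenceConfig()
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown reference option {k!r}")
        setattr(cfg, k, v)
    for name, length in cfg.chrom_sizes.items():
        if length < 10_000:
            raise ValueError(f"chromosome {name} shorter than 10 kb ({length})")

    total = sum(cfg.chrom_sizes.values())
    if cfg.n_cgi * (cfg.cgi_len + cfg.min_feature_gap) > 0.6 * total:
        raise ValueError(
            f"infeasible packing: {cfg.n_cgi} CGIs of {cfg.cgi_len} bp exceed 60% of the {total} bp genome"
        )

    rng = np.random.default_rng(seed)
    chrom_names = list(cfg.chrom_sizes)
    seqs = {
        name: _random_seq(rng, cfg.chrom_sizes[name], [0.3, 0.2, 0.2, 0.3])
        for name in chrom_names
    }
    for s in seqs.values():
        _deplete_cpg(s, rng)

    # --- CGIs: spread proportionally to chromosome length, non-overlapping
    cgi_rows = []
    quota = _proportional_quota(cfg.n_cgi, cfg.chrom_sizes)
    for name, k in quota.items():
        L = cfg.chrom_sizes[name]
        starts = _place_nonoverlapping(rng, k, cfg.cgi_len, L, cfg.min_feature_gap)
        if starts is None:
            raise ValueError(f"infeasible packing: cannot place {k} CGIs on {name} ({L} bp)")
        for s0 in starts:
            seqs[name][s0:s0 + cfg.cgi_len] = _cgi_seq(rng, cfg.cgi_len)
            cgi_rows.append((name, int(s0), int(s0 + cfg.cgi_len)))
    cgi = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True)

    # --- TSSs: CGI promoters first, surplus TSSs in background
    tss_rows = []
    cgi_shuffled = cgi.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    n_cgi_tss = min(cfg.n_tss, len(cgi_shuffled))
    for i in range(n_cgi_tss):
        row = cgi_shuffled.iloc[i]
        strand = "+" if rng.random() < 0.5 else "-"
        pos = int(row.start + cfg.cgi_len // 3) if strand == "+" else int(row.end - cfg.cgi_len // 3)
        tss_rows.append((row.chrom, pos, strand, f"gene{i + 1:04d}"))
    for i in range(n_cgi_tss, cfg.n_tss):
        name = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(2_000, cfg.chrom_sizes[name] - 2_000))
        strand = "+" if rng.random() < 0.5 else "-"
        tss_rows.append((name, pos, strand, f"gene{i + 1:04d}"))
    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "gene"]).sort_values(
        ["chrom", "pos"], ignore_index=True)

    # --- motif sites: promoter-proximal and distal
    motif = np.frombuffer(MOTIF_CONSENSUS.encode(), dtype="S1")
    mlen = len(MOTIF_CONSENSUS)
    n_prom = min(int(round(cfg.promoter_motif_frac * cfg.n_motif_sites)), n_cgi_tss)
    motif_rows = []
    prom_tss = tss.iloc[:n_cgi_tss].sample(frac=1.0, random_state=int(rng.integers(2**31)))
    for _, t in prom_tss.head(n_prom).iterrows():
        offset = int(rng.integers(-60, 20))
        start = int(t.pos + offset)
        motif_rows.append((t.chrom, start))
    n_distal = cfg.n_motif_sites - len(motif_rows)
    placed = _place_distal_motifs(rng, n_distal, cfg, tss, cgi, motif_rows, mlen)
    if placed is None:
        raise ValueError(
            f"infeasible packing: cannot place {n_distal} distal motif sites "
            f">= {cfg.distal_margin} bp from every TSS"
        )
    motif_rows.extend(placed)

    out_rows = []
    for chrom, start in motif_rows:
        strand = "+" if rng.random() < 0.5 else "-"
        exact = rng.random() >= cfg.degenerate_frac
        planted = motif.copy()
        if not exact:
            j = int(rng.integers(mlen))
            alts = [b for b in (b"A", b"C", b"G", b"T") if b != bytes(planted[j])]
            planted[j] = alts[int(rng.integers(3))]
        if strand == "-":
            planted = np.frombuffer(revcomp(planted.tobytes().decode()).encode(), dtype="S1")
        seqs[chrom][start:start + mlen] = planted
        out_rows.append((chrom, int(start), strand, 1.0 if exact else 0.6, bool(exact)))
    motif_sites = pd.DataFrame(
        out_rows, columns=["chrom", "start", "strand", "affinity", "exact"]
    ).sort_values(["chrom", "start"], ignore_index=True)

    # --- spike contigs (uniform base composition, CpGs retained)
    spike_seqs = {
        "lambda_spike": _random_seq(rng, cfg.lambda_spike_len, [0.25, 0.25, 0.25, 0.25]),
        "pUC19_hmC_spike": _random_seq(rng, cfg.puc19_spike_len, [0.25, 0.25, 0.25, 0.25]),
    }
    spike_truth = {"lambda_spike": "unmethylated", "pUC19_hmC_spike": "hydroxymethylated"}

    return ReferenceSet(
        sequences={k: v.tobytes().decode() for k, v in seqs.items()},
        spike_sequences={k: v.tobytes().decode() for k, v in spike_seqs.items()},
        spike_truth=spike_truth,
        tss=tss,
        cgi=cgi,
        motif_sites=motif_sites,
        config=cfg,
        seed=seed,
    )


def _proportional_quota(n: int, sizes: dict) -> dict:
    total = sum(sizes.values())
    quota = {k: int(n * v / total) for k, v in sizes.items()}
    names = list(sizes)
    i = 0
    while sum(quota.values()) < n:
        quota[names[i % len(names)]] += 1
        i += 1
    return quota


def _place_nonoverlapping(rng, k, feat_len, chrom_len, gap):
    """k random non-overlapping starts, or None when infeasible."""
    slot = feat_len + gap
    usable = chrom_len - 2 * gap
    if k * slot > usable or k < 0:
        return None
    if k == 0:
        return []
    # sample-in-reduced-space trick: choose starts in a genome shrunk by the
    # space the features themselves occupy, then re-expand
    free = usable - k * slot
    cuts = np.sort(rng.integers(0, free + 1, size=k))
    return gap + cuts + slot * np.arange(k)


def _place_distal_motifs(rng, n, cfg, tss, cgi, taken, mlen, max_tries=20_000):
    placed = []
    chrom_names = list(cfg.chrom_sizes)
    tss_by_chrom = {c: g["pos"].to_numpy() for c, g in tss.groupby("chrom")}
    cgi_by_chrom = {c: g[["start", "end"]].to_numpy() for c, g in cgi.groupby("chrom")}
    tries = 0
    while len(placed) < n and tries < max_tries:
        tries += 1
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        start = int(rng.integers(500, cfg.chrom_sizes[chrom] - 500 - mlen))
        t = tss_by_chrom.get(chrom, np.array([]))
        if t.size and np.min(np.abs(t - start)) < cfg.distal_margin:
            continue
        g = cgi_by_chrom.get(chrom)
        if g is not None and np.any((start < g[:, 1] + 50) & (start + mlen > g[:, 0] - 50)):
            continue
        if any(c == chrom and abs(s - start) < 300 for c, s in taken + placed):
            continue
        placed.append((chrom, start))
    return placed if len(placed) == n else None


def _build_site_table(ref: ReferenceSet) -> SiteTable:
    chrom_names = list(ref.sequences) + list(ref.spike_sequences)
    spike_set = set(ref.spike_sequences)
    cgi_by_chrom = {c: g[["start", "end"]].to_numpy() for c, g in ref.cgi.groupby("chrom")}

    all_ci, all_pos, all_strand, all_ctx, all_penta, all_cgi, all_spike = ([] for _ in range(7))
    for ci, name in enumerate(chrom_names):
        seq = np.frombuffer(ref.all_sequences[name].encode(), dtype="S1")
        n = len(seq)
        interior = np.zeros(n, dtype=bool)
        interior[2:n - 2] = True
        plus = np.flatnonzero((seq == b"C") & interior)
        minus = np.flatnonzero((seq == b"G") & interior)

        def penta_of(idx, is_minus):
            stack = np.stack([seq[idx + o] for o in (-2, -1, 0, 1, 2)], axis=1)
            mers = stack.view("S5").ravel().astype("U5")
            if is_minus:
                mers = np.array([revcomp(m) for m in mers])
            return mers

        for idx, strand in ((plus, "+"), (minus, "-")):
            if idx.size == 0:
                continue
            p5 = penta_of(idx, strand == "-")
            nxt1 = np.array([m[3] for m in p5])
            nxt2 = np.array([m[4] for m in p5])
            ctx = np.where(nxt1 == "G", "CG", np.where(nxt2 == "G", "CHG", "CHH"))
            in_cgi = np.zeros(idx.size, dtype=bool)
            g = cgi_by_chrom.get(name)
            if g is not None:
                for s0, e0 in g:
                    in_cgi |= (idx >= s0) & (idx < e0)
            all_ci.append(np.full(idx.size, ci))
            all_pos.append(idx)
            all_strand.append(np.full(idx.size, strand))
            all_ctx.append(ctx)
            all_penta.append(p5)
            all_cgi.append(in_cgi)
            all_spike.append(np.full(idx.size, name in spike_set))

    chrom_index = np.concatenate(all_ci)
    pos = np.concatenate(all_pos)
    order = np.lexsort((pos, chrom_index))
    return SiteTable(
        chrom_names=chrom_names,
        chrom_index=chrom_index[order],
        pos=pos[order].astype(np.int64),
        strand=np.concatenate(all_strand)[order],
        context=np.concatenate(all_ctx)[order],
        penta=np.concatenate(all_penta)[order],
        in_cgi=np.concatenate(all_cgi)[order],
        is_spike=np.concatenate(all_spike)[order],
    )
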