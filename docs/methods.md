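# Methods

This note documents the models, rules and numerical choices behind
methylforge, and what the synthetic experiments do and do not establish
about real data.

## The experimental design being modelled

An inducible zinc-finger–DNMT3A fusion binds a 12-bp consensus
(`CCCTCCTCCCCC`) and its degenerate variants, depositing mCG and mCH around
its binding sites. Conditions follow the standard induction/withdrawal
design: `noDox` (uninduced baseline), `Dox` (induced), `DoxWD-3d` /
`DoxWD-7d` (3 and 7 days after withdrawal) and `Dox-mut` (catalytically dead
control, modelled as distributionally identical to baseline methylation).
The assays consumed are WGBS methylation calls (CGmap or bedGraph+counts
dialects), per-read CpG call records, TAB-seq hmC calls, gene × sample
RNA-seq counts with ERCC spike rows, and BED interval sets.

## Synthetic reference and methylome model

**Reference.** Chromosomes are CpG-depleted random sequence (a fraction of
CpG dinucleotides is destroyed by mutating the G) with GC-rich, CpG-retaining
islands overwritten at sampled positions; island CpG density exceeds
background by well over an order of magnitude, which also means island CpGs
dominate any site-weighted global average on this miniature genome. TSSs sit
inside islands (CGI promoters) with any surplus in background; motif copies
are planted verbatim (affinity 1.0) or with one mismatch (affinity 0.6),
partly in promoters and partly ≥ 2.5 kb from any TSS. Two spike contigs
carry fixed truth: a lambda-like contig is fully unmethylated (non-conversion
control) and a pUC19-like contig fully hydroxymethylated (TAB-seq protection
control). Feature packing is checked and an explicit error names the
violated constraint.

**Deposition.** Each condition holds `n_molecules` whole-genome molecules;
every cytosine of every molecule is unmethylated, mC or hmC. Baseline: CpGs
methylated with probability 0.8 outside islands and 0.01 inside; CpH
baseline 0.002. Induced gain at a site is
`base_rate × exposure × protection`, where `base_rate` is `p_gain_cg` (0.7)
for CpG or `p_gain_ch_base` (0.02) times a context multiplier for CpH
(default 5× for 5-mers matching `TNCAC`, the TxCAC class of native DNMT3A);
`exposure` is the maximum motif affinity within `gain_radius` (1 kb, flat
kernel); and `protection` is `nucleosome_protection` (0.25) within ± 73 bp
of a dyad, 1 outside. Dyads are a phased array at ± spacing·(k+½) around
each motif centre (spacing 190 bp, 147 bp footprint).  Binding displaces
nucleosomes, but no kinetic model of the displacement is available, so the
post-binding phased state is simulated directly.

**Withdrawal kinetics.** Per division, an mC site is oxidised to hmC with
probability `k_tet` (0.02), otherwise retained with `p_maintain` (0.8),
otherwise lost; hmC resolves to unmethylated on the following division.
Withdrawal days map to divisions via `divisions_per_day` (1.0 — the cell
line's division rate is not stated anywhere authoritative, so this is a free
parameter). With `k_tet = 0` the expected mCG frequency after d divisions
is exactly m₀·p_maintainᵈ; the test suite verifies this closed form within
3 binomial SE across a (m₀, p, d) grid. Withdrawal states are derived from
the *same* Dox molecules, so no de novo deposition can appear after
withdrawal.

**Designed DMR truth.** The designed target regions are contiguous clusters
(split at > 1 kb gaps, matching the window-plus-merge-gap scale of the
default analysis) of CpGs whose expected per-site gain
`p_gain × (1 − baseline)` is ≥ 0.2, with the cluster's mean expected gain
recorded as `designed_delta`. Gene response classes (repressed /
insensitive / activated, default mix 0.52/0.40/0.08 with |log2FC| = 1.5)
are drawn for genes whose promoter (−2000/+200, strand-aware) overlaps a
designed region; all other genes are insensitive.

**Read emission.** Reads are pre-aligned per-molecule call records — there
is no FASTQ or alignment layer, and no sequencing error beyond bisulfite
non-conversion: an unconverted cytosine reads as methylated with probability
`epsilon_nonconv` (0.005). Fragments (150 bp) may overhang contig ends and
are clipped, making expected coverage uniform at the requested depth. In
the WGBS channel mC and hmC both read methylated; in the TAB channel only
hmC does. Spike contigs are sequenced at the coverage implied by their mass
fraction of the library (0.5% w/w default). Aggregate call tables are exact
tallies over the emitted reads (the suite asserts byte-exact conservation
against a per-read recount). Sequencing replicates are independent fragment
and molecule draws from the same population.

**Expression counts.** Negative-binomial counts with per-gene log-normal
base means, gene means scaled by 2^log2FC in Dox and by a per-condition
global mRNA scale; 92 `ERCC-` rows with log-uniform abundances over four
orders of magnitude are fixed in expectation across conditions (a fixed
absolute amount per cell), which is what makes their library fraction a
global-shift detector.

## Analysis stages: definitions and numerical choices

**Coordinates.** 0-based half-open internally everywhere; CGmap's 1-based
positions are converted only at the I/O boundary.

**Weighted methylation** is Σm/Σt over sites with coverage ≥ `min_coverage`
(default 1); an uncovered region is NaN ("no data"), never 0. Strand
collapsing maps a − strand CG call at p to the unit at p−1 and sums counts;
totals are conserved exactly.

**Per-read classes.** The thresholds separating "full / intermediate /
lack" classes have no standard definition; the default is the strictest reading (f = 0 / f = 1) with
configurable bins. The 80% overlap rule divides by the *read* length
("80% of their sequence" refers to the read). Merged read pairs are one
record; every read derives from exactly one molecule.

**DMR detection (stand-in).** dmrseq's transformed-coefficient GLS model is
deliberately not reproduced. Candidate windows (≤ 500 bp, ≥ 5 CpGs, tiled
at half-window steps within max-gap-delimited CpG segments) are scored by
the difference of pooled weighted mCG; windows with |Δ| ≥ 0.1 merge into
same-sign regions, whose edges are then grown over adjacent sign-consistent
CpGs and trimmed: an edge CpG anchors the boundary only if at least one of
its two inward neighbours also carries signal, which stops isolated noisy
flank CpGs from freezing the trim. The permutation null pools **all** window
statistics under every balanced replicate-label permutation across the whole
genome — with 2 + 2 replicates a per-region permutation has only three
distinct relabelings and could never reach p < 0.05; genome-wide pooling is
the same resolution device dmrseq uses. p = (1 + #{null ≥ |Δ|})/(1 + N),
BH-adjusted. Defaults mirror the dmrseq settings this detector stands in
for (bpSpan 500, maxGap 500, 20 permutations, ≥ 2 replicates).

**Downstream DMR rules** are implemented verbatim (q < 0.05 and |Δ| ≥ 20%;
promoter subset q < 0.01 over −2000/+200, with a −2000/+500 variant
available by argument since both windows are in common use; retention
thresholds as in the README). The strict retention rule (with the 2×
condition) is the default; the looser variant without it is a caller
choice. The UMR caller is a simplified stand-in (maximal runs of
≥ 10 consecutive CpGs at ≤ 10% mCG), not a segmentation model. The overlap
permutation test re-places regions uniformly per chromosome with lengths
preserved and no exclusion masks; with 100 permutations its p floor is
1/101 ≈ 0.0099.

**Periodicity.** The profile channel for period estimation is methylation
*gain* (Dox − noDox), since absolute levels carry the island/background
structure. The profile is detrended by subtracting a moving average whose
window is the largest candidate period; power at period P is the squared
modulus of the discrete Fourier sum at 1/P over bin centres, maximised over
120–300 bp. The permutation p-value shuffles the *raw* profile and re-applies
detrending plus the power statistic, so the null inherits the filter's
spectral response — permuting only the detrended values is anti-conservative
(the filter's gain exceeds 1 inside the candidate band). Phase is the cosine
peak nearest the anchor. CpH context enrichment is the context's pooled
level over the pooled level of all contexts in the supplied calls, so the
coverage-weighted mean enrichment is 1 by construction; because exposure and
base composition correlate on a genome with GC-rich islands, the designed
multiplier is recovered cleanly when the calls are restricted to the
motif-proximal windows the question is about.

**Expression.** Size factors are median-of-ratios; the estimation basis is
selectable (genes / spikes / all). With a large, asymmetric responding
fraction the gene basis is intrinsically biased (the median ratio no longer
sits on unchanged genes — DESeq2 shares this), and the spike basis is the
principled anchor exactly because spike amounts are fixed per cell; the
validation scenarios with ≥ 50% responding genes therefore normalize on
spikes. The low-count filter keeps genes expressed (> 0) in at least half
the samples — a fixed-sample-count filter rescaled proportionally so it
ports across designs.
The DE test is a labelled stand-in (equal-variance t on log2(normalized+1),
BH); "> 50 normalized counts in any given condition" is read as the
condition-mean, with the per-replicate reading available through the same
columns. The trend smoother is lowess (tricube local linear, span 0.75).

**Chromatin.** Bulk-vs-IP peak methylation uses a paired two-sided signed
rank over peaks covered in both sets (all-zero differences short-circuit to
p = 1); a one-sided rank-sum is available for cross-condition contrasts,
Differential accessibility is the same
normalization + t + BH stand-in. hmC contrasts are one-sided Welch t tests
on per-region weighted hmC; zero-variance contrasts are flagged NaN rather
than invented.

## Problem sizes and what the tests establish

The validation suite runs miniature experiments — 100 kb genomes, 100–200
molecules, 30× coverage, 2 replicates for methylation and 4 for expression,
50–200 seeds for the calibration loops — sizes chosen so the entire suite
completes in about a minute while every estimate retains enough events for
3-SE comparisons. Passing establishes internal correctness and calibration
of the implementations on data generated by this package's own forward
models: exact oracle agreement for the counting operations, type-I control
and ≥ 90% recall for the DMR stand-in under its stated signal regime
(Δ ≥ 0.4, ≥ 15 CpGs, well-separated targets on a near-saturated background),
retention-rule agreement with the analytic kinetics, period recovery within
one bin at SNR ≥ 3, spike-test calibration and power, and response-class
recovery. It does not establish that the stand-in detectors numerically
match dmrseq/MethylSeekR/DESeq2 on real data, that the kinetic
parameterisation is the true biology of any cell line, or that real bisulfite
data contain no artefacts beyond non-conversion (mapping bias, incomplete
conversion of hmC, PCR duplicates are all outside the generator).

## Known limitations

- The nucleosome model is a static phased array; no remodelling dynamics.
- Motif exposure is a flat kernel with hard radius; no occupancy kinetics.
- The simulator's read layer has no sequence errors, no mapping, no
  duplicates; "reads" are molecule excerpts.
- CH strand-specific collapsing is not implemented (CH calls pass through
  collapsing untouched).
- The DMR q-values are empirical-permutation based; with few permutations
  and few candidate windows their resolution is bounded by the null pool
  size.
- Expression fold changes apply in the Dox condition only; withdrawal
  transcriptomes are not modelled.
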