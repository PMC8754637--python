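# Methods

`upfchip` re-implements, as a tested pipeline, the computational analysis of
Upf1 and RNA polymerase II (Pol II) chromosomal association in fission
yeast: tiling-array (ChIP-chip) signal processing and enriched-gene
calling, input-normalized ChIP-seq coverage, metagene profiling,
occupancy–expression correlation, classification of genes by their
Upf1-to-Pol II signal ratio, gene-set overlap statistics, and the small
closed-form qPCR quantifications. Because the original microarray and
sequencing datasets are not bundled, every stage is driven and verified by
a synthetic-data generator that plants known structure.

## Coordinate conventions

All internal coordinates are 0-based half-open; GFF3 is converted at the
I/O boundary, BED/bedGraph pass through. The TSS is `start` on the plus
strand and `end − 1` on the minus strand; the TES is the opposite end.
Masked bases in coverage tracks are NaN and are excluded — never
zero-filled — from every downstream mean.

## ChIP-chip signal model

Per-gene signals use a simplified MAS5-style estimator. For each PM/MM
probe pair the ideal mismatch is

    IM = MM            if MM < PM
         PM / 2        otherwise,

the probe value is `log2(PM − IM)` floored at `2^-20`, and the gene signal
is `2^T` where `T` is the one-step Tukey biweight location of the probe
values (median/MAD centre, tuning constant c = 5, epsilon = 1e-4). The
single-step IM rule replaces the full Affymetrix specific-background chain
with one testable rule; it preserves the PM-corrected log-signal behaviour
but is discontinuous at PM = MM, so signal monotonicity in PM holds on
either side of that crossover, not through it.

Control (and replicate IP) array pairs are scaled so both medians equal
the mean of the two medians, then averaged gene-wise; IP signals are
divided by their control to give normalized per-gene signals. Per-probe
normalized values are PM/MM ratios divided by the mean control ratio, with
replicate IP arrays averaged probe-wise.

## Enriched-gene calling

The published analysis used the MAT probabilistic model, which requires
probe sequences we do not simulate. The caller here preserves the
downstream decision rules exactly (P cutoffs of 1e-3 and 1e-4, the ≥50%
coverage rule, score averaging over the enriched span) on a simpler,
fully specified statistic: probe scores are log normalized values
standardized genome-wide by median and MAD (MAD·1.4826, SD fallback when
MAD = 0, error when both are 0 — degenerate inputs must fail loudly); the
per-probe statistic is the 10%-trimmed mean of scores within ±window_bp/2
(default 300 bp windows), scaled by √(effective n) and referred to the
standard normal one-sided. Significant probes within maxgap_bp (300)
merge into regions; a gene is enriched when merged regions cover at least
half of its length, and its enrichment score is the mean normalized probe
value over the merged span. Because windows bleed ~window_bp/2 past a
signal boundary, partial-coverage rules are sharp only for genes long
relative to the window; the stricter cutoff always calls a subset of the
looser one.

## ChIP-seq coverage

Raw coverage counts reads (BED intervals) covering each base; depth
normalization divides by the total number of aligned reads; input
normalization divides IP by input base-wise. Bases with zero input are
masked by default (a pseudocount policy is available); replicate
averages leave a base missing when it is missing in any input, so
averaging never fabricates coverage. No smoothing is applied.

## Metagene profiles

Array profiles place each probe at the percentage through its gene of the
probe's 5′-most transcribed base, from the TSS (0%) to 24 bp upstream of
the TES (100% for 25-mers), pooled into 1000 half-open 0.1% blocks
(bin = ⌊1000·u/(L−25)⌋, 100% in the last bin — integer arithmetic, so tie
handling is exact). Coverage profiles combine a 1000 bp per-base upstream
flank, a body scaled into 1000 fractional windows with overlap-fraction
weighting, and a 1000 bp downstream flank, all in transcription
direction; flank positions clipped at chromosome edges are dropped from
the means. Each gene contributes one observation per flank base and one
per body window; bin counts record exactly the number of contributions.
Genes shorter than body_bins/10 bp are excluded; overlapping genes are
not excluded (configurable).

## Association statistics

Expression is summarized as the replicate-mean FPKM transformed by
natural `log(FPKM + 1)`. Spearman correlations use average ranks with a
two-sided t-approximation P; the "top-f expressed" filter removes genes
below the (1−f) quantile of the expression variable only. Ratio groups
use `d = log2(upf1) − log2(polII)` against thresholds (default ±1 in
log2): `high_ratio`, `low_ratio`, or `similar`; genes with both signals
below `min_signal`, or any non-positive signal, are excluded as
unclassified. In the pipeline the classifier receives occupancy
estimates `(normalized_signal − 1)/gain`, i.e. the array readout with its
unenriched baseline removed, so that the estimated ratio is commensurate
with the planted occupancy ratio.

The overlap between two gene sets is tested twice. The random-sampling
test draws |A| genes from universe A and |B| from universe B (independent
draws, matched by id — the two universes need not coincide), records the
intersection size per repetition, and reports `(r+1)/(reps+1)` where r
counts repetitions with overlap ≥ observed; the add-one estimator never
reports zero. The Fisher's-exact-style test reports the one-sided
hypergeometric upper tail `P(X ≥ k)` computed in log space, with the
universe defaulting to universe A — with the published counts
(k=47, K=420, n=543, N=7054) this reproduces the printed 0.006, and the
up/down subsets (31/384, 16/159) the printed 0.05 and 0.03.

## qPCR quantities

Relative expression is `2^−(Ct_target − Ct_reference)`; the reference
target is data, never hard-coded. Percent of input adjusts the input Ct
by `log2(1/input_fraction)` before `100·2^(adjusted − Ct_IP)`; the input
dilution is a required configuration value with no default. Signal ratios
propagate SEM to first order (`ratio·√(cv²_num + cv²_den)`). Decay
profiles divide by the t0 value and fit `ln(relative)` against time by
least squares, `t½ = ln2/|slope|`, with a non-decaying series flagged
infinite. The t-test is the pooled-variance Student test, one-tailed
(Welch available by flag); identical zero-variance groups give p = 0.5 by
convention.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the sequences: no FASTA, mappability, or PCR duplicates.

* **Annotation** — non-overlapping genes, log-normal lengths (median
  1500 bp, σ = 0.5, clipped to [300, 8000] — fission-yeast-like), ≥200 bp
  intergenic gaps with exponential excess (mean 300 bp), Bernoulli(½)
  strands, laid out round-robin over chromosomes.
* **Occupancy** — latent transcription rate τ ~ log-normal(0, 1); Pol II
  occupancy equals τ. The bound subset is the top `frac_bound` (default
  0.3) of genes by τ: Upf1 recruitment is modelled as co-transcriptional,
  so unbound genes are the weakly transcribed ones. Bound genes get
  `upf1 = τ^β · e^ε` (β = 1); unbound genes sit strictly below a recorded
  background occupancy (0.05). Two noise modes: a fixed `sigma_eps`
  (default 0.3, chosen for testability — the underlying studies report no
  noise magnitudes), or, when `rho_target` is given, σ solved by Brent's
  method so the realized Spearman(upf1, polII) over all genes matches the
  target (the solved σ and realized ρ are recorded). The modes are
  separate because matching the genome-wide ρ ≈ 0.56 requires σ ≈ 3 —
  an occupancy spread of ~e^±6 under which a sizeable fraction of bound
  genes is genuinely undetectable by any caller; detection-recovery
  studies therefore use the fixed moderate noise, correlation-recovery
  studies the calibrated mode.
* **Probe arrays** — probes tile genes and gaps every 20 bp (platform-like
  density for 25-mer tiling). `PM = B·e^η·(1 + g·occ_local)`,
  `MM = B·κ·e^η′` with B = 100, κ = 0.7 cross-hybridization, g = 5 gain,
  σ_η = 0.3; occ_local is the gene occupancy smoothed by a 500 bp moving
  average across gene boundaries (fragment-size spreading). The
  multiplicative link keeps log-scale noise homoscedastic. Control arrays
  use occ_local = 0 with independent noise. The simulated experiment
  mirrors the original array design: one usable Upf1 IP array plus a
  control pair, and a Pol II IP pair plus a control pair, with pairs
  median-scaled and averaged.
* **ChIP-seq** — fragment midpoints ∝ occupancy + floor (uniform for
  input), lengths ~ Normal(500, 100) truncated at the read length, one
  50 bp read per fragment from its 5′ end on a random strand;
  out-of-bounds fragments are resampled with a retry cap.
* **Expression / DE labels** — `FPKM_rep = fpkm_true·e^ε` with
  `fpkm_true ∝ τ`; DE labels plant an exact overlap with the bound set and
  an up/down split, so the overlap test's inputs have known truth.

All generators are pure functions of (seed, parameters); a root seed
derives fixed per-component child seeds, recorded in the run manifest.
What the generator does **not** emulate: probe-sequence affinity (hence
MAT itself is out of scope), mappability and repeat artifacts, antisense
transcription, and any wild-type vs deletion-strain redistribution of
Pol II — passing recovery tests shows the pipeline's rules are
implemented correctly under the stated noise model, not that they would
behave identically on real arrays.

## Problem sizes and numerical choices

Recovery studies run at 500 genes (enrichment and classification) and
5000 genes (correlation calibration); the oracle comparisons use 20
random configurations at 10⁴ repetitions for the permutation test and
exhaustive enumeration for all universes N ≤ 30. Brentq tolerance for the
σ solve is 1e-4; the probe-value log floor is 2^-20; robust z uses
MAD·1.4826 with SD fallback. Ties in percent-position binning are
resolved by integer arithmetic; the permutation P uses the add-one
estimator. These sizes were chosen so every study is comfortably
reproducible on a single CPU.

## Known limitations

The enriched-gene caller is a documented stand-in for MAT: cutoffs are
not numerically comparable to MAT P-values, only the downstream rules
are. The ≥50% rule is measured in bp of gene length (the alternative —
probe count — is not implemented). The published genome-scale counts
(594/696 enriched genes, ρ = 0.56/0.58 and 0.38/0.42, group sizes
587/124/4177) depend on the deposited datasets and are represented here
only through the property-based recovery studies above. Amplification
efficiency correction and quantile normalization across arrays are out
of scope.
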