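# Methods

## Coordinate and data conventions

All coordinates are 0-based half-open in transcript space, uniformly across
modules. A transcript is 5′UTR | CDS | 3′UTR with the CDS starting at its
AUG and ending one past the stop codon; CDS length is a multiple of 3.
Footprint tracks hold one integer count per nucleotide: each read is
assigned a single position, by default its 5′ end plus a configurable
species-specific offset (`offset_40s`, `offset_80s`, both 0). Full P-site
calibration is deliberately out of scope; the offsets are explicit
configuration so a calibrated value can be supplied. Raw reads are
size-selected before assignment: 25–35 nt for 80S and 20–80 nt for 40S
libraries, inclusive, mirroring gel excision windows.

A gene is *detected* when its total-80S CDS count is at least
`min_counts` (default 32) in every library being compared; ratio
statistics are unstable below that.

## The step-function assembly score

For each detected gene the CDS is divided into `n_bins` (default 100)
near-equal nucleotide bins, scaling every CDS to 0–100%. Selective and
total bin sums are depth-matched — both rescaled to the shallower
library's depth — and the per-bin ratio is
(selective + pc) / (total + pc) with pseudocount pc = 0.5 *reads at the
matched depth*. This choice bounds the ratio on sparse bins (a single
stray read cannot produce an arbitrarily large spike, which would
otherwise dominate the genome-wide ranking through one-bin step
segments) while leaving the flat case unbiased: equal per-depth signal
gives ratio 1 for any pc. Bins with no coverage resolve to the neutral
value 1 rather than being dropped, so bin indices stay comparable
across genes; a gene with no total coverage in any bin is flagged
unusable and skipped.

The fit tries every breakpoint b ∈ [1, n−1], computes the two side means
and the summed squared residuals, and keeps the SSE-minimizing b; ties —
exact or within a relative tolerance of 1e−9 scaled by the profile's sum
of squares, so that the direct and the prefix-sum implementation resolve
floating-point ties identically — go to the smallest b. The score is
mean(right) − mean(left); positive scores mean binding increases along
the message. With biological replicates, scores are computed per
replicate and averaged.

The null distribution of the score is bimodal: the best split of a pure
noise profile has a typical magnitude set by the noise level with a gap
near zero, so "centered at zero" is a statement about the mean and the
sign balance, not the sample median (see the tests).

## uORF calling

The 5′UTR is scanned 5′→3′; each AUG (optionally each single-mismatch
near-cognate: CUG, GUG, UUG, ACG, AUA, AUU, AUC, AAG, AGG — off by
default) is extended in frame to the first stop codon. If the stop ends
at or before the main start, the ORF is a uORF; otherwise — including a
stop codon straddling the main start, since a ribosome terminating past
that point cannot have initiated the main ORF — it is recorded as an
oORF. Overlapping and nested ORFs are all reported; no masking. A uORF
is *translated* when it contains ≥ `min_uorf_reads` (default 1) 80S
footprints — a deliberately low-stringency rule, exposed as
configuration. Transcript categories (no uORF / non-translated /
translated) partition the gene set; a single translated uORF puts the
transcript in the translated class.

## Metagene construction

Anchors are main-ORF or uORF start/stop codons (stop anchors sit at the
first nucleotide of the stop codon). uORF anchors require an
AUG-initiated, translated uORF with ≥80 nt between its stop and the main
start, so initiation-zone signal does not bleed into uORF-stop windows.
Default windows are −100..+200 nt around starts and −200..+100 around
stops; offsets outside a transcript are masked and each offset is
averaged over its contributing transcripts only, which avoids edge
artifacts from short 5′UTRs. 80S profiles are scaled to counts per
million; 40S profiles are multiplied by the factor equalizing the summed
signal at −100..−80 nt (the scanning plateau upstream of the start
codon) across libraries, with the first library as reference — so
conditions are compared at matched scanning flux. Smoothing is a
centered moving average whose window shrinks symmetrically at edges
(even windows round down to the next odd); window 3 removes triplet
periodicity, window 1 is the identity. Both raw and smoothed traces are
emitted.

## Selectivity and translation efficiency

Gene-level ratios (40S binding in 5′UTRs; TE = 80S CDS footprints over
mRNA count) use counts-per-million normalization with the same 0.5
pseudocount on the CPM scale. Gene-level sums are large enough that the
pseudocount only guards zero counts, and CPM keeps these ratios exactly
invariant under rescaling any single library — a property the binned
profile's depth-matching intentionally trades away for spike-bounding.
ΔTE is the log₂ ratio of treated to control TE; formal differential
significance is delegated to dedicated tools and out of scope here.

Decile groups take the top and bottom ⌊fraction·n⌋ genes by binding
ratio (ties broken by gene id for determinism). Category comparisons use
Kruskal–Wallis for the omnibus test and Dunn's z-statistics on pooled
midranks with tie correction for the pairwise contrasts, Bonferroni-
adjusted over the pairs; the Dunn test is implemented here (validated by
a hand-computed example and by type-I calibration at the nominal 5%
level) since no installed package provides it. Binding–ΔTE association
uses Spearman rank correlation: the ratios are heavy-tailed, and no
linearity is assumed. The overlap of two gene sets in a universe of N
detected genes is tested with the upper-tail binomial probability
P(X ≥ observed), X ~ Binomial(|A|, |B|/N).

## The synthetic generator

One unit of 43S scanning flux enters each 5′UTR at the cap. At each uORF
start a Kozak-dependent fraction p initiates and leaves the scanning
pool; the rest leaky-scans. An optional per-uORF reinitiation
probability (default 0) returns a fraction of terminating ribosomes to
the pool. 40S counts are Poisson with mean `scan_density` × local flux;
80S counts on an ORF are Poisson with mean `elong_density` × initiation
flux into it. Selective libraries are binomial thinnings of the matched
totals: 80S capture is `ip_base_rate` (0.05), stepping to `ip_step_rate`
(0.5) at `breakpoint_frac` (40%) of the CDS on interactor transcripts;
40S capture is `ip_utr_base_rate` (0.2), or `ip_utr_uorf_rate` on
transcripts with an actively translated uORF when set — setting it
higher couples factor binding to uORF content and hence, through the
knockdown, to ΔTE. The knockdown condition multiplies every uORF
initiation probability by `depletion_leak_shift` (2.0; values > 1 mean
less leaky scanning). RNA-seq counts are Poisson at `rna_depth` × length
and identical in expectation across conditions.

Defaults describe a scaled-down transcriptome of 200 genes with 150–300
nt 5′UTRs, 300–900 nt CDSs, and Poisson(0.8) AUG-uORFs per 5′UTR drawn
with Kozak strengths {0, 0.1, 0.25, 0.5} — the zero class models
bioinformatically annotated but silent uORFs, so all three transcript
categories occur. `elong_density` 16 puts a detected CDS at ~4–6
reads/nt (the coverage a ~3×10⁷-read library gives well-detected genes),
i.e. ≳20 total reads per profile bin; `scan_density` 0.5 makes 40S
5′UTR sums of ~50–150 reads per gene. The mORF initiation probability is
a fixed 0.65 (strong context).

Per-transcript, per-condition RNG substreams are derived from the seed,
so output is bit-identical for identical configuration and independent
of iteration order.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analyses rely on: flux
conservation through leaky scanning, Poisson counting noise, thinned
selective capture with a positional step, condition shifts in uORF
initiation. It does not emulate codon-level pausing, sequence
composition (GC, codon usage), rRNA contamination, isoform mixtures,
P-site frame structure, or overdispersion beyond Poisson. Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to every artifact of real libraries — in
particular, real data's extra dispersion will widen all null
distributions relative to the calibrations shown here.

## Numerical and design choices

- Bin edges come from rounding a linear partition of the CDS; with a CDS
  shorter than `n_bins` the profile falls back to per-nt bins with a
  warning.
- The breakpoint reported in nucleotides is the bin edge mapped back to
  CDS coordinates.
- Simulated 5′UTR sequences are scrubbed of spurious AUGs (by C
  substitutions, which can neither create starts nor stops) so the
  annotated uORF list is exactly what a sequence scan recovers; in-frame
  premature stops inside planted ORFs are removed the same way.
- The one-step model is fitted to the ratio profile, not raw counts, and
  only a single breakpoint is considered; multi-step segmentation and a
  formal significance for the score are out of scope.
- Transcript isoforms are not collapsed: one principal transcript per
  gene is assumed throughout.

## Problem sizes

Test-suite simulations use 60–1000 transcripts; calibration loops use
200–1000 replicates; the acceptance script's largest run is 1000
transcripts × 2 conditions. These sizes put every Monte-Carlo acceptance
quantity's sampling error well inside its decision band while keeping a
full run in tens of seconds.
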