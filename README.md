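# riboselect

Analysis toolkit for **selective 40S/80S ribosome footprinting** — the
experiment in which ribosomes bound by a factor of interest (an initiation
factor, a ribosome-associated protein) are immunoprecipitated and their
protected mRNA fragments sequenced alongside a matched total-ribosome
library. The package is aimed at researchers studying translational
control: co-translational complex assembly, upstream open reading frames
(uORFs), leaky scanning, and factor-dependent translation efficiency.

## What it computes

**Co-translational assembly score.** A factor that binds the ribosome once
its partner's interaction domain emerges from the exit tunnel produces a
step in the ratio of selective to total 80S footprints along the CDS. For
each gene the CDS is scaled to 0–100% and binned; the depth-normalized
ratio profile *r* is fitted with a one-breakpoint step function by least
squares, trying every breakpoint *b* and keeping the one minimizing

&nbsp;&nbsp;&nbsp;&nbsp;SSE(b) = Σ<sub>i&lt;b</sub> (r<sub>i</sub> − r̄<sub>left</sub>)² + Σ<sub>i≥b</sub> (r<sub>i</sub> − r̄<sub>right</sub>)²

The score is r̄<sub>right</sub> − r̄<sub>left</sub>: large positive values
mean binding switches on part-way through translation. Both the direct
exhaustive fit and an algebraically identical linear-time prefix-sum fit
are provided.

**uORF annotation and classification.** AUG-initiated (optionally
near-cognate) uORFs are called from 5′UTR sequence; ORFs running past the
main start codon are reported separately as oORFs. A uORF counts as
*translated* if it carries at least one 80S footprint (low-stringency,
threshold configurable), and transcripts are partitioned into
no-uORF / non-translated-uORF / translated-uORF categories.

**Metagene profiles.** Footprint signal is aggregated around start/stop
codons of main ORFs or of translated AUG-uORFs with ≥80 nt intercistronic
space. 80S profiles are normalized per million library reads; 40S profiles
are rescaled to equalize scanning-ribosome signal 80–100 nt upstream of
the start codon across libraries. A 3-nt sliding window removes triplet
periodicity.

**Selectivity and ΔTE statistics.** Per-gene selective/total 40S binding
ratios in 5′UTRs, decile grouping, Kruskal–Wallis + Dunn comparison across
uORF categories, translation efficiency TE = (80S CDS footprints)/(mRNA)
per condition, log₂ΔTE between conditions, and the Spearman correlation of
binding with ΔTE.

**Synthetic data.** A generative model of the whole experiment — scanning
43S flux with Kozak-dependent leaky scanning at uORFs, Poisson footprint
counts, binomial selective-IP thinning with an optional capture step on
interactor transcripts, and a factor-depletion condition that shifts uORF
initiation — so every stage is testable end to end without sequencing data.

## Worked example

```python
from riboselect import (SimConfig, simulate_transcriptome,
                        simulate_footprints, score_all_genes)

cfg = SimConfig(n_transcripts=200, interactor_fraction=0.02, seed=7)
transcripts, truth = simulate_transcriptome(cfg)
libs = simulate_footprints(transcripts, truth, "control", cfg)
scores = score_all_genes(libs["selective_80s"], libs["total_80s"], transcripts)
print(scores.head(5).to_string(index=False))
```

```
transcript_id    score  breakpoint_bin  breakpoint_nt  mean_left  mean_right        sse  coverage
      TX00075 7.328327            40.0          329.0   0.905176    8.233503  42.705438      8503
      TX00029 6.794201            40.0          155.0   0.839406    7.633607  90.138642      4085
      TX00006 6.777768            40.0          236.0   1.018925    7.796692  57.303974      5561
      TX00068 6.664124            40.0          323.0   0.972352    7.636476  91.226512      4329
      TX00047 6.211847            40.0          127.0   0.973808    7.185655 110.485789      3370
```

The five top-ranked genes are exactly the five simulated interactors
(`truth` records them), each with the fitted breakpoint at bin 40 — the
configured 40% of the CDS — and `breakpoint_nt` matching the planted
breakpoint in nucleotides. A score of ~7 says factor-bound ribosome
density jumps roughly seven-fold (in depth-matched ratio units) once the
interacting domain has been translated; the background of non-interactors
scores near 0.

The same analyses run from the shell:

```bash
riboselect simulate --seed 7 --n-transcripts 200 --outdir run/
riboselect score --selective run/control_selective_80s.bedgraph \
                 --total run/control_total_80s.bedgraph \
                 --gff run/annotation.gff3 -o run/scores.tsv
riboselect run --config run.yaml        # full pipeline with manifest
```

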