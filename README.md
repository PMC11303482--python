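# atacmotif

Motif enrichment and promoter integration for differential ATAC-seq peaks.

## The problem

When a treatment reprograms a cell's chromatin (for example endothelial
colony-forming cells driven through endothelial-to-mesenchymal transition),
ATAC-seq yields a set of *treatment-dependent peaks* — regions significantly
more accessible after treatment — and RNA-seq yields lists of up- and
down-regulated genes. Two questions follow for anyone hunting the
transcription factor behind the change:

1. **Enrichment.** Do the treatment-dependent peaks contain a TF's binding
   motif more often than random genomic regions of the same lengths would?
2. **Targets.** Which upregulated genes have a treatment-dependent peak near
   their promoter, and which of those peaks carry the motif — the candidate
   direct targets of that TF?

`atacmotif` implements this analysis end to end for users who already have
the standard upstream products (peak calls with differential statistics,
gene annotation, differential expression tables) and want a tested,
reproducible downstream: PWM scanning with an exactly calibrated match
threshold, a permutation null for region-set enrichment, TSS accessibility
metaprofiles, and the promoter-window integration. A synthetic-data module
generates genomes, peaks and tables with planted ground truth so the whole
pipeline can be exercised — and its statistical recovery verified — without
any sequencing data.

## The statistic

A motif *match* is a window whose log2-odds score against the background
base composition reaches a threshold `t(α)` chosen so a random background
L-mer passes with probability ≤ α (default `α = 1e-4`), computed exactly by
dynamic programming over the discretised score distribution — no sampling.
A peak *contains* the motif if it holds ≥ 1 match on either strand.

The enrichment test compares the observed number of motif-containing peaks
`k_obs` with its null distribution over `N` random placements of a
length-matched region set:

    fold = k_obs / mean(k_null)
    p    = (1 + #{k_null ≥ k_obs}) / (1 + N)

The add-one permutation p-value can never be zero. Null regions may
optionally avoid an exclusion list (e.g. the peaks themselves) and be
GC-matched to the observed peaks within a tolerance.

## Worked example

Plant SOX9-like consensus motifs into random peaks at 1.7× the calibrated
background containment rate, then ask the enrichment stage to recover it:

```python
import atacmotif as am
from atacmotif.simulate import (
    generate_genome, generate_peaks, plant_motifs, sox9_synthetic_pcm,
)

genome = generate_genome(n_contigs=1, lengths=2_000_000, gc=0.41, seed=1)
peaks = generate_peaks(genome, n_peaks=2000, length_mean=400, seed=2)
pwm = am.calibrate_threshold(
    am.build_pwm(sox9_synthetic_pcm(), am.BackgroundModel.from_genome(genome)),
    alpha=1e-4,
)
genome, truth = plant_motifs(genome, peaks, pwm, target_fold=1.7, seed=3)
result = am.MotifEnrichmentTest(peaks, genome, pwm, exclusions=peaks).fit(
    n_perm=1000, seed=4
)
print(result.summary())
```

```
Motif enrichment (permutation test)
==========================================
motif                       SOX9_synthetic
peaks scanned                         2000
peaks with motif                       274
null mean                           172.48
null sd                              12.99
fold enrichment                      1.589
empirical p                       0.000999
z                                     7.82
permutations                          1000
seed                                     4
```

274 of the 2000 peaks (14%) contain the motif, against a null expectation
of ~172 — a fold of 1.59 for this single replicate (the estimator is
unbiased but noisy per run; averaged over 20 seeds it recovers 1.7 within a
few percent). The empirical p of 0.000999 is the smallest value 1000
permutations can resolve.

The same machinery runs from the shell:

```bash
atacmotif simulate figure2h --seed 42 --outdir fixture/
atacmotif run --config config.yaml        # filter -> scan -> enrich -> profile -> integrate
```

The `run` report includes, for the deterministic fixture above, 3633
treatment-up peaks of which 847 (23%) contain a SOX9 motif, and 95
upregulated genes with a peak within 5 kb of their TSS of which 16 have a
motif-bearing peak — counts that are exact by construction and reproduced
from scratch every run.

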