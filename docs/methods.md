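# Methods

## Coordinate conventions

All coordinates inside the package are 0-based half-open `[start, end)`.
BED input passes through unchanged; GTF (1-based inclusive) is converted on
read and back on write. For a "+" transcript the TSS is `start − 1`; for a
"−" transcript it is `end − 1`. When a gene has several transcripts the
canonical TSS defaults to the 5′-most on the gene's strand
(`canonical_rule="five_prime_most"`); first-in-file order is available.
Soft-masked (lowercase) genome sequence is uppercased on read; repeat
masking is not tracked, since nothing downstream uses it.

## Motif model

A motif is a 4×L position count matrix `c`. With background frequencies
`q_b` (estimated from the genome's GC content, G=C and A=T split evenly)
and pseudocount `s` (default 0.8, distributed by background), the weight
matrix is

    f[b,i] = (c[b,i] + s·q_b) / (N_i + s),   N_i = Σ_b c[b,i]
    w[b,i] = log2(f[b,i] / q_b)

A window of length L scores `Σ_i w[seq[i], i]`; the reverse strand is
scored by the reverse-complemented matrix at the same forward coordinates,
so hits are reported strandlessly-positioned, which is what peak-level
containment needs. Windows containing N are skipped rather than scored with
a neutral contribution — conservative, and it keeps masked fixtures from
inflating counts.

### Threshold calibration

The match threshold is calibrated to a target tail probability α (default
`1e-4`, conventional PWM-match stringency) by exact dynamic programming:
each column's score mass function is discretised at a granularity of
`1e-3` bits and convolved across columns, giving the full distribution of a
random background L-mer's score. The threshold is the smallest discretised
score whose upper tail is ≤ α, relaxed by half a granularity step per
column so a word sitting on a quantisation boundary is never rejected; the
attained tail mass is stored alongside. The total discretisation error is
bounded by L·granularity (≤ 0.01 bits for typical L), and the unit tests
sandwich the DP tail between exhaustive 4^L enumerations evaluated at
threshold ± L·granularity. With α = 1 the threshold falls at or below the
minimum achievable score and every word matches.

### Scanning

The scanner precomputes per-position window scores for a whole contig with
vectorised column lookups. For permutation work, `GenomeScanIndex` reduces
"does region [s, e) contain ≥ 1 hit?" to one prefix-sum difference over the
genome-wide hit indicator, so a million null-region queries cost
milliseconds rather than re-scans.

## Differential filters

Peaks: significant at `fdr ≤ fdr_max` (inclusive) with fold change
strictly `> fc_min` (treatment-up) or `< −fc_min` (control-up); defaults
`fdr_max = 0.05`, `fc_min = 1`. The fold-change scale defaults to log2, the
scale differential-accessibility tools emit, so `fc_min = 1` means a
two-fold linear change; `fc_scale="linear"` reads the same column as a
linear ratio instead, and the choice is logged because tables in the wild
are ambiguous. Genes: `adjusted p < 0.05` split by the sign of log2FC;
significant genes with exactly zero effect belong to neither set and are
counted in a warning.

## Permutation enrichment

The test statistic is the number of peaks containing ≥ 1 motif (not the
total hit count, which is offered behind a flag): containment is the
region-level event the integration stage consumes. Each of `n_perm`
(default 1000, giving 1e-3 resolution on the empirical p) null samples
places one random region per peak, length-matched one-to-one: a contig is
chosen with probability proportional to its placeable positions
(len − l + 1), then a uniform start. Options:

- `exclusions` — rejection-sample until no null region overlaps the given
  intervals (typically the peak set itself);
- `gc_match` — resample until each region's GC is within the tolerance of
  its matched peak's, with bounded retries; regions that exhaust retries
  are accepted and counted, and a warning fires if they exceed 10%.

Determinism: one master seed spawns one child generator per permutation via
`numpy.random.SeedSequence`, so results are bit-identical for fixed inputs
and seed, and permutations are independent of each other's draw counts.
`fold = observed / null_mean` (+∞ with a warning if the null mean is zero)
and the empirical p uses the add-one estimator, which is a valid p-value
and never reports zero. Multi-TF runs reuse the identical null placements
across motifs (same seed, same sampler) so rows differ only through the
motif; ties in fold break lexicographically by name.

**Background universe.** When peaks are planted with motifs and cover a
substantial fraction of a small synthetic genome, genome-wide null regions
absorb the planted signal and bias fold recovery toward 1. The recovery
experiments therefore use the peak-avoiding null (`exclusions = peaks`),
which measures the unplanted background that the planting was calibrated
against; on real data the choice between a genome-wide null, a
peak-avoiding null, or a user-supplied region universe (e.g. a footprint
BED used as the peak source) is an explicit configuration, not a default
buried in code.

## TSS metaprofile and promoter integration

The metaprofile bins `[tss − w, tss + w)` (default w = 1 kb, 100 bins of
20 bp) and records the fraction of each bin covered by the union of peaks;
minus-strand genes are reversed so bins run 5′→3′, bins beyond a contig
edge are NaN and excluded from the aggregate mean. Coverage queries use
merged intervals with binary search rather than per-base arrays.

A peak is promoter-proximal to a gene when its distance to the TSS point is
≤ 5 kb, measured edge-to-TSS (zero if the TSS lies inside the peak) and
inclusive at exactly 5 kb — the conservative literal reading of a "within
5 kb" rule; centre-to-TSS is available via `anchor="center"`, and a
promoter *span* instead of a point can be emulated by widening `max_dist`.
A peak may serve several genes and a gene may hold several peaks, because
the final counting is per gene. The integration result maintains the
invariant `motif-bearing ⊆ proximal ⊆ upregulated` by construction and
assertion.

## Synthetic data

Generators are pure functions of (parameters, seed) and emit a ground-truth
manifest. The genome is i.i.d. with configurable GC (default 0.41, a
mammalian-like composition); peaks have truncated-normal lengths (mean
400 bp, minimum 50 bp), matching typical ATAC peak widths; differential
tables draw significant effects from `±|N(2, 0.5)|` log2 units with
adjusted p uniform below 0.05 and null effects near zero.

`plant_motifs` first measures the background containment rate p0
empirically — 5000 random length-matched regions of the unplanted genome —
rather than from a closed form, so it stays correct under any
threshold/α/background combination. It then overwrites the PWM consensus
(random offset and strand, no insertions, so all coordinates stay valid)
into randomly chosen motif-free peaks until the containment count reaches
`round(target_fold · p0 · n_peaks)`. Because peaks may overlap, one planted
word can flip several peaks; planting is incremental and propagates flags
to every peak fully containing the planted word, so realized containment
lands on the target rather than overshooting. Planting demands
`target_fold · p0 ≤ 1` and fails loudly otherwise ("saturated planting").

The deterministic integration fixture lays out one contig in functional
segments — 95 isolated 12 kb gene blocks whose TSS sits 3 kb from its own
peak and > 7.5 kb from any other, a dense block of the remaining genes with
no peaks within 20 kb, and a distal block of the remaining peaks — then
scrubs every spontaneous motif hit from the treatment-up peaks
(rescan-and-rewrite with background bases) before planting exactly 847
consensus words: 16 into promoter-proximal peaks, 831 distal. The generator
re-derives every promised count from its own output and refuses to return
otherwise. Counts are exact for every seed; the seed varies only sequence
content and planting offsets.

**What the synthetic data does not emulate:** real nucleotide composition
(CpG islands, repeats, isochores), Tn5 insertion bias, fragment-length
structure, replicate noise, correlated peak–gene geometry, or motif
degeneracy beyond the single consensus planted. Passing recovery tests
therefore demonstrates the statistical machinery is calibrated and
correctly implemented, not that any particular biological dataset will show
a given fold.

## Problem sizes

Recovery experiments use a 2 Mb genome with 2000 peaks and 1000
permutations per test, averaged over 20 independent replicates — sizes at
which the Monte-Carlo error on a mean fold is a few percent and a full
replicate runs in seconds. Null calibration uses 200 simulated datasets of
400 peaks on 500 kb with 200 permutations, enough to place the rejection
rate inside an exact binomial 99% interval around the nominal 0.05.

## Known limitations

- Zeroth-order background only; no dinucleotide or higher-order Markov
  match model.
- GC matching is a simple per-region tolerance, not binned stratification.
- The analytic (binomial) approximation to enrichment is deliberately not
  offered as a primary path; the permutation null is the method.
- De novo motif discovery, peak calling and differential testing are out of
  scope: the package consumes their outputs.
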