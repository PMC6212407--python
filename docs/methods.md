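# Methods

`captss` implements the computation of a TSS-seq (5′CAP-seq) experiment
comparing transcription initiation between two conditions (here labelled
*control* and *cold*, after the cold-exposure design the pipeline was built
for), plus a mechanistic simulator of convergent sense/antisense
transcription with RNAPII collisions. This note records the models, the
parameters that matter, and the design decisions taken where the design was
genuinely open.

## Coordinate conventions

All in-memory coordinates are 0-based half-open. GFF3 (1-based inclusive)
is converted at the I/O boundary; bedGraph and BED pass through unchanged.
A gene's annotated TSS is its `start` base on the plus strand and `end − 1`
on the minus strand.

## Read preprocessing

The library structure is: 8-nt random barcode (UMI) at the 5′ end of the
read, insert, and — for short inserts — the fixed adapter `ATCTCGTATGCCG`
read into the 3′ end. Preprocessing trims the adapter first and extracts
the UMI second: the UMI sits 5′ of the insert, so the adapter boundary is
defined on the untouched 3′ end.

Adapter matching considers full occurrences anywhere in the read and
partial occurrences where an adapter *prefix* runs into the read's 3′ end.
A candidate needs overlap ≥ `min_overlap` (default 3) and mismatch rate
≤ `max_error_rate` (default 0.1); the longest overlap wins, ties going to
the leftmost (most-trimming) start. These thresholds are common trimmer
defaults; partial-match policies differ between trimming tools, so ours is
documented here and configurable.

The UMI is moved into the read name after a single `_`; the deduplication
stage parses the same convention, fixed in one place
(`preprocess.UMI_SEPARATOR`).

## Tags, filters, deduplication

Each mapped alignment is reduced to its 5′ event (`AlignedTag`): leftmost
aligned base on the plus strand, rightmost aligned base across all splice
blocks on the minus strand. Spliced alignments are supported; splice
blocks are kept only for feature-overlap tests. Whether a real experiment
should keep spliced 5′ alignments is protocol-dependent, so nothing in the
pipeline forbids them.

Filters, in pipeline order (the final tag multiset is order-independent,
which the tests assert):

* **Structural-RNA filter** — a tag is removed iff any aligned block
  overlaps ≥ 1 bp of an rRNA/tRNA/snRNA/snoRNA gene. The test is
  strand-blind because this class of contamination maps to both strands;
  the excluded biotype set is configurable.
* **MAPQ filter** — keep tags with MAPQ ≥ 10 (boundary kept); removes
  ambiguous multimappers.
* **UMI deduplication** — within each (chrom, strand, 5′ position) group,
  one tag is kept per distinct UMI. Matching is exact (Hamming distance
  0): error-tolerant UMI collapsing is deliberately not applied, and which
  physical copy survives is irrelevant downstream (tie-break: first by
  (position, read id)). Dedup treats the two strands at one coordinate as
  distinct TSS events.

## Coverage and candidate positions

Deduplicated tags become per-sample stranded single-base coverage. Raw
integer counts feed everything statistical; counts-per-million
normalization (shared denominator across both strands of a sample; the
normalized values sum to 10⁶) exists only for browser tracks and
reporting. The candidate-TSS filter keeps positions with raw count ≥ 2,
applied per sample and then pooled across samples for clustering — a count
threshold on raw integers is exact, and the differential test needs raw
counts anyway. A pooled-counts variant of the threshold is available via
configuration.

## Cluster calling, quantification, annotation

Candidate positions on one strand of one chromosome are merged by
single-linkage: positions `p < q` join one cluster iff `q − p ≤ 20` (so a
gap of exactly 20 bp merges, 21 bp splits); clustering is the transitive
closure, and the cluster interval spans `[min member, max member + 1)`.
Per-sample cluster counts sum raw coverage over the whole span, including
bases that individually failed the ≥ 2 filter. The summit is the base of
maximal pooled count, ties broken to the smallest coordinate — a fixed,
documented rule since any tie-break is defensible.

Each cluster receives one category from

`intergenic < antisense < intron < exon < 5′UTR < proximal < promoter`

evaluated at the summit base: the summit is the cluster's representative
TSS, and whole-interval overlap would make the hierarchy ambiguous for
wide clusters (an interval mode that pools labels over the span is
available via configuration). Windows are oriented in the annotated
gene's direction: promoter = [−100, +100] around the gene TSS (inclusive),
proximal = [−500, −100) upstream; minus-strand windows are mirrored.
"Antisense" means the summit lies inside an opposite-strand gene body.
3′UTR bases classify as exonic sequence under this seven-category
hierarchy. Cluster ids are `chrom:strand:start-end`, stable across runs.

## Differential TSS usage

Per cluster, a negative-binomial GLM with log link:

K_cs ~ NB(μ_cs, α_c),  log μ_cs = β₀_c + β₁_c·x_s + log f_s

with x_s the condition indicator and f_s median-of-ratios size factors
(median taken on the log scale, the standard convention). The condition
coefficient β₁ (log2FC = β₁ / ln 2) is tested by a Wald statistic from the
Fisher information at the MLE.

Dispersion: per-cluster method of moments on size-factor-scaled counts.
With per-condition means m_g and pooled within-condition variance s², the
NB variance relation gives

α̂ = max(0, (s² − mean_g m_g) / mean_g m_g²),  floored at 10⁻⁸.

Using `mean_g m_g²` rather than the square of the grand mean matters: the
grand-mean form is biased upward exactly for clusters with a real fold
change, which costs power where it is needed; the two coincide under the
null. There is **no** information sharing across clusters (no
empirical-Bayes dispersion shrinkage) — a deliberate divergence from
DESeq2-style tools, acceptable because the test is validated by
calibration, not by replicating any specific tool's internals.

Reference distribution: with an *estimated* dispersion and only n = 4
samples, the plug-in normal reference is badly anticonservative (≈ 18%
null rejections at nominal 5% in our simulations), so the Wald statistic
is referred to a t distribution with the residual degrees of freedom
(n − 2), the usual small-sample quasi-likelihood practice. With a *fixed*
dispersion the statistic is asymptotically normal and the normal reference
is used — which also makes the α = 0 case reduce exactly to the Poisson
GLM Wald test. Measured at the study design (2 vs 2): null type-I error
≈ 0.034 at nominal 0.05; power ≈ 0.82 for 4-fold effects at mean 200,
dispersion 0.05; log2FC bias ≈ −0.08. All three are recomputed by
`analysis/03_differential_usage.py` and `scripts/acceptance.py`.

All-zero clusters get NA p-values. Benjamini–Hochberg `padj` is always
reported alongside raw `p`; classification (up/down/ns at α = 0.05) uses a
config-chosen column. The default is raw `p` — matching the significance
rule the pipeline was built to reproduce — while `padj` is the safer
choice for new analyses; every output header states which column was used.

## Collision simulator

The locus is a 1D lattice of L = 50 polymerase footprints with hard-core
exclusion. Sense polymerases initiate at site 0 (rate `k_init_sense`) and
step rightward at `k_elong` when the next site is free; antisense
polymerases initiate at site L−1 and step leftward. The antisense unit is
short: it covers only the distal `anti_len` sites, and an antisense
polymerase leaves the lattice after traversing it — mirroring an antisense
read-through transcript that terminates before reaching far into the sense
gene body. When a sense and an antisense polymerase become adjacent head
to head, the pair stalls; the stall resolves at rate `k_term`, whereupon
the collision rule applies: `both_terminate` (default) removes both,
`sense_terminates` removes only the sense polymerase. Whether colliding
polymerases terminate, pause, or dislodge each other is not settled
biology; the first two readings are implemented, dislodging is not.
Dynamics are exact continuous-time Gillespie — at this lattice size
exactness is cheap and removes a discretization parameter.

All rates are invented, phenomenological quantities (per unit time):

| parameter | default | why |
|---|---|---|
| L | 50 | desk-scale lattice, fast exact simulation |
| k_init_sense | 1 | sets the time unit's meaning: one initiation attempt per unit time |
| k_elong | 10 | elongation ≫ initiation, the usual transcription regime |
| k_term | 1 | stall lifetime ~ 10 elongation steps: collisions are slow to resolve |
| anti_len | 10 | the antisense unit covers only the 3′ fifth of the sense unit |
| T | 100 | ≫ lattice transit time (5), so fill-in transients are negligible |

The choice that matters qualitatively is the *stall*: if collisions
resolved instantly, removing polymerases on contact, the annihilation
front between the two traffics would drift toward the weaker side and
sense occupancy would always decay toward 3′. Finite stall lifetimes with
a short antisense unit instead hold a standing queue of sense polymerases
just upstream of the antisense territory, reproducing the experimentally
observed RNAPII buildup toward the 3′ end of a convergently transcribed
gene while full-length sense yield falls. The simulator claims this
qualitative correspondence only; no kinetic parameter is fitted to data.

## Synthetic data generator

`simulate.make_genome` lays out non-overlapping genes (multi-exon
protein-coding genes with 5′/3′UTRs plus single-exon structural-RNA
decoys) on small chromosomes; `plant_tss` rejection-samples cluster
summits until the pipeline's own annotator confirms the requested
category, keeping same-strand summits ≥ 60 bp apart (so distinct planted
clusters cannot merge at the 20-bp rule) and away from decoy genes (whose
tags the pipeline filters); `simulate_tags` draws per-cluster, per-sample
negative-binomial counts (mean = expression × fold change × size factor),
scatters tag 5′ positions around the summit with a discretized Gaussian
(sd ∈ {1, 2, 4} bp — sharp/broad TSS shapes are approximated by this one
parameter), and adds the three nuisances the pipeline must remove: PCR
duplicates (exact copies re-emitted with probability `dup_rate`),
contaminants placed uniformly inside structural-RNA genes, and a fraction
of tags with MAPQ < 10.

Default study conditions: 2 conditions × 2 replicates, 200 planted
clusters (45% promoter, 10% proximal, 10% 5′UTR, 10% exon, 5% intron, 10%
antisense, 10% intergenic — a promoter-dominated landscape), expression
lognormal(ln 40, 0.8), effects 80% null / 10% up at 4-fold / 10% down at
0.25-fold, dup_rate 0.3, contam_frac 0.1, lowmapq_frac 0.05, NB dispersion
0.05. UMIs are drawn *without replacement* within a batch: biological
molecules carry distinct UMIs by assumption, so a shared (position, UMI)
pair always identifies a PCR copy. The generator emits aligned tags
directly — genome alignment is outside the pipeline's scope, so its tests
must not require an aligner; an optional FASTQ emission (UMI prepended,
adapter appended, read bodies random DNA whose 3′ tail cannot mimic an
adapter prefix) exercises the read-level preprocessing with exact ground
truth.

What passing tests on this generator do **not** show: behaviour on real
genomes (sequence-dependent mappability, true multimapping structure),
TSS shape families beyond a Gaussian spread, UMI sequencing errors, or
dispersion trends across the expression range. The generator is a
correctness harness, not a realism benchmark.

## Problem sizes and numerical choices

Default simulations run in seconds on one CPU: the end-to-end synthetic
study uses ~50–80k tags over 4 samples; the calibration simulation uses
2000 null clusters; the power simulation 200 replicates of 1000 clusters
(the NB fits are vectorized Fisher scoring across clusters, converging in
a handful of iterations; steps are clipped via a linear-predictor bound of
±30); the collision scans use 100 replicates per rate with common random
numbers across rates (paired seeds), which makes the yield curve's
monotonicity a low-variance comparison. IRLS singularities (empty
groups, all-zero clusters) fall back to NA p-values rather than failing.

## Known limitations

* Two-condition, single-factor designs only; no multi-factor GLMs, no
  outlier handling, no independent filtering.
* No dispersion shrinkage across clusters; at n = 2 + 2 the moment
  estimator is noisy and the t reference compensates conservatively
  (measured type-I ≈ 0.034 at nominal 0.05).
* Annotation assigns one category per cluster; clusters spanning feature
  boundaries are represented by their summit unless interval mode is
  chosen.
* The collision simulator has no pausing/backtracking states, no
  exonuclease (torpedo) kinetics, and no sequence-dependent rates.
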