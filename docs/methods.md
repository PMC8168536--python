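# Methods

This note records the models implemented in `scatk`, the assumptions behind
them, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that matter
when reproducing results.

## Fragment model and conventions

A *fragment* is the genomic interval released by two transposition events,
tagged with a 16 bp cell barcode. Coordinates are 0-based half-open (BED
convention); the two transposition events of a fragment sit at `start` and
`end − 1`. Read pairs sharing (chrom, start, end, barcode) are PCR
duplicates and collapse to one fragment carrying their multiplicity; all
downstream counting uses unique fragments only. TSS positions follow BED:
interval start for `+`-strand genes, `end − 1` for `−`-strand genes.

## Barcode correction

Observed barcodes are matched to a whitelist. A read off the whitelist is
compared with every whitelist entry within Hamming distance 2 (found by a
pigeonhole segment index: any ≤2-substitution neighbor matches exactly on one
of three barcode segments). Candidates are scored with

* likelihood = ∏ mismatch positions (10^(−Q/10)/3) × ∏ match positions (1 − 10^(−Q/10)),
* prior ∝ exact-match abundance + 1 (the pseudocount keeps unobserved
  whitelist entries reachable),

and the read is corrected to the maximum-posterior candidate only when its
normalized posterior strictly exceeds 0.9. Ties at exactly 0.9 abstain.
Reads with more than two `N` bases are discarded: they cannot satisfy the
distance bound informatively. Fragment files carry no per-base qualities, so
the batch API assumes a uniform Phred 30; the single-read API accepts real
quality strings. The quality-based substitution likelihood is this package's
concrete choice — upstream tools do not document theirs.

## QC profiles

The fragment-length histogram is computed over unique fragments (duplicate
counts not multiplied). TSS enrichment aggregates transposition events at
offsets −2000..+2000 around every TSS (offsets mirrored for minus-strand
genes) and normalizes as `(counts + 1) / (mean of the outer 100 bp flank
counts + 1)`, so the flank level is exactly 1 by construction and the
enrichment score is the curve value at offset 0. The flank normalization is
this package's choice; the pseudocount guards sparse desk-scale libraries
against division by zero.

## Peak calling

Per-base transposition-event counts are smoothed with a 401 bp moving window
(window sum, clipped at chromosome ends). The smoothed counts are fitted
with a three-component mixture: a geometric distribution on {0, 1, 2, …}
(P(k) = p(1−p)^k) for the zero-inflated background, and two negative
binomials for noise and signal. NB(μ, φ) has variance μ + μ²/φ. Zeros
receive mass from all three components; EM apportions them.

EM details:

* fitted on the aggregated value → multiplicity table, so a million
  observations with a few hundred distinct counts cost ~1 ms per iteration;
* initialization (deterministic given the seed): the zero fraction seeds the
  geometric weight, 2-means on log1p of the nonzero values seeds the two NB
  means, dispersions by method of moments;
* M-steps: weighted means for μ and the geometric p = 1/(1 + weighted mean);
  φ by bounded 1-D likelihood maximization over log φ, accepted only when it
  improves the weighted likelihood — a generalized EM whose log-likelihood
  is non-decreasing by construction;
* convergence: mean per-observation log-likelihood change ≤ 1e−9, up to
  4,000 iterations. The tight criterion matters: the geometric-vs-noise-NB
  decomposition at low counts is weakly identified and a looser stop (e.g.
  1e−6 for a few hundred iterations) leaves the noise mean 10–20% off on
  simulated mixtures, whereas full convergence recovers both NB means to
  within a few percent at n = 10⁶. Iterations are cheap enough that the
  tight default costs ~2 s at that scale.
* degenerate inputs (all zeros, or fewer than two distinct nonzero values)
  return `w_zero = 1` with a degeneracy flag; no peaks are callable.

A base is called signal when posterior(signal)/posterior(noise) ≥ 1/5 — the
ratio taken between the two NB components of the three-component posterior
(the shared normalizer cancels). Classification covers every base; the EM
fit itself uses a uniform subsample of at most 10⁶ bases for tractability.
Maximal runs of signal bases become intervals and intervals with gaps
< 500 bp are merged into a position-sorted peak set. With these constants
the method cannot resolve sub-kilobase features: boundaries blur by up to
half the smoothing window on each side, which is why the synthetic peaks
default to 1,500 bp (see below).

## Cell calling and the count matrix

Per barcode we tally total fragments and fragments overlapping any peak
(half-open interval intersection). The cross-droplet contamination
subtraction is operationalized as `fixed = round(0.02 × mean in-peak count
over barcodes with ≥1 fragment)`, clamped at zero — the upstream description
states the intent (fragments originating from another droplet at rate 0.02)
but not the estimator. A two-NB mixture is fitted to the adjusted counts
(EM as above, initialized by splitting at the 90th percentile since most
droplet barcodes are ambient) and a barcode is a cell when posterior odds
signal:noise ≥ 1,000. Degeneracy is declared when the components collapse,
one weight vanishes, or a single NB explains the data at least as well by
BIC — the BIC check catches EM carving a spurious "signal" component out of
one population's tail, in which case the call is all-or-nothing and flagged.

The analysis matrix counts fragment *ends* per peak per cell barcode: a
fragment fully inside a peak contributes 2, a straddling fragment 1. Both
ends count even when they land in the same peak (the alternative — capping
at one — is defensible but undocumented upstream). Non-cell barcodes are
dropped.

## Clustering

IDF weighting multiplies each peak's counts by `log(1 + N/df)` where `df` is
the number of barcodes with a nonzero count at that peak; all-zero peaks are
dropped. The weighted matrix is reduced by truncated SVD (ARPACK with a
seeded start vector; components ordered by singular value; the sign of each
component fixed by making its largest-magnitude peak loading positive), and
each cell's coordinate vector (right singular vectors scaled by singular
values) is normalized to unit L2 norm — the depth normalization in the
reduced space. 15 components by default; the dimensionality is not dictated
by the underlying method description.

k-medoids uses PAM-style alternation (assign to nearest medoid by Euclidean
distance, then per-cluster medoid update) until labels stabilize.
Initialization is a seeded greedy farthest-point rule rather than uniform
sampling: with three equal blobs, uniform init places two medoids in one
blob ~78% of the time and plain alternation cannot recover. k is swept over
3–6 and chosen by maximal mean silhouette, since downstream per-cluster
tests need one labeling.

Graph clustering builds a shared-nearest-neighbor graph (k = 15 neighbors;
edge weight = Jaccard overlap of neighbor sets) and runs greedy modularity
optimization at resolution 0.8, the customary setting for single-cell SNN
graphs — plain modularity (resolution 1) fragments large sparse
neighborhoods even when they form one well-separated population. The
procedure is deterministic; the seed argument exists for interface
uniformity. t-SNE (scikit-learn, PCA init, seeded) provides 2-D coordinates
for plots only and feeds no inference.

## Annotation and term enrichment

Each peak is assigned the gene whose TSS is closest to any peak base
(distance 0 when the TSS lies inside the peak; ties break to the
lexicographically smallest gene name). Term enrichment of the peak-related
gene set uses the upper-tail hypergeometric probability
P = 1 − Σ_{i=0}^{m−1} C(M,i)C(N−M,n−i)/C(N,n) with N the annotated universe,
n the peak-related genes in it, M the term's genes and m the overlap. The
sum is evaluated as the upper tail directly, in log space via log-binomial
coefficients and logsumexp — computing 1 − lower-tail literally would cancel
catastrophically for small probabilities. FDR is Benjamini–Hochberg;
significance requires FDR strictly below 0.05. The universe defaults to all
genes appearing in the term map; KEGG-style maps use the identical code
path. Ontology-graph propagation is out of scope: term maps are taken as
given.

## Motif analysis

PWMs (JASPAR text format) get a pseudocount of 0.8 added to every count
before normalization (pseudocount choice undocumented upstream). Peaks are
ranked by GC fraction and split into 5 equal-frequency buckets; each
bucket's background is the ACGT frequency of its member sequences. Per
bucket and PWM, the exact distribution of the log-odds score of a random
background window is computed by position-wise convolution over scores
discretized at 1e−3 log-odds units, and the threshold is the smallest score
whose upper tail is ≤ 1e−7. When even the maximal score is too likely (flat
or short PWMs, or a skewed background) the threshold is unattainable and the
PWM yields no hits by contract. Both strands are scanned (minus strand =
reverse-complement PWM on the forward sequence); windows containing non-ACGT
bases are skipped; hits are unified across buckets. The 1e−3 resolution was
validated against exhaustive 4^L enumeration for short motifs.

Per-cell motif activity: proportion = (counts in motif-bearing peaks) /
(total counts) per barcode — this already divides by depth, so no second
depth normalization is applied — standardized across barcodes with the
modified z-score (x − median)/(1.4826 × MAD), with z ≡ 0 when the MAD is
zero. Barcodes with zero total counts are excluded.

## Differential accessibility

Relative library size per cell = total cut-site count / median across cells
(zero-total cells excluded); the median of the factors is 1 by construction.
The test, per feature: counts are size-factor normalized; a per-feature NB
dispersion α comes from the method of moments on the pooled within-group
variance of the normalized counts, floored at 1e−8; the Wald statistic is
(log m̂_A − log m̂_B) over its asymptotic standard error with
Var(log m̂_g) = (m_g + α m_g²)/(n_g m_g²); two-sided normal p-values and BH
FDR across features. Group means of zero are floored at half a count per
group (0.5/Σ size factors) so the statistic stays finite and informative.
Because every statistic is a function of the normalized counts alone,
scaling one cell's counts and its size factor together changes nothing.
Features with no counts anywhere report p = 1 and FC = 1. Fold changes are
(m_A + 0.1)/(m_B + 0.1) on normalized means — the pseudocount keeps FC
finite for empty groups. This NB Wald test is the package's concrete,
documented choice for the "fast asymptotic test" family; agreement with
planted truth, not with any specific external implementation, is the
validation surface. For derived per-cell scores (motif z-scores) a Welch
t-test is provided instead, since those are not counts; its reported fold
change is computed on +1-shifted scores so the ratio is defined for
negative values (reporting only).

Filters: `two_sided` keeps p < 0.05 and |log₂FC| > log₂(1.2); `enriched`
keeps p < 0.05 and FC > 2. Both inequalities are strict.

## Pipeline

Stages run in order: correct → dedup/QC → peaks → cells/matrix → cluster →
annotate/enrich → motifs → differential. One global seed derives per-stage
seeds by fixed offsets, so any stage is independently reproducible; all
thresholds live in `PipelineConfig`, defaulted to the constants above, never
hard-coded in stage logic. Each stage records parameters, SHA-256 digests of
its outputs and runtime in a manifest; identical seed + inputs reproduce
identical digests, and a failed stage is recorded and stops the run before
downstream stages. The full standard dataset runs in well under a minute on
one CPU.

## The synthetic-data generator

What it emulates, per seeded `SyntheticConfig`:

* a random genome (2 × 1 Mb, GC 0.41 by default) with `n_peaks = 300`
  planted accessible regions of 1,500 bp, at least 2 kb apart and away from
  chromosome edges;
* three cell types × 200 cells plus 2,000 ambient barcodes, drawn from a
  4,000-entry whitelist of 16-mers with pairwise Hamming distance ≥ 3 (so
  ≤2-substitution correction is unambiguous);
* 40% of peaks shared across types; the rest type-specific, with the
  within-type rate scaled so every peak has the same expected aggregate
  coverage (peak strength is then not confounded with type specificity, and
  the "signal" mixture component is well defined); cross-type leak 0.1;
* per cell, Poisson(200) fragments; each lands in a peak of the cell's type
  or in uniform background, with the background fraction calibrated so the
  least-covered peak's per-base rate is 10× the genome-wide background rate
  — counting both the cells' background fragments and the ambient barcodes'
  emission. Peak fragments lie entirely inside their peak (both transposition
  events in open chromatin); fragment lengths are drawn from a three-mode
  normal mixture (75/250/425 bp at weights 0.55/0.35/0.10 — nucleosome-free,
  mono- and di-nucleosome; the mode positions are conventional defaults, not
  values asserted against any measurement);
* ambient barcodes emit Poisson(20) uniform-background fragments;
* per-record barcode substitution errors at 0.005 per base, and PCR
  duplicates re-emitted with probability 0.2;
* a strong 15 bp PWM whose consensus (GC-balanced so exact-p thresholds stay
  attainable under any bucket background) is written into 80% of the type-0
  peaks, plus an unplanted decoy PWM;
* 1,000 gene models, 25% with TSS inside a peak (accessible promoters), the
  rest anywhere; 40 terms of 10–50 genes plus one planted term drawn from
  peak-proximal genes — the positive control for enrichment. With a small
  genome, every peak is "near" some gene, so the peak-related baseline rate
  must stay well below 1 for enrichment to be detectable at all; the
  25%/1,000 design keeps it near 0.3;
* a case/control split (half of each type) multiplying the accessibility of
  15% of peaks by 3 in case cells.

What it does not emulate: read-level sequencing and alignment, mappability
and repeat structure, realistic genome composition, copy-number or
Tn5-sequence bias, doublets, and per-cell depth heterogeneity beyond
Poisson. Passing tests therefore demonstrate the correctness and internal
consistency of the chain under its own model assumptions — not performance
on real libraries, where dispersion, contamination structure and peak
morphology are all harsher.

## Numerical choices and degenerate inputs

* EM: aggregated-count likelihoods; generalized-EM φ updates; per-observation
  convergence at 1e−9; monotone log-likelihood asserted in tests.
* Posterior odds are computed in log space throughout; mixture weights are
  floored at 1e−300 inside logs.
* The hypergeometric tail and PWM score distributions are exact (log-space
  sums / integer-bin convolutions), not sampled.
* Ties: barcode posterior exactly 0.9 → no correction; nearest-TSS ties →
  lexicographically smallest gene; differential thresholds strict.
* Degenerate inputs: all-zero coverage → flagged mixture, no peaks; empty
  candidate sets → no correction (not an error); zero-norm cells excluded
  before clustering; zero-total cells excluded from size factors; singleton
  clusters skipped in cluster-vs-rest; empty peak lists fall back to a single
  GC bucket.

## Known limitations

* The NB Wald test uses asymptotic normal p-values; at very small group
  sizes (tens of cells) it runs mildly anti-conservative, and no exact or
  permutation fallback is provided.
* Peak boundaries are systematically wider than the underlying accessible
  region by up to half the smoothing window per side; the method cannot
  localize sub-kilobase elements.
* The motif stage plants and detects consensus occurrences; weak/degenerate
  motif occurrences below the exact-p threshold are invisible by design.
* Barcode correction assumes substitution errors only (no indels), matching
  the fixed-length barcode design.
* The pipeline holds per-chromosome base-resolution arrays in memory, which
  is fine at desk scale (megabase genomes) and would need chunking for
  mammalian genomes.
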