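# scatk — a desk-scale single-cell ATAC-seq analysis toolkit

`scatk` reimplements, as a small tested Python package, the fragment-level
analysis chain used to profile chromatin accessibility in single cells:
starting from mapped fragment coordinates it corrects droplet barcodes against
a whitelist, deduplicates read pairs into fragments, computes library QC
(fragment-length periodicity, TSS enrichment), calls open-chromatin peaks with
a zero-inflated count mixture, separates cell from ambient barcodes with a
second mixture, clusters cells by latent semantic analysis of the peak × cell
matrix, annotates peaks by closest TSS with hypergeometric term enrichment,
scores per-cell transcription-factor motif activity from PWM scans, and tests
differential accessibility between cell groups.

It is aimed at method developers and teaching: every stage is an importable,
unit-tested function, and a seeded synthetic-data generator with planted
ground truth (cell types, peaks, motif placements, case/control effects)
makes the whole chain verifiable end to end on a laptop — no downloads, no
alignment step.

## The models at the core

**Peak calling.** Each fragment contributes its two transposition events
(positions `start` and `end − 1`). Per-base event counts are smoothed with a
401 bp moving window and the smoothed counts *y* are modeled as a
three-component mixture

> *y* ~ *w*₀·Geom(*p*) + *w*₁·NB(*μ*_noise, *φ*_noise) + *w*₂·NB(*μ*_signal, *φ*_signal),

with NB(μ, φ) parameterized so Var = μ + μ²/φ, fitted by EM. A base is called
open chromatin when the posterior odds signal:noise reach 1/5; runs of called
bases are merged across gaps under 500 bp.

**Cell calling.** Per barcode, the number of fragments overlapping any peak
is tallied; a depth-dependent fixed count (cross-droplet contamination at
rate 0.02) is subtracted and a two-NB mixture separates cells from ambient
barcodes at posterior odds 1,000.

**Clustering.** The peak × cell matrix is IDF-weighted
(`x · log(1 + N/df)`), reduced by truncated SVD, L2-normalized per cell
(depth normalization), then clustered by PAM k-medoids (k swept 3–6, chosen
by silhouette) and by shared-nearest-neighbor graph communities.

**Annotation & enrichment.** Peaks are assigned to the gene with the closest
TSS; term enrichment of peak-related genes uses the upper-tail
hypergeometric probability

> P = 1 − Σᵢ₌₀^{m−1} C(M,i)·C(N−M,n−i) / C(N,n),

computed in log space, with Benjamini–Hochberg FDR < 0.05.

**Motifs.** Peaks are split into five equal-frequency GC buckets; per bucket
the log-odds threshold matching an exact scan p-value of 1 × 10⁻⁷ is derived
by dynamic programming over the discretized score distribution, both strands
are scanned, and per-cell motif activity is the proportion of counts in
motif-bearing peaks, standardized with a modified z-score
(x − median)/(1.4826 · MAD).

**Differential accessibility.** Per-cell relative library size = total cut
sites / median. Counts are compared cluster-vs-rest or case-vs-control with a
negative-binomial Wald test (method-of-moments dispersion); the stock filters
are p < 0.05 with |FC| > 1.2, or FC > 2 for enriched-only lists.

## Worked example

Generate the standard synthetic dataset (2 Mb genome, 300 planted peaks,
3 cell types × 200 cells plus 2,000 ambient barcodes, a planted motif in the
type-0 peaks and a case/control effect on 15% of peaks), run the full
pipeline, and score it against the planted truth:

```python
import tempfile
from pathlib import Path
from scatk.synthetic import SyntheticConfig, generate_dataset, write_dataset
from scatk.pipeline import PipelineConfig, run_all, report

config = SyntheticConfig(seed=1)
dataset = generate_dataset(config)
tmp = Path(tempfile.mkdtemp())
paths = write_dataset(dataset, tmp / "data")
run_cfg = PipelineConfig(
    fragments=str(paths["fragments"]), whitelist=str(paths["whitelist"]),
    genome=str(paths["genome"]), genes=str(paths["genes"]),
    terms=str(paths["terms"]), pwms=str(paths["pwms"]),
    groups=str(paths["groups"]), out_dir=str(tmp / "run"), seed=5)
run_all(run_cfg)
summary = report(tmp / "run", truth=dataset.truth)

print(summary["clusters"])
for key, value in summary["scorecard"].items():
    print(f"{key}: {value:.3f}")
```

which prints (about a minute on one CPU):

```
         n_cells     ratio
cluster
0            200  0.333333
1            200  0.333333
2            200  0.333333

ari_kmedoids: 1.000
ari_graph: 0.569
peak_jaccard: 0.846
cell_precision: 1.000
cell_recall: 1.000
```

Reading the scorecard: all 600 true cells were called with no ambient
barcodes admitted (precision/recall 1.0); the called peak set overlaps the
planted peaks at base-level Jaccard 0.846 (boundaries blur by roughly the
401 bp smoothing window); k-medoids recovers the three planted cell types
exactly (ARI 1.0). The graph ARI of 0.569 against the three *types* is not a
failure: the dataset also carries a planted case/control effect, and the
graph communities resolve the six type × condition groups (ARI ≈ 0.98
against those joint labels).

The same chain is available as shell commands: `scatk simulate`,
`correct-barcodes`, `qc`, `callpeaks`, `callcells`, `matrix`, `cluster`,
`annotate`, `enrich`, `motifs`, `diff`, and `scatk run --config <yaml>` for
the whole pipeline. See `docs/methods.md` for the modeling details and
design choices.

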