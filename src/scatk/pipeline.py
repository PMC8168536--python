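"""End-to-end orchestration: fragments in, analysis tables out.

Stages run in the Methods order -- barcode correction, deduplication/QC,
peak calling, cell calling and matrix construction, LSA clustering,
TSS annotation with term enrichment, motif scanning/activity, differential
accessibility -- each writing plain-text outputs and recording parameter and
file digests in a manifest, so identical seed + inputs reproduce identical
digests and a run can resume from any completed stage's files.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import barcodes as bcs
from . import cells as cel
from . import cluster as clu
from . import differential as dif
from . import fragments as frg
from . import io as skio
from . import motifs as mot
from . import peaks as pks

# fixed per-stage seed offsets derived from the one pipeline seed
STAGE_SEEDS = {
    "peaks": 101,
    "cells": 202,
    "cluster": 303,
    "tsne": 404,
}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed + STAGE_SEEDS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    """All inputs, stage parameters and the global seed in one place.

    Defaults are the fixed constants of the analysis chain: 401 bp smoothing
    window, odds 1/5 for peak bases and 1,000 for cells, 500 bp peak merging,
    contamination 0.02, motif scan p-value 1e-7, 15 LSA components, k swept
    over 3..6, differential cuts p<0.05 with |FC|>1.2 or FC>2.
    """

    fragments: str = ""
    whitelist: str = ""
    genome: str = ""
    genes: str = ""
    terms: str = ""
    pwms: str = ""
    groups: str = ""
    out_dir: str = "scatk_out"
    seed: int = 0
    window: int = 401
    peak_odds: float = 1.0 / 5.0
    merge_dist: int = 500
    contamination: float = 0.02
    cell_odds: float = 1000.0
    motif_pvalue: float = 1e-7
    gc_buckets: int = 5
    n_components: int = 15
    k_min: int = 3
    k_max: int = 6
    n_neighbors: int = 15
    p_cut: float = 0.05
    fc_cut_two_sided: float = 1.2
    fc_cut_enriched: float = 2.0

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunManifest:
    stages: dict = field(default_factory=dict)

    def record(self, name: str, params: dict, outputs: dict[str, Path],
               runtime: float) -> None:
        self.stages[name] = {
            "params": params,
            "outputs": {str(p): _digest(p) for p in outputs.values()},
            "runtime_s": round(runtime, 3),
        }

    def record_failure(self, name: str, error: str) -> None:
        self.stages[name] = {"failed": True, "error": error}

    def digests(self) -> dict[str, str]:
        out = {}
        for st in self.stages.values():
            out.update(st.get("outputs", {}))
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.stages, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageFailure(RuntimeError):
    """A stage failed; the manifest records it and downstream stages skip."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order, writing outputs under ``out_dir``.

    Raises StageFailure on the first failing stage after recording it in the
    manifest (saved regardless), leaving downstream stages untouched.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    manifest_path = out / "manifest.json"

    try:
        _run_stages(config, out, manifest)
    finally:
        manifest.save(manifest_path)
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: RunManifest):
    seed = config.seed

    # ---- barcode correction ---------------------------------------------
    t0 = time.time()
    raw = skio.read_fragments(config.fragments)
    whitelist = skio.read_whitelist(config.whitelist)
    corrected = bcs.correct_fragments(raw, whitelist)
    p_corr = out / "fragments.corrected.tsv"
    skio.write_fragments(corrected, p_corr)
    manifest.record("correct", {"whitelist": config.whitelist},
                    {"fragments": p_corr}, time.time() - t0)

    # ---- deduplication + QC ---------------------------------------------
    t0 = time.time()
    frags = frg.deduplicate(corrected)
    genes_bed = skio.read_bed6(config.genes)
    qc = frg.tss_enrichment(frags, frg.tss_positions(genes_bed))
    p_frags = out / "fragments.dedup.tsv"
    skio.write_fragments(frags, p_frags)
    p_hist = out / "qc.lengths.tsv"
    qc.length_histogram.rename_axis("length").to_csv(p_hist, sep="\t")
    p_tss = out / "qc.tss.tsv"
    qc.tss_curve.rename_axis("offset").to_csv(p_tss, sep="\t")
    p_qc = out / "qc.json"
    skio.write_json({"tss_enrichment_score": qc.tss_enrichment_score,
                     "n_fragments": int(len(frags))}, p_qc)
    manifest.record("qc", {}, {"fragments": p_frags, "lengths": p_hist,
                              "tss": p_tss, "summary": p_qc}, time.time() - t0)

    # ---- peak calling ----------------------------------------------------
    t0 = time.time()
    genome = skio.read_fasta(config.genome)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    if len(frags) == 0:
        manifest.record_failure("peaks", "no fragments after correction")
        raise StageFailure("peaks", "no fragments after correction")
    peaks, zmodel = pks.call_peaks_from_fragments(
        frags, chrom_sizes, seed=_stage_seed(seed, "peaks"),
        window=config.window, odds=config.peak_odds,
        merge_dist=config.merge_dist,
    )
    if zmodel.degenerate or len(peaks) == 0:
        manifest.record_failure("peaks", "degenerate coverage: no peaks callable")
        raise StageFailure("peaks", "degenerate coverage: no peaks callable")
    p_peaks = out / "peaks.bed"
    peaks.to_bed(p_peaks)
    p_model = out / "peaks.model.json"
    skio.write_json({k: v for k, v in asdict(zmodel).items()
                     if k != "loglik_history"}, p_model)
    manifest.record("peaks", {"window": config.window, "odds": config.peak_odds,
                              "merge_dist": config.merge_dist},
                    {"peaks": p_peaks, "model": p_model}, time.time() - t0)

    # ---- cell calling + matrix ------------------------------------------
    t0 = time.time()
    stats = cel.barcode_stats(frags, peaks)
    cmodel, cell_set = cel.call_cells(
        stats, seed=_stage_seed(seed, "cells"),
        odds_threshold=config.cell_odds, contamination=config.contamination,
    )
    matrix = cel.build_matrix(frags, peaks, cell_set)
    p_cells = out / "cells.txt"
    with open(p_cells, "w") as fh:
        fh.write("\n".join(sorted(cell_set)) + "\n")
    matrix.to_files(out / "matrix")
    p_cmodel = out / "cells.model.json"
    skio.write_json({k: v for k, v in asdict(cmodel).items()
                     if k != "loglik_history"}, p_cmodel)
    manifest.record(
        "cells", {"contamination": config.contamination,
                  "odds": config.cell_odds},
        {"cells": p_cells, "matrix": out / "matrix.mtx",
         "peaks": out / "matrix.peaks.bed",
         "barcodes": out / "matrix.barcodes.tsv", "model": p_cmodel},
        time.time() - t0,
    )

    # ---- clustering ------------------------------------------------------
    t0 = time.time()
    weighted = clu.idf_normalize(matrix)
    emb = clu.l2_depth_normalize(
        clu.lsa_embed(weighted, n_components=config.n_components,
                      seed=_stage_seed(seed, "cluster"))
    )
    km = clu.kmedoids_sweep(emb, config.k_min, config.k_max,
                            seed=_stage_seed(seed, "cluster"))
    gc_labels = clu.graph_cluster(emb, n_neighbors=config.n_neighbors,
                                  seed=_stage_seed(seed, "cluster"))
    coords = clu.embed_2d(emb, seed=_stage_seed(seed, "tsne"))
    p_emb = out / "embedding.tsv"
    emb.to_frame().rename_axis("barcode").to_csv(p_emb, sep="\t")
    p_lab = out / "clusters.tsv"
    pd.DataFrame({"kmedoids": km.labels, "graph": gc_labels.labels}).rename_axis(
        "barcode"
    ).to_csv(p_lab, sep="\t")
    p_tsne = out / "tsne.tsv"
    coords.rename_axis("barcode").to_csv(p_tsne, sep="\t")
    manifest.record("cluster", {"n_components": config.n_components,
                                "k": km.k},
                    {"embedding": p_emb, "labels": p_lab, "tsne": p_tsne},
                    time.time() - t0)

    # ---- annotation + enrichment ----------------------------------------
    t0 = time.time()
    gene_models = ann.genes_from_bed(genes_bed)
    peak_to_gene = ann.nearest_tss(peaks, gene_models)
    term_map = skio.read_term_map(config.terms)
    peak_genes = set(peak_to_gene.dropna())
    enr = ann.enrich_terms(peak_genes, term_map)
    p_ann = out / "peak_genes.tsv"
    pd.DataFrame({"chrom": peaks.intervals["chrom"],
                  "start": peaks.intervals["start"],
                  "end": peaks.intervals["end"],
                  "gene": peak_to_gene}).to_csv(p_ann, sep="\t", index=False)
    p_enr = out / "enrichment.tsv"
    ann.enrichment_table(enr).to_csv(p_enr, sep="\t", index=False)
    manifest.record("annotate", {}, {"peak_genes": p_ann, "enrichment": p_enr},
                    time.time() - t0)

    # ---- motifs ----------------------------------------------------------
    t0 = time.time()
    pwms = mot.read_jaspar(config.pwms)
    seqs = mot.peak_sequences(peaks, genome)
    buckets, backgrounds = mot.gc_buckets(seqs, config.gc_buckets)
    hit_frames = [mot.scan(seqs, p, buckets, backgrounds,
                           pvalue=config.motif_pvalue) for p in pwms]
    hits = mot.concat_hits(hit_frames)
    props = mot.motif_proportions(matrix, hits)
    zscores = mot.motif_zscores(props) if not props.empty else props
    p_hits = out / "motif_hits.tsv"
    hits.to_csv(p_hits, sep="\t", index=False)
    p_z = out / "motif_zscores.tsv"
    zscores.rename_axis("barcode").to_csv(p_z, sep="\t")
    manifest.record("motifs", {"pvalue": config.motif_pvalue,
                               "gc_buckets": config.gc_buckets},
                    {"hits": p_hits, "zscores": p_z}, time.time() - t0)

    # ---- differential ----------------------------------------------------
    t0 = time.time()
    factors = dif.size_factors(matrix.column_totals(), index=matrix.barcodes)
    kept = [b in factors.index for b in matrix.barcodes]
    counts = matrix.matrix[:, np.flatnonzero(kept)]
    bcs_kept = [b for b, k in zip(matrix.barcodes, kept) if k]
    fac = factors.loc[bcs_kept].to_numpy()
    labels = km.labels.loc[bcs_kept]
    feature_ids = [f"{r.chrom}:{r.start}-{r.end}"
                   for r in matrix.peaks.itertuples(index=False)]
    per_cluster = dif.cluster_vs_rest(counts, labels, fac,
                                      feature_ids=feature_ids)
    outputs = {}
    cfg2 = dif.ThresholdConfig(config.p_cut, config.fc_cut_two_sided)
    summary_rows = []
    for cl, res in per_cluster.items():
        p_res = out / f"diff.cluster{cl}.tsv"
        res.to_csv(p_res, sep="\t", index=False)
        outputs[f"cluster{cl}"] = p_res
        _, n_two = dif.apply_thresholds(res, cfg2, "two_sided")
        summary_rows.append({"cluster": cl, "n_cells": int((labels == cl).sum()),
                             "n_diff_peaks": n_two})
    # case vs control when group labels are provided
    if config.groups:
        groups = pd.read_csv(config.groups, sep="\t", header=None,
                             names=["barcode", "group"], index_col=0)["group"]
        gA = np.array([groups.get(b) == "case" for b in bcs_kept])
        gB = np.array([groups.get(b) == "control" for b in bcs_kept])
        if gA.any() and gB.any():
            res_cc = dif.nb_test(counts, gA, gB, fac, feature_ids=feature_ids)
            p_cc = out / "diff.case_control.tsv"
            res_cc.to_csv(p_cc, sep="\t", index=False)
            outputs["case_control"] = p_cc
    p_sum = out / "diff.summary.tsv"
    pd.DataFrame(summary_rows).to_csv(p_sum, sep="\t", index=False)
    outputs["summary"] = p_sum
    manifest.record("differential",
                    {"p_cut": config.p_cut,
                     "fc_two_sided": config.fc_cut_two_sided,
                     "fc_enriched": config.fc_cut_enriched},
                    outputs, time.time() - t0)


def report(out_dir, truth=None) -> dict:
    """Summaries of a completed run; with truth, a recovery scorecard.

    Returns per-cluster cell counts/ratios, differential peak counts at the
    standard cuts, the enrichment table, and (when the generator's truth is
    supplied) ARI against planted types, peak Jaccard and cell-call
    precision/recall.
    """
    out = Path(out_dir)
    if not (out / "clusters.tsv").exists():
        raise FileNotFoundError("clustering outputs missing: stage 'cluster'")
    labels = pd.read_csv(out / "clusters.tsv", sep="\t", index_col=0)
    counts = labels["kmedoids"].value_counts().sort_index()
    summary = pd.DataFrame({
        "n_cells": counts,
        "ratio": counts / counts.sum(),
    }).rename_axis("cluster")
    diff_summary = pd.read_csv(out / "diff.summary.tsv", sep="\t")
    enrichment = pd.read_csv(out / "enrichment.tsv", sep="\t")
    result = {"clusters": summary, "differential": diff_summary,
              "enrichment": enrichment}

    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        bt = truth.barcode_to_type
        common = [b for b in labels.index if bt.get(b, AMBIENT_LABEL) != AMBIENT_LABEL]
        true_lab = [bt[b] for b in common]
        result["scorecard"] = {
            "ari_kmedoids": adjusted_rand_score(
                true_lab, labels.loc[common, "kmedoids"]),
            "ari_graph": adjusted_rand_score(
                true_lab, labels.loc[common, "graph"]),
        }
        called = pks.PeakSet.from_bed(out / "peaks.bed")
        result["scorecard"]["peak_jaccard"] = pks.jaccard(
            called, pks.PeakSet(truth.true_peaks))
        with open(out / "cells.txt") as fh:
            called_cells = {line.strip() for line in fh if line.strip()}
        true_cells = set(truth.cell_barcodes())
        tp = len(called_cells & true_cells)
        result["scorecard"]["cell_precision"] = (
            tp / len(called_cells) if called_cells else 0.0)
        result["scorecard"]["cell_recall"] = (
            tp / len(true_cells) if true_cells else 0.0)
    return result


AMBIENT_LABEL = "ambient"
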