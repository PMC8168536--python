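"""Shared fixtures: one standard synthetic dataset processed once per session.

The standard dataset (2 Mb genome, 300 peaks, 3 types x 200 cells) is
expensive enough that every consumer shares the same session-scoped products:
corrected/deduplicated fragments, called peaks, cell matrix and embedding.
A small config is provided for cheap per-test generation.
"""

from __future__ import annotations

import numpy as np
import pytest

from scatk import barcodes as bcs
from scatk import cells as cel
from scatk import cluster as clu
from scatk import fragments as frg
from scatk import peaks as pks
from scatk.synthetic import SyntheticConfig, generate_dataset

STD_SEED = 1


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A miniature dataset for fast unit tests (~1/20 the standard size)."""
    base = dict(
        seed=seed,
        n_chroms=1,
        chrom_length=150_000,
        n_cell_types=2,
        cells_per_type=30,
        n_ambient_barcodes=120,
        n_peaks=15,
        peak_width=800,
        min_peak_gap=1500,
        edge_margin=2000,
        fragments_per_cell_mean=120.0,
        ambient_fragments_mean=10.0,
        whitelist_size=400,
        n_genes=120,
        n_terms=10,
        planted_term_size=10,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def std_config():
    return SyntheticConfig(seed=STD_SEED)


@pytest.fixture(scope="session")
def std_dataset(std_config):
    """Standard dataset with a case/control split."""
    return generate_dataset(std_config)


@pytest.fixture(scope="session")
def std_fragments(std_dataset):
    """Corrected + deduplicated fragments of the standard dataset."""
    corrected = bcs.correct_fragments(std_dataset.fragments,
                                      std_dataset.whitelist)
    return frg.deduplicate(corrected)


@pytest.fixture(scope="session")
def std_peaks(std_dataset, std_fragments, std_config):
    peaks, model = pks.call_peaks_from_fragments(
        std_fragments, std_config.chrom_sizes(), seed=101
    )
    return peaks, model


@pytest.fixture(scope="session")
def std_matrix(std_dataset, std_fragments, std_peaks):
    peaks, _ = std_peaks
    stats = cel.barcode_stats(std_fragments, peaks)
    model, cell_set = cel.call_cells(stats, seed=202)
    matrix = cel.build_matrix(std_fragments, peaks, cell_set)
    return matrix, model, cell_set


@pytest.fixture(scope="session")
def nogroup_embedding():
    """LSA embedding of the standard dataset generated WITHOUT a case/control
    split: the planted structure is then exactly the three cell types."""
    config = SyntheticConfig(seed=STD_SEED)
    ds = generate_dataset(config, with_groups=False)
    frags = frg.deduplicate(bcs.correct_fragments(ds.fragments, ds.whitelist))
    peaks, _ = pks.call_peaks_from_fragments(frags, config.chrom_sizes(),
                                             seed=101)
    stats = cel.barcode_stats(frags, peaks)
    _, cell_set = cel.call_cells(stats, seed=202)
    matrix = cel.build_matrix(frags, peaks, cell_set)
    emb = clu.l2_depth_normalize(
        clu.lsa_embed(clu.idf_normalize(matrix), seed=303)
    )
    truth_types = np.array([ds.truth.barcode_to_type[b] for b in emb.barcodes])
    return emb, truth_types


@pytest.fixture(scope="session")
def std_pipeline_runs(tmp_path_factory, std_dataset):
    """Two full pipeline runs (same seed) on the written standard dataset."""
    from scatk.pipeline import PipelineConfig, run_all
    from scatk.synthetic import write_dataset

    root = tmp_path_factory.mktemp("pipeline")
    paths = write_dataset(std_dataset, root / "data")
    manifests = []
    for name in ("run1", "run2"):
        cfg = PipelineConfig(
            fragments=str(paths["fragments"]),
            whitelist=str(paths["whitelist"]),
            genome=str(paths["genome"]),
            genes=str(paths["genes"]),
            terms=str(paths["terms"]),
            pwms=str(paths["pwms"]),
            groups=str(paths["groups"]),
            out_dir=str(root / name),
            seed=5,
        )
        manifests.append(run_all(cfg))
    return root, manifests
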