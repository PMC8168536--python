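"""Generator contracts: determinism, planted truth, marginal statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scatk import io as skio
from scatk.synthetic import (
    SyntheticConfig,
    SyntheticTruth,
    generate_dataset,
    generate_genome,
    generate_whitelist,
    simulate_fragments,
    write_dataset,
)
from conftest import small_config


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    dirs = []
    for name in ("a", "b"):
        ds = generate_dataset(small_config(seed=5))
        paths = write_dataset(ds, tmp_path / name)
        dirs.append(paths)
    for key in dirs[0]:
        assert dirs[0][key].read_bytes() == dirs[1][key].read_bytes(), key


def test_no_peaks_means_empty_truth():
    cfg = small_config(seed=0, n_peaks=0, planted_motifs=(), diff_fraction=0.0)
    genome, truth = generate_genome(cfg)
    assert len(truth.true_peaks) == 0
    assert len(truth.planted_motif_sites) == 0
    assert len(genome["chr1"]) == cfg.chrom_length


def test_peaks_that_cannot_fit_raise():
    cfg = small_config(seed=0, n_peaks=500)
    with pytest.raises(ValueError, match="fit"):
        generate_genome(cfg)


def test_motif_planting_fraction_and_recorded_sites():
    cfg = small_config(seed=2, n_peaks=20, planted_motifs=(("SYN1", 0.5, None),))
    genome, truth = generate_genome(cfg)
    sites = truth.planted_motif_sites
    assert len(sites) == 10  # 0.5 * 20 peaks
    assert sites["peak"].is_unique
    # the consensus (or its reverse complement) really is in the genome
    from scatk.synthetic import default_pwms, _revcomp

    pwm = default_pwms(cfg)[0]
    cons = pwm.consensus()
    for row in sites.itertuples(index=False):
        seq = genome[row.chrom][row.start:row.end]
        assert seq == (cons if row.strand == "+" else _revcomp(cons))


def test_empty_cell_layout_gives_empty_stream():
    cfg = small_config(seed=0, cells_per_type=0, n_ambient_barcodes=0)
    ds = generate_dataset(cfg)
    assert len(ds.fragments) == 0


def test_total_fragments_within_poisson_bounds():
    cfg = small_config(seed=3, n_cell_types=2, cells_per_type=50,
                       n_ambient_barcodes=0, fragments_per_cell_mean=200.0,
                       duplicate_rate=0.0)
    ds = generate_dataset(cfg, with_groups=False)
    expected = 100 * 200
    sd = np.sqrt(expected)
    assert abs(len(ds.fragments) - expected) < 3 * sd


def test_zero_error_rate_emits_only_whitelisted_barcodes():
    cfg = small_config(seed=4, barcode_error_rate=0.0)
    ds = generate_dataset(cfg)
    assert set(ds.fragments["barcode"]) <= set(ds.whitelist)


def test_whitelist_min_pairwise_distance():
    wl = generate_whitelist(150, 16, min_dist=3, seed=9)
    codes = np.array([[("ACGT".index(c)) for c in b] for b in wl])
    d = (codes[:, None, :] != codes[None, :, :]).sum(axis=2)
    np.fill_diagonal(d, 99)
    assert d.min() >= 3


def test_per_cell_counts_consistent_with_poisson():
    """Chi-square goodness of fit of realized per-cell fragment counts."""
    cfg = small_config(seed=6, n_cell_types=2, cells_per_type=500,
                       n_ambient_barcodes=0, whitelist_size=1100,
                       fragments_per_cell_mean=50.0, duplicate_rate=0.0,
                       barcode_error_rate=0.0)
    ds = generate_dataset(cfg, with_groups=False)
    counts = ds.fragments.groupby("barcode").size()
    counts = counts.reindex(ds.truth.cell_barcodes(), fill_value=0).to_numpy()
    lam = 50.0
    # half-integer bin edges align the histogram with the discrete CDF
    edges = stats.poisson.ppf(np.linspace(0.05, 0.95, 10), lam) + 0.5
    edges = np.unique(np.concatenate([[-np.inf], edges, [np.inf]]))
    obs, _ = np.histogram(counts, bins=edges)
    probs = np.diff(stats.poisson.cdf(edges, lam))
    chi2 = ((obs - len(counts) * probs) ** 2 / (len(counts) * probs)).sum()
    p = stats.chi2.sf(chi2, df=len(obs) - 1)
    assert p > 0.01


def test_fragment_length_modes_match_config(std_dataset, std_config):
    from scatk.fragments import histogram_modes, length_histogram

    # background fragments are unconstrained by peak width; use them
    hist = length_histogram(std_dataset.fragments)
    modes = histogram_modes(hist)
    configured = [m[0] for m in std_config.frag_len_modes]
    assert len(modes) == len(configured)
    for found, want in zip(modes, configured):
        assert abs(found - want) <= 10


def test_fragments_file_round_trip_and_sorted(tmp_path):
    ds = generate_dataset(small_config(seed=8))
    paths = write_dataset(ds, tmp_path)
    back = skio.read_fragments(paths["fragments"])
    pd.testing.assert_frame_equal(
        back, ds.fragments[back.columns], check_dtype=False
    )
    assert (back.groupby("chrom")["start"].apply(
        lambda s: (s.diff().dropna() >= 0).all())).all()


def test_truth_round_trips_through_json(tmp_path):
    ds = generate_dataset(small_config(seed=8))
    paths = write_dataset(ds, tmp_path)
    loaded = SyntheticTruth.from_dict(skio.read_json(paths["truth"]))
    assert loaded.barcode_to_type == ds.truth.barcode_to_type
    assert np.array_equal(loaded.diff_peaks, ds.truth.diff_peaks)
    pd.testing.assert_frame_equal(loaded.true_peaks, ds.truth.true_peaks)


def test_case_cells_are_enriched_in_diff_peaks():
    cfg = small_config(seed=10, diff_fraction=0.3, diff_fold=4.0,
                       barcode_error_rate=0.0, duplicate_rate=0.0)
    ds = generate_dataset(cfg, with_groups=True)
    truth, frags = ds.truth, ds.fragments
    peaks = truth.true_peaks
    dp = peaks.iloc[truth.diff_peaks]

    def in_diff_rate(group):
        cells = [b for b, g in ds.groups.items() if g == group]
        sub = frags[frags["barcode"].isin(cells)]
        mids = (sub["start"] + sub["end"]) // 2
        hit = np.zeros(len(sub), bool)
        for row in dp.itertuples(index=False):
            hit |= ((sub["chrom"] == row.chrom) & (mids >= row.start)
                    & (mids < row.end)).to_numpy()
        return hit.mean()

    assert in_diff_rate("case") > 1.5 * in_diff_rate("control")


def test_invalid_configs_are_rejected():
    with pytest.raises(ValueError):
        small_config(barcode_error_rate=1.5).validate()
    with pytest.raises(ValueError):
        small_config(diff_fold=-1.0).validate()
    with pytest.raises(ValueError):
        small_config(frag_len_modes=((100.0, 10.0, 0.5),)).validate()
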