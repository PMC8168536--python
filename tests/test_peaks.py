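"""Event counting, smoothing, ZINB mixture fitting and peak calling."""

import numpy as np
import pandas as pd
import pytest

from scatk.mixtures import fit_zinba, nb_logpmf
from scatk.peaks import (
    PeakSet,
    call_peaks,
    count_events,
    merge_intervals,
    smooth,
)


def _frags(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode"])
    df["count"] = 1
    return df


def test_events_land_on_start_and_last_base():
    track = count_events(_frags([("chr1", 100, 250, "AA")]), {"chr1": 300})
    assert track["chr1"][100] == 1
    assert track["chr1"][249] == 1
    assert track["chr1"].sum() == 2


def test_shared_start_accumulates():
    track = count_events(
        _frags([("chr1", 5, 50, "AA"), ("chr1", 5, 80, "CC")]), {"chr1": 100}
    )
    assert track["chr1"][5] == 2


def test_total_events_is_twice_fragment_count():
    rng = np.random.default_rng(0)
    starts = rng.integers(0, 900, 500)
    rows = [("chr1", int(s), int(s) + 50, "AA") for s in starts]
    track = count_events(_frags(rows), {"chr1": 1000})
    assert track["chr1"].sum() == 2 * 500


def test_out_of_bounds_fragments_are_dropped():
    track = count_events(
        _frags([("chr1", 990, 1020, "AA"), ("chr1", 10, 20, "AA")]),
        {"chr1": 1000},
    )
    assert track["chr1"].sum() == 2


def test_single_event_smooths_to_a_plateau():
    track = np.zeros(1001, dtype=np.int32)
    track[500] = 1
    sm = smooth(track, 401)
    assert (sm[300:701] == 1).all()
    assert sm[299] == 0 and sm[701] == 0
    assert smooth(np.zeros(50, np.int32), 401).sum() == 0


def test_smooth_matches_bruteforce_window_sum():
    rng = np.random.default_rng(3)
    track = rng.poisson(0.3, 10_000).astype(np.int32)
    sm = smooth(track, 401)
    brute = np.array([
        track[max(0, i - 200): i + 201].sum() for i in range(track.size)
    ])
    assert np.array_equal(sm, brute)


def test_even_window_is_rejected():
    with pytest.raises(ValueError, match="odd"):
        smooth(np.zeros(10, np.int32), 400)


def test_all_zero_fit_is_degenerate():
    model = fit_zinba(np.zeros(5000, dtype=np.int64), seed=0)
    assert model.degenerate
    assert model.w_zero == 1.0


def test_em_loglik_never_decreases():
    rng = np.random.default_rng(5)
    vals = np.concatenate([
        rng.poisson(1.0, 20_000), rng.negative_binomial(2, 0.1, 2_000)
    ])
    model = fit_zinba(vals, seed=5)
    hist = np.array(model.loglik_history)
    assert (np.diff(hist) >= -1e-7 * (1 + np.abs(hist[:-1]))).all()


def test_mixture_parameter_recovery_small():
    """Moderate-size version of the planted three-component recovery."""
    rng = np.random.default_rng(1)
    n = 200_000
    comp = rng.choice(3, size=n, p=[0.70, 0.25, 0.05])
    vals = np.empty(n, dtype=np.int64)
    vals[comp == 0] = rng.geometric(0.9, (comp == 0).sum()) - 1
    vals[comp == 1] = rng.negative_binomial(1, 1 / 3, (comp == 1).sum())
    vals[comp == 2] = rng.negative_binomial(2, 2 / 32, (comp == 2).sum())
    model = fit_zinba(vals, seed=1)
    assert abs(model.mu_signal - 30) / 30 < 0.10
    assert abs(model.mu_noise - 2) / 2 < 0.10


def test_merge_rule_on_constructed_intervals():
    df = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [100, 400],
                       "end": [200, 500]})
    merged = merge_intervals(df, merge_dist=500)
    assert merged.to_dict("records") == [
        {"chrom": "chr1", "start": 100, "end": 500}
    ]
    kept = merge_intervals(df, merge_dist=200)  # gap == merge_dist: kept
    assert len(kept) == 2


def test_no_signal_means_empty_peakset(std_peaks):
    _, model = std_peaks
    # threshold so high that no base can pass
    empty = call_peaks({"chr1": np.zeros(1000, np.int64)}, model)
    assert len(empty) == 0


def test_threshold_equals_direct_density_evaluation(std_peaks, std_fragments,
                                                    std_config):
    """call_peaks equals plain thresholding at the smallest count whose
    posterior odds (evaluated directly from the fitted densities) reach 1/5."""
    peaks, model = std_peaks
    ks = np.arange(0, 5000)
    log_odds = (
        np.log(model.w_signal)
        + nb_logpmf(ks, model.mu_signal, model.phi_signal)
        - np.log(model.w_noise)
        - nb_logpmf(ks, model.mu_noise, model.phi_noise)
    )
    called = log_odds >= np.log(1 / 5)
    c = int(np.argmax(called))  # odds monotone here: contiguous upper set
    assert called[c:].all()
    assert peaks.threshold_count == c

    smoothed = smooth(count_events(std_fragments, std_config.chrom_sizes()))
    simple = merge_intervals(
        pd.concat([
            _runs_to_df(chrom, vals >= c) for chrom, vals in smoothed.items()
        ], ignore_index=True),
        merge_dist=500,
    )
    recomputed = call_peaks(smoothed, model)
    pd.testing.assert_frame_equal(
        recomputed.intervals.sort_values(["chrom", "start"]).reset_index(drop=True),
        simple.sort_values(["chrom", "start"]).reset_index(drop=True),
        check_dtype=False,
    )


def _runs_to_df(chrom, mask):
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(np.int8),
                                                   [0]])))
    return pd.DataFrame({"chrom": chrom, "start": edges[::2],
                         "end": edges[1::2]})


def test_raising_odds_never_adds_called_bases(std_peaks, std_fragments,
                                              std_config):
    _, model = std_peaks
    smoothed = smooth(count_events(std_fragments, std_config.chrom_sizes()))
    loose = call_peaks(smoothed, model, odds=1 / 5)
    strict = call_peaks(smoothed, model, odds=1.0, merge_dist=0)
    loose_mask = {c: np.zeros(n, bool) for c, n in std_config.chrom_sizes().items()}
    for r in loose.intervals.itertuples(index=False):
        loose_mask[r.chrom][r.start:r.end] = True
    for r in strict.intervals.itertuples(index=False):
        assert loose_mask[r.chrom][r.start:r.end].all()


def test_posterior_odds_monotone_above_noise_mean(std_peaks):
    _, model = std_peaks
    ks = np.arange(int(np.ceil(model.mu_noise)) + 1, 5000)
    lo = model.log_odds_signal_noise(ks)
    assert (np.diff(lo) >= -1e-9).all()


def test_peakset_bed_round_trip(tmp_path, std_peaks):
    peaks, _ = std_peaks
    path = tmp_path / "peaks.bed"
    peaks.to_bed(path)
    back = PeakSet.from_bed(path)
    pd.testing.assert_frame_equal(back.intervals, peaks.intervals)
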