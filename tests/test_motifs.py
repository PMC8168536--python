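"""PWM threshold DP, scanning, GC buckets, proportions and MAD z-scores."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scatk.cells import PeakBarcodeMatrix
from scatk.motifs import (
    Pwm,
    gc_buckets,
    mad_zscore,
    motif_proportions,
    motif_zscores,
    read_jaspar,
    scan,
    score_distribution,
    score_threshold,
    window_scores,
    encode_sequence,
    write_jaspar,
)

UNIFORM = np.full(4, 0.25)


def _consensus_pwm(cons, strength=85.0, other=5.0):
    counts = np.full((4, len(cons)), other)
    for j, b in enumerate(cons):
        counts["ACGT".index(b), j] = strength
    return Pwm("TST1", "TEST", counts)


def test_dp_tail_matches_exhaustive_enumeration():
    """Exact DP score distribution equals brute force over all 4^L windows."""
    rng = np.random.default_rng(2)
    for L, bg in ((4, UNIFORM), (5, np.array([0.3, 0.2, 0.2, 0.3])),
                  (6, UNIFORM)):
        pwm = Pwm("r", "r", rng.integers(1, 50, size=(4, L)).astype(float))
        lom_bins = np.round(pwm.log_odds(bg) / 1e-3).astype(np.int64)
        scores, probs = score_distribution(pwm, bg)
        brute = {}
        for word in itertools.product(range(4), repeat=L):
            key = sum(int(lom_bins[b, j]) for j, b in enumerate(word))
            p = float(np.prod([bg[b] for b in word]))
            brute[key] = brute.get(key, 0.0) + p
        for target in np.quantile(scores, [0.1, 0.5, 0.9, 0.999]):
            dp_tail = probs[scores >= target].sum()
            bf_tail = sum(p for k, p in brute.items() if k * 1e-3 >= target)
            assert dp_tail == pytest.approx(bf_tail, rel=1e-9, abs=1e-12)


def test_point_mass_consensus_threshold():
    """Near-deterministic length-8 PWM: the top score is reached only by the
    consensus word, with background probability exactly 4^-8 ~ 1.5e-5.
    Requesting a p-value just above 4^-8 therefore yields a threshold that
    only the consensus clears; below 4^-8 no window can ever pass."""
    cons = "ACGTACGT"
    counts = np.zeros((4, 8))
    for j, b in enumerate(cons):
        counts["ACGT".index(b), j] = 100.0
    pwm = Pwm("c", "c", counts)
    lom = pwm.log_odds(UNIFORM)
    max_score = lom.max(axis=0).sum()
    one_off = max_score - (lom.max(axis=0) - np.sort(lom, axis=0)[-2]).min()
    thr = score_threshold(pwm, UNIFORM, pvalue=4 ** -8.0 + 1e-9)
    assert one_off < thr <= max_score + 5e-3
    scores, probs = score_distribution(pwm, UNIFORM)
    assert probs[scores >= thr].sum() == pytest.approx(4 ** -8.0, rel=1e-9)
    assert score_threshold(pwm, UNIFORM, pvalue=1e-7) == np.inf


def test_flat_pwm_is_unattainable():
    pwm = Pwm("f", "f", np.ones((4, 6)))
    assert score_threshold(pwm, UNIFORM, pvalue=1e-7) == np.inf


def test_pvalue_validation():
    pwm = Pwm("f", "f", np.ones((4, 6)))
    with pytest.raises(ValueError):
        score_threshold(pwm, UNIFORM, pvalue=0.0)


def test_minus_strand_consensus_yields_one_hit():
    rng = np.random.default_rng(4)
    cons = "AACCGGTTACGTGCA"
    pwm = _consensus_pwm(cons)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(cons))
    seq = "".join(rng.choice(list("ACGT"), 200)) + rc + \
        "".join(rng.choice(list("ACGT"), 185))
    hits = scan([seq], pwm, np.array([0]), [UNIFORM], pvalue=1e-7)
    assert len(hits) == 1
    assert hits.iloc[0]["strand"] == "-"
    assert hits.iloc[0]["offset"] == 200


def test_null_sequence_produces_no_hits():
    """10 kb of 40% GC background: expected false positives ~ 2e4 * 1e-7."""
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), 10_000,
                             p=[0.3, 0.2, 0.2, 0.3]))
    pwm = _consensus_pwm("AACCGGTTACGTGCA")
    hits = scan([seq], pwm, np.array([0]),
                [np.array([0.3, 0.2, 0.2, 0.3])], pvalue=1e-7)
    assert len(hits) == 0


def test_scan_matches_per_window_rescoring():
    rng = np.random.default_rng(6)
    pwm = _consensus_pwm("ACGTAACCGGTTAGC", strength=20.0, other=8.0)
    seqs = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(100)]
    buckets = np.zeros(len(seqs), dtype=int)
    hits = scan(seqs, pwm, buckets, [UNIFORM], pvalue=1e-3)
    thr = score_threshold(pwm, UNIFORM, pvalue=1e-3)
    lom = pwm.log_odds(UNIFORM)
    lom_rc = pwm.reverse_complement().log_odds(UNIFORM)
    expected = []
    for i, seq in enumerate(seqs):
        for strand, mat in (("+", lom), ("-", lom_rc)):
            for off in range(len(seq) - pwm.length + 1):
                s = sum(mat["ACGT".index(seq[off + j]), j]
                        for j in range(pwm.length))
                if s >= thr:
                    expected.append((i, off, strand, round(s, 9)))
    got = [(r.peak, r.offset, r.strand, round(r.score, 9))
           for r in hits.itertuples(index=False)]
    assert sorted(got) == sorted(expected)


def test_strand_symmetry_of_scanning():
    """Scanning the reverse-complement genome mirrors the hit list."""
    rng = np.random.default_rng(7)
    pwm = _consensus_pwm("ACGTAACCGGTTAGC", strength=30.0, other=6.0)
    seq = "".join(rng.choice(list("ACGT"), 500))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rcseq = "".join(comp[b] for b in reversed(seq))
    fwd = scan([seq], pwm, np.array([0]), [UNIFORM], pvalue=1e-3)
    rev = scan([rcseq], pwm, np.array([0]), [UNIFORM], pvalue=1e-3)
    flip = {"+": "-", "-": "+"}
    mirrored = sorted(
        (len(seq) - pwm.length - r.offset, flip[r.strand], round(r.score, 9))
        for r in rev.itertuples(index=False)
    )
    direct = sorted((r.offset, r.strand, round(r.score, 9))
                    for r in fwd.itertuples(index=False))
    assert direct == mirrored


def test_gc_bucket_sizes_and_background():
    rng = np.random.default_rng(8)
    seqs = ["".join(rng.choice(list("ACGT"), 400)) for _ in range(23)]
    assignment, backgrounds = gc_buckets(seqs, n_buckets=5)
    sizes = np.bincount(assignment)
    assert sizes.max() - sizes.min() <= 1
    gc = np.array([(s.count("G") + s.count("C")) / len(s) for s in seqs])
    order = np.argsort(assignment, kind="mergesort")
    assert (np.diff(gc[np.argsort(gc)]) >= 0).all()  # sanity
    # bucket-mean GC must be non-decreasing with bucket index
    means = [gc[assignment == b].mean() for b in range(5)]
    assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))
    pooled = sum(
        backgrounds[b] * (assignment == b).sum() for b in range(5)
    ) / len(seqs)
    np.testing.assert_allclose(pooled, UNIFORM, atol=0.02)


def test_single_bucket_fallback():
    assignment, backgrounds = gc_buckets(["ACGT" * 10], n_buckets=5)
    assert len(backgrounds) == 1
    assert (assignment == 0).all()


def test_proportions_are_count_ratios():
    mat = PeakBarcodeMatrix(
        sp.csr_matrix(np.array([[4, 0], [6, 3], [0, 7]])),
        pd.DataFrame({"chrom": ["chr1"] * 3, "start": [0, 10, 20],
                      "end": [5, 15, 25]}),
        ["b1", "b2"],
    )
    hits = pd.DataFrame({"pwm": ["m"], "peak": [0], "offset": [0],
                         "strand": ["+"], "score": [1.0]})
    props = motif_proportions(mat, hits)
    assert props.loc["b1", "m"] == pytest.approx(0.4)
    assert props.loc["b2", "m"] == pytest.approx(0.0)
    all_hits = pd.DataFrame({"pwm": ["m"] * 3, "peak": [0, 1, 2],
                             "offset": [0] * 3, "strand": ["+"] * 3,
                             "score": [1.0] * 3})
    allp = motif_proportions(mat, all_hits)
    assert (allp["m"] == 1.0).all()


def test_mad_zscore_worked_example():
    z = mad_zscore(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
    assert z[2] == 0.0
    assert z[4] == pytest.approx(97 / 1.4826, rel=1e-12)


def test_mad_zero_rule_and_input_validation():
    assert (mad_zscore(np.full(8, 3.3)) == 0).all()
    with pytest.raises(ValueError):
        mad_zscore(np.array([1.0]))


def test_zscore_table_median_is_zero():
    rng = np.random.default_rng(9)
    props = pd.DataFrame({"m1": rng.random(101), "m2": rng.random(101)})
    z = motif_zscores(props)
    assert np.median(z["m1"]) == pytest.approx(0.0, abs=1e-9)


def test_jaspar_round_trip(tmp_path):
    pwm = _consensus_pwm("ACGTACGTACGT")
    path = tmp_path / "m.jaspar"
    write_jaspar([pwm], path)
    back = read_jaspar(path)
    assert len(back) == 1
    assert back[0].id == pwm.id
    np.testing.assert_allclose(back[0].counts, pwm.counts)


def test_window_scores_mask_ambiguous_bases():
    pwm = _consensus_pwm("ACGT")
    lom = pwm.log_odds(UNIFORM)
    scores = window_scores(encode_sequence("ACGTNACGT"), lom)
    assert np.isfinite(scores[0])
    assert np.isneginf(scores[1:5]).all()
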