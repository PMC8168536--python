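"""Barcode correction: candidate search, posterior scoring, batch behavior."""

import numpy as np
import pytest

from scatk.barcodes import (
    BarcodeRead,
    WhitelistIndex,
    correct_barcodes,
    hamming_candidates,
    posterior_correct,
)

Q30 = np.full(16, 30.0)


def _mutate(seq, positions, alphabet="ACGT"):
    s = list(seq)
    for p in positions:
        s[p] = alphabet[(alphabet.index(s[p]) + 1) % 4]
    return "".join(s)


@pytest.fixture(scope="module")
def random_whitelist():
    rng = np.random.default_rng(42)
    seqs = {"".join("ACGT"[c] for c in rng.integers(0, 4, 16))
            for _ in range(1000)}
    return WhitelistIndex(sorted(seqs))


def test_exact_match_is_its_own_candidate(random_whitelist):
    bc = random_whitelist.barcodes[3]
    assert bc in hamming_candidates(BarcodeRead(bc, Q30), random_whitelist)


def test_single_substitution_from_disjoint_whitelist():
    wl = WhitelistIndex(["A" * 16, "C" * 16])
    read = BarcodeRead(_mutate("A" * 16, [5]), Q30)
    assert hamming_candidates(read, wl) == ["A" * 16]


def test_candidates_match_brute_force_scan(random_whitelist):
    """Segment-index candidate search equals the all-pairs Hamming scan."""
    rng = np.random.default_rng(7)
    wl_codes = np.array(
        [[("ACGT".index(c)) for c in b] for b in random_whitelist.barcodes],
        dtype=np.uint8,
    )
    for _ in range(300):
        if rng.random() < 0.5:  # bias toward near-whitelist reads
            base = wl_codes[rng.integers(len(wl_codes))].copy()
            k = rng.integers(0, 4)
            pos = rng.choice(16, size=k, replace=False)
            base[pos] = (base[pos] + rng.integers(1, 4, size=k)) % 4
        else:
            base = rng.integers(0, 4, 16).astype(np.uint8)
        seq = "".join("ACGT"[c] for c in base)
        expected = sorted(
            random_whitelist.barcodes[i]
            for i in np.flatnonzero((wl_codes != base).sum(axis=1) <= 2)
        )
        got = hamming_candidates(BarcodeRead(seq, Q30), random_whitelist)
        assert got == expected


def test_wrong_read_length_rejected(random_whitelist):
    with pytest.raises(ValueError, match="length"):
        hamming_candidates(BarcodeRead("ACGT", np.full(4, 30.0)),
                           random_whitelist)


def test_exact_match_corrects_to_itself(random_whitelist):
    bc = random_whitelist.barcodes[0]
    res = posterior_correct(BarcodeRead(bc, Q30), random_whitelist)
    assert res.corrected == bc and res.posterior == 1.0


def test_symmetric_candidates_tie_and_abstain():
    """Equidistant candidates at equal quality split 0.5/0.5: no correction."""
    wl = WhitelistIndex(["AAAA", "TTTT"], {"AAAA": 5, "TTTT": 5})
    # read at distance 2 from both
    read = BarcodeRead("AATT", np.full(4, 30.0))
    res = posterior_correct(read, wl)
    assert res.corrected is None
    posts = dict(res.candidates)
    assert posts["AAAA"] == pytest.approx(0.5)
    assert posts["TTTT"] == pytest.approx(0.5)


def test_toy_posterior_matches_hand_enumeration():
    """Length-4 whitelist {AAAA, AAAT}, observed AACT at Q30 everywhere.

    AAAT is one substitution away, AAAA two; enumerating the likelihood
    products by hand gives AAAT a posterior above 0.9, so it is corrected.
    """
    wl = WhitelistIndex(["AAAA", "AAAT"], {"AAAA": 3, "AAAT": 3})
    read = BarcodeRead("AACT", np.full(4, 30.0))
    e = 10 ** -3.0
    lik_aaat = (e / 3) ** 1 * (1 - e) ** 3
    lik_aaaa = (e / 3) ** 2 * (1 - e) ** 2
    prior = 3 + 1.0
    expect = (prior * lik_aaat) / (prior * lik_aaat + prior * lik_aaaa)
    res = posterior_correct(read, wl)
    assert res.corrected == "AAAT"
    assert res.posterior == pytest.approx(expect, rel=1e-12)
    assert expect > 0.9


def test_posteriors_normalize_when_candidates_exist(random_whitelist):
    rng = np.random.default_rng(3)
    for _ in range(50):
        bc = random_whitelist.barcodes[rng.integers(1000)]
        seq = _mutate(bc, rng.choice(16, 2, replace=False))
        res = posterior_correct(BarcodeRead(seq, Q30), random_whitelist)
        if res.candidates:
            total = sum(p for _, p in res.candidates)
            assert total == pytest.approx(1.0, abs=1e-9)


def test_no_correction_beyond_hamming_two(random_whitelist):
    rng = np.random.default_rng(8)
    wl_set = set(random_whitelist.barcodes)
    checked = 0
    while checked < 40:
        bc = random_whitelist.barcodes[rng.integers(1000)]
        seq = _mutate(bc, rng.choice(16, 3, replace=False))
        if seq in wl_set:
            continue
        res = posterior_correct(BarcodeRead(seq, Q30), random_whitelist)
        if res.corrected is not None:
            d = sum(a != b for a, b in zip(seq, res.corrected))
            assert d <= 2
        checked += 1


def test_many_ns_are_discarded(random_whitelist):
    bc = random_whitelist.barcodes[0]
    seq = "NNN" + bc[3:]
    res = posterior_correct(BarcodeRead(seq, Q30), random_whitelist)
    assert res.corrected is None and res.candidates == []


def test_abundance_prior_breaks_symmetric_ties():
    """With equal mismatch counts and qualities the posterior reduces to the
    abundance priors: (1000+1)/(1000+1+9+1) ~ 0.99 > 0.9, so the abundant
    candidate wins a tie the likelihood alone cannot break."""
    a, b = "A" * 16, "A" * 15 + "C"
    wl = WhitelistIndex([a, b], {a: 1000, b: 9})
    read = BarcodeRead("A" * 15 + "G", Q30)  # one mismatch to each
    res = posterior_correct(read, wl)
    assert res.corrected == a
    assert res.posterior == pytest.approx(1001.0 / 1011.0, rel=1e-9)


def test_batch_correction_on_synthetic_reads():
    """Low-error synthetic reads against a distance->=3 whitelist: nearly all
    error-bearing reads with <=2 substitutions return to their true barcode."""
    from scatk.synthetic import generate_whitelist

    wl = generate_whitelist(500, 16, seed=2)
    rng = np.random.default_rng(2)
    idx = rng.integers(0, len(wl), 3000)
    truth = [wl[i] for i in idx]
    reads = []
    n_sub = []
    for t in truth:
        k = rng.binomial(16, 0.005)
        pos = rng.choice(16, size=min(k, 16), replace=False)
        reads.append(_mutate(t, pos))
        n_sub.append(len(pos))
    corrected = correct_barcodes(reads, wl)
    ok = sum(
        c == t for c, t, k in zip(corrected, truth, n_sub) if 1 <= k <= 2
    )
    tot = sum(1 for k in n_sub if 1 <= k <= 2)
    assert tot > 0 and ok / tot >= 0.99
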