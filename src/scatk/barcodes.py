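"""Whitelist-based droplet barcode error correction.

Observed barcodes are matched against a whitelist of true barcode sequences.
A read off the whitelist is compared with every whitelist entry within
Hamming distance 2; each candidate is scored with a quality-aware
substitution likelihood and an abundance prior, and the read is corrected to
the maximum-posterior candidate only when that posterior exceeds 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(_BASES)}
_BASE_TO_CODE["N"] = 4

MAX_HAMMING = 2
POSTERIOR_CUTOFF = 0.9  # corrected only when posterior is strictly above


def _encode(seqs: list[str], length: int) -> np.ndarray:
    arr = np.empty((len(seqs), length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        if len(s) != length:
            raise ValueError(f"barcode {s!r} is not {length} bases long")
        try:
            arr[i] = [_BASE_TO_CODE[b] for b in s]
        except KeyError as exc:
            raise ValueError(f"invalid base in barcode {s!r}") from exc
    return arr


@dataclass
class BarcodeRead:
    """One observed barcode with per-base Phred qualities."""

    sequence: str
    qualities: np.ndarray

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=float)
        if len(self.sequence) != self.qualities.size:
            raise ValueError("sequence and qualities disagree in length")
        if any(b not in _BASE_TO_CODE for b in self.sequence):
            raise ValueError(f"invalid base in {self.sequence!r}")

    @property
    def n_count(self) -> int:
        return self.sequence.count("N")


@dataclass
class WhitelistIndex:
    """A whitelist with segment indexes for fast Hamming-2 candidate lookup.

    The barcode is cut into ``MAX_HAMMING + 1`` segments; by pigeonhole any
    read within Hamming distance 2 of a whitelist entry matches it exactly on
    at least one segment, so candidate sets come from three hash lookups plus
    a distance check.
    """

    barcodes: list[str]
    abundance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.barcodes:
            raise ValueError("empty whitelist")
        self.length = len(self.barcodes[0])
        self._codes = _encode(self.barcodes, self.length)
        self._lookup = {bc: i for i, bc in enumerate(self.barcodes)}
        bounds = np.linspace(0, self.length, MAX_HAMMING + 2).astype(int)
        self._segments = list(zip(bounds[:-1], bounds[1:]))
        self._seg_index: list[dict[str, list[int]]] = []
        for a, b in self._segments:
            d: dict[str, list[int]] = {}
            for i, bc in enumerate(self.barcodes):
                d.setdefault(bc[a:b], []).append(i)
            self._seg_index.append(d)
        unknown = set(self.abundance) - set(self.barcodes)
        if unknown:
            raise ValueError("abundance keys outside the whitelist")

    def __contains__(self, seq: str) -> bool:
        return seq in self._lookup

    def prior(self, barcode: str) -> float:
        # +1 pseudocount keeps unobserved whitelist entries reachable
        return self.abundance.get(barcode, 0) + 1.0

    @classmethod
    def from_observed(cls, barcodes: list[str], observed) -> "WhitelistIndex":
        """Build the index with abundances = exact-match counts in ``observed``."""
        counts = pd.Series(observed).value_counts()
        wl = set(barcodes)
        ab = {bc: int(c) for bc, c in counts.items() if bc in wl}
        return cls(barcodes, ab)


@dataclass
class CorrectionResult:
    corrected: str | None
    posterior: float
    candidates: list[tuple[str, float]]


def hamming_candidates(
    read: BarcodeRead, wl: WhitelistIndex, max_dist: int = MAX_HAMMING
) -> list[str]:
    """Whitelist barcodes within ``max_dist`` substitutions of the read.

    ``N`` bases mismatch every base.  Uses the segment index for the default
    distance bound, falling back to a full scan for larger bounds.
    """
    if len(read.sequence) != wl.length:
        raise ValueError(
            f"read length {len(read.sequence)} != whitelist length {wl.length}"
        )
    codes = _encode([read.sequence], wl.length)[0]
    if max_dist == MAX_HAMMING:
        cand_idx: set[int] = set()
        for (a, b), index in zip(wl._segments, wl._seg_index):
            cand_idx.update(index.get(read.sequence[a:b], ()))
        idx = np.fromiter(cand_idx, dtype=np.int64, count=len(cand_idx))
    else:
        idx = np.arange(len(wl.barcodes))
    if idx.size == 0:
        return []
    dists = (wl._codes[idx] != codes).sum(axis=1)
    keep = idx[dists <= max_dist]
    return sorted(wl.barcodes[i] for i in keep)


def posterior_correct(read: BarcodeRead, wl: WhitelistIndex) -> CorrectionResult:
    """Score Hamming-<=2 candidates and correct when the winner clears 0.9.

    Candidate likelihood: product over mismatching positions of
    ``10**(-Q/10) / 3`` and over matching positions of ``1 - 10**(-Q/10)``;
    prior proportional to exact-match abundance plus one.  An exact whitelist
    match is returned unchanged with posterior 1.
    """
    if read.sequence in wl:
        return CorrectionResult(read.sequence, 1.0, [(read.sequence, 1.0)])
    if read.n_count > MAX_HAMMING:
        return CorrectionResult(None, 0.0, [])
    cands = hamming_candidates(read, wl)
    if not cands:
        return CorrectionResult(None, 0.0, [])

    err = np.power(10.0, -read.qualities / 10.0)
    log_err = np.log(err / 3.0)
    log_match = np.log1p(-err)
    codes = _encode([read.sequence], wl.length)[0]
    scores = np.empty(len(cands))
    for j, c in enumerate(cands):
        ccodes = wl._codes[wl._lookup[c]]
        mism = ccodes != codes
        scores[j] = np.log(wl.prior(c)) + log_err[mism].sum() + log_match[~mism].sum()
    scores -= scores.max()
    post = np.exp(scores)
    post /= post.sum()
    order = np.argsort(-post, kind="stable")
    ranked = [(cands[i], float(post[i])) for i in order]
    best, best_p = ranked[0]
    if best_p > POSTERIOR_CUTOFF:
        return CorrectionResult(best, best_p, ranked)
    return CorrectionResult(None, best_p, ranked)


def correct_barcodes(
    observed: pd.Series | list[str],
    whitelist: list[str],
    default_quality: float = 30.0,
) -> pd.Series:
    """Correct a column of observed barcodes against a whitelist.

    Fragment files carry no base qualities, so a uniform Phred quality is
    assumed.  Returns a Series indexed like ``observed`` whose values are the
    corrected barcode or ``None`` for unrecoverable reads.  Each distinct
    observed sequence is corrected once and the result broadcast.
    """
    observed = pd.Series(observed)
    wl = WhitelistIndex.from_observed(whitelist, observed)
    qual = np.full(wl.length, default_quality)
    mapping: dict[str, str | None] = {}
    for seq in pd.unique(observed):
        if seq in wl:
            mapping[seq] = seq
            continue
        try:
            read = BarcodeRead(seq, qual)
        except ValueError:
            mapping[seq] = None
            continue
        mapping[seq] = posterior_correct(read, wl).corrected
    return observed.map(mapping)


def correct_fragments(frags: pd.DataFrame, whitelist: list[str]) -> pd.DataFrame:
    """Replace fragment barcodes by corrected ones, dropping unrecoverable rows."""
    corrected = correct_barcodes(frags["barcode"], whitelist)
    out = frags.copy()
    out["barcode"] = corrected
    return out.dropna(subset=["barcode"]).reset_index(drop=True)
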