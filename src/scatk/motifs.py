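"""PWM motif scanning in peaks and per-barcode motif activity scores.

Peaks are binned into equal-frequency GC buckets; within each bucket the
background nucleotide frequencies are those observed in the bucket's peak
sequences, the log-odds threshold matching an exact scan p-value of 1e-7 is
derived by dynamic programming over discretized scores, and both strands are
scanned.  Hits are unified across buckets.  Per-barcode motif activity is the
proportion of the barcode's matrix counts falling in motif-bearing peaks,
robustly standardized with a modified z-score (median and scaled MAD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cells import PeakBarcodeMatrix

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

DEFAULT_PVALUE = 1e-7
DEFAULT_BUCKETS = 5
DEFAULT_PSEUDOCOUNT = 0.8
SCORE_RESOLUTION = 1e-3
MAD_SCALE = 1.4826  # makes the MAD consistent with the SD under normality


@dataclass
class Pwm:
    """Position weight matrix as per-position base counts (4 x length, ACGT).

    A pseudocount is added to every cell before converting to probabilities,
    so zero-count bases stay scoreable.
    """

    id: str
    name: str
    counts: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("PWM counts must be 4 x length")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("PWM column sums must be positive")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        c = self.counts + self.pseudocount
        return c / c.sum(axis=0, keepdims=True)

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """Natural-log odds matrix against the given base frequencies."""
        background = np.asarray(background, dtype=float)
        if not np.isclose(background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        bg = np.clip(background, 1e-9, None)
        return np.log(self.probabilities()) - np.log(bg)[:, None]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.id, self.name, self.counts[::-1, ::-1].copy(),
                   self.pseudocount)


def read_jaspar(path) -> list[Pwm]:
    """Read PWMs from JASPAR text format via Bio.motifs."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in _BASES], dtype=float)
            out.append(Pwm(m.matrix_id or m.name, m.name, counts))
    return out


def write_jaspar(pwms: list[Pwm], path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.id}\t{p.name}\n")
            for b, row in zip(_BASES, p.counts):
                vals = " ".join(f"{v:.2f}" for v in row)
                fh.write(f"{b}  [ {vals} ]\n")


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N, soft-masked leftovers) -> 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def score_threshold(pwm: Pwm, background: np.ndarray,
                    pvalue: float = DEFAULT_PVALUE,
                    resolution: float = SCORE_RESOLUTION) -> float:
    """Smallest log-odds score whose exact upper-tail probability under the
    background model is at most ``pvalue``.

    The score distribution of a random background window is computed by
    position-wise convolution over scores discretized at ``resolution``.
    Returns ``inf`` when even the maximal score is too likely, in which case
    scanning yields no hits by contract.
    """
    if not (0.0 < pvalue < 1.0):
        raise ValueError("pvalue must be in (0, 1)")
    scores, probs = score_distribution(pwm, background, resolution)
    tail = np.cumsum(probs[::-1])[::-1]  # tail[i] = P(score >= scores[i])
    ok = np.flatnonzero(tail <= pvalue)
    if ok.size == 0:
        return float("inf")
    return float(scores[ok[0]])


def score_distribution(pwm: Pwm, background: np.ndarray,
                       resolution: float = SCORE_RESOLUTION):
    """(scores, probabilities) of the exact discretized background score law."""
    lom = pwm.log_odds(background)
    bins = np.round(lom / resolution).astype(np.int64)
    bg = np.asarray(background, dtype=float)
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(pwm.length):
        col = bins[:, j]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(cur) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            if bg[b] <= 0:
                continue
            shift = cur_lo + int(col[b]) - new_lo
            new[shift : shift + len(cur)] += bg[b] * cur
        cur, cur_lo = new, new_lo
    scores = (np.arange(len(cur)) + cur_lo) * resolution
    return scores, cur


def peak_sequences(peaks, genome: dict[str, str]) -> list[str]:
    """Extract the sequence under every peak interval."""
    out = []
    for row in peaks.intervals.itertuples(index=False):
        out.append(genome[row.chrom][int(row.start):int(row.end)])
    return out


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def gc_buckets(peak_seqs: list[str], n_buckets: int = DEFAULT_BUCKETS):
    """Rank peaks by GC and split into equal-frequency buckets.

    Returns (bucket index per peak, per-bucket ACGT background frequencies).
    Falls back to a single bucket when there are fewer peaks than buckets.
    """
    n = len(peak_seqs)
    if n == 0:
        raise ValueError("no peaks")
    if n < n_buckets:
        n_buckets = 1
    gc = np.array([gc_fraction(s) for s in peak_seqs])
    order = np.argsort(gc, kind="mergesort")
    assignment = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_buckets)):
        assignment[chunk] = b
    backgrounds = []
    for b in range(n_buckets):
        counts = np.ones(4)  # one pseudo-base per letter guards empty buckets
        for i in np.flatnonzero(assignment == b):
            codes = encode_sequence(peak_seqs[i])
            counts += np.bincount(codes[codes < 4], minlength=4)
        backgrounds.append(counts / counts.sum())
    return assignment, backgrounds


def window_scores(seq_codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing non-ACGT get -inf."""
    L = lom.shape[1]
    n = seq_codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(seq_codes, L)
    valid = (win < 4).all(axis=1)
    safe = np.where(win < 4, win, 0)
    scores = np.zeros(n)
    for j in range(L):
        scores += lom[safe[:, j], j]
    scores[~valid] = -np.inf
    return scores


def scan(
    peak_seqs: list[str],
    pwm: Pwm,
    bucket_assignment: np.ndarray,
    backgrounds: list[np.ndarray],
    pvalue: float = DEFAULT_PVALUE,
) -> pd.DataFrame:
    """Scan both strands of every peak at its bucket's exact-p threshold.

    Minus-strand hits are scored with the reverse-complement PWM on the
    forward sequence; offsets always refer to the forward strand window
    start.  Hits from all buckets come back in one unified list.
    """
    thresholds = [score_threshold(pwm, bg, pvalue) for bg in backgrounds]
    loms = [pwm.log_odds(bg) for bg in backgrounds]
    rc = pwm.reverse_complement()
    loms_rc = [rc.log_odds(bg) for bg in backgrounds]
    rows = []
    for i, seq in enumerate(peak_seqs):
        if len(seq) < pwm.length:
            continue
        b = int(bucket_assignment[i])
        thr = thresholds[b]
        if not np.isfinite(thr):
            continue
        codes = encode_sequence(seq)
        for strand, lom in (("+", loms[b]), ("-", loms_rc[b])):
            sc = window_scores(codes, lom)
            for off in np.flatnonzero(sc >= thr):
                rows.append((pwm.id, i, int(off), strand, float(sc[off])))
    return pd.DataFrame(rows, columns=["pwm", "peak", "offset", "strand", "score"])


def concat_hits(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-PWM hit tables, tolerating empty ones."""
    nonempty = [f for f in frames if len(f)]
    if not nonempty:
        return pd.DataFrame(columns=["pwm", "peak", "offset", "strand", "score"])
    return pd.concat(nonempty, ignore_index=True)


def motif_proportions(matrix: PeakBarcodeMatrix,
                      hits: pd.DataFrame) -> pd.DataFrame:
    """Per-barcode proportion of counts in motif-bearing peaks, per PWM.

    Barcodes with zero total counts are excluded.  The proportion already
    divides by per-barcode depth, so no second depth normalization applies.
    """
    totals = matrix.column_totals()
    keep = totals > 0
    barcodes = [b for b, k in zip(matrix.barcodes, keep) if k]
    out = {}
    for pwm_id, sub in hits.groupby("pwm", sort=True):
        peak_idx = np.unique(sub["peak"].to_numpy())
        in_motif = np.asarray(matrix.matrix[peak_idx].sum(axis=0)).ravel()
        out[pwm_id] = in_motif[keep] / totals[keep]
    return pd.DataFrame(out, index=barcodes)


def mad_zscore(values: np.ndarray) -> np.ndarray:
    """Modified z-score: (x - median) / (1.4826 * MAD); all zeros if MAD = 0."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.zeros_like(values)
    return (values - med) / (MAD_SCALE * mad)


def motif_zscores(proportions: pd.DataFrame) -> pd.DataFrame:
    """Column-wise modified z-scores of the motif proportion table."""
    return proportions.apply(lambda col: mad_zscore(col.to_numpy()), axis=0,
                             result_type="broadcast")
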