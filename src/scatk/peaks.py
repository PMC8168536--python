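"""Peak calling from smoothed transposition-event coverage.

The genome-wide count of transposition events (each fragment contributes its
start and its last base) is smoothed with a 401 bp moving window, a
three-component mixture (zero-inflation / noise NB / signal NB) is fitted to
the smoothed counts, and a base is called open chromatin when the posterior
odds of the signal component against the noise component reach 1/5.  Runs of
called bases become intervals; intervals closer than 500 bp are merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixtures import ZinbaMixture, fit_zinba  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 401
DEFAULT_ODDS = 1.0 / 5.0
DEFAULT_MERGE_DIST = 500


def count_events(frags: pd.DataFrame, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base transposition-event counts: +1 at start and at end-1.

    Duplicate counts are ignored -- only unique fragments contribute.  Out of
    bounds fragments are dropped with a log message.
    """
    track = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_sizes.items()}
    n_rejected = 0
    for chrom, sub in frags.groupby("chrom", sort=False):
        if chrom not in track:
            n_rejected += len(sub)
            continue
        n = chrom_sizes[chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ok = (starts >= 0) & (ends <= n) & (ends > starts)
        n_rejected += int((~ok).sum())
        ev = np.concatenate([starts[ok], ends[ok] - 1])
        track[chrom] += np.bincount(ev, minlength=n).astype(np.int32)
    if n_rejected:
        logger.warning("rejected %d out-of-bounds fragments", n_rejected)
    return track


def smooth(track: dict[str, np.ndarray] | np.ndarray,
           window: int = DEFAULT_WINDOW):
    """Moving-window sum: value at i sums events in [i-w//2, i+w//2],
    clipped at the chromosome ends."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    if isinstance(track, dict):
        return {c: smooth(v, window) for c, v in track.items()}
    half = window // 2
    cum = np.concatenate([[0], np.cumsum(track, dtype=np.int64)])
    n = track.size
    hi = np.minimum(np.arange(n) + half + 1, n)
    lo = np.maximum(np.arange(n) - half, 0)
    return cum[hi] - cum[lo]


@dataclass
class PeakSet:
    """Sorted, merged open-chromatin intervals (BED-style, half-open)."""

    intervals: pd.DataFrame  # columns chrom, start, end
    threshold_count: int | None = None

    def __post_init__(self):
        self.intervals = self.intervals.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        return out

    def total_bases(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def to_bed(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "PeakSet":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end"],
                         dtype={"chrom": str, "start": np.int64, "end": np.int64})
        return cls(df)

    @classmethod
    def from_arrays(cls, chroms, starts, ends, threshold_count=None) -> "PeakSet":
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        df = df.sort_values(["chrom", "start"], kind="mergesort")
        return cls(df, threshold_count)


def merge_intervals(df: pd.DataFrame, merge_dist: int = DEFAULT_MERGE_DIST) -> pd.DataFrame:
    """Union intervals whose gap is below ``merge_dist`` (per chromosome)."""
    rows = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s - cur_e < merge_dist:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def signal_counts(model: ZinbaMixture, max_count: int,
                  odds: float = DEFAULT_ODDS) -> np.ndarray:
    """Boolean table over counts 0..max_count: posterior signal:noise >= odds."""
    ks = np.arange(max_count + 1)
    return model.log_odds_signal_noise(ks) >= np.log(odds)


def call_peaks(
    smoothed: dict[str, np.ndarray],
    model: ZinbaMixture,
    odds: float = DEFAULT_ODDS,
    merge_dist: int = DEFAULT_MERGE_DIST,
) -> PeakSet:
    """Threshold the smoothed track on mixture posterior odds and merge runs.

    Degenerate models cannot separate signal from noise and yield an empty
    peak set with a warning.
    """
    if model.degenerate:
        logger.warning("degenerate mixture model: no peaks callable")
        return PeakSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    max_count = max((int(v.max()) if v.size else 0) for v in smoothed.values())
    is_signal = signal_counts(model, max_count, odds)
    threshold = int(np.argmax(is_signal)) if is_signal.any() else None

    pieces = []
    for chrom in sorted(smoothed):
        mask = is_signal[smoothed[chrom]]
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
        starts, ends = edges[::2], edges[1::2]
        pieces.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not pieces:
        logger.warning("no base passed the odds threshold")
        return PeakSet(pd.DataFrame(columns=["chrom", "start", "end"]),
                       threshold_count=threshold)
    merged = merge_intervals(pd.concat(pieces, ignore_index=True), merge_dist)
    return PeakSet(merged, threshold_count=threshold)


def call_peaks_from_fragments(
    frags: pd.DataFrame,
    chrom_sizes: dict[str, int],
    seed: int = 0,
    window: int = DEFAULT_WINDOW,
    odds: float = DEFAULT_ODDS,
    merge_dist: int = DEFAULT_MERGE_DIST,
    max_fit_bases: int = 1_000_000,
) -> tuple[PeakSet, ZinbaMixture]:
    """End-to-end peak calling: count, smooth, fit (on a base subsample), call.

    The mixture is fitted on a uniform subsample of at most ``max_fit_bases``
    positions for tractability; classification then covers every base.
    """
    smoothed = smooth(count_events(frags, chrom_sizes), window)
    values = np.concatenate([v for v in smoothed.values()])
    if values.size > max_fit_bases:
        rng = np.random.default_rng(seed)
        values = values[rng.choice(values.size, max_fit_bases, replace=False)]
    model = fit_zinba(values, seed=seed)
    return call_peaks(smoothed, model, odds=odds, merge_dist=merge_dist), model


def jaccard(a: PeakSet, b: PeakSet) -> float:
    """Base-level Jaccard overlap between two interval sets."""

    def to_mask_bounds(ps):
        out = {}
        for chrom, (s, e) in ps.per_chrom().items():
            out[chrom] = (s, e)
        return out

    ma, mb = to_mask_bounds(a), to_mask_bounds(b)
    inter = union = 0
    for chrom in set(ma) | set(mb):
        sa, ea = ma.get(chrom, (np.array([]), np.array([])))
        sb, eb = mb.get(chrom, (np.array([]), np.array([])))
        la = int(np.sum(ea - sa)) if sa.size else 0
        lb = int(np.sum(eb - sb)) if sb.size else 0
        ov = 0
        i = j = 0
        while i < sa.size and j < sb.size:
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                ov += hi - lo
            if ea[i] <= eb[j]:
                i += 1
            else:
                j += 1
        inter += ov
        union += la + lb - ov
    return inter / union if union else 0.0
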