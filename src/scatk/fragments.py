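"""Fragment deduplication and library-level QC profiles.

A fragment is the interval between the two transposition events of one
sequenced molecule.  Read pairs sharing (chrom, start, end, barcode) are PCR
duplicates and collapse to a single fragment carrying their multiplicity.
QC covers the fragment-length histogram (nucleosome periodicity) and the
enrichment of transposition events around transcription start sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class QcProfile:
    """TSS-centred coverage curve plus its summary score.

    ``tss_curve`` is indexed by offset (-window..window, strand-oriented) and
    normalized so that the outermost 100 bp flanks average 1; the enrichment
    score is the curve value at offset 0.
    """

    length_histogram: pd.Series
    tss_curve: pd.Series
    tss_enrichment_score: float


def deduplicate(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw records to unique fragments with duplicate counts.

    Input rows need (chrom, start, end, barcode); a ``count`` column, when
    present, is summed (so deduplication is idempotent).  Rows with
    ``end <= start`` are rejected and logged.  Output is position-sorted.
    """
    df = pairs
    bad = df["end"] <= df["start"]
    if bad.any():
        logger.warning("rejecting %d records with end <= start", int(bad.sum()))
        df = df[~bad]
    if "count" not in df.columns:
        df = df.assign(count=1)
    out = (
        df.groupby(["chrom", "start", "end", "barcode"], as_index=False, sort=True)
        ["count"].sum()
    )
    return out.sort_values(["chrom", "start", "end", "barcode"],
                           kind="mergesort").reset_index(drop=True)


def length_histogram(frags: pd.DataFrame) -> pd.Series:
    """Counts of unique fragments per length (duplicates not multiplied)."""
    if len(frags) == 0:
        return pd.Series(dtype=np.int64)
    lengths = (frags["end"] - frags["start"]).to_numpy()
    vals, counts = np.unique(lengths, return_counts=True)
    return pd.Series(counts, index=vals, name="count")


def histogram_modes(hist: pd.Series, min_separation: int = 80,
                    smooth_bw: int = 10) -> list[int]:
    """Locations of local maxima of a kernel-smoothed length histogram.

    Used to compare a synthetic library's periodicity against its configured
    nucleosome modes.
    """
    if hist.empty:
        return []
    lengths = np.arange(int(hist.index.min()), int(hist.index.max()) + 1)
    dense = hist.reindex(lengths, fill_value=0).to_numpy(dtype=float)
    x = np.arange(-3 * smooth_bw, 3 * smooth_bw + 1)
    kern = np.exp(-0.5 * (x / smooth_bw) ** 2)
    kern /= kern.sum()
    sm = np.convolve(dense, kern, mode="same")
    # genuine local maxima only, then greedy by height with a separation gap
    is_max = np.ones(sm.size, dtype=bool)
    is_max[1:] &= sm[1:] >= sm[:-1]
    is_max[:-1] &= sm[:-1] > sm[1:]
    is_max &= sm > 0.02 * sm.max()
    cand = np.flatnonzero(is_max)
    modes: list[int] = []
    for i in cand[np.argsort(-sm[cand], kind="mergesort")]:
        pos = int(lengths[i])
        if all(abs(pos - m) >= min_separation for m in modes):
            modes.append(pos)
    return sorted(modes)


def tss_positions(genes: pd.DataFrame) -> pd.DataFrame:
    """TSS per gene: interval start for + strand, end-1 for - strand (BED)."""
    tss = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    return pd.DataFrame(
        {"chrom": genes["chrom"].to_numpy(), "tss": tss,
         "strand": genes["strand"].to_numpy()}
    )


def tss_enrichment(frags: pd.DataFrame, tss_list: pd.DataFrame,
                   window: int = 2000, flank: int = 100) -> QcProfile:
    """Aggregate transposition events around TSSs and normalize by the flanks.

    Each fragment contributes events at ``start`` and ``end - 1``.  Offsets
    are strand-flipped for minus-strand genes so "downstream" is always
    positive.  The curve is ``(counts + 1) / (mean outer-flank counts + 1)``,
    which pins the flank mean at 1; the score is the curve at offset 0.
    """
    if len(tss_list) == 0:
        raise ValueError("tss_list must be nonempty")
    offsets = np.arange(-window, window + 1)
    counts = np.zeros(offsets.size, dtype=np.int64)
    for chrom, sub in frags.groupby("chrom", sort=False):
        events = np.sort(
            np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy() - 1])
        )
        sites = tss_list[tss_list["chrom"] == chrom]
        for tss, strand in zip(sites["tss"], sites["strand"]):
            lo = np.searchsorted(events, tss - window, side="left")
            hi = np.searchsorted(events, tss + window, side="right")
            off = events[lo:hi] - tss
            if strand == "-":
                off = -off
            counts += np.bincount(off + window, minlength=offsets.size)
    flank_mask = (np.abs(offsets) > window - flank)
    flank_mean = counts[flank_mask].mean()
    curve = (counts + 1.0) / (flank_mean + 1.0)
    curve = pd.Series(curve, index=offsets, name="normalized_depth")
    score = float(curve.loc[0])
    hist = length_histogram(frags)
    return QcProfile(length_histogram=hist, tss_curve=curve,
                     tss_enrichment_score=score)
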