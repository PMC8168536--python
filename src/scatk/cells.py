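"""Cell calling and the peak x barcode count matrix.

Barcodes are ranked by the number of fragments overlapping any peak; a
depth-dependent fixed count (whitelist contamination at rate 0.02) is
subtracted, a two-NB mixture is fitted to the adjusted counts, and a barcode
is declared a cell when the posterior odds of the high-count component reach
1,000.  The analysis substrate is then the sparse matrix of fragment-end
counts per peak per cell barcode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .mixtures import TwoNbModel, fit_two_nb  # noqa: F401
from .peaks import PeakSet

logger = logging.getLogger(__name__)

DEFAULT_CONTAMINATION = 0.02
DEFAULT_CELL_ODDS = 1000.0


def barcode_stats(frags: pd.DataFrame, peaks: PeakSet) -> pd.DataFrame:
    """Per-barcode totals and in-peak fragment counts.

    A fragment overlaps a peak when the half-open intervals intersect.  Peaks
    are sorted and disjoint, so one searchsorted per fragment suffices.
    """
    in_peak = np.zeros(len(frags), dtype=bool)
    per_chrom = peaks.per_chrom()
    for chrom, sub in frags.groupby("chrom", sort=False):
        if chrom not in per_chrom:
            continue
        ps, pe = per_chrom[chrom]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        # first peak not entirely left of the fragment
        idx = np.searchsorted(pe, s, side="right")
        hit = (idx < len(ps)) & (ps[np.minimum(idx, len(ps) - 1)] < e)
        in_peak[sub.index.to_numpy()] = hit
    stats = pd.DataFrame(
        {
            "total_fragments": frags.groupby("barcode").size(),
            "fragments_in_peaks": pd.Series(in_peak, index=frags.index)
            .groupby(frags["barcode"]).sum().astype(np.int64),
        }
    ).fillna(0)
    return stats


def subtract_contamination(stats: pd.DataFrame,
                           rate: float = DEFAULT_CONTAMINATION) -> tuple[pd.DataFrame, int]:
    """Remove the estimated cross-droplet contamination from in-peak counts.

    The fixed count is ``round(rate * mean in-peak count)`` over barcodes with
    at least one fragment; adjusted counts are clamped at zero.
    """
    active = stats["total_fragments"] >= 1
    mean_in_peak = float(stats.loc[active, "fragments_in_peaks"].mean()) if active.any() else 0.0
    fixed = int(round(rate * mean_in_peak))
    out = stats.copy()
    out["adjusted_count"] = np.maximum(out["fragments_in_peaks"] - fixed, 0)
    return out, fixed


def call_cells(
    stats: pd.DataFrame,
    seed: int = 0,
    odds_threshold: float = DEFAULT_CELL_ODDS,
    contamination: float = DEFAULT_CONTAMINATION,
) -> tuple[TwoNbModel, set[str]]:
    """Separate cell barcodes from ambient barcodes with a two-NB mixture.

    Returns the fitted model (with the subtracted fixed count recorded) and
    the set of barcodes whose posterior signal:noise odds reach the
    threshold.  A degenerate fit (components merged) makes an all-or-nothing
    call: every barcode is kept when the single component mean is large,
    otherwise none, and the flag is propagated.
    """
    if len(stats) == 0:
        empty = TwoNbModel(1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0, degenerate=True)
        return empty, set()
    adj, fixed = subtract_contamination(stats, contamination)
    counts = adj["adjusted_count"].to_numpy()
    model = fit_two_nb(counts, seed=seed)
    model.fixed_count = fixed
    model.odds_threshold = odds_threshold
    if model.degenerate:
        logger.warning("two-NB fit degenerate: all-or-nothing cell call")
        keep = model.mu_signal >= 1.0
        cells = set(adj.index) if keep else set()
        return model, cells
    log_odds = model.log_odds_signal_noise(counts)
    is_cell = log_odds >= np.log(odds_threshold)
    return model, set(adj.index[is_cell])


@dataclass
class PeakBarcodeMatrix:
    """Sparse counts of fragment ends per peak (rows) per cell barcode (cols)."""

    matrix: sp.csr_matrix
    peaks: pd.DataFrame  # chrom, start, end per row
    barcodes: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def column_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def row_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def to_files(self, prefix) -> None:
        from pathlib import Path
        from scipy.io import mmwrite

        prefix = Path(prefix)
        mmwrite(str(prefix.with_suffix(".mtx")), self.matrix)
        self.peaks.to_csv(prefix.parent / (prefix.name + ".peaks.bed"),
                          sep="\t", header=False, index=False)
        with open(prefix.parent / (prefix.name + ".barcodes.tsv"), "w") as fh:
            fh.write("\n".join(self.barcodes) + "\n")


def build_matrix(frags: pd.DataFrame, peaks: PeakSet,
                 cells: set[str]) -> PeakBarcodeMatrix:
    """Count fragment ends inside each peak per cell barcode.

    Each fragment contributes its two transposition events (start and end-1)
    independently, so a fragment fully inside a peak adds 2 and a straddling
    fragment adds 1.  Non-cell barcodes are dropped.
    """
    barcodes = sorted(cells)
    bc_index = {b: i for i, b in enumerate(barcodes)}
    peak_df = peaks.intervals
    rows, cols, data = [], [], []
    per_chrom = {}
    offset = 0
    for chrom, sub in peak_df.groupby("chrom", sort=False):
        per_chrom[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                            sub.index.to_numpy())
    keep = frags["barcode"].isin(bc_index).to_numpy()
    sub_frags = frags[keep]
    for chrom, sub in sub_frags.groupby("chrom", sort=False):
        if chrom not in per_chrom:
            continue
        ps, pe, pidx = per_chrom[chrom]
        cidx = sub["barcode"].map(bc_index).to_numpy()
        for pos in (sub["start"].to_numpy(), sub["end"].to_numpy() - 1):
            j = np.searchsorted(ps, pos, side="right") - 1
            ok = (j >= 0) & (pos < pe[np.maximum(j, 0)])
            rows.append(pidx[j[ok]])
            cols.append(cidx[ok])
            data.append(np.ones(int(ok.sum()), dtype=np.int64))
    if rows:
        mat = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(peak_df), len(barcodes)),
        ).tocsr()
    else:
        mat = sp.csr_matrix((len(peak_df), len(barcodes)), dtype=np.int64)
    return PeakBarcodeMatrix(matrix=mat, peaks=peak_df.reset_index(drop=True),
                             barcodes=barcodes)
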