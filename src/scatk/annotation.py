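"""Peak-to-gene assignment and term enrichment.

Each peak is assigned to the gene with the closest transcription start site
(distance from the nearest peak base, zero when the TSS lies inside the
peak).  Term enrichment over the resulting peak-related gene set uses the
upper-tail hypergeometric probability

    P = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M,n-i) / C(N,n)

with N the annotated universe, n the peak-related genes in it, M the genes
annotated to the term and m the overlap, followed by Benjamini-Hochberg
adjustment; a term is significant when FDR < 0.05 (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from .peaks import PeakSet

logger = logging.getLogger(__name__)

FDR_CUTOFF = 0.05


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    tss: int
    strand: str


def genes_from_bed(bed: pd.DataFrame) -> list[GeneModel]:
    """BED6 rows -> gene models; TSS at start for +, end-1 for - strand."""
    out = []
    for row in bed.itertuples(index=False):
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        out.append(GeneModel(str(row.name), str(row.chrom), tss, str(row.strand)))
    return out


def nearest_tss(peaks: PeakSet, genes: list[GeneModel]) -> pd.Series:
    """Assign every peak to the gene with the minimal TSS distance.

    Distance is measured from the nearest peak base; ties break to the
    lexicographically smallest gene name.  Peaks on chromosomes without genes
    stay unassigned (NaN) and are logged.
    """
    if not genes:
        raise ValueError("gene list must be nonempty")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gl in by_chrom.values():
        gl.sort(key=lambda g: (g.tss, g.name))

    assigned = pd.Series(index=peaks.intervals.index, dtype=object)
    n_missing = 0
    for i, row in peaks.intervals.iterrows():
        gl = by_chrom.get(row.chrom)
        if not gl:
            n_missing += 1
            continue
        start, end = int(row.start), int(row.end)
        best_name, best_d = None, None
        for g in gl:
            if start <= g.tss < end:
                d = 0
            else:
                d = min(abs(start - g.tss), abs((end - 1) - g.tss))
            if best_d is None or d < best_d or (d == best_d and g.name < best_name):
                best_name, best_d = g.name, d
        assigned.iloc[i] = best_name
    if n_missing:
        logger.warning("%d peaks on chromosomes without genes", n_missing)
    return assigned


def hypergeom_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m), computed in log space.

    Equals 1 for m = 0 (the empty sum).  Summing the upper tail directly
    avoids the catastrophic cancellation of literally computing
    1 - lower tail for small probabilities.
    """
    if not (0 <= m <= min(n, M) <= N and n <= N and M <= N):
        raise ValueError(f"inconsistent arguments N={N} n={n} M={M} m={m}")
    if m == 0:
        return 1.0
    i = np.arange(m, min(n, M) + 1)
    log_terms = (
        _logcomb(M, i) + _logcomb(N - M, n - i) - _logcomb(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _logcomb(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where((b < 0) | (b > a), -np.inf, out)


@dataclass
class EnrichmentResult:
    term: str
    N: int
    n: int
    M: int
    m: int
    p: float
    fdr: float
    significant: bool


def enrich_terms(
    peak_genes: set[str],
    term_map: dict[str, set[str]],
    universe: set[str] | None = None,
    fdr_cutoff: float = FDR_CUTOFF,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each term in the peak-related gene set.

    The universe defaults to every gene appearing in the term map; term gene
    sets and the peak gene set are intersected with it.  BH adjustment across
    terms; significance requires FDR strictly below the cutoff.  The same
    routine serves GO- and KEGG-style maps (only the term map changes).
    """
    if universe is None:
        universe = set().union(*term_map.values()) if term_map else set()
    if not universe:
        raise ValueError("empty gene universe")
    N = len(universe)
    pg = peak_genes & universe
    n = len(pg)
    terms = sorted(term_map)
    results = []
    pvals = []
    for t in terms:
        tg = term_map[t] & universe
        M = len(tg)
        m = len(pg & tg)
        p = hypergeom_p(N, n, M, m)
        pvals.append(p)
        results.append(EnrichmentResult(t, N, n, M, m, p, np.nan, False))
    if results:
        fdr = false_discovery_control(np.asarray(pvals), method="bh")
        for r, q in zip(results, fdr):
            r.fdr = float(q)
            r.significant = bool(q < fdr_cutoff)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term": r.term, "N": r.N, "n": r.n, "M": r.M, "m": r.m,
             "p": r.p, "fdr": r.fdr, "significant": r.significant}
            for r in results
        ]
    ).sort_values("p", kind="mergesort").reset_index(drop=True)
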