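"""Differential accessibility between cell groups.

Counts are compared with a negative-binomial Wald test: per-cell totals give
relative library sizes (total cut sites / median), counts are size-factor
normalized, a per-feature NB dispersion comes from the method of moments, and
the test statistic is the difference of log group means over its asymptotic
standard error.  Fold changes use a small pseudocount so they stay finite.
The stock filters are p < 0.05 with |FC| > 1.2 (two-sided) or FC > 2
(enriched-only).  A plain two-sample t-test is provided for derived per-cell
scores such as motif z-scores, where counts-based modeling does not apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import false_discovery_control, norm, ttest_ind

logger = logging.getLogger(__name__)

FC_PSEUDOCOUNT = 0.1
DISPERSION_FLOOR = 1e-8


@dataclass
class ThresholdConfig:
    p_cut: float = 0.05
    fc_cut: float = 1.2  # use 2.0 for the enriched-only mode

    def __post_init__(self):
        if not (0.0 < self.p_cut < 1.0):
            raise ValueError("p_cut must be in (0,1)")
        if self.fc_cut <= 1.0:
            raise ValueError("fc_cut must exceed 1")


def size_factors(totals: pd.Series | np.ndarray,
                 index=None) -> pd.Series:
    """Relative library size: per-cell total cut sites over their median.

    Zero-total cells are excluded (logged); the median of the returned
    factors is 1 by construction.
    """
    s = pd.Series(totals, index=index, dtype=float)
    zero = s <= 0
    if zero.any():
        logger.warning("excluding %d zero-total cells", int(zero.sum()))
        s = s[~zero]
    if s.empty:
        raise ValueError("no cells with positive totals")
    return s / s.median()


def _as_dense(counts) -> np.ndarray:
    if sp.issparse(counts):
        return np.asarray(counts.todense(), dtype=float)
    return np.asarray(counts, dtype=float)


def nb_test(
    counts,
    group_a: np.ndarray,
    group_b: np.ndarray,
    factors: np.ndarray,
    feature_ids=None,
) -> pd.DataFrame:
    """NB Wald test of group A against group B for every feature (row).

    ``counts`` is features x cells; ``group_a``/``group_b`` are boolean cell
    masks; ``factors`` the per-cell size factors.  All statistics are
    computed from size-factor-normalized counts only, so scaling one cell's
    counts and factor together leaves every result unchanged.  Features with
    no counts at all get p = 1 and FC = 1.
    """
    x = _as_dense(counts)
    factors = np.asarray(factors, dtype=float)
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if not group_a.any() or not group_b.any():
        raise ValueError("both groups must be nonempty")
    z = x / factors[None, :]
    za, zb = z[:, group_a], z[:, group_b]
    na, nb_ = za.shape[1], zb.shape[1]
    ma, mb = za.mean(axis=1), zb.mean(axis=1)

    # pooled within-group variance and moment dispersion alpha = 1/phi
    va = za.var(axis=1, ddof=1) if na > 1 else np.zeros_like(ma)
    vb = zb.var(axis=1, ddof=1) if nb_ > 1 else np.zeros_like(mb)
    dof = max(na + nb_ - 2, 1)
    v_pool = ((max(na - 1, 0)) * va + (max(nb_ - 1, 0)) * vb) / dof
    m_pool = (na * ma + nb_ * mb) / (na + nb_)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(m_pool > 0, (v_pool - m_pool) / m_pool**2, 0.0)
    alpha = np.clip(alpha, DISPERSION_FLOOR, None)

    # half-a-count continuity floor on zero group means keeps the Wald
    # statistic finite and informative when one group is empty of signal
    fa = np.asarray(factors[group_a]).sum()
    fb = np.asarray(factors[group_b]).sum()
    ma_eff = np.maximum(ma, 0.5 / fa)
    mb_eff = np.maximum(mb, 0.5 / fb)

    var_log_a = (ma_eff + alpha * ma_eff**2) / (na * ma_eff**2)
    var_log_b = (mb_eff + alpha * mb_eff**2) / (nb_ * mb_eff**2)
    wald = (np.log(ma_eff) - np.log(mb_eff)) / np.sqrt(var_log_a + var_log_b)
    p = 2.0 * norm.sf(np.abs(wald))

    allzero = (ma == 0) & (mb == 0)
    p[allzero] = 1.0
    fc = (ma + FC_PSEUDOCOUNT) / (mb + FC_PSEUDOCOUNT)
    fc[allzero] = 1.0
    fdr = false_discovery_control(p, method="bh")
    ids = feature_ids if feature_ids is not None else np.arange(x.shape[0])
    return pd.DataFrame(
        {
            "feature": ids,
            "mean_a": ma,
            "mean_b": mb,
            "fc": fc,
            "log2_fc": np.log2(fc),
            "p": p,
            "fdr": fdr,
        }
    )


def t_test_scores(scores: pd.DataFrame, group_a, group_b) -> pd.DataFrame:
    """Welch t-test per column of a per-cell score table (e.g. motif z-scores).

    Suited to derived continuous scores; count features go through nb_test.
    """
    a = scores.loc[group_a]
    b = scores.loc[group_b]
    stat, p = ttest_ind(a.to_numpy(), b.to_numpy(), axis=0, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    diff_a, diff_b = a.mean(axis=0).to_numpy(), b.mean(axis=0).to_numpy()
    fc = (diff_a + FC_PSEUDOCOUNT + 1.0) / (diff_b + FC_PSEUDOCOUNT + 1.0)
    return pd.DataFrame(
        {
            "feature": scores.columns,
            "mean_a": diff_a,
            "mean_b": diff_b,
            "fc": fc,
            "log2_fc": np.log2(np.maximum(fc, 1e-12)),
            "p": p,
            "fdr": false_discovery_control(p, method="bh"),
        }
    )


def cluster_vs_rest(
    counts,
    labels: pd.Series,
    factors: np.ndarray,
    feature_ids=None,
) -> dict[int, pd.DataFrame]:
    """Run nb_test for every cluster against all remaining cells.

    Singleton clusters are skipped with a warning (no within-group variance).
    """
    labels_arr = labels.to_numpy()
    out: dict[int, pd.DataFrame] = {}
    for cl in sorted(pd.unique(labels_arr)):
        mask = labels_arr == cl
        if mask.sum() < 2:
            logger.warning("skipping singleton cluster %s", cl)
            continue
        out[cl] = nb_test(counts, mask, ~mask, factors, feature_ids=feature_ids)
    return out


def apply_thresholds(
    results: pd.DataFrame,
    cfg: ThresholdConfig,
    mode: str = "two_sided",
) -> tuple[pd.DataFrame, int]:
    """Filter differential results by the p and fold-change cuts.

    ``two_sided`` keeps p < p_cut and |log2 FC| > log2(fc_cut); ``enriched``
    keeps p < p_cut and FC > fc_cut.  Both inequalities are strict.
    """
    if len(results) == 0:
        return results, 0
    if mode == "two_sided":
        keep = (results["p"] < cfg.p_cut) & (
            results["log2_fc"].abs() > np.log2(cfg.fc_cut)
        )
    elif mode == "enriched":
        keep = (results["p"] < cfg.p_cut) & (results["fc"] > cfg.fc_cut)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    filtered = results[keep].reset_index(drop=True)
    return filtered, len(filtered)
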