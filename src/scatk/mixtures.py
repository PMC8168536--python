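"""EM fitting of count mixtures used for peak and cell calling.

Two models live here:

* a three-component "ZINBA-like" mixture -- a geometric component for the
  zero-inflated background, a negative binomial (NB) for diffuse noise and a
  second NB for open-chromatin signal -- fitted to smoothed per-base
  transposition-event counts;
* a two-component NB mixture separating ambient barcodes from real cells,
  fitted to contamination-adjusted in-peak fragment counts.

Both are fitted by EM on the aggregated value -> multiplicity table, so a
million observations with a few hundred distinct counts cost almost nothing
per iteration.  NB components are parameterized by mean ``mu`` and dispersion
``phi`` with variance ``mu + mu**2 / phi``.  The M-step for ``phi`` is a
bounded 1-D likelihood maximization seeded at the previous value and only
accepted when it improves the weighted likelihood, so the EM log-likelihood
sequence is non-decreasing by construction (a generalized EM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

_PHI_LO, _PHI_HI = 1e-3, 1e6


def nb_logpmf(k: np.ndarray, mu: float, phi: float) -> np.ndarray:
    """Log pmf of NB(mean mu, dispersion phi) at non-negative integers k."""
    k = np.asarray(k, dtype=float)
    if mu <= 0:
        # point mass at zero in the limit
        return np.where(k == 0, 0.0, -np.inf)
    r = phi
    p = phi / (phi + mu)  # success prob in scipy's convention
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1)
        + r * np.log(p)
        + k * np.log1p(-p)
    )


def geometric_logpmf(k: np.ndarray, p: float) -> np.ndarray:
    """Log pmf of the geometric law on {0,1,2,...}: P(k) = p (1-p)^k."""
    k = np.asarray(k, dtype=float)
    if p >= 1.0:
        return np.where(k == 0, 0.0, -np.inf)
    return np.log(p) + k * np.log1p(-p)


def _nb_weighted_loglik(values, weights, mu, phi) -> float:
    return float(np.sum(weights * nb_logpmf(values, mu, phi)))


def _update_phi(values, weights, mu, phi_old) -> float:
    """M-step for the NB dispersion: bounded 1-D maximization over log(phi).

    Keeps the previous value when the optimizer fails to improve the weighted
    likelihood, preserving EM monotonicity.
    """
    if np.sum(weights) <= 0 or mu <= 0:
        return phi_old

    def neg(logphi: float) -> float:
        return -_nb_weighted_loglik(values, weights, mu, float(np.exp(logphi)))

    res = minimize_scalar(
        neg, bounds=(np.log(_PHI_LO), np.log(_PHI_HI)), method="bounded",
        options={"xatol": 1e-6},
    )
    phi_new = float(np.exp(res.x))
    if _nb_weighted_loglik(values, weights, mu, phi_new) >= _nb_weighted_loglik(
        values, weights, mu, phi_old
    ):
        return phi_new
    return phi_old


def _moment_phi(values, weights) -> float:
    w = np.sum(weights)
    if w <= 0:
        return 1.0
    mu = float(np.sum(weights * values) / w)
    var = float(np.sum(weights * (values - mu) ** 2) / max(w, 1.0))
    excess = var - mu
    if excess <= 0:
        return _PHI_HI  # at or under Poisson: effectively no overdispersion
    return float(np.clip(mu * mu / excess, _PHI_LO, _PHI_HI))


def aggregate_counts(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse an integer sample to (unique values, multiplicities)."""
    values = np.asarray(values)
    if values.size and np.any(values < 0):
        raise ValueError("counts must be non-negative")
    uniq, counts = np.unique(values, return_counts=True)
    return uniq.astype(np.int64), counts.astype(np.float64)


@dataclass
class ZinbaMixture:
    """Fitted three-component mixture over smoothed event counts.

    Components: zero-inflation (geometric on {0,1,...}), noise NB and signal
    NB, with ``mu_signal > mu_noise`` enforced by relabeling after the fit.
    """

    w_zero: float
    w_noise: float
    w_signal: float
    p_geom: float
    mu_noise: float
    phi_noise: float
    mu_signal: float
    phi_signal: float
    loglik: float
    n_iter: int
    degenerate: bool = False
    loglik_history: list[float] = field(default_factory=list, repr=False)

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w_zero, self.w_noise, self.w_signal])

    def component_logpmf(self, k: np.ndarray) -> np.ndarray:
        """(3, len(k)) matrix of per-component log pmfs."""
        k = np.asarray(k)
        return np.vstack(
            [
                geometric_logpmf(k, self.p_geom),
                nb_logpmf(k, self.mu_noise, self.phi_noise),
                nb_logpmf(k, self.mu_signal, self.phi_signal),
            ]
        )

    def log_odds_signal_noise(self, k: np.ndarray) -> np.ndarray:
        """log posterior(signal)/posterior(noise) at counts k.

        Prior-to-posterior conversion shares the normalizer, so the ratio is
        the weighted likelihood ratio of the two NB components.
        """
        lp = self.component_logpmf(k)
        with np.errstate(divide="ignore"):
            return (np.log(self.w_signal) + lp[2]) - (np.log(self.w_noise) + lp[1])


def _em_loop(values, counts, comp_logpmf, m_step, weights, tol, max_iter):
    """Generic weighted EM driver; returns (weights, loglik_history, n_iter)."""
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logw = np.log(np.maximum(weights, 1e-300))[:, None]
        lp = comp_logpmf() + logw  # (K, V)
        norm = logsumexp(lp, axis=0)
        loglik = float(np.sum(counts * norm))
        history.append(loglik)
        resp = np.exp(lp - norm)  # responsibilities, (K, V)
        weights = (resp * counts).sum(axis=1) / counts.sum()
        m_step(resp)
        # converge on the mean per-observation log-likelihood change, which
        # keeps the criterion meaningful regardless of sample size
        if len(history) > 1 and (history[-1] - history[-2]) / counts.sum() <= tol:
            break
    return weights, history, n_iter


def fit_zinba(
    values: np.ndarray,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 4000,
) -> ZinbaMixture:
    """EM fit of the zero/noise/signal mixture to smoothed counts.

    Initialization (deterministic given ``seed``): zeros seed the geometric
    component; 2-means on log1p of the nonzero values seeds the two NB means,
    with dispersions from the method of moments.  Degenerate inputs (all
    zeros, or fewer than two distinct nonzero values) return ``w_zero`` mass
    on the geometric component with ``degenerate=True``.
    """
    vals, cnts = aggregate_counts(values)
    n = cnts.sum()
    if n == 0:
        raise ValueError("cannot fit a mixture to an empty sample")

    nz = vals > 0
    if nz.sum() < 2:
        return ZinbaMixture(
            w_zero=1.0, w_noise=0.0, w_signal=0.0, p_geom=1.0,
            mu_noise=0.0, phi_noise=1.0, mu_signal=0.0, phi_signal=1.0,
            loglik=0.0, n_iter=0, degenerate=True,
        )

    # ---- initialization -------------------------------------------------
    from sklearn.cluster import KMeans

    x = np.log1p(vals[nz].astype(float)).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=1, random_state=seed % (2**31))
    lab = km.fit_predict(x, sample_weight=cnts[nz])
    means = [vals[nz][lab == j].mean() if np.any(lab == j) else 0.0 for j in (0, 1)]
    lo, hi = (0, 1) if means[0] <= means[1] else (1, 0)

    def grp(j):
        m = np.zeros(vals.size, dtype=bool)
        m[np.where(nz)[0][lab == j]] = True
        return m

    lo_mask, hi_mask = grp(lo), grp(hi)
    mu_noise = float(np.sum(cnts[lo_mask] * vals[lo_mask]) / cnts[lo_mask].sum())
    mu_signal = float(np.sum(cnts[hi_mask] * vals[hi_mask]) / cnts[hi_mask].sum())
    phi_noise = _moment_phi(vals[lo_mask], cnts[lo_mask])
    phi_signal = _moment_phi(vals[hi_mask], cnts[hi_mask])
    p_geom = 0.8

    frac_zero = cnts[~nz].sum() / n if np.any(~nz) else 0.0
    w_zero = 0.5 * frac_zero
    rest = 1.0 - w_zero
    n_lo, n_hi = cnts[lo_mask].sum(), cnts[hi_mask].sum()
    w_noise = rest * n_lo / (n_lo + n_hi)
    w_signal = rest - w_noise

    state = {
        "p_geom": p_geom,
        "mu_noise": mu_noise, "phi_noise": phi_noise,
        "mu_signal": mu_signal, "phi_signal": phi_signal,
    }
    kf = vals.astype(float)

    def comp_logpmf():
        return np.vstack(
            [
                geometric_logpmf(vals, state["p_geom"]),
                nb_logpmf(vals, state["mu_noise"], state["phi_noise"]),
                nb_logpmf(vals, state["mu_signal"], state["phi_signal"]),
            ]
        )

    def m_step(resp):
        w = resp * cnts
        # geometric MLE on {0,1,...}: p = 1 / (1 + weighted mean)
        if w[0].sum() > 0:
            mean0 = float(np.sum(w[0] * kf) / w[0].sum())
            state["p_geom"] = min(1.0, 1.0 / (1.0 + mean0))
        for name, row in (("noise", w[1]), ("signal", w[2])):
            if row.sum() <= 0:
                continue
            mu = float(np.sum(row * kf) / row.sum())
            state[f"mu_{name}"] = mu
            state[f"phi_{name}"] = _update_phi(kf, row, mu, state[f"phi_{name}"])

    weights, history, n_iter = _em_loop(
        vals, cnts, comp_logpmf, m_step,
        np.array([w_zero, w_noise, w_signal]), tol, max_iter,
    )

    if state["mu_signal"] < state["mu_noise"]:  # enforce ordering
        state["mu_noise"], state["mu_signal"] = state["mu_signal"], state["mu_noise"]
        state["phi_noise"], state["phi_signal"] = state["phi_signal"], state["phi_noise"]
        weights = weights[[0, 2, 1]]

    return ZinbaMixture(
        w_zero=float(weights[0]), w_noise=float(weights[1]),
        w_signal=float(weights[2]), p_geom=float(state["p_geom"]),
        mu_noise=float(state["mu_noise"]), phi_noise=float(state["phi_noise"]),
        mu_signal=float(state["mu_signal"]), phi_signal=float(state["phi_signal"]),
        loglik=history[-1], n_iter=n_iter, degenerate=False,
        loglik_history=history,
    )


@dataclass
class TwoNbModel:
    """Two-NB mixture separating ambient-noise barcodes from cells."""

    w_noise: float
    w_signal: float
    mu_noise: float
    phi_noise: float
    mu_signal: float
    phi_signal: float
    loglik: float
    n_iter: int
    fixed_count: int = 0
    odds_threshold: float = 1000.0
    degenerate: bool = False
    loglik_history: list[float] = field(default_factory=list, repr=False)

    def log_odds_signal_noise(self, k: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return (
                np.log(self.w_signal)
                + nb_logpmf(k, self.mu_signal, self.phi_signal)
            ) - (np.log(self.w_noise) + nb_logpmf(k, self.mu_noise, self.phi_noise))


def fit_two_nb(
    values: np.ndarray,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 2000,
    split_quantile: float = 0.90,
) -> TwoNbModel:
    """EM fit of a two-NB mixture to per-barcode adjusted in-peak counts.

    Initialized by splitting at the ``split_quantile`` of the counts (most
    droplet barcodes are ambient).  Components are relabeled afterwards so
    ``mu_signal > mu_noise``.  When the two components collapse onto each
    other the model is flagged degenerate.
    """
    vals, cnts = aggregate_counts(values)
    if cnts.sum() == 0:
        raise ValueError("cannot fit a mixture to an empty sample")

    cut = float(np.quantile(np.repeat(vals, cnts.astype(int)), split_quantile))
    hi = vals.astype(float) > cut
    if not hi.any() or not (~hi).any():
        order = np.argsort(vals)
        hi = np.zeros(vals.size, dtype=bool)
        hi[order[-1]] = True

    def seg_stats(mask):
        mu = float(np.sum(cnts[mask] * vals[mask]) / cnts[mask].sum())
        return mu, _moment_phi(vals[mask], cnts[mask])

    mu_n, phi_n = seg_stats(~hi)
    mu_s, phi_s = seg_stats(hi)
    w_s = cnts[hi].sum() / cnts.sum()
    state = {"mu_noise": mu_n, "phi_noise": phi_n,
             "mu_signal": max(mu_s, mu_n + 1.0), "phi_signal": phi_s}
    kf = vals.astype(float)

    def comp_logpmf():
        return np.vstack(
            [
                nb_logpmf(vals, state["mu_noise"], state["phi_noise"]),
                nb_logpmf(vals, state["mu_signal"], state["phi_signal"]),
            ]
        )

    def m_step(resp):
        w = resp * cnts
        for name, row in (("noise", w[0]), ("signal", w[1])):
            if row.sum() <= 0:
                continue
            mu = float(np.sum(row * kf) / row.sum())
            state[f"mu_{name}"] = mu
            state[f"phi_{name}"] = _update_phi(kf, row, mu, state[f"phi_{name}"])

    weights, history, n_iter = _em_loop(
        vals, cnts, comp_logpmf, m_step, np.array([1.0 - w_s, w_s]), tol, max_iter,
    )

    if state["mu_signal"] < state["mu_noise"]:
        state["mu_noise"], state["mu_signal"] = state["mu_signal"], state["mu_noise"]
        state["phi_noise"], state["phi_signal"] = state["phi_signal"], state["phi_noise"]
        weights = weights[[1, 0]]

    mu_n, mu_s = state["mu_noise"], state["mu_signal"]
    # degeneracy: components collapsed onto each other, one component
    # vanished, or a single NB explains the data as well (BIC comparison --
    # catches EM carving a spurious "signal" out of one component's tail)
    mu1 = float(np.sum(cnts * kf) / cnts.sum())
    phi1 = _update_phi(kf, cnts, mu1, _moment_phi(vals, cnts))
    ll1 = _nb_weighted_loglik(vals, cnts, mu1, phi1)
    log_n = np.log(cnts.sum())
    bic_two = -2.0 * history[-1] + 5.0 * log_n
    bic_one = -2.0 * ll1 + 2.0 * log_n
    degenerate = (
        mu_s <= 0
        or (mu_s - mu_n) < 0.05 * max(mu_s, 1.0)
        or min(weights) < 1e-6
        or bic_one <= bic_two
    )
    return TwoNbModel(
        w_noise=float(weights[0]), w_signal=float(weights[1]),
        mu_noise=mu_n, phi_noise=float(state["phi_noise"]),
        mu_signal=mu_s, phi_signal=float(state["phi_signal"]),
        loglik=history[-1], n_iter=n_iter, degenerate=degenerate,
        loglik_history=history,
    )
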