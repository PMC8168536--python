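"""Latent semantic analysis embedding and clustering of cell barcodes.

The peak x cell matrix is IDF-weighted, reduced by truncated SVD, and each
cell is scaled to unit L2 norm (depth normalization in the reduced space).
Cells are then grouped by PAM-style k-medoids over a small k sweep and,
alternatively, by shared-nearest-neighbor graph clustering with greedy
modularity optimization.  A 2-D t-SNE projection is provided for plots only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cells import PeakBarcodeMatrix

DEFAULT_COMPONENTS = 15


@dataclass
class LsaEmbedding:
    """Barcode coordinates in the truncated-SVD space (cells x components)."""

    coords: np.ndarray
    barcodes: list[str]
    singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coords, index=self.barcodes,
            columns=[f"lsa_{i}" for i in range(self.n_components)],
        )


@dataclass
class ClusterLabels:
    labels: pd.Series  # barcode -> cluster id in 0..k-1
    k: int
    method: str


def idf_normalize(matrix: PeakBarcodeMatrix) -> PeakBarcodeMatrix:
    """Weight each peak by log(1 + n_barcodes / df); drop all-zero peaks.

    df is the number of barcodes with a nonzero count at the peak, so peaks
    open in nearly every cell are down-weighted toward log 2.
    """
    m = matrix.matrix.tocsr()
    n_bc = m.shape[1]
    df = np.asarray((m > 0).sum(axis=1)).ravel()
    keep = df > 0
    weights = np.zeros(m.shape[0])
    weights[keep] = np.log1p(n_bc / df[keep])
    weighted = sp.diags(weights) @ m.astype(float)
    weighted = weighted[keep]
    return PeakBarcodeMatrix(
        matrix=weighted.tocsr(),
        peaks=matrix.peaks[keep].reset_index(drop=True),
        barcodes=matrix.barcodes,
    )


def lsa_embed(matrix: PeakBarcodeMatrix, n_components: int = DEFAULT_COMPONENTS,
              seed: int = 0) -> LsaEmbedding:
    """Truncated SVD of the weighted matrix; cells are the right singular
    vectors scaled by their singular values.

    Deterministic given the seed (fixed ARPACK start vector); the sign of
    each component is fixed by making its largest-magnitude peak loading
    positive.
    """
    m = matrix.matrix
    if n_components >= min(m.shape):
        raise ValueError("n_components must be smaller than both matrix dims")
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(m.shape))
    u, s, vt = sp.linalg.svds(m.astype(float), k=n_components, v0=v0)
    order = np.argsort(-s)
    u, s, vt = u[:, order], s[order], vt[order]
    # sign convention: largest-|loading| entry of each left vector positive
    flip = np.sign(u[np.abs(u).argmax(axis=0), np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    u *= flip
    vt *= flip[:, None]
    coords = (vt * s[:, None]).T  # cells x components
    return LsaEmbedding(coords=coords, barcodes=list(matrix.barcodes),
                        singular_values=s)


def l2_depth_normalize(embedding: LsaEmbedding) -> LsaEmbedding:
    """Scale every cell vector to unit Euclidean norm; zero vectors are
    excluded (flagged by omission)."""
    norms = np.linalg.norm(embedding.coords, axis=1)
    keep = norms > 0
    if not keep.all():
        import logging

        logging.getLogger(__name__).warning(
            "excluding %d zero-norm barcodes", int((~keep).sum())
        )
    coords = embedding.coords[keep] / norms[keep, None]
    barcodes = [b for b, k in zip(embedding.barcodes, keep) if k]
    return LsaEmbedding(coords=coords, barcodes=barcodes,
                        singular_values=embedding.singular_values)


def _pam_iterate(x: np.ndarray, medoids: np.ndarray, max_iter: int = 100):
    """Alternate nearest-medoid assignment and per-cluster medoid update."""
    objective = []
    labels = None
    for _ in range(max_iter):
        d = np.linalg.norm(x[:, None, :] - x[medoids][None, :, :], axis=2)
        new_labels = d.argmin(axis=1)
        objective.append(float(d[np.arange(len(x)), new_labels].sum()))
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(len(medoids)):
            members = np.flatnonzero(labels == j)
            if members.size == 0:
                continue
            dd = np.linalg.norm(x[members][:, None] - x[members][None], axis=2)
            medoids[j] = members[dd.sum(axis=1).argmin()]
    return labels, medoids, objective


def _spread_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy D^2-style seeding: start at a random point, then repeatedly take
    the point farthest from the chosen medoids.  Keeps the initial medoids in
    distinct dense regions, which plain random init does not guarantee."""
    medoids = [int(rng.integers(len(x)))]
    d = np.linalg.norm(x - x[medoids[0]], axis=1)
    for _ in range(1, k):
        nxt = int(d.argmax())
        medoids.append(nxt)
        d = np.minimum(d, np.linalg.norm(x - x[nxt], axis=1))
    return np.array(medoids)


def kmedoids(embedding: LsaEmbedding, k: int, seed: int = 0,
             max_iter: int = 100) -> ClusterLabels:
    """PAM-style k-medoids with Euclidean distance, deterministic given seed."""
    x = embedding.coords
    if len(x) < k:
        raise ValueError(f"need at least k={k} points, got {len(x)}")
    rng = np.random.default_rng(seed)
    medoids = _spread_init(x, k, rng)
    labels, _, objective = _pam_iterate(x, medoids, max_iter)
    if any(b - a > 1e-9 for a, b in zip(objective, objective[1:])):
        raise AssertionError("PAM objective increased")  # pragma: no cover
    return ClusterLabels(
        labels=pd.Series(labels, index=embedding.barcodes, name="cluster"),
        k=k, method="kmedoids",
    )


def kmedoids_sweep(embedding: LsaEmbedding, k_min: int = 3, k_max: int = 6,
                   seed: int = 0) -> ClusterLabels:
    """Sweep k over [k_min, k_max] and keep the labeling with the highest mean
    silhouette (the per-cluster differential stages need one labeling)."""
    from sklearn.metrics import silhouette_score

    best, best_score = None, -np.inf
    for k in range(k_min, min(k_max, len(embedding.coords) - 1) + 1):
        labels = kmedoids(embedding, k, seed=seed)
        if labels.labels.nunique() < 2:
            continue
        score = silhouette_score(embedding.coords, labels.labels.to_numpy())
        if score > best_score:
            best, best_score = labels, score
    if best is None:
        raise ValueError("no valid k in sweep")
    return best


def graph_cluster(embedding: LsaEmbedding, n_neighbors: int = 15,
                  seed: int = 0, resolution: float = 0.8) -> ClusterLabels:
    """Shared-nearest-neighbor graph + greedy modularity communities.

    The seed is accepted for interface uniformity; the SNN construction and
    networkx's greedy modularity optimization are deterministic regardless.
    Resolution defaults to 0.8, the customary community-detection setting for
    single-cell SNN graphs: plain modularity (resolution 1) fragments large
    sparse neighborhoods even when they form one well-separated population.
    """
    import networkx as nx
    from sklearn.neighbors import NearestNeighbors

    x = embedding.coords
    n = len(x)
    if n <= n_neighbors:
        raise ValueError("need more points than n_neighbors")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)
    neigh = [set(row[1:]) for row in idx]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i, 1:]:
            j = int(j)
            a, b = (i, j) if i < j else (j, i)
            if g.has_edge(a, b):
                continue
            shared = len(neigh[i] & neigh[j])
            w = shared / (2 * n_neighbors - shared) if shared else 1e-6
            g.add_edge(a, b, weight=w)
    comms = nx.community.greedy_modularity_communities(
        g, weight="weight", resolution=resolution
    )
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(comms):
        labels[list(members)] = cid
    return ClusterLabels(
        labels=pd.Series(labels, index=embedding.barcodes, name="cluster"),
        k=len(comms), method="graph",
    )


def embed_2d(embedding: LsaEmbedding, seed: int = 0) -> pd.DataFrame:
    """t-SNE to 2-D, for visualization only (never used for inference)."""
    from sklearn.manifold import TSNE

    n = len(embedding.coords)
    perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    ts = TSNE(n_components=2, random_state=seed, init="pca",
              perplexity=perplexity)
    xy = ts.fit_transform(embedding.coords)
    return pd.DataFrame(xy, index=embedding.barcodes, columns=["tsne_1", "tsne_2"])
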