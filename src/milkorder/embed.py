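"""Linear and manifold embeddings of inter-animal relationships.

Two views of the cows x days quantile matrix:

* **PCA on the pairwise-complete correlation matrix** — days are the
  variables, cows the observations.  Missing records are handled by
  computing each day-day correlation over the cow pairs observed on both
  days; scores are computed after per-day standardisation with missing
  entries set to the day mean.

* **Diffusion-map-style spectral embedding** — pairwise cow distances
  are Euclidean distances between temporally aligned quantile vectors,
  scaled by sqrt(T / |S_ij|) to compensate for missing records, then
  inverted to similarities; a k-nearest-neighbour graph (k = 10, union
  symmetrised) is built and the symmetric normalised graph Laplacian
  eigendecomposed.  The smallest non-trivial eigenvectors are the
  embedding coordinates.

Spectral embeddings of chain-like ("rope") data imprint a cosine
harmonic series on every axis; :func:`harmonic_reference` returns the
path-graph Laplacian eigenvectors so this artifact can be overlaid on an
embedding and recognised for what it is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse.csgraph as csgraph

from .wrangle import QuantileMatrix

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "scaled_pairwise",
    "scaled_distance",
    "pca_correlation",
    "similarity_invert",
    "knn_graph",
    "laplacian_embedding",
    "harmonic_reference",
    "gap_statistic",
    "QueuePCA",
    "DiffusionMap",
]


class OverlapError(ValueError):
    """Raised when cow pairs share too few observation days."""


@dataclass
class DistanceMatrix:
    """Symmetric cow-cow distances with per-pair overlap counts."""

    values: pd.DataFrame  # cows x cows
    overlap: pd.DataFrame  # |S_ij| = days both observed
    total_days: int

    @property
    def cow_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class Embedding:
    """Spectral embedding: sorted eigenvalues + coordinates per cow."""

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame  # cows x dims
    n_significant: int
    method: str
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        ev = np.array2string(self.eigenvalues[:8], precision=4)
        return (
            f"{self.method} embedding: {self.coordinates.shape[0]} cows, "
            f"{self.coordinates.shape[1]} stored dims, "
            f"{self.n_significant} significant\nleading eigenvalues: {ev}"
        )


def scaled_pairwise(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Missingness-scaled Euclidean distances between the rows of ``x``.

    Returns ``(d, overlap)``; see :func:`scaled_distance` for the
    definition.  Rows with no shared observations get NaN.
    """
    x = np.asarray(x, float)
    m = (~np.isnan(x)).astype(float)
    x0 = np.where(np.isnan(x), 0.0, x)
    t = x.shape[1]
    overlap = m @ m.T
    sq = (x0**2) @ m.T + m @ (x0**2).T - 2.0 * (x0 @ x0.T)
    sq = np.maximum(sq, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(np.where(overlap > 0, t / np.maximum(overlap, 1) * sq, np.nan))
    np.fill_diagonal(d, 0.0)
    return d, overlap


def scaled_distance(
    qm: QuantileMatrix, overlap_min: int = 10, on_insufficient: str = "error"
) -> DistanceMatrix:
    """Missingness-scaled Euclidean distance between cow quantile vectors.

    d_ij = sqrt( (T / |S_ij|) * sum_{t in S_ij} (q_it - q_jt)^2 ) with T
    the total number of days and S_ij the days both cows were recorded.
    The T/|S_ij| factor makes d invariant to masking days of a
    constant-difference pair.  Pairs with |S_ij| < overlap_min raise
    (``on_insufficient="error"``) or are set NaN (``"nan"``).
    """
    d, overlap = scaled_pairwise(qm.values.to_numpy(float))
    t = qm.n_days
    ids = qm.cow_ids
    low = (overlap < overlap_min) & ~np.eye(len(ids), dtype=bool)
    if low.any():
        pairs = [
            (ids[i], ids[j]) for i, j in zip(*np.nonzero(np.triu(low))) if i < j
        ]
        if on_insufficient == "error":
            raise OverlapError(
                f"{len(pairs)} cow pair(s) share < {overlap_min} days: "
                f"{pairs[:10]}{'...' if len(pairs) > 10 else ''}"
            )
        d[low] = np.nan
    return DistanceMatrix(
        pd.DataFrame(d, index=ids, columns=ids),
        pd.DataFrame(overlap.astype(int), index=ids, columns=ids),
        total_days=t,
    )


def pca_correlation(
    qm: QuantileMatrix, n_dims_store: int = 10, missing_fill: str = "day-mean"
) -> Embedding:
    """PCA of the pairwise-complete day-day correlation matrix.

    Days are variables, cows observations.  Zero-variance days are
    dropped with a warning.  Cow scores are the standardised (mean-0,
    SD-1 per day) data projected onto the eigenvectors; missing entries
    are filled with the day mean (0 after standardisation) by default,
    or with the cow's own median (``missing_fill="row-median"``).
    ``n_significant`` counts eigenvalues above 1 (Kaiser rule); the full
    spectrum is kept in ``extra["scree"]`` for manual override.
    """
    if qm.n_cows < 3 or qm.n_days < 3:
        raise ValueError("need at least 3 cows and 3 days")
    vals = qm.values
    sd = vals.std(ddof=1)
    flat = sd.fillna(0.0) == 0.0
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} zero-variance day(s)")
        vals = vals.loc[:, ~flat]
    corr = vals.corr(min_periods=2).to_numpy()
    corr = np.where(np.isnan(corr), 0.0, corr)  # disjoint pairs carry no signal
    np.fill_diagonal(corr, 1.0)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    z = (vals - vals.mean()) / vals.std(ddof=1)
    if missing_fill == "day-mean":
        z = z.fillna(0.0)
    elif missing_fill == "row-median":
        z = z.apply(lambda row: row.fillna(row.median()), axis=1).fillna(0.0)
    else:
        raise ValueError(f"unknown missing_fill {missing_fill!r}")
    z = z.to_numpy()
    k = min(n_dims_store, len(evals))
    scores = z @ evecs[:, :k]
    med = qm.values.median(axis=1).to_numpy()
    scores = _orient(scores, med)
    coords = pd.DataFrame(
        scores, index=qm.cow_ids, columns=[f"pc{i + 1}" for i in range(k)]
    )
    n_sig = int((evals > 1.0).sum())
    return Embedding(
        eigenvalues=evals,
        coordinates=coords,
        n_significant=n_sig,
        method="pca",
        extra={"scree": pd.Series(evals, name="eigenvalue"), "loadings": evecs[:, :k]},
    )


def similarity_invert(dm: DistanceMatrix) -> pd.DataFrame:
    """Invert distances to similarities: s_ij = 1/d_ij.

    Distinct cows at distance 0 receive ten times the largest finite
    similarity in the matrix (a regularised stand-in for infinity); the
    diagonal is set to 0 and excluded from graph construction.
    """
    d = dm.values.to_numpy(float).copy()
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        s = np.where(off & (d > 0), 1.0 / d, 0.0)
    finite_max = s[off & np.isfinite(s) & (s > 0)].max() if (d[off] > 0).any() else 1.0
    zero_pairs = off & (d == 0)
    s[zero_pairs] = finite_max * 10.0
    np.fill_diagonal(s, 0.0)
    return pd.DataFrame(s, index=dm.cow_ids, columns=dm.cow_ids)


def knn_graph(similarity: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Union-symmetrised k-nearest-neighbour graph weighted by similarity.

    Edge (i, j) exists iff j is among i's k most similar neighbours OR
    vice versa, so every node has degree >= k.  Disconnected graphs are
    allowed (warning with component sizes); the spectral embedding
    handles each component's trivial eigenvector.
    """
    s = similarity.to_numpy(float)
    n = s.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of cows {n}")
    mask = np.zeros_like(s, dtype=bool)
    for i in range(n):
        nbr = np.argpartition(s[i], -k)[-k:]
        mask[i, nbr] = True
    mask |= mask.T
    np.fill_diagonal(mask, False)
    w = np.where(mask, s, 0.0)
    n_comp, comp = csgraph.connected_components(w > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        warnings.warn(f"kNN graph has {n_comp} components with sizes {sizes}")
    return pd.DataFrame(w, index=similarity.index, columns=similarity.columns)


def _orient(coords: np.ndarray, reference: np.ndarray | None) -> np.ndarray:
    """Flip each column's sign so its correlation with the reference
    (median entry quantile) is non-negative; stabilises plots."""
    if reference is None:
        return coords
    out = coords.copy()
    ref = reference - np.nanmean(reference)
    for j in range(out.shape[1]):
        c = np.nansum(ref * (out[:, j] - np.nanmean(out[:, j])))
        if c < 0:
            out[:, j] = -out[:, j]
    return out


def laplacian_embedding(
    adjacency: pd.DataFrame,
    n_dims_max: int = 10,
    normalization: str = "symmetric",
    orient_by: np.ndarray | None = None,
    trivial_tol: float = 1e-9,
) -> Embedding:
    """Spectral embedding from the graph Laplacian of a weighted graph.

    With the symmetric normalised Laplacian L = I - D^{-1/2} W D^{-1/2}
    (default; ``"unnormalized"`` and ``"random_walk"`` also available),
    the eigenvectors of the smallest non-trivial eigenvalues are the
    coordinates.  One near-zero eigenpair per connected component is
    trivial and excluded.  ``n_significant`` is chosen at the largest
    relative eigengap among the first ``n_dims_max`` non-trivial
    eigenvalues; the full spectrum is exported for manual audit.
    """
    w = adjacency.to_numpy(float)
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if (w < 0).any():
        raise ValueError("adjacency must be non-negative")
    n = w.shape[0]
    deg = w.sum(axis=1)
    deg_safe = np.where(deg > 0, deg, 1.0)
    if normalization == "symmetric":
        dis = 1.0 / np.sqrt(deg_safe)
        lap = np.eye(n) - dis[:, None] * w * dis[None, :]
        evals, evecs = np.linalg.eigh(lap)
    elif normalization == "unnormalized":
        lap = np.diag(deg) - w
        evals, evecs = np.linalg.eigh(lap)
    elif normalization == "random_walk":
        # generalised problem L u = lambda D u shares eigenvalues with rw
        lap = np.diag(deg) - w
        evals, evecs = scipy.linalg.eigh(lap, np.diag(deg_safe))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    n_comp, _ = csgraph.connected_components(w > 0, directed=False)
    n_trivial = max(int((evals < trivial_tol).sum()), n_comp)
    n_trivial = min(n_trivial, n - 1)
    nt_vals = evals[n_trivial:]
    nt_vecs = evecs[:, n_trivial:]
    k = min(n_dims_max, len(nt_vals))
    lead = nt_vals[:k]
    # largest relative gap among consecutive non-trivial eigenvalues
    if k >= 2:
        gaps = np.diff(lead) / np.maximum(lead[:-1], 1e-12)
        n_sig = int(np.argmax(gaps)) + 1
    else:
        n_sig = k
    coords = _orient(nt_vecs[:, :k], orient_by)
    cols = [f"dim{i + 1}" for i in range(k)]
    coords_df = pd.DataFrame(coords, index=adjacency.index, columns=cols)
    return Embedding(
        eigenvalues=evals,
        coordinates=coords_df,
        n_significant=n_sig,
        method="diffusion",
        extra={
            "n_trivial": n_trivial,
            "n_components": n_comp,
            "nontrivial_eigenvalues": nt_vals[:k],
        },
    )


def harmonic_reference(n_points: int, n_dims: int) -> np.ndarray:
    """Path-graph Laplacian eigenvectors: the harmonic artifact curves.

    v_k(j) = cos(pi * k * (j + 0.5) / n), k = 1..n_dims, each unit
    normalised.  v_k has exactly k sign changes; overlaying these on an
    embedding sorted by its first coordinate shows how much of the
    embedding's curvature is the spectral artifact of chain-like data
    rather than real structure.
    """
    if n_dims >= n_points:
        raise ValueError("n_dims must be < n_points")
    j = np.arange(n_points)
    vecs = np.empty((n_points, n_dims))
    for k in range(1, n_dims + 1):
        v = np.cos(np.pi * k * (j + 0.5) / n_points)
        vecs[:, k - 1] = v / np.linalg.norm(v)
    return vecs


def gap_statistic(
    coords: np.ndarray, k_max: int = 5, n_ref: int = 10, seed: int = 0
) -> int:
    """Number of clusters selected by the gap statistic on embedding
    coordinates (Tibshirani rule: smallest k with Gap(k) >= Gap(k+1) -
    s_{k+1}); 1 means no evidence of clustering / social cohesion."""
    from sklearn.cluster import KMeans

    x = np.asarray(coords, float)
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)

    def log_wk(data, k):
        if k == 1:
            return np.log(((data - data.mean(axis=0)) ** 2).sum())
        km = KMeans(n_clusters=k, n_init=4, random_state=0).fit(data)
        return np.log(max(km.inertia_, 1e-300))

    gaps, sks = [], []
    for k in range(1, k_max + 1):
        ref = [
            log_wk(rng.uniform(lo, hi, size=x.shape), k) for _ in range(n_ref)
        ]
        gaps.append(np.mean(ref) - log_wk(x, k))
        sks.append(np.std(ref) * np.sqrt(1 + 1 / n_ref))
    for k in range(1, k_max):
        if gaps[k - 1] >= gaps[k] - sks[k]:
            return k
    return k_max


class QueuePCA:
    """Model-style front end for :func:`pca_correlation`."""

    def __init__(self, qm: QuantileMatrix, n_dims_store: int = 10):
        self.qm = qm
        self.n_dims_store = n_dims_store

    def fit(self) -> Embedding:
        return pca_correlation(self.qm, self.n_dims_store)


class DiffusionMap:
    """Model-style front end for the full spectral-embedding pipeline.

    scaled distances -> inverted similarities -> kNN graph -> Laplacian
    eigendecomposition, with eigenvectors oriented by median entry
    quantile.
    """

    def __init__(
        self,
        qm: QuantileMatrix,
        k: int = 10,
        overlap_min: int = 10,
        n_dims_max: int = 10,
        normalization: str = "symmetric",
    ):
        self.qm = qm
        self.k = k
        self.overlap_min = overlap_min
        self.n_dims_max = n_dims_max
        self.normalization = normalization

    def fit(self) -> Embedding:
        dm = scaled_distance(self.qm, self.overlap_min)
        sim = similarity_invert(dm)
        adj = knn_graph(sim, self.k)
        med = self.qm.values.median(axis=1).to_numpy()
        emb = laplacian_embedding(
            adj,
            self.n_dims_max,
            normalization=self.normalization,
            orient_by=med,
        )
        emb.extra["median_quantile"] = pd.Series(med, index=self.qm.cow_ids)
        return emb
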