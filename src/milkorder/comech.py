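"""Data Mechanics iterative co-clustering of the cows x days matrix.

The algorithm alternately clusters rows (cows) and columns (days),
letting each axis's clustering inform the other's distance metric:

1. compute missingness-scaled Euclidean distances between cows and
   between days from the raw quantile matrix;
2. build Ward (D2) hierarchical trees on both axes and cut them at r
   row clusters and c column clusters;
3. re-represent each day by its r-vector of within-cow-cluster mean
   quantiles and each cow by its c-vector of within-day-cluster means;
4. recompute the two distance matrices in these reduced representations
   and repeat until both label vectors stop changing.

The *energy* of a co-clustering is the sum over the r x c cells of the
within-cell variance of entry quantiles; iteration drives the
contingency structure toward maximally homogeneous cells, visually
enhancing block structure (subperiod shifts, drifting subgroups) when
the matrix is drawn as a heatmap.  Running the full 1..r_max x 1..c_max
grid and scanning the heatmaps is how granularity is chosen; days that
land in tiny column clusters across most fine-granularity grid cells
are whole-herd outliers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .embed import scaled_pairwise
from .wrangle import QuantileMatrix

__all__ = [
    "CoClustering",
    "ward_tree",
    "cut_tree",
    "dm_cocluster",
    "dm_grid",
    "flag_outlier_days",
    "DataMechanics",
]


def ward_tree(distances: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Ward minimum-variance linkage (ward.D2 convention) on a distance matrix.

    Accepts a square symmetric matrix (or condensed vector) of
    dissimilarities on the distance scale; merge heights come out on the
    same scale and are non-decreasing.  Deterministic for a given input.
    """
    d = np.asarray(distances, float)
    if d.ndim == 2:
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite entries")
        d = squareform(d, checks=False)
    elif not np.all(np.isfinite(d)):
        raise ValueError("condensed distances contain non-finite entries")
    return sch.linkage(d, method="ward")


def cut_tree(linkage: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage at k clusters; labels 1..k in order of first appearance."""
    lab = sch.fcluster(linkage, t=k, criterion="maxclust")
    # canonicalise label numbering for deterministic comparisons
    _, canon = np.unique(lab, return_inverse=True)
    first = {}
    out = np.empty_like(lab)
    nxt = 1
    for i, c in enumerate(canon):
        if c not in first:
            first[c] = nxt
            nxt += 1
        out[i] = first[c]
    return out


@dataclass
class CoClustering:
    """Row/column cluster labels with the iteration energy trace."""

    row_labels: pd.Series  # cow -> cluster 1..r
    col_labels: pd.Series  # day -> cluster 1..c
    energy_trace: list
    converged: bool
    iterations: int
    r: int
    c: int

    def contingency(self) -> pd.DataFrame:
        """Cell observation counts, row clusters x column clusters."""
        return pd.crosstab(self.row_labels, self.col_labels)

    def cell_means(self, qm: QuantileMatrix) -> pd.DataFrame:
        x = qm.values
        out = np.full((self.r, self.c), np.nan)
        for a in range(1, self.r + 1):
            rows = self.row_labels.index[self.row_labels == a]
            for b in range(1, self.c + 1):
                cols = self.col_labels.index[self.col_labels == b]
                cell = x.loc[rows, cols].to_numpy()
                if np.isfinite(cell).any():
                    out[a - 1, b - 1] = np.nanmean(cell)
        return pd.DataFrame(
            out,
            index=pd.RangeIndex(1, self.r + 1, name="row_cluster"),
            columns=pd.RangeIndex(1, self.c + 1, name="col_cluster"),
        )

    def summary(self) -> str:
        return (
            f"Data Mechanics co-clustering r={self.r}, c={self.c}: "
            f"{'converged' if self.converged else 'NOT converged'} in "
            f"{self.iterations} iteration(s); final energy "
            f"{self.energy_trace[-1]:.6g}"
        )


def _energy(x: np.ndarray, row_lab: np.ndarray, col_lab: np.ndarray) -> float:
    """Sum of within-cell variances (population), missing cells excluded."""
    total = 0.0
    empty = 0
    for a in np.unique(row_lab):
        xr = x[row_lab == a]
        for b in np.unique(col_lab):
            cell = xr[:, col_lab == b]
            vals = cell[np.isfinite(cell)]
            if vals.size == 0:
                empty += 1
                continue
            total += float(np.var(vals))
    if empty:
        warnings.warn(f"{empty} empty co-cluster cell(s) contribute zero energy")
    return total


def _cluster_means(x: np.ndarray, lab: np.ndarray, axis: int) -> np.ndarray:
    """Mean of x within each cluster along ``axis``; NaN-aware.

    axis=0: returns (n_clusters x n_cols) means over row clusters.
    """
    if axis == 1:
        return _cluster_means(x.T, lab, 0).T
    ks = np.unique(lab)
    out = np.full((len(ks), x.shape[1]), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, k in enumerate(ks):
            out[i] = np.nanmean(x[lab == k], axis=0)
    return out


def dm_cocluster(
    qm: QuantileMatrix,
    r: int,
    c: int,
    max_iter: int = 20,
    cross_update: bool = True,
) -> CoClustering:
    """Iterative co-clustering of cows (rows) and days (columns).

    Converges when both label vectors repeat; if labels oscillate past
    ``max_iter`` the minimum-energy iterate is returned with
    ``converged=False``.  With ``cross_update=False`` the reduced
    re-representation step is skipped and the result is exactly two
    independent Ward clusterings of the raw matrix.
    """
    x = qm.values.to_numpy(float)
    n, t = x.shape
    if not (1 <= r <= n):
        raise ValueError(f"r={r} outside 1..{n}")
    if not (1 <= c <= t):
        raise ValueError(f"c={c} outside 1..{t}")

    def labels_from(mat_rows: np.ndarray, mat_cols: np.ndarray):
        if r == 1:
            row_lab = np.ones(n, int)
        else:
            dr, _ = scaled_pairwise(mat_rows)
            row_lab = cut_tree(ward_tree(np.nan_to_num(dr)), r)
        if c == 1:
            col_lab = np.ones(t, int)
        else:
            dc, _ = scaled_pairwise(mat_cols)
            col_lab = cut_tree(ward_tree(np.nan_to_num(dc)), c)
        return row_lab, col_lab

    row_lab, col_lab = labels_from(x, x.T)
    trace = [_energy(x, row_lab, col_lab)]
    seen = {(tuple(row_lab), tuple(col_lab)): 0}
    best = (trace[0], row_lab, col_lab)
    converged = False
    it = 1
    if cross_update:
        while it < max_iter:
            # days in cow-cluster-mean space, cows in day-cluster-mean space
            day_repr = _cluster_means(x, row_lab, axis=0).T  # days x r
            cow_repr = _cluster_means(x, col_lab, axis=1)  # cows x c
            new_row, new_col = labels_from(cow_repr, day_repr)
            e = _energy(x, new_row, new_col)
            trace.append(e)
            if e < best[0]:
                best = (e, new_row, new_col)
            key = (tuple(new_row), tuple(new_col))
            if key in seen:
                converged = (new_row == row_lab).all() and (new_col == col_lab).all()
                row_lab, col_lab = new_row, new_col
                # a confirming pass does not count as a new iteration
                it = seen[key] + 1 if converged else it + 1
                break
            seen[key] = it
            row_lab, col_lab = new_row, new_col
            it += 1
        else:
            converged = False
    else:
        converged = True

    if not converged and cross_update:
        _, row_lab, col_lab = best
    final_e = _energy(x, row_lab, col_lab)
    if not trace or trace[-1] != final_e:
        trace.append(final_e)
    return CoClustering(
        row_labels=pd.Series(row_lab, index=qm.cow_ids, name="row_cluster"),
        col_labels=pd.Series(col_lab, index=qm.days, name="col_cluster"),
        energy_trace=trace,
        converged=converged,
        iterations=it,
        r=r,
        c=c,
    )


def dm_grid(
    qm: QuantileMatrix,
    r_max: int = 10,
    c_max: int = 10,
    max_iter: int = 20,
) -> dict[tuple[int, int], CoClustering]:
    """Full (r, c) grid of co-clusterings, 1..r_max x 1..c_max.

    The grid is the raw material for the visual scan that picks the
    clustering granularity; :func:`grid_summary` tabulates per-cell
    diagnostics to guide it.
    """
    if r_max > qm.n_cows or c_max > qm.n_days:
        raise ValueError("grid bounds exceed matrix dimensions")
    return {
        (r, c): dm_cocluster(qm, r, c, max_iter=max_iter)
        for r, c in itertools.product(range(1, r_max + 1), range(1, c_max + 1))
    }


def grid_summary(
    ensemble: dict[tuple[int, int], CoClustering],
    qm: QuantileMatrix | None = None,
) -> pd.DataFrame:
    """Per-grid-cell diagnostics: final energy, smallest column-cluster
    size, and subperiod purity of the column clusters."""
    rows = []
    for (r, c), cc in sorted(ensemble.items()):
        col_sizes = cc.col_labels.value_counts()
        purity = np.nan
        if qm is not None:
            sub = qm.subperiods.loc[cc.col_labels.index]
            purity = float(
                pd.crosstab(cc.col_labels, sub).max(axis=1).sum() / len(sub)
            )
        rows.append(
            {
                "r": r,
                "c": c,
                "energy": cc.energy_trace[-1],
                "iterations": cc.iterations,
                "converged": cc.converged,
                "min_col_cluster_size": int(col_sizes.min()),
                "subperiod_purity": purity,
            }
        )
    return pd.DataFrame(rows).set_index(["r", "c"])


def flag_outlier_days(
    ensemble: dict[tuple[int, int], CoClustering],
    max_size: int = 2,
    min_persistence: float = 0.8,
    c_min: int = 6,
) -> list:
    """Days persistently isolated into tiny column clusters.

    A day is flagged iff it falls in a column cluster of size <=
    ``max_size`` in at least ``min_persistence`` of the grid cells with
    c >= ``c_min`` (fine temporal granularity), across all row
    granularities.  Whole-herd outlier days stay isolated no matter how
    the social axis is stratified, which separates them from ordinary
    cluster-boundary churn.
    """
    if max_size <= 0:
        return []
    cells = [cc for (r, c), cc in ensemble.items() if c >= c_min]
    if not cells:
        return []
    hits: dict = {}
    for cc in cells:
        sizes = cc.col_labels.value_counts()
        small = sizes[sizes <= max_size].index
        for day in cc.col_labels.index[cc.col_labels.isin(small)]:
            hits[day] = hits.get(day, 0) + 1
    n_cells = len(cells)
    return sorted(d for d, h in hits.items() if h / n_cells >= min_persistence)


class DataMechanics:
    """Model-style front end for the co-clustering pipeline.

    ``fit()`` returns a single CoClustering at (r, c); ``fit_grid()``
    computes the full grid and attaches the diagnostic table and the
    outlier-day list.
    """

    def __init__(self, qm: QuantileMatrix, r: int = 2, c: int = 2, max_iter: int = 20):
        self.qm = qm
        self.r = r
        self.c = c
        self.max_iter = max_iter

    def fit(self) -> CoClustering:
        return dm_cocluster(self.qm, self.r, self.c, self.max_iter)

    def fit_grid(self, r_max: int = 10, c_max: int = 10) -> "DataMechanicsGrid":
        ens = dm_grid(self.qm, r_max, c_max, self.max_iter)
        return DataMechanicsGrid(
            ensemble=ens,
            summary_table=grid_summary(ens, self.qm),
            outlier_days=flag_outlier_days(ens),
        )


@dataclass
class DataMechanicsGrid:
    ensemble: dict
    summary_table: pd.DataFrame
    outlier_days: list = field(default_factory=list)

    def summary(self) -> str:
        tbl = self.summary_table
        return (
            f"Data Mechanics grid: {len(self.ensemble)} co-clusterings\n"
            f"energy range: {tbl['energy'].min():.4g} .. {tbl['energy'].max():.4g}\n"
            f"outlier days (persistent tiny column clusters): {self.outlier_days}"
        )
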