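"""Entropy- and variance-based quantification of queue stochasticity.

Two complementary views of how random queue formation is:

* **Per queue segment** — the queue is divided into K equal quantile
  segments (default 20) and Shannon entropy of *cow identity* is
  computed within each segment, pooling counts over days:

      H_q = -sum_c (n_c|q / N_q) * log2(n_c|q / N_q)

  The more consistently a small set of cows occupies a segment, the
  lower H_q; under fully random queueing every cow is equally likely and
  H_q approaches log2(number of cows).

* **Per cow** — entropy of *segment membership* for each cow:

      H_c = -sum_q (n_q|c / N_c) * log2(n_q|c / N_c)

  bounded by log2(K).  Unlike the sample variance of a cow's entry
  quantiles, H_c is robust to outliers and detects multimodal queueing
  (a cow always first or always last has maximal variance but entropy of
  only 1 bit).

Significance is assessed by permuting entry quantiles within each
observation day (preserving missingness and each day's quantile
multiset) and recomputing the statistics; one-sided p-values use the
add-one correction p = (1 + #{null <= observed}) / (B + 1), small
statistic = less stochastic than random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wrangle import QuantileMatrix

__all__ = [
    "Segmentation",
    "segment_labels",
    "segment_entropy",
    "cow_entropy",
    "cow_variance",
    "permute_within_days",
    "permutation_pvalues",
    "QueueStochasticity",
    "StochasticityResults",
]


@dataclass(frozen=True)
class Segmentation:
    """K equal half-open quantile segments ((j-1)/K, j/K], j = 1..K."""

    n_segments: int = 20

    def labels_of(self, values: np.ndarray) -> np.ndarray:
        """Map quantiles in (0, 1] to segment indices 1..K (NaN -> -1)."""
        v = np.asarray(values, float)
        out = np.full(v.shape, -1, dtype=np.int64)
        ok = ~np.isnan(v)
        if ((v[ok] <= 0) | (v[ok] > 1)).any():
            bad = v[ok][(v[ok] <= 0) | (v[ok] > 1)]
            raise ValueError(f"quantiles outside (0, 1]: {bad[:5]}")
        # tolerance so that e.g. 0.05 * 20 lands in segment 1, not 2
        lab = np.ceil(v[ok] * self.n_segments - 1e-9).astype(np.int64)
        out[ok] = np.clip(lab, 1, self.n_segments)
        return out


def segment_labels(qm: QuantileMatrix, seg: Segmentation | None = None) -> pd.DataFrame:
    """Discretise a quantile matrix into segment indices (missing -> <NA>)."""
    seg = seg or Segmentation()
    lab = seg.labels_of(qm.values.to_numpy())
    df = pd.DataFrame(lab, index=qm.cow_ids, columns=qm.days).astype("Int64")
    return df.mask(df == -1)


def _label_array(labels) -> np.ndarray:
    """Coerce a label DataFrame / array to int64 with -1 for missing."""
    if isinstance(labels, pd.DataFrame):
        arr = labels.to_numpy(dtype="float64", na_value=np.nan)
    else:
        arr = np.asarray(labels, float)
    out = np.full(arr.shape, -1, np.int64)
    ok = ~np.isnan(arr)
    out[ok] = arr[ok].astype(np.int64)
    return out


def _entropy_bits(counts: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy (base 2) along an axis of a count array; 0*log0 = 0."""
    c = np.asarray(counts, float)
    tot = c.sum(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, c / np.where(tot > 0, tot, 1), 0.0)
        term = np.where(p > 0, p * np.log2(p), 0.0)
    return -term.sum(axis=axis)


def _cow_by_segment_counts(lab: np.ndarray, n_segments: int) -> np.ndarray:
    """n_cows x K matrix of times cow i was observed in segment j."""
    n = lab.shape[0]
    ok = lab > 0
    rows = np.nonzero(ok)[0]
    flat = rows * n_segments + (lab[ok] - 1)
    return np.bincount(flat, minlength=n * n_segments).reshape(n, n_segments)


def segment_entropy(labels, cow_index=None, n_segments: int | None = None) -> pd.Series:
    """Entropy of cow identity within each queue segment (H_q), in bits.

    Counts are pooled over all days.  Empty segments are reported NaN
    with a warning.  Bounded by log2(number of distinct cows observed in
    the segment).
    """
    lab = _label_array(labels)
    K = n_segments if n_segments is not None else max(int(lab.max()), 1)
    counts = _cow_by_segment_counts(lab, K)  # cows x K
    h = _entropy_bits(counts.T, axis=-1)  # per segment over cows
    empty = counts.sum(axis=0) == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} empty segment(s); entropy reported NaN")
        h = np.where(empty, np.nan, h)
    idx = pd.RangeIndex(1, K + 1, name="segment")
    return pd.Series(h, index=idx, name="H_q")


def cow_entropy(labels, n_segments: int | None = None) -> pd.Series:
    """Entropy of segment membership for each cow (H_c), in bits.

    Bounded by log2(K).  Cows with zero observations are reported NaN
    with a warning.
    """
    lab = _label_array(labels)
    K = n_segments if n_segments is not None else max(int(lab.max()), 1)
    counts = _cow_by_segment_counts(lab, K)
    h = _entropy_bits(counts, axis=-1)
    none = counts.sum(axis=1) == 0
    if none.any():
        warnings.warn(f"{int(none.sum())} cow(s) with zero observations")
        h = np.where(none, np.nan, h)
    idx = (
        labels.index
        if isinstance(labels, pd.DataFrame)
        else pd.RangeIndex(lab.shape[0], name="cow")
    )
    return pd.Series(h, index=idx, name="H_c")


def cow_variance(qm: QuantileMatrix) -> pd.Series:
    """Unbiased sample variance of each cow's entry quantiles.

    Cows with fewer than two observations are reported NaN.
    """
    x = qm.values.to_numpy()
    m = (~np.isnan(x)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v = np.nanvar(x, axis=1, ddof=1)
    v = np.where(m >= 2, v, np.nan)
    return pd.Series(v, index=qm.cow_ids, name="variance")


def permute_within_days(qm: QuantileMatrix, seed: int = 0) -> QuantileMatrix:
    """Shuffle each day's quantiles among that day's present cows.

    The per-day multiset of values and the missingness pattern are both
    preserved; only the assignment of values to cows is randomised.
    """
    rng = np.random.default_rng(seed)
    x = qm.values.to_numpy().copy()
    for j in range(x.shape[1]):
        idx = np.flatnonzero(~np.isnan(x[:, j]))
        x[idx, j] = x[idx[rng.permutation(idx.size)], j]
    return QuantileMatrix(
        pd.DataFrame(x, index=qm.cow_ids, columns=qm.days),
        qm.subperiods.copy(),
        None if qm.enrolled is None else qm.enrolled.copy(),
        qm.provenance + [f"permute_within_days(seed={seed})"],
    )


def _permuted_value_matrix(
    x: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One within-day permutation of a cows x days matrix, vectorised.

    Each column's non-missing values are reassigned uniformly at random
    among that column's present rows.
    """
    n, d = x.shape
    miss = np.isnan(x)
    keys = rng.random((n, d))
    keys[miss] = np.inf  # missing rows sort last
    order = np.argsort(keys, axis=0, kind="stable")
    # stack each column's present values first, padded with NaN
    vals = np.full_like(x, np.nan)
    cnt = (~miss).sum(axis=0)
    sort_vals = np.sort(x, axis=0)  # NaNs go last
    vals[: sort_vals.shape[0], :] = sort_vals
    out = np.full_like(x, np.nan)
    np.put_along_axis(out, order, vals, axis=0)
    # columns with zero present cows stay all-NaN by construction
    assert (cnt == (~np.isnan(out)).sum(axis=0)).all()
    return out


def _row_stats(x: np.ndarray, K: int, seg: Segmentation):
    """Per-row (cow) entropy and unbiased variance of a value matrix."""
    lab = np.full(x.shape, -1, np.int64)
    ok = ~np.isnan(x)
    lab[ok] = np.clip(np.ceil(x[ok] * K - 1e-9).astype(np.int64), 1, K)
    counts = _cow_by_segment_counts(lab, K)
    h = _entropy_bits(counts, axis=-1)
    m = ok.sum(axis=1)
    s1 = np.nansum(x, axis=1)
    s2 = np.nansum(x * x, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (s2 - s1 * s1 / np.maximum(m, 1)) / np.maximum(m - 1, 1)
    var = np.where(m >= 2, np.maximum(var, 0.0), np.nan)
    h = np.where(m >= 1, h, np.nan)
    return h, var, counts


def permutation_pvalues(
    qm: QuantileMatrix,
    statistic: str = "entropy",
    B: int = 5000,
    seed: int = 0,
    seg: Segmentation | None = None,
) -> pd.Series:
    """Per-cow one-sided permutation p-values for entropy or variance.

    Each of the B iterations permutes quantiles within every day and
    recomputes the per-cow statistic, giving each cow a null sample that
    respects her own attendance pattern.  p = (1 + #{null <= observed})
    / (B + 1): small observed statistic = less stochastic than random.
    """
    if statistic not in ("entropy", "variance"):
        raise ValueError("statistic must be 'entropy' or 'variance'")
    if B < 1:
        raise ValueError("B must be >= 1")
    seg = seg or Segmentation()
    res = _permutation_null(qm, B=B, seed=seed, seg=seg)
    key = "p_entropy" if statistic == "entropy" else "p_variance"
    return res[key]


def _permutation_null(
    qm: QuantileMatrix, B: int, seed: int, seg: Segmentation
) -> dict:
    """Shared permutation stream: per-cow entropy & variance p-values and
    per-segment entropy null summaries, all from the same B permutations."""
    K = seg.n_segments
    x = qm.values.to_numpy()
    rng = np.random.default_rng(seed)

    obs_h, obs_v, counts = _row_stats(x, K, seg)
    obs_hq = _entropy_bits(counts.T, axis=-1)

    n = x.shape[0]
    ge_h = np.zeros(n)  # null <= observed counts
    ge_v = np.zeros(n)
    null_hq = np.empty((B, K))
    for b in range(B):
        xb = _permuted_value_matrix(x, rng)
        hb, vb, cb = _row_stats(xb, K, seg)
        ge_h += (hb <= obs_h) & ~np.isnan(hb)
        ge_v += (vb <= obs_v) & ~np.isnan(vb)
        null_hq[b] = _entropy_bits(cb.T, axis=-1)

    p_h = (1.0 + ge_h) / (B + 1.0)
    p_v = (1.0 + ge_v) / (B + 1.0)
    p_h = np.where(np.isnan(obs_h), np.nan, p_h)
    p_v = np.where(np.isnan(obs_v), np.nan, p_v)
    return {
        "p_entropy": pd.Series(p_h, index=qm.cow_ids, name="p_entropy"),
        "p_variance": pd.Series(p_v, index=qm.cow_ids, name="p_variance"),
        "obs_entropy": pd.Series(obs_h, index=qm.cow_ids, name="H_c"),
        "obs_variance": pd.Series(obs_v, index=qm.cow_ids, name="variance"),
        "obs_segment_entropy": pd.Series(
            obs_hq, index=pd.RangeIndex(1, K + 1, name="segment"), name="H_q"
        ),
        "null_segment_entropy": null_hq,
    }


class QueueStochasticity:
    """Model-style front end: quantify queue randomness on a quantile matrix.

    Parameters
    ----------
    qm : QuantileMatrix
    n_segments : number of equal quantile segments (default 20).
    """

    def __init__(self, qm: QuantileMatrix, n_segments: int = 20):
        self.qm = qm
        self.segmentation = Segmentation(n_segments)

    def fit(self, B: int = 5000, seed: int = 0) -> "StochasticityResults":
        seg = self.segmentation
        K = seg.n_segments
        res = _permutation_null(self.qm, B=B, seed=seed, seg=seg)

        lab = _label_array(segment_labels(self.qm, seg))
        x = self.qm.values.to_numpy()
        med_cow = np.nanmedian(
            np.where(np.isnan(x), np.nan, x), axis=1
        )
        # median observed quantile within each segment
        med_seg = np.full(K, np.nan)
        for j in range(1, K + 1):
            vals = x[lab == j]
            if vals.size:
                med_seg[j - 1] = np.median(vals)

        nq = res["null_segment_entropy"]
        per_segment = pd.DataFrame(
            {
                "median_quantile": med_seg,
                "H_q": res["obs_segment_entropy"].to_numpy(),
                "null_mean": np.nanmean(nq, axis=0),
                "null_q05": np.nanquantile(nq, 0.05, axis=0),
                "null_q95": np.nanquantile(nq, 0.95, axis=0),
            },
            index=pd.RangeIndex(1, K + 1, name="segment"),
        )
        per_cow = pd.DataFrame(
            {
                "median_quantile": med_cow,
                "H_c": res["obs_entropy"].to_numpy(),
                "variance": res["obs_variance"].to_numpy(),
                "p_entropy": res["p_entropy"].to_numpy(),
                "p_variance": res["p_variance"].to_numpy(),
            },
            index=self.qm.cow_ids,
        )
        return StochasticityResults(
            per_cow=per_cow,
            per_segment=per_segment,
            n_segments=K,
            n_permutations=B,
            max_entropy_cow=float(np.log2(K)),
            max_entropy_segment=float(np.log2(self.qm.n_cows)),
        )


@dataclass
class StochasticityResults:
    """Per-cow and per-segment stochasticity table with permutation nulls."""

    per_cow: pd.DataFrame
    per_segment: pd.DataFrame
    n_segments: int
    n_permutations: int
    max_entropy_cow: float
    max_entropy_segment: float

    def rejection_rate(self, alpha: float = 0.05, statistic: str = "entropy") -> float:
        p = self.per_cow["p_entropy" if statistic == "entropy" else "p_variance"]
        return float((p.dropna() <= alpha).mean())

    def summary(self) -> str:
        pc = self.per_cow
        lines = [
            "Queue stochasticity",
            "===================",
            f"cows: {len(pc)}   segments: {self.n_segments}   "
            f"permutations: {self.n_permutations}",
            f"max H_c = log2({self.n_segments}) = {self.max_entropy_cow:.2f} bits; "
            f"max H_q = log2({len(pc)}) = {self.max_entropy_segment:.2f} bits",
            f"median H_c: {pc['H_c'].median():.3f}   "
            f"median variance: {pc['variance'].median():.4f}",
            f"cows rejecting randomness (entropy, alpha=0.05): "
            f"{(pc['p_entropy'] <= 0.05).sum()} / {pc['p_entropy'].notna().sum()}",
            f"cows rejecting randomness (variance, alpha=0.05): "
            f"{(pc['p_variance'] <= 0.05).sum()} / {pc['p_variance'].notna().sum()}",
        ]
        return "\n".join(lines)

    def to_csv(self, cow_path, segment_path) -> None:
        self.per_cow.to_csv(cow_path, index_label="cow_id")
        self.per_segment.to_csv(segment_path)
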