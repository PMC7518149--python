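"""Summary figures and tables for a full analysis run.

Covers the pipeline's standard deliverables: stochasticity scatter
plots with their maximum-entropy reference lines, the pen-vs-pasture
subperiod consistency scatter with Pearson and Kendall correlations,
annotated co-clustering heatmaps, 3-D embedding scatters, and the
"tube plot" median tables of hourly sensor budgets per queue group.
All tabular artifacts are CSV/JSON; plots are static PNGs rendered
with matplotlib.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .comech import CoClustering
from .simulate import SensorLog, lounging_mask
from .stochastic import StochasticityResults
from .embed import Embedding
from .wrangle import PASTURE, PEN, QuantileMatrix

__all__ = [
    "SubperiodSummary",
    "subperiod_consistency",
    "tube_table",
    "render_all",
    "MissingArtifactError",
]


class MissingArtifactError(FileNotFoundError):
    """An upstream artifact needed by the renderer is absent."""


@dataclass
class SubperiodSummary:
    """Per-cow subperiod medians with Pearson/Kendall agreement."""

    medians: pd.DataFrame  # columns: pen, pasture
    pearson_r: float
    pearson_p: float
    kendall_tau: float
    kendall_p: float

    def summary(self) -> str:
        return (
            "Subperiod consistency (pen vs. pasture median entry quantile)\n"
            f"cows with both medians: {len(self.medians)}\n"
            f"Pearson R = {self.pearson_r:.3f} (p = {self.pearson_p:.2e})\n"
            f"Kendall tau = {self.kendall_tau:.3f} (p = {self.kendall_p:.2e})"
        )


def subperiod_consistency(qm: QuantileMatrix) -> SubperiodSummary:
    """Agreement of per-cow median entry quantiles across subperiods.

    Medians are computed over non-missing days within each subperiod;
    Pearson r and Kendall tau-b (tie-corrected) are computed on cows
    with a median in both.
    """
    present = set(qm.subperiods.unique())
    if not {PEN, PASTURE} <= present:
        raise ValueError(f"both subperiods required; found {sorted(present)}")
    meds = {}
    for sp in (PEN, PASTURE):
        cols = qm.subperiods.index[qm.subperiods == sp]
        meds[sp] = qm.values.loc[:, cols].median(axis=1)
    both = pd.DataFrame(meds).dropna()
    if len(both) < 3:
        raise ValueError("need >= 3 cows with medians in both subperiods")
    r, rp = stats.pearsonr(both[PEN], both[PASTURE])
    tau, tp = stats.kendalltau(both[PEN], both[PASTURE])
    return SubperiodSummary(both, float(r), float(rp), float(tau), float(tp))


def tube_table(sensor: SensorLog, queue_labels: pd.Series) -> pd.DataFrame:
    """Within-day, within-hour median sensor values per queue group.

    ``queue_labels`` maps every cow in the sensor log to a queue group
    (groups are reported in label order; order labels by median entry
    quantile upstream).  Returns long records (day, hour, queue_group,
    channel, median); groups with zero cows are omitted with a warning.
    """
    rec = sensor.records
    missing = set(rec["cow_id"].unique()) - set(queue_labels.index)
    if missing:
        raise KeyError(f"queue_labels missing cows: {sorted(missing)[:5]}")
    empty = set(queue_labels.unique()) - set(
        queue_labels.loc[queue_labels.index.intersection(rec["cow_id"].unique())]
    )
    if empty:
        warnings.warn(f"queue group(s) with zero cows omitted: {sorted(empty)}")
    df = rec.assign(queue_group=queue_labels.loc[rec["cow_id"]].to_numpy())
    channels = [c for c in list(sensor.channels) + ["temperature"] if c in df]
    med = (
        df.groupby(["day", "hour", "queue_group"])[channels]
        .median()
        .reset_index()
        .melt(
            id_vars=["day", "hour", "queue_group"],
            var_name="channel",
            value_name="median",
        )
    )
    return med


def _require(obj, name: str, stage: str):
    if obj is None:
        raise MissingArtifactError(
            f"artifact {name!r} missing; rerun the {stage!r} pipeline stage"
        )
    return obj


def render_all(
    outdir: str | Path,
    qm: QuantileMatrix = None,
    stoch: StochasticityResults = None,
    pca: Embedding = None,
    diffusion: Embedding = None,
    cocluster: CoClustering = None,
    subperiod: SubperiodSummary = None,
    tube: pd.DataFrame = None,
    attributes: pd.DataFrame = None,
    config: dict | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write every figure/table for the artifacts supplied.

    Artifacts not passed are skipped unless nothing at all is supplied.
    A JSON run manifest (config, seed, versions, filter provenance) is
    always written.  Returns the list of files created.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if all(a is None for a in (qm, stoch, pca, diffusion, cocluster, subperiod, tube)):
        raise MissingArtifactError(
            "no artifacts supplied; run the upstream pipeline stages first"
        )

    def _save(fig, name):
        p = outdir / name
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

    if qm is not None:
        p = outdir / "quantile_matrix.csv"
        qm.to_csv(p)
        written += [p, p.with_suffix(".json")]

    if stoch is not None:
        stoch.to_csv(outdir / "stochasticity_cows.csv", outdir / "stochasticity_segments.csv")
        written += [outdir / "stochasticity_cows.csv", outdir / "stochasticity_segments.csv"]
        fig, ax = plt.subplots(figsize=(6, 4))
        ps = stoch.per_segment
        ax.scatter(ps["median_quantile"], ps["H_q"], c="firebrick", label="observed")
        ax.scatter(ps["median_quantile"], ps["null_mean"], c="steelblue", s=12,
                   label="permuted mean")
        ax.axhline(stoch.max_entropy_segment, ls="--", c="gray",
                   label=f"log2(n cows) = {stoch.max_entropy_segment:.2f}")
        ax.set_xlabel("median entry quantile of segment")
        ax.set_ylabel("H_q (bits)")
        ax.legend(fontsize=7)
        _save(fig, "segment_entropy.png")

        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
        pc = stoch.per_cow
        axes[0].scatter(pc["median_quantile"], pc["H_c"], s=10, c="firebrick")
        axes[0].axhline(stoch.max_entropy_cow, ls="--", c="gray")
        axes[0].set_xlabel("median entry quantile")
        axes[0].set_ylabel("H_c (bits)")
        axes[1].scatter(pc["median_quantile"], pc["variance"], s=10, c="darkorange")
        axes[1].set_xlabel("median entry quantile")
        axes[1].set_ylabel("variance of entry quantile")
        _save(fig, "cow_stochasticity.png")

    for emb, name in ((pca, "pca"), (diffusion, "diffusion")):
        if emb is None:
            continue
        emb.coordinates.to_csv(outdir / f"embedding_{name}.csv", index_label="cow_id")
        pd.Series(emb.eigenvalues, name="eigenvalue").to_csv(
            outdir / f"eigenvalues_{name}.csv", index_label="rank"
        )
        written += [outdir / f"embedding_{name}.csv", outdir / f"eigenvalues_{name}.csv"]
        col = (
            emb.extra.get("median_quantile")
            if emb.extra.get("median_quantile") is not None
            else (qm.values.median(axis=1) if qm is not None else None)
        )
        coords = emb.coordinates.to_numpy()
        fig = plt.figure(figsize=(5.5, 5))
        if coords.shape[1] >= 3:
            ax = fig.add_subplot(projection="3d")
            sc = ax.scatter(coords[:, 0], coords[:, 1], coords[:, 2],
                            c=None if col is None else np.asarray(col), cmap="viridis", s=12)
        else:
            ax = fig.add_subplot()
            sc = ax.scatter(coords[:, 0], coords[:, 1] if coords.shape[1] > 1 else 0 * coords[:, 0],
                            c=None if col is None else np.asarray(col), cmap="viridis", s=12)
        if col is not None:
            fig.colorbar(sc, label="median entry quantile", shrink=0.7)
        ax.set_title(f"{name} embedding ({emb.n_significant} significant dims)")
        _save(fig, f"embedding_{name}.png")

    if subperiod is not None:
        subperiod.medians.to_csv(outdir / "subperiod_medians.csv", index_label="cow_id")
        written.append(outdir / "subperiod_medians.csv")
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(subperiod.medians[PEN], subperiod.medians[PASTURE], s=12)
        ax.plot([0, 1], [0, 1], c="gray", lw=0.8)
        ax.set_xlabel("median entry quantile (pen)")
        ax.set_ylabel("median entry quantile (pasture)")
        ax.set_title(
            f"R = {subperiod.pearson_r:.2f}, tau = {subperiod.kendall_tau:.2f}"
        )
        _save(fig, "subperiod_consistency.png")

    if cocluster is not None:
        _require(qm, "qm", "wrangle")
        cocluster.row_labels.to_csv(outdir / "cocluster_rows.csv")
        cocluster.col_labels.to_csv(outdir / "cocluster_cols.csv")
        pd.Series(cocluster.energy_trace, name="energy").to_csv(
            outdir / "cocluster_energy.csv", index_label="iteration"
        )
        written += [outdir / f"cocluster_{s}.csv" for s in ("rows", "cols", "energy")]
        # heatmap ordered by cluster then leaf order within cluster
        row_order = cocluster.row_labels.sort_values(kind="stable").index
        col_order = cocluster.col_labels.sort_values(kind="stable").index
        mat = qm.values.loc[row_order, col_order]
        fig, axes = plt.subplots(
            2, 2, figsize=(8.8, 6.5),
            height_ratios=[1, 14], width_ratios=[30, 1],
        )
        axes[0, 1].axis("off")
        sub = qm.subperiods.loc[col_order].map({PEN: 0, PASTURE: 1}).to_numpy()
        axes[0, 0].imshow(sub[None, :], aspect="auto", cmap="coolwarm")
        axes[0, 0].set_yticks([])
        axes[0, 0].set_xticks([])
        axes[0, 0].set_title(
            "column annotation: pen (blue) / pasture (red)", fontsize=8
        )
        im = axes[1, 0].imshow(mat.to_numpy(), aspect="auto", cmap="viridis",
                               interpolation="nearest")
        axes[1, 0].set_xlabel("day (clustered)")
        axes[1, 0].set_ylabel("cow (clustered)")
        if attributes is not None and "n_health_events" in attributes:
            sick = (
                attributes["n_health_events"].reindex(row_order).fillna(0) > 0
            ).astype(int).to_numpy()
            axes[1, 1].imshow(sick[:, None], aspect="auto", cmap="Reds",
                              vmin=0, vmax=1)
            axes[1, 1].set_xticks([])
            axes[1, 1].set_yticks([])
            axes[1, 1].set_title("health", fontsize=7)
        else:
            axes[1, 1].axis("off")
        fig.colorbar(im, ax=axes[1, 0], label="entry quantile", shrink=0.8)
        _save(fig, f"cocluster_heatmap_r{cocluster.r}_c{cocluster.c}.png")

    if tube is not None:
        tube.to_csv(outdir / "tube_table.csv", index=False)
        written.append(outdir / "tube_table.csv")
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        act = tube[tube["channel"] == tube["channel"].iloc[0]]
        theta = 2 * np.pi * act["hour"] / 24.0
        for g, grp in act.groupby("queue_group"):
            th = 2 * np.pi * grp["hour"] / 24.0
            ax.scatter(np.cos(th), np.sin(th), grp["day"], s=6, label=f"group {g}")
        ax.set_zlabel("day")
        ax.set_title(f"tube plot: {act['channel'].iloc[0]}")
        ax.legend(fontsize=7)
        _save(fig, "tube_plot.png")

    manifest = {
        "config": config or {},
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "provenance": [] if qm is None else qm.provenance,
        "files": [p.name for p in written],
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=1, default=str))
    written.append(mp)
    return written
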