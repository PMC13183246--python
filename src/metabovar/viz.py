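"""Radar plots, metabolite-pair heatmaps and MAD boxplots.

All plotting is presentation-only: flags and intervals are computed on the
raw concentration scale elsewhere; radar axes are min-max scaled per
metabolite over the cohort purely for display.  Every figure is written as
both PNG and SVG next to the requested path.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .data_model import MetaboDataset  # noqa: E402
from .simulation import SimulationResult  # noqa: E402

__all__ = ["radar_plot", "pair_heatmap", "mad_boxplot", "flagged_metabolites"]


def flagged_metabolites(flags: pd.DataFrame, individual, level: float,
                        timepoint: int) -> set[str]:
    """Metabolites flagged for one individual at one timepoint and level.

    These are the axis labels the radar plot marks bold with an asterisk.
    """
    sub = flags[(flags["individual"] == individual)
                & (flags["level"] == level)
                & (flags["timepoint"] == timepoint)]
    return set(sub.loc[sub["flagged"] == True, "metabolite"])  # noqa: E712


def _save(fig, out_path) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    stem = out_path.with_suffix("")
    for ext in (".png", ".svg"):
        fig.savefig(stem.with_suffix(ext), bbox_inches="tight", dpi=150)
    plt.close(fig)
    return out_path if out_path.suffix else stem.with_suffix(".png")


def radar_plot(dataset: MetaboDataset, flags: pd.DataFrame, individual,
               level: float, out_path) -> Path:
    """One polar panel per timepoint for a single individual.

    Cohort traces in light grey, the individual's trace highlighted, the
    HPD band shaded; a metabolite flagged at a timepoint gets a bold,
    asterisked axis label on that panel.
    """
    sc = dataset.schema
    mets = dataset.metabolites
    if individual not in set(dataset.data[sc.id_col]):
        raise ValueError(f"unknown individual {individual!r}")
    sub = flags[(flags["individual"] == individual) & (flags["level"] == level)]
    if sub.empty:
        raise ValueError(f"no flags at level {level} for {individual!r}")

    pooled = dataset.metabolite_frame()
    lo = pooled.min().to_numpy()
    hi = pooled.max().to_numpy()
    span = np.where(hi > lo, hi - lo, 1.0)

    def scale(vals):
        return (np.asarray(vals, dtype=float) - lo) / span

    T = dataset.n_timepoints
    angles = np.linspace(0, 2 * np.pi, len(mets), endpoint=False)
    closed = np.concatenate([angles, angles[:1]])
    fig, axes = plt.subplots(1, T, figsize=(4.2 * T, 4.6),
                             subplot_kw={"projection": "polar"})
    axes = np.atleast_1d(axes)
    for t, ax in zip(range(1, T + 1), axes):
        cohort = dataset.data[dataset.data[sc.time_col] == t]
        for _, row in cohort.iterrows():
            vals = scale(row[mets].to_numpy(dtype=float))
            if np.isfinite(vals).all():
                ax.plot(closed, np.r_[vals, vals[:1]], color="0.8",
                        lw=0.5, zorder=1)
        ft = sub[sub["timepoint"] == t].set_index("metabolite")
        if not ft.empty:
            band_lo = scale(ft.loc[mets, "lower"].to_numpy())
            band_hi = scale(ft.loc[mets, "upper"].to_numpy())
            ax.fill_between(closed, np.r_[band_lo, band_lo[:1]],
                            np.r_[band_hi, band_hi[:1]],
                            color="tab:blue", alpha=0.25, zorder=2)
            obs = ft.loc[mets, "observed"].to_numpy(dtype=float)
            if np.isfinite(obs).all():
                v = scale(obs)
                ax.plot(closed, np.r_[v, v[:1]], color="tab:red", lw=1.8,
                        zorder=3)
            flagged = flagged_metabolites(flags, individual, level, t)
        else:
            flagged = set()
        labels = [f"{m}*" if m in flagged else m for m in mets]
        ax.set_xticks(angles)
        ax.set_xticklabels(labels, fontsize=8)
        for lbl, m in zip(ax.get_xticklabels(), mets):
            if m in flagged:
                lbl.set_fontweight("bold")
        ax.set_yticklabels([])
        ax.set_title(f"timepoint {t}", fontsize=10)
    fig.suptitle(f"{individual} — {level:.1%} HPD prediction intervals")
    return _save(fig, out_path)


def pair_heatmap(counts: pd.DataFrame | np.ndarray, out_path) -> Path:
    """Symmetric heatmap of pair-flag counts on a sequential red scale."""
    if isinstance(counts, pd.DataFrame):
        labels = list(counts.index)
        mat = counts.to_numpy()
    else:
        mat = np.asarray(counts)
        labels = [f"m{i + 1}" for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1] or not np.array_equal(mat, mat.T):
        raise ValueError("pair-count matrix must be square and symmetric")
    M = mat.shape[0]
    fig, ax = plt.subplots(figsize=(0.55 * M + 2.5, 0.55 * M + 2))
    vmax = mat.max() if mat.max() > 0 else 1
    im = ax.imshow(mat, cmap="Reds", vmin=0, vmax=vmax)
    ax.set_xticks(range(M), labels, rotation=90, fontsize=8)
    ax.set_yticks(range(M), labels, fontsize=8)
    for i in range(M):
        for j in range(M):
            ax.text(j, i, str(int(mat[i, j])), ha="center", va="center",
                    fontsize=7,
                    color="white" if mat[i, j] > 0.6 * vmax else "black")
    fig.colorbar(im, ax=ax, label="flagged individuals")
    ax.set_title("Flagged individuals per metabolite pair")
    return _save(fig, out_path)


def mad_boxplot(result: SimulationResult, out_path, title: str = "") -> Path:
    """Grouped boxplots of MAD: x = timepoint, paired boxes per model."""
    table = result.table
    if table.empty:
        raise ValueError("empty simulation result")
    models = sorted(table["model"].unique())
    tps = sorted(table["timepoint"].unique())
    fig, ax = plt.subplots(figsize=(1.6 * len(tps) + 2, 4))
    width = 0.35
    colors = {"multivariate": "tab:blue", "independent": "tab:orange"}
    for k, model in enumerate(models):
        data = [table.loc[(table["model"] == model)
                          & (table["timepoint"] == t), "mad"] for t in tps]
        offset = (k - (len(models) - 1) / 2) * (width + 0.05)
        bp = ax.boxplot(data, positions=np.array(tps) + offset, widths=width,
                        patch_artist=True)
        for box in bp["boxes"]:
            box.set_facecolor(colors.get(model, f"C{k}"))
            box.set_alpha(0.6)
    ax.set_xticks(tps, [str(t) for t in tps])
    ax.set_xlabel("timepoint")
    ax.set_ylabel("MAD between correlation matrices")
    handles = [plt.Rectangle((0, 0), 1, 1,
                             facecolor=colors.get(m, f"C{k}"), alpha=0.6)
               for k, m in enumerate(models)]
    ax.legend(handles, models)
    if title:
        ax.set_title(title)
    return _save(fig, out_path)
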