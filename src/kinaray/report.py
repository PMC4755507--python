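"""Descriptive outputs: volcano plots, fold-change distributions,
kinetic-profile figures and the ranked differential-kinase table.

All operations are pure readers of analysis results; figures are
regenerable bit-identically from the same inputs (fixed styles, no
timestamps embedded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from kinaray.diffstats import fold_change_table, kinetic_profile, substrate_ttest

matplotlib.rcParams["svg.hashsalt"] = "kinaray"

DEFAULT_BIN_WIDTH = 0.25


@dataclass(frozen=True)
class VolcanoPoint:
    substrate_id: str
    x: float          # log2 FC Treg over Teff at the chosen time
    y: float          # -log10 p
    significant: bool


def _save(fig, outfile):
    if outfile is None:
        plt.close(fig)
        return None
    outfile = Path(outfile)
    outfile.parent.mkdir(parents=True, exist_ok=True)
    meta = {"Date": None} if outfile.suffix == ".svg" else {}
    fig.savefig(outfile, metadata=meta)
    plt.close(fig)
    return outfile


def volcano_points(matrix, time_min: int, diff: pd.DataFrame | None = None,
                   p_source: str = "ttest", p_thresh: float = 0.05,
                   fc_thresh: float | None = None) -> list[VolcanoPoint]:
    """One volcano point per retained substrate at one time point.

    ``p_source="ttest"`` (default) uses a per-time Welch t-test between
    the cell types' replicates; ``"model"`` takes the cell-type p-value
    from a differential table.  Points are ordered by substrate id.
    """
    s = matrix.samples
    times = set(s["time_min"])
    if time_min not in times:
        raise ValueError(f"unknown time point {time_min}; have {sorted(times)}")
    fc = fold_change_table(matrix)[f"log2FC_t{time_min}"]

    if p_source == "model":
        if diff is None:
            raise ValueError("p_source='model' needs a differential table")
        pvals = diff.set_index("substrate_id")["p_celltype"]
    elif p_source == "ttest":
        cells = {}
        for cell in ("Treg", "Teff"):
            cols = list(s[(s["cell_type"] == cell)
                          & (s["time_min"] == time_min)]["sample_id"])
            cells[cell] = matrix.values[cols].to_numpy(dtype=float)
        pvals = {}
        for i, sid in enumerate(matrix.values.index):
            a, b = cells["Treg"][i], cells["Teff"][i]
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if a.size < 2 or b.size < 2:
                pvals[sid] = np.nan
            else:
                pvals[sid] = substrate_ttest(a, b).pvalue
        pvals = pd.Series(pvals)
    else:
        raise ValueError(f"unknown p_source: {p_source!r}")

    points = []
    for sid in sorted(matrix.values.index):
        p = float(pvals.get(sid, np.nan))
        x = float(fc.get(sid, np.nan))
        y = float(-np.log10(p)) if p > 0 else (np.inf if p == 0 else np.nan)
        sig = (p <= p_thresh) if np.isfinite(p) else False
        if fc_thresh is not None:
            sig = sig and abs(x) >= fc_thresh
        points.append(VolcanoPoint(sid, x, y, bool(sig)))
    return points


def make_volcano(matrix, time_min: int, diff: pd.DataFrame | None = None,
                 p_source: str = "ttest", p_thresh: float = 0.05,
                 fc_thresh: float | None = None, outfile=None):
    """Volcano plot of log2 FC (Treg/Teff) vs -log10 p at one time point."""
    points = volcano_points(matrix, time_min, diff, p_source, p_thresh,
                            fc_thresh)
    xs = np.array([p.x for p in points])
    ys = np.array([p.y for p in points])
    sig = np.array([p.significant for p in points])

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(xs[~sig], ys[~sig], s=8, c="0.6", linewidths=0)
    ax.scatter(xs[sig], ys[sig], s=10, c="crimson", linewidths=0)
    ax.axhline(-np.log10(p_thresh), ls="--", lw=0.8, c="0.3")
    ax.set_xlabel("log2 FC Treg / Teff")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"t = {time_min} min ({p_source})")
    fig.tight_layout()
    path = _save(fig, outfile)
    return points, path


def make_distributions(matrix, times=None, bin_width: float = DEFAULT_BIN_WIDTH,
                       outfile=None):
    """Fold-change histograms and Treg-Teff difference boxplots per time.

    Returns a dict with, per time point, histogram bin edges/counts and
    the five-number summary of the per-substrate differences, plus the
    figure path.  Histogram counts sum to the number of substrates with a
    computable fold change.
    """
    s = matrix.samples
    all_times = sorted(s["time_min"].unique())
    times = list(times) if times is not None else all_times
    fc = fold_change_table(matrix)

    result = {}
    fig, axes = plt.subplots(2, len(times), figsize=(3 * len(times), 6),
                             squeeze=False)
    for k, t in enumerate(times):
        if t not in all_times:
            raise ValueError(f"unknown time point {t}")
        vals = fc[f"log2FC_t{t}"].dropna().to_numpy()
        lo = np.floor(vals.min() / bin_width) * bin_width if vals.size else 0.0
        hi = np.ceil(vals.max() / bin_width) * bin_width if vals.size else bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(vals, bins=edges)
        q = (np.percentile(vals, [0, 25, 50, 75, 100]).tolist()
             if vals.size else [np.nan] * 5)
        result[t] = {
            "bin_edges": edges.tolist(),
            "counts": counts.tolist(),
            "n": int(vals.size),
            "five_num": dict(zip(["min", "q1", "median", "q3", "max"], q)),
        }
        axes[0][k].bar(edges[:-1], counts, width=bin_width, align="edge",
                       color="steelblue")
        axes[0][k].set_title(f"t = {t} min")
        axes[0][k].set_xlabel("log2 FC")
        if vals.size:
            axes[1][k].boxplot(vals, widths=0.5)
        axes[1][k].set_ylabel("Treg - Teff (log2)")
    axes[0][0].set_ylabel("substrates")
    fig.tight_layout()
    path = _save(fig, outfile)
    return result, path


def make_kinetic_figure(matrix, substrate_ids, outfile=None):
    """Mean activity curves over time per cell type, replicate dots overlaid."""
    substrate_ids = list(substrate_ids)
    fig, axes = plt.subplots(1, len(substrate_ids),
                             figsize=(3.2 * len(substrate_ids), 3.2),
                             squeeze=False)
    colors = {"Treg": "crimson", "Teff": "steelblue"}
    for ax, sid in zip(axes[0], substrate_ids):
        prof = kinetic_profile(matrix, sid)
        for cell, grp in prof["means"].groupby("cell_type"):
            c = colors.get(cell, "0.4")
            ax.plot(grp["time_min"], grp["mean"], "-o", ms=4, color=c,
                    label=cell)
        pts = prof["points"].dropna(subset=["value"])
        for cell, grp in pts.groupby("cell_type"):
            ax.scatter(grp["time_min"], grp["value"], s=10, alpha=0.5,
                       color=colors.get(cell, "0.4"), linewidths=0)
        ax.set_title(sid)
        ax.set_xlabel("time (min)")
    axes[0][0].set_ylabel("log2 net intensity")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return _save(fig, outfile)


def make_table1(diff: pd.DataFrame, annotation: pd.DataFrame,
                p_thresh: float | None = None, top_k: int | None = None,
                p_column: str = "p_celltype") -> pd.DataFrame:
    """Ranked table of significant kinases with annotation joined.

    Filters the differential table to significant substrates (by
    ``p_thresh`` on ``p_column``, or the table's own ``significant``
    call, optionally capped at ``top_k``), sorts ascending by p with
    ties broken by kinase name, and joins kinase / substrate protein /
    peptide / phospho-site columns.  A significant substrate missing from
    the annotation is kept with blank annotation and a warning.
    """
    tbl = diff.copy()
    if p_thresh is not None:
        tbl = tbl[tbl[p_column] <= p_thresh]
    elif "significant" in tbl.columns:
        tbl = tbl[tbl["significant"]]

    ann = annotation.rename(columns={"substrate": "substrate_protein"})
    ann_cols = ["kinase", "substrate_protein", "peptide", "site"]
    tbl = tbl.drop(columns=[c for c in ann_cols if c in tbl.columns])
    tbl = tbl.merge(ann[["substrate_id"] + ann_cols], on="substrate_id",
                    how="left")
    unannotated = tbl[tbl["kinase"].isna()]
    if not unannotated.empty:
        warnings.warn(
            f"{len(unannotated)} significant substrate(s) lack annotation: "
            f"{list(unannotated['substrate_id'])}"
        )
    tbl[ann_cols] = tbl[ann_cols].fillna("")
    tbl = tbl.sort_values([p_column, "kinase", "substrate_id"],
                          kind="stable").reset_index(drop=True)
    if top_k is not None:
        tbl = tbl.head(top_k)
    cols = ["kinase", p_column, "substrate_protein", "peptide", "site",
            "substrate_id"]
    extra = [c for c in ("q_celltype", "bonferroni_p", "estimate_celltype")
             if c in tbl.columns]
    return tbl[cols + extra]


def write_run_report(path, sections: dict) -> None:
    """Write a small markdown run-report linking artifacts and counts."""
    lines = ["# kinaray run report", ""]
    for title, body in sections.items():
        lines.append(f"## {title}")
        if isinstance(body, dict):
            lines.extend(f"- {k}: {v}" for k, v in body.items())
        else:
            lines.append(str(body))
        lines.append("")
    Path(path).write_text("\n".join(lines))
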