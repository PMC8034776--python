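"""Per-TR analysis plots.

Two figures per factor, mirroring the result table:

* the empirical CDF of the factor's per-dataset association scores
  (AUC), highlighted against the CDF of all other datasets' scores —
  a factor truly associated with the query shows a right-shifted curve;
* a rank-dot plot of -log10 Irwin-Hall p-value against absolute rank
  for every TR, with the factor highlighted.

Plots are written as SVG with no embedded date so identical tables
regenerate identical files.
"""

from __future__ import annotations

import difflib
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "bartcore"  # deterministic SVG ids
import matplotlib.pyplot as plt  # noqa: E402

from .association import AssociationTable  # noqa: E402
from .statistics import TRResultTable  # noqa: E402

__all__ = ["plot_tr", "ecdf", "rank_dot_coordinates"]


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF support points and cumulative fractions."""
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, len(x) + 1) / len(x)
    return x, y


def rank_dot_coordinates(table: TRResultTable, tr_name: str):
    """(ranks, -log10 p, highlight mask) exactly as plotted."""
    rows = table.rows
    ranks = np.arange(1, len(rows) + 1)
    logp = -np.log10(rows["irwin_hall_pvalue"].to_numpy())
    hit = rows["tr_name"].to_numpy() == tr_name
    return ranks, logp, hit


def plot_tr(association: AssociationTable, table: TRResultTable,
            tr_name: str, outdir: str | Path) -> tuple[Path, Path]:
    """Write the two per-TR plots; returns (cdf_path, rank_dot_path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trs = set(table.rows["tr_name"])
    if tr_name not in trs:
        near = difflib.get_close_matches(tr_name, sorted(trs), n=5)
        raise KeyError(
            f"unknown TR {tr_name!r}; close matches: {near or 'none'}")

    df = association.scores
    own = df.loc[df["tr_name"] == tr_name, "auc"].to_numpy()
    other = df.loc[df["tr_name"] != tr_name, "auc"].to_numpy()

    fig, ax = plt.subplots(figsize=(4.5, 4))
    if other.size:
        x, y = ecdf(other)
        ax.step(x, y, where="post", color="0.6",
                label=f"other datasets (n={other.size})")
    x, y = ecdf(own)
    ax.step(x, y, where="post", color="crimson",
            label=f"{tr_name} (n={own.size})")
    ax.set_xlabel("association score (AUC)")
    ax.set_ylabel("cumulative fraction of datasets")
    ax.set_title(f"{tr_name}: association-score CDF")
    ax.legend(loc="best", fontsize=8)
    cdf_path = outdir / f"{tr_name}_auc_cdf.svg"
    fig.savefig(cdf_path, metadata={"Date": None})
    plt.close(fig)

    ranks, logp, hit = rank_dot_coordinates(table, tr_name)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(ranks[~hit], logp[~hit], s=12, color="0.6", label="other TRs")
    ax.scatter(ranks[hit], logp[hit], s=40, color="crimson", label=tr_name)
    ax.set_xlabel("rank")
    ax.set_ylabel(r"$-\log_{10}$ Irwin-Hall $P$-value")
    ax.set_title(f"{tr_name}: integrative rank significance")
    ax.legend(loc="best", fontsize=8)
    dot_path = outdir / f"{tr_name}_rank_dot.svg"
    fig.savefig(dot_path, metadata={"Date": None})
    plt.close(fig)
    return cdf_path, dot_path
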