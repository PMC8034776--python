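"""Per-TR summary statistics and the integrative Irwin-Hall ranking.

For each transcriptional regulator (TR) the per-dataset association AUCs
are aggregated into the six scores of the output table:

1. Wilcoxon rank-sum statistic — the TR's AUCs against all other
   datasets' AUCs, standardized with mid-rank tie correction;
2. its one-sided (greater) normal-approximation p-value;
3. Z-score — the Wilcoxon statistic standardized against a background
   model built from the same statistic over a collection of unrelated
   (background) queries, measuring how specific the enrichment is to
   this query rather than a property of that TR's datasets;
4. Max AUC — the best single dataset;
5. relative rank — the mean of the TR's descending ranks in statistics
   1, 3 and 4, divided by the number of TRs;
6. Irwin-Hall p-value — the probability that three independent uniform
   ranks sum below the observed rank sum; TRs are ranked by it by
   default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, factorial, floor
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .association import AssociationTable
from .library_io import TRBindingLibrary

__all__ = [
    "BackgroundModel",
    "TRResultTable",
    "FactorNotInLibraryError",
    "wilcoxon_tr",
    "z_score",
    "max_auc",
    "relative_rank",
    "irwin_hall_cdf",
    "irwin_hall_pvalue",
    "build_background_models",
    "assemble_results",
    "call_true_prediction",
]

P_FLOOR = 1e-300  # keeps -log10 plots finite

RESULT_COLUMNS = [
    "tr_name", "wilcoxon_statistic", "wilcoxon_pvalue", "z_score",
    "max_auc", "relative_rank", "irwin_hall_pvalue", "dataset_count",
]


class FactorNotInLibraryError(KeyError):
    """The queried factor has no datasets in the TR library."""


@dataclass
class BackgroundModel:
    """Null location/scale of one statistic over background queries."""

    statistic_name: str
    mean: float
    sd: float
    source: str = ""
    per_background_stats: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("background sd must be > 0")

    @classmethod
    def from_stats(cls, stats: Sequence[float], *,
                   statistic_name: str = "wilcoxon_statistic",
                   source: str = "") -> "BackgroundModel":
        arr = np.asarray(stats, dtype=float)
        return cls(statistic_name=statistic_name,
                   mean=float(arr.mean()), sd=float(arr.std(ddof=1)),
                   source=source, per_background_stats=list(map(float, arr)))


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def wilcoxon_tr(scores_tr, scores_background) -> tuple[float, float]:
    """One-sided (greater) Wilcoxon rank-sum of a TR's AUCs vs the rest.

    The statistic is the rank-sum standardized with mid-rank tie
    correction and *no* continuity correction, so swapping the groups
    negates it exactly; the p-value applies the 0.5 continuity correction
    inside the normal approximation.
    """
    x = np.asarray(scores_tr, dtype=float)
    bg = np.asarray(scores_background, dtype=float)
    if x.size == 0 or bg.size == 0:
        raise ValueError("empty group in Wilcoxon test")
    n1, n0 = x.size, bg.size
    N = n1 + n0
    if N < 3:
        raise ValueError("combined sample too small for the rank-sum test")
    pooled = np.concatenate([x, bg])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    mean = n1 * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    var = n1 * n0 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:  # all values tied
        return 0.0, 1.0
    sd = np.sqrt(var)
    statistic = (r1 - mean) / sd
    z_cc = (r1 - mean - 0.5) / sd
    pvalue = max(float(norm.sf(z_cc)), P_FLOOR)
    return float(statistic), pvalue


def z_score(statistic: float, background: BackgroundModel) -> float:
    """Standardize a statistic against its background model."""
    if not background.sd > 0:
        raise ValueError("background sd must be > 0")
    return (statistic - background.mean) / background.sd


def max_auc(scores_tr) -> float:
    arr = np.asarray(scores_tr, dtype=float)
    if arr.size == 0:
        raise ValueError("empty AUC list")
    return float(arr.max())


def relative_rank(table: pd.DataFrame,
                  total_trs: int | None = None) -> pd.Series:
    """Average descending rank across the three statistics, / #TRs.

    *table* needs columns wilcoxon_statistic, z_score and max_auc; ranks
    are descending (best = 1) with mid-rank ties.
    """
    needed = ["wilcoxon_statistic", "z_score", "max_auc"]
    for col in needed:
        if col not in table.columns or table[col].isna().any():
            raise ValueError(f"missing statistic: {col}")
    T = total_trs if total_trs is not None else len(table)
    if T != len(table):
        raise ValueError("total_trs must equal the number of rows")
    ranks = np.column_stack(
        [rankdata(-table[col].to_numpy()) for col in needed])
    return pd.Series(ranks.mean(axis=1) / T, index=table.index)


def irwin_hall_cdf(s: float, k: int) -> float:
    """CDF of the sum of k i.i.d. Uniform(0,1) variables.

    F(s) = (1/k!) * sum_{j=0..floor(s)} (-1)^j C(k,j) (s-j)^k on [0, k];
    0 below, 1 above.  Exact alternating closed form, stable for the
    small k used here (k = 3).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    s = float(s)
    if s <= 0:
        return 0.0
    if s >= k:
        return 1.0
    total = 0.0
    for j in range(floor(s) + 1):
        total += (-1) ** j * comb(k, j) * (s - j) ** k
    return min(max(total / factorial(k), 0.0), 1.0)


def irwin_hall_pvalue(rank_triplet) -> float:
    """P-value of three relative ranks under the unrelated-ranks null.

    Each component is a relative rank in (0, 1]; under the null they are
    independent uniforms, so their sum follows the Irwin-Hall(3)
    distribution and small sums (top ranks in all three statistics) give
    small p-values.
    """
    triplet = [float(r) for r in rank_triplet]
    if len(triplet) != 3:
        raise ValueError("expected exactly three relative ranks")
    for r in triplet:
        if not (0 < r <= 1):
            raise ValueError(f"relative rank {r} outside (0, 1]")
    return max(irwin_hall_cdf(sum(triplet), 3), P_FLOOR)


# ---------------------------------------------------------------------------
# Backgrounds and table assembly
# ---------------------------------------------------------------------------


def _tr_groups(association: AssociationTable) -> dict[str, np.ndarray]:
    df = association.scores
    return {tr: grp["auc"].to_numpy()
            for tr, grp in df.groupby("tr_name", sort=False)}


def _wilcoxon_stats(association: AssociationTable) -> dict[str, float]:
    groups = _tr_groups(association)
    out = {}
    for tr, aucs in groups.items():
        rest = np.concatenate([v for t, v in groups.items() if t != tr])
        out[tr], _ = wilcoxon_tr(aucs, rest)
    return out


def build_background_models(library: TRBindingLibrary,
                            background_profiles,
                            *, source: str = "background collection",
                            ) -> dict[str, BackgroundModel]:
    """Per-TR background of the Wilcoxon statistic over unrelated queries.

    *background_profiles* is an iterable of CisRegulatoryProfile (or raw
    score vectors); each is scored against the library and every TR's
    Wilcoxon statistic is recorded.  A TR's background model is the
    mean/sd of its statistics across the collection.
    """
    from .association import score_library
    from .profile_inference import CisRegulatoryProfile

    per_tr: dict[str, list[float]] = {}
    n_runs = 0
    for prof in background_profiles:
        if not isinstance(prof, CisRegulatoryProfile):
            prof = CisRegulatoryProfile(np.asarray(prof, float),
                                        mode="region_scores",
                                        provenance="background query")
        table = score_library(prof, library)
        for tr, stat in _wilcoxon_stats(table).items():
            per_tr.setdefault(tr, []).append(stat)
        n_runs += 1
    if n_runs < 2:
        raise ValueError("need at least 2 background runs")
    return {tr: BackgroundModel.from_stats(
                stats, source=f"{source} ({n_runs} runs)")
            for tr, stats in per_tr.items()}


@dataclass
class TRResultTable:
    """The ranked per-TR output table (one row per TR, 6 statistics)."""

    rows: pd.DataFrame
    sort_key: str = "irwin_hall_pvalue"

    def __post_init__(self):
        missing = [c for c in RESULT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"result table missing columns {missing}")
        self.rows = self.rows.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    def rank_of(self, tr_name: str) -> int:
        """1-based position of a TR in the current ordering."""
        idx = np.flatnonzero(self.rows["tr_name"].to_numpy() == tr_name)
        if idx.size == 0:
            raise FactorNotInLibraryError(tr_name)
        return int(idx[0]) + 1

    def to_tsv(self, path: str | Path) -> None:
        out = self.rows.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = out[col].map(lambda v: f"{v:.10g}")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TRResultTable":
        return cls(pd.read_csv(path, sep="\t"))


def assemble_results(association: AssociationTable,
                     library: TRBindingLibrary | None = None,
                     background: Mapping[str, BackgroundModel] | BackgroundModel | None = None,
                     *, sort_by: str = "irwin_hall_pvalue",
                     ascending: bool | None = None) -> TRResultTable:
    """Build the full per-TR result table from per-dataset AUCs.

    For each TR its datasets' AUCs are tested against all other
    datasets' AUCs (Wilcoxon), standardized against the background
    model, and summarized by the maximum; the three statistics are then
    rank-averaged across TRs and the rank sum is converted to an
    Irwin-Hall p-value.  Rows are sorted by *sort_by* (default the
    Irwin-Hall p, ascending) with the TR name as deterministic
    tie-break.

    *background* may be one model per TR (mapping) or a single global
    model; omitted, it defaults to the standard-normal null of the
    standardized rank-sum.
    """
    groups = _tr_groups(association)
    if len(groups) < 2:
        raise ValueError("need at least 2 distinct TRs")
    if library is not None:
        missing = set(library.tr_names) - set(groups)
        if missing:
            raise ValueError(
                f"association table does not cover TRs: {sorted(missing)}")

    default_bg = BackgroundModel(statistic_name="wilcoxon_statistic",
                                 mean=0.0, sd=1.0,
                                 source="standard normal null")

    records = []
    for tr, aucs in groups.items():
        rest = np.concatenate([v for t, v in groups.items() if t != tr])
        stat, pval = wilcoxon_tr(aucs, rest)
        if isinstance(background, Mapping):
            bg = background.get(tr, default_bg)
        elif isinstance(background, BackgroundModel):
            bg = background
        else:
            bg = default_bg
        records.append({
            "tr_name": tr,
            "wilcoxon_statistic": stat,
            "wilcoxon_pvalue": pval,
            "z_score": z_score(stat, bg),
            "max_auc": max_auc(aucs),
            "dataset_count": len(aucs),
        })
    df = pd.DataFrame(records).sort_values("tr_name").reset_index(drop=True)

    rel = relative_rank(df)
    T = len(df)
    ranks = np.column_stack([
        rankdata(-df[col].to_numpy())
        for col in ("wilcoxon_statistic", "z_score", "max_auc")]) / T
    df["relative_rank"] = rel
    df["irwin_hall_pvalue"] = [
        irwin_hall_pvalue(ranks[i]) for i in range(T)]

    if ascending is None:
        ascending = sort_by in ("irwin_hall_pvalue", "wilcoxon_pvalue",
                                "relative_rank")
    df = df.sort_values([sort_by, "tr_name"],
                        ascending=[ascending, True]).reset_index(drop=True)
    return TRResultTable(df[RESULT_COLUMNS], sort_key=sort_by)


def call_true_prediction(table: TRResultTable, factor: str,
                         top_fraction: float = 0.10,
                         p_threshold: float = 0.01) -> bool:
    """Benchmark rule: is *factor* a true prediction of this run?

    True iff the factor ranks within the top *top_fraction* of all TRs by
    Irwin-Hall p-value AND its p-value is below *p_threshold*.  A factor
    absent from the library raises FactorNotInLibraryError (such cases
    are excluded from benchmark denominators, not counted false).
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    df = table.rows
    order = df.sort_values(["irwin_hall_pvalue", "tr_name"]).reset_index(drop=True)
    hits = np.flatnonzero(order["tr_name"].to_numpy() == factor)
    if hits.size == 0:
        raise FactorNotInLibraryError(factor)
    rank = int(hits[0]) + 1
    pval = float(order.loc[hits[0], "irwin_hall_pvalue"])
    return rank <= top_fraction * len(order) and pval < p_threshold
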