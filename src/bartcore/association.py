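"""Profile-vs-binding association scores.

Each ChIP-seq dataset in the TR library divides UDHS into occupied and
unoccupied sites.  Its association score is the probability that the
cis-regulatory profile scores a random occupied site above a random
unoccupied one (ties counted half) — the Mann-Whitney / ROC AUC of the
profile as a classifier of occupancy.  It is computed from mid-ranks,
which makes it invariant under any strictly monotone transform of the
profile and lets one global profile ranking serve every dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .library_io import TRBindingLibrary
from .profile_inference import CisRegulatoryProfile

__all__ = ["AssociationTable", "compute_auc", "score_library"]


@dataclass
class AssociationTable:
    """Per-dataset AUCs: columns dataset_id, tr_name, auc."""

    scores: pd.DataFrame
    profile_provenance: str = ""

    def __post_init__(self):
        required = {"dataset_id", "tr_name", "auc"}
        if not required.issubset(self.scores.columns):
            raise ValueError(f"scores must have columns {sorted(required)}")
        if self.scores["dataset_id"].duplicated().any():
            raise ValueError("duplicate dataset_id in association table")
        aucs = self.scores["auc"]
        if ((aucs < 0) | (aucs > 1)).any():
            raise ValueError("auc outside [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index=False,
                           columns=["dataset_id", "tr_name", "auc"])

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "AssociationTable":
        return cls(pd.read_csv(path, sep="\t"), provenance)


def _auc_from_ranks(ranks: np.ndarray, occupancy: np.ndarray) -> float:
    occ = occupancy.astype(bool)
    n1 = int(occ.sum())
    n0 = occ.size - n1
    r1 = float(ranks[occ].sum())
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def compute_auc(profile, occupancy) -> float:
    """Mann-Whitney AUC of profile scores against binary occupancy.

    Equals P(score_occupied > score_unoccupied) + 1/2 P(tie), computed via
    the mid-rank rank-sum identity.
    """
    scores = profile.scores if isinstance(profile, CisRegulatoryProfile) \
        else np.asarray(profile, dtype=float)
    occ = np.asarray(occupancy)
    if occ.shape != scores.shape:
        raise ValueError("occupancy length does not match profile")
    n1 = int(occ.sum())
    if n1 == 0 or n1 == occ.size:
        raise ValueError("degenerate dataset: occupancy all-zero or all-one")
    # an all-tied profile yields 0.5 under the mid-rank convention
    return _auc_from_ranks(rankdata(scores), occ)


def score_library(profile: CisRegulatoryProfile,
                  library: TRBindingLibrary) -> AssociationTable:
    """One AUC per QC-passing dataset; the profile is ranked once.

    Datasets that are degenerate on this UDHS frame (all or no sites
    occupied) are dropped with a warning rather than failing the run.
    """
    if len(profile) != library.udhs.site_count:
        raise ValueError("profile length does not match the library's UDHS")
    ranks = rankdata(profile.scores)
    rows = []
    for d in library.datasets:
        n1 = int(d.occupancy.sum())
        if n1 == 0 or n1 == len(d.occupancy):
            warnings.warn(f"dropping degenerate dataset {d.dataset_id}",
                          UserWarning, stacklevel=2)
            continue
        rows.append((d.dataset_id, d.tr_name,
                     _auc_from_ranks(ranks, d.occupancy)))
    table = pd.DataFrame(rows, columns=["dataset_id", "tr_name", "auc"])
    return AssociationTable(table, profile_provenance=profile.provenance)
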