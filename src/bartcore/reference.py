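"""The reference-data bundle a run consumes, and its directory format.

A bundle directory carries everything an analysis needs besides the
query itself:

    udhs.bed            candidate-CRE coordinate frame
    datasets.tsv        dataset_id, tr_name, peak_count
    occupancy.mtx       sparse binary datasets x UDHS matrix
    meta.json           species
    rp_matrix.npz       genes x samples regulatory-potential matrix
    signal_matrix.npz   UDHS x samples H3K27ac signal matrix
    background.json     per-TR background models of the Wilcoxon statistic

All formats round-trip exactly (integer coordinates/occupancy, float64
matrices in npz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .library_io import (
    TRBindingLibrary,
    load_matrix,
    read_library,
    save_matrix,
    write_library,
)
from .profile_inference import H3K27acSignalMatrix, RegulatoryPotentialMatrix
from .statistics import BackgroundModel

__all__ = ["ReferenceBundle", "read_reference", "write_reference"]


@dataclass
class ReferenceBundle:
    species: str
    library: TRBindingLibrary
    rp: RegulatoryPotentialMatrix
    signals: H3K27acSignalMatrix
    backgrounds: dict[str, BackgroundModel]

    @property
    def udhs(self):
        return self.library.udhs


def write_reference(bundle: ReferenceBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_library(bundle.library, directory)
    save_matrix(directory / "rp_matrix.npz", bundle.rp.values,
                bundle.rp.genes, bundle.rp.samples,
                normalization=bundle.rp.normalization)
    save_matrix(directory / "signal_matrix.npz", bundle.signals.values,
                [str(i) for i in range(bundle.signals.site_count)],
                bundle.signals.samples)
    bg = {tr: {"statistic_name": m.statistic_name, "mean": m.mean,
               "sd": m.sd, "source": m.source,
               "per_background_stats": m.per_background_stats}
          for tr, m in bundle.backgrounds.items()}
    (directory / "background.json").write_text(json.dumps(bg))


def read_reference(directory: str | Path) -> ReferenceBundle:
    directory = Path(directory)
    library = read_library(directory)
    rp_values, genes, samples, meta = load_matrix(directory / "rp_matrix.npz")
    rp = RegulatoryPotentialMatrix(
        genes=genes, samples=samples, values=rp_values,
        normalization=meta.get("normalization", "unknown"))
    sig_values, _, sig_samples, _ = load_matrix(directory / "signal_matrix.npz")
    signals = H3K27acSignalMatrix(samples=sig_samples, values=sig_values)
    raw = json.loads((directory / "background.json").read_text())
    backgrounds = {tr: BackgroundModel(**m) for tr, m in raw.items()}
    return ReferenceBundle(species=library.species, library=library,
                           rp=rp, signals=signals, backgrounds=backgrounds)
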