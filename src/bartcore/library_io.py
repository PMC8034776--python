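"""Reference-data formats and input transforms.

Everything downstream of input parsing is indexed on a fixed catalogue of
candidate cis-regulatory elements: the union of DNase-hypersensitive sites
(UDHS), a sorted, non-overlapping set of genomic intervals.  This module
owns that coordinate frame, the on-disk formats (BED, plain-text gene
lists, the library directory), and the transforms that reduce each of the
three supported query types to a vector over UDHS:

* a gene list           -> matched against a gene universe (the profile is
                           then inferred by the adaptive-lasso model);
* mapped ChIP-seq reads -> per-site read pile-up;
* scored regions        -> per-site score assignment.

All intervals follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "InputRecommendationWarning",
    "UDHSIndex",
    "GeneSet",
    "ReadInput",
    "RegionInput",
    "TRBindingDataset",
    "TRBindingLibrary",
    "read_gene_list",
    "map_regions_to_udhs",
    "pileup_reads_on_udhs",
    "filter_library_datasets",
    "read_bed_intervals",
    "read_scored_bed",
    "bam_to_intervals",
    "read_library",
    "write_library",
    "save_matrix",
    "load_matrix",
]

#: recommended input minimums; falling short warns, never errors
MIN_RECOMMENDED_GENES = 100
MIN_RECOMMENDED_READS = 1_000_000
MIN_RECOMMENDED_REGIONS = 1000

#: default QC threshold: a binding dataset must have at least this many peaks
DEFAULT_MIN_PEAKS = 2000


class InputRecommendationWarning(UserWarning):
    """An input is below the recommended size; results may be unstable."""


# ---------------------------------------------------------------------------
# UDHS coordinate frame
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UDHSIndex:
    """Sorted, non-overlapping catalogue of candidate CREs.

    The site order is the canonical index for every vector over UDHS
    (profiles, occupancy vectors, signal-matrix rows).
    """

    chroms: np.ndarray  # str array, length = site_count
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64

    def __post_init__(self):
        chroms = np.asarray(self.chroms, dtype=object)
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(chroms) == len(starts) == len(ends)):
            raise ValueError("chroms/starts/ends length mismatch")
        if np.any(starts >= ends):
            bad = int(np.flatnonzero(starts >= ends)[0])
            raise ValueError(f"site {bad}: start >= end")
        # sorted by (chrom, start) with chromosomes in blocks, and
        # non-overlapping within each chromosome
        for chrom, sl in _chrom_slices(chroms).items():
            s, e = starts[sl], ends[sl]
            if np.any(np.diff(s) < 0):
                raise ValueError(f"{chrom}: sites not sorted by start")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"{chrom}: overlapping sites")
        object.__setattr__(self, "chroms", chroms)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)

    @property
    def site_count(self) -> int:
        return len(self.starts)

    def __len__(self) -> int:
        return self.site_count

    def chrom_slices(self) -> dict[str, slice]:
        return _chrom_slices(self.chroms)

    @classmethod
    def from_bed(cls, path: str | Path) -> "UDHSIndex":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        return cls(df["chrom"].to_numpy(dtype=object),
                   df["start"].to_numpy(np.int64),
                   df["end"].to_numpy(np.int64))

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c, s, e in zip(self.chroms, self.starts, self.ends):
                fh.write(f"{c}\t{s}\t{e}\n")


def _chrom_slices(chroms: np.ndarray) -> dict[str, slice]:
    """Contiguous block per chromosome; raises if a chromosome recurs."""
    out: dict[str, slice] = {}
    if len(chroms) == 0:
        return out
    change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
    bounds = [0, *change.tolist(), len(chroms)]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        chrom = str(chroms[lo])
        if chrom in out:
            raise ValueError(f"chromosome {chrom} appears in multiple blocks")
        out[chrom] = slice(lo, hi)
    return out


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    """A query gene set matched against the gene universe.

    ``symbols`` holds the universe's canonical spellings of every matched
    symbol; ``unmatched`` records input symbols with no match (reported,
    never silently dropped).
    """

    species: str
    symbols: list[str]
    source_label: str = ""
    unmatched: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.symbols:
            raise ValueError("GeneSet must be non-empty")

    def __len__(self) -> int:
        return len(self.symbols)


def read_gene_list(text: str, universe: Sequence[str], *,
                   species: str = "hg38",
                   source_label: str = "") -> GeneSet:
    """Parse a plain-text gene list (one official symbol per line).

    Blank lines and ``#`` comments are skipped; duplicates (after case
    normalisation) are collapsed; symbols are matched case-insensitively
    against *universe* and reported back in the universe's spelling.

    Raises ``ValueError`` if nothing parses or nothing matches; warns when
    fewer than 100 symbols match (recommended minimum).
    """
    raw = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            raw.append(line.split()[0])
    if not raw:
        raise ValueError("no genes: input empty after stripping blanks/comments")

    seen: set[str] = set()
    deduped = []
    for sym in raw:
        key = sym.upper()
        if key not in seen:
            seen.add(key)
            deduped.append(sym)

    canon = {str(u).upper(): str(u) for u in universe}
    matched, unmatched = [], []
    for sym in deduped:
        hit = canon.get(sym.upper())
        (matched if hit is not None else unmatched).append(hit or sym)
    if not matched:
        raise ValueError("no genes matched universe")
    if len(matched) < MIN_RECOMMENDED_GENES:
        warnings.warn(
            f"only {len(matched)} genes matched; at least "
            f"{MIN_RECOMMENDED_GENES} are recommended",
            InputRecommendationWarning, stacklevel=2)
    return GeneSet(species=species, symbols=matched,
                   source_label=source_label, unmatched=unmatched)


# ---------------------------------------------------------------------------
# Interval inputs
# ---------------------------------------------------------------------------


@dataclass
class ReadInput:
    """Mapped-read intervals (from BED, or BAM via :func:`bam_to_intervals`)."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class RegionInput:
    """Scored genomic regions (BED with a score column)."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)


def _as_interval_arrays(intervals) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(intervals, (ReadInput, RegionInput)):
        return intervals.chroms, intervals.starts, intervals.ends
    rows = list(intervals)
    chroms = np.array([r[0] for r in rows], dtype=object)
    starts = np.array([r[1] for r in rows], dtype=np.int64)
    ends = np.array([r[2] for r in rows], dtype=np.int64)
    return chroms, starts, ends


def map_regions_to_udhs(regions, udhs: UDHSIndex,
                        scores=None) -> np.ndarray:
    """Assign region scores to the UDHS sites they overlap.

    A site overlapped by several regions takes the *maximum* of their
    scores (order-independent, peak-like semantics); sites overlapped by
    no region score 0.  Overlap means non-empty intersection of half-open
    intervals.
    """
    if isinstance(regions, RegionInput):
        chroms, starts, ends = regions.chroms, regions.starts, regions.ends
        scores = regions.scores
    else:
        rows = list(regions)
        if rows and scores is None:
            chroms = np.array([r[0] for r in rows], dtype=object)
            starts = np.array([r[1] for r in rows], dtype=np.int64)
            ends = np.array([r[2] for r in rows], dtype=np.int64)
            scores = np.array([r[3] for r in rows], dtype=float)
        else:
            chroms, starts, ends = _as_interval_arrays(rows)
            scores = np.asarray(scores, dtype=float)
    if len(starts) == 0:
        raise ValueError("empty region list")
    bad = np.flatnonzero(starts >= ends)
    if bad.size:
        raise ValueError(f"malformed interval at line {int(bad[0]) + 1}: "
                         f"start >= end")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite region score")
    if len(starts) < MIN_RECOMMENDED_REGIONS:
        warnings.warn(
            f"only {len(starts)} regions; at least "
            f"{MIN_RECOMMENDED_REGIONS} are recommended",
            InputRecommendationWarning, stacklevel=2)

    out = np.zeros(udhs.site_count, dtype=float)
    slices = udhs.chrom_slices()
    for chrom, sl in slices.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        site_starts = udhs.starts[sl]
        site_ends = udhs.ends[sl]
        # sites overlapping [s, e): site_end > s and site_start < e
        lo = np.searchsorted(site_ends, starts[mask], side="right")
        hi = np.searchsorted(site_starts, ends[mask], side="left")
        base = sl.start
        for l, h, sc in zip(lo, hi, scores[mask]):
            if h > l:
                seg = out[base + l:base + h]
                np.maximum(seg, sc, out=seg)
    return out


def pileup_reads_on_udhs(reads, udhs: UDHSIndex) -> np.ndarray:
    """Count reads per UDHS site.

    A read contributes to the single site containing its midpoint
    ``(start + end) // 2`` (half-open membership), so no read is
    double-counted across adjacent sites.
    """
    chroms, starts, ends = _as_interval_arrays(reads)
    if len(starts) == 0:
        raise ValueError("zero reads")
    if len(starts) < MIN_RECOMMENDED_READS:
        warnings.warn(
            f"only {len(starts)} reads; at least {MIN_RECOMMENDED_READS} "
            f"are recommended", InputRecommendationWarning, stacklevel=2)

    out = np.zeros(udhs.site_count, dtype=np.int64)
    mids = (starts + ends) // 2
    for chrom, sl in udhs.chrom_slices().items():
        mask = chroms == chrom
        if not mask.any():
            continue
        site_starts = udhs.starts[sl]
        site_ends = udhs.ends[sl]
        m = mids[mask]
        idx = np.searchsorted(site_starts, m, side="right") - 1
        ok = (idx >= 0) & (m < site_ends[np.clip(idx, 0, None)])
        counts = np.bincount(idx[ok], minlength=len(site_starts))
        out[sl] += counts
    return out


# ---------------------------------------------------------------------------
# TR binding library
# ---------------------------------------------------------------------------


@dataclass
class TRBindingDataset:
    """One ChIP-seq dataset: binary occupancy of UDHS sites by its peaks."""

    dataset_id: str
    tr_name: str
    occupancy: np.ndarray  # uint8 over UDHS; 1 = >=1 peak overlaps the site
    peak_count: int  # peaks in the source file, pre-overlap

    def __post_init__(self):
        if not self.tr_name:
            raise ValueError("tr_name must be non-empty")
        if self.peak_count < 0:
            raise ValueError("peak_count must be >= 0")
        self.occupancy = np.asarray(self.occupancy, dtype=np.uint8)


@dataclass
class TRBindingLibrary:
    """A QC-filtered collection of binding datasets on one UDHS frame."""

    species: str
    udhs: UDHSIndex
    datasets: list[TRBindingDataset]

    def __post_init__(self):
        n = self.udhs.site_count
        for d in self.datasets:
            if len(d.occupancy) != n:
                raise ValueError(
                    f"dataset {d.dataset_id}: occupancy length "
                    f"{len(d.occupancy)} != UDHS site count {n}")
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate dataset_id in library")

    @property
    def tr_names(self) -> list[str]:
        """Deduplicated TR names, in order of first appearance."""
        seen: set[str] = set()
        out = []
        for d in self.datasets:
            if d.tr_name not in seen:
                seen.add(d.tr_name)
                out.append(d.tr_name)
        return out

    def __len__(self) -> int:
        return len(self.datasets)


def filter_library_datasets(datasets: Iterable[TRBindingDataset],
                            min_peaks: int = DEFAULT_MIN_PEAKS,
                            ) -> list[TRBindingDataset]:
    """Keep datasets with at least *min_peaks* peaks (inclusive), in order."""
    if min_peaks < 0:
        raise ValueError("min_peaks must be >= 0")
    kept = [d for d in datasets if d.peak_count >= min_peaks]
    if not kept:
        raise ValueError("library empty after QC")
    return kept


# ---------------------------------------------------------------------------
# BED / BAM readers
# ---------------------------------------------------------------------------


def read_bed_intervals(path: str | Path) -> ReadInput:
    """First three BED columns as intervals (reads or peaks)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return ReadInput(df["chrom"].to_numpy(dtype=object),
                     df["start"].to_numpy(np.int64),
                     df["end"].to_numpy(np.int64))


def read_scored_bed(path: str | Path) -> RegionInput:
    """Scored regions: column 5 of standard BED, or column 4 of 4-column BED."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("scored BED needs a score column (>=4 columns)")
    score_col = 4 if df.shape[1] >= 5 else 3
    return RegionInput(df[0].to_numpy(dtype=object),
                       df[1].to_numpy(np.int64),
                       df[2].to_numpy(np.int64),
                       df[score_col].to_numpy(float))


def bam_to_intervals(path: str | Path) -> ReadInput:
    """Adapter: mapped BAM/SAM records to read intervals."""
    import pysam

    chroms, starts, ends = [], [], []
    with pysam.AlignmentFile(str(path), require_index=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
    return ReadInput(np.array(chroms, dtype=object),
                     np.array(starts, dtype=np.int64),
                     np.array(ends, dtype=np.int64))


# ---------------------------------------------------------------------------
# Library directory format
# ---------------------------------------------------------------------------
#
# DIR/
#   udhs.bed        — the coordinate frame
#   datasets.tsv    — dataset_id, tr_name, peak_count (library order)
#   occupancy.mtx   — sparse binary matrix, datasets × UDHS sites
#   meta.json       — species
# Round-trips are bit-exact: integer coordinates, integer matrix entries.


def write_library(library: TRBindingLibrary, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    library.udhs.to_bed(directory / "udhs.bed")
    pd.DataFrame({
        "dataset_id": [d.dataset_id for d in library.datasets],
        "tr_name": [d.tr_name for d in library.datasets],
        "peak_count": [d.peak_count for d in library.datasets],
    }).to_csv(directory / "datasets.tsv", sep="\t", index=False)
    occ = scipy.sparse.csr_matrix(
        np.stack([d.occupancy for d in library.datasets]))
    scipy.io.mmwrite(str(directory / "occupancy.mtx"), occ, field="integer")
    (directory / "meta.json").write_text(
        json.dumps({"species": library.species}))


def read_library(directory: str | Path) -> TRBindingLibrary:
    directory = Path(directory)
    udhs = UDHSIndex.from_bed(directory / "udhs.bed")
    meta = json.loads((directory / "meta.json").read_text())
    table = pd.read_csv(directory / "datasets.tsv", sep="\t")
    occ = scipy.io.mmread(str(directory / "occupancy.mtx")).tocsr()
    datasets = [
        TRBindingDataset(dataset_id=str(row.dataset_id),
                         tr_name=str(row.tr_name),
                         occupancy=np.asarray(occ[i].todense()).ravel(),
                         peak_count=int(row.peak_count))
        for i, row in enumerate(table.itertuples(index=False))
    ]
    return TRBindingLibrary(species=meta["species"], udhs=udhs,
                            datasets=datasets)


# ---------------------------------------------------------------------------
# Matrix containers (RP matrix, UDHS signal matrix)
# ---------------------------------------------------------------------------


def save_matrix(path: str | Path, values: np.ndarray,
                row_ids: Sequence[str], col_ids: Sequence[str],
                **metadata: str) -> None:
    """Rectangular numeric matrix with id sidecars, exact round-trip."""
    np.savez(path, values=np.asarray(values, dtype=np.float64),
             row_ids=np.array([str(r) for r in row_ids]),
             col_ids=np.array([str(c) for c in col_ids]),
             metadata=np.array(json.dumps(metadata)))


def load_matrix(path: str | Path):
    with np.load(path) as z:
        values = z["values"]
        row_ids = [str(x) for x in z["row_ids"]]
        col_ids = [str(x) for x in z["col_ids"]]
        metadata = json.loads(str(z["metadata"]))
    return values, row_ids, col_ids, metadata
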