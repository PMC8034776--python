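"""Synthetic reference data with a planted ground-truth regulator.

The generator emulates the causal structure the ranking algorithm
assumes, in its simplest falsifiable form.  A single latent per-site
*activity* vector ties everything together:

* informative H3K27ac samples carry signal proportional to activity
  (times multiplicative noise); the remaining samples carry independent
  signal of the same marginal;
* a designated block of target genes has elevated regulatory potential
  exactly in the informative samples, so a query with those genes should
  make the adaptive lasso recover the informative samples and hence a
  profile that rank-correlates with activity;
* the planted TR's datasets occupy high-activity sites at an enriched
  rate (``peak_rate * enrichment`` in the top activity quantile,
  ``peak_rate`` elsewhere), while decoy TRs occupy uniformly at
  ``peak_rate`` — so the planted TR, and only it, should float to the
  top of the final table.

With ``enrichment = 1`` the planted TR is statistically identical to the
decoys, giving an exact null for calibration checks.  Everything is
drawn from one integer-seeded generator: identical config and seed give
bit-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .library_io import (
    GeneSet,
    ReadInput,
    RegionInput,
    TRBindingDataset,
    TRBindingLibrary,
    UDHSIndex,
    filter_library_datasets,
)
from .profile_inference import (
    CisRegulatoryProfile,
    H3K27acSignalMatrix,
    RegulatoryPotentialMatrix,
)
from .reference import ReferenceBundle
from .statistics import build_background_models

__all__ = ["FixtureConfig", "SyntheticReference", "generate_reference",
           "generate_query"]

_CHROM_COUNT = 5
_CHROM_LENGTH = 10_000_000  # synthetic genome: 5 chromosomes of 10 Mb


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions of the synthetic benchmark."""

    seed: int = 0
    n_genes: int = 10_000
    n_samples: int = 200
    n_udhs_sites: int = 20_000
    n_trs: int = 50
    datasets_per_tr: int = 3
    n_informative_samples: int = 5
    n_target_genes: int = 200
    effect_size: float = 2.0
    peak_rate: float = 0.15
    enrichment: float = 5.0
    planted_tr: str = "PLANTED"
    top_active_fraction: float = 0.1
    signal_noise_sd: float = 0.25
    min_peaks: int = 2000
    n_background_runs: int = 100
    n_reads: int = 1_000_000
    read_length: int = 50
    n_regions: int = 1000
    region_score_noise_sd: float = 0.1
    species: str = "hg38"

    def __post_init__(self):
        for name in ("n_genes", "n_samples", "n_udhs_sites", "n_trs",
                     "datasets_per_tr", "n_informative_samples",
                     "n_target_genes", "n_background_runs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.peak_rate < 1):
            raise ValueError("peak_rate must be in (0, 1)")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if self.n_informative_samples > self.n_samples:
            raise ValueError("n_informative_samples > n_samples")
        if self.n_target_genes > self.n_genes:
            raise ValueError("n_target_genes > n_genes")
        if self.n_regions > self.n_udhs_sites:
            raise ValueError("n_regions > n_udhs_sites")

    def scaled(self, **overrides) -> "FixtureConfig":
        return replace(self, **overrides)


@dataclass
class SyntheticReference(ReferenceBundle):
    """Reference bundle plus the fixture's hidden ground truth."""

    latent_activity: np.ndarray = None
    informative_samples: list[str] = None
    target_genes: list[str] = None
    planted_tr: str = ""


def _make_udhs(rng: np.random.Generator, n_sites: int) -> UDHSIndex:
    per_chrom = np.full(_CHROM_COUNT, n_sites // _CHROM_COUNT)
    per_chrom[: n_sites % _CHROM_COUNT] += 1
    chroms, starts, ends = [], [], []
    for c, k in enumerate(per_chrom, start=1):
        k = int(k)
        if k == 0:
            continue
        widths = rng.integers(200, 1000, size=k)
        free = _CHROM_LENGTH - int(widths.sum())
        if free <= k + 1:
            raise ValueError("too many sites for the synthetic chromosome")
        # k+1 strictly-positive gaps summing to exactly `free`
        gaps = rng.multinomial(free - (k + 1),
                               np.full(k + 1, 1.0 / (k + 1))) + 1
        pos = 0
        for i in range(k):
            pos += int(gaps[i])
            chroms.append(f"chr{c}")
            starts.append(pos)
            pos += int(widths[i])
            ends.append(pos)
    return UDHSIndex(np.array(chroms, dtype=object),
                     np.array(starts, dtype=np.int64),
                     np.array(ends, dtype=np.int64))


def generate_reference(config: FixtureConfig) -> SyntheticReference:
    """Deterministically build UDHS, RP/signal matrices, TR library and
    per-TR background models from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    S, m, n = config.n_udhs_sites, config.n_samples, config.n_genes

    udhs = _make_udhs(rng, S)
    activity = rng.lognormal(0.0, 1.0, S)

    sample_ids = [f"H3K27AC_{j:04d}" for j in range(m)]
    informative = np.sort(rng.choice(m, config.n_informative_samples,
                                     replace=False))
    signal = rng.lognormal(0.0, 1.0, (S, m))
    for j in informative:
        signal[:, j] = activity * rng.lognormal(
            0.0, config.signal_noise_sd, S)
    signals = H3K27acSignalMatrix(samples=sample_ids, values=signal)

    genes = [f"GENE{g:05d}" for g in range(n)]
    target_idx = np.sort(rng.choice(n, config.n_target_genes, replace=False))
    rp_values = rng.normal(0.0, 1.0, (n, m))
    rp_values[np.ix_(target_idx, informative)] += config.effect_size
    rp_values = (rp_values - rp_values.mean(axis=0)) / rp_values.std(axis=0)
    rp = RegulatoryPotentialMatrix(genes=genes, samples=sample_ids,
                                   values=rp_values,
                                   normalization="column z-score")

    top_sites = activity >= np.quantile(activity,
                                        1.0 - config.top_active_fraction)
    tr_names = [config.planted_tr] + [
        f"TR{t:03d}" for t in range(1, config.n_trs)]
    datasets = []
    for tr in tr_names:
        p = np.full(S, config.peak_rate)
        if tr == config.planted_tr:
            p[top_sites] = min(config.peak_rate * config.enrichment, 0.95)
        for d in range(config.datasets_per_tr):
            occupancy = (rng.random(S) < p).astype(np.uint8)
            datasets.append(TRBindingDataset(
                dataset_id=f"{tr}_ds{d}", tr_name=tr,
                occupancy=occupancy, peak_count=int(occupancy.sum())))
    datasets = filter_library_datasets(datasets, min_peaks=config.min_peaks)
    library = TRBindingLibrary(species=config.species, udhs=udhs,
                               datasets=datasets)

    bg_profiles = (
        CisRegulatoryProfile(rng.standard_normal(S), mode="region_scores",
                             provenance=f"decoy background run {b}")
        for b in range(config.n_background_runs))
    backgrounds = build_background_models(
        library, bg_profiles, source="synthetic decoy-profile collection")

    return SyntheticReference(
        species=config.species, library=library, rp=rp, signals=signals,
        backgrounds=backgrounds, latent_activity=activity,
        informative_samples=[sample_ids[j] for j in informative],
        target_genes=[genes[g] for g in target_idx],
        planted_tr=config.planted_tr)


def generate_query(config: FixtureConfig,
                   mode: Literal["geneset", "reads", "regions"],
                   reference: SyntheticReference):
    """Build a query of the given mode tied to the fixture's ground truth.

    geneset -> the target-gene block (a GeneSet); reads -> read intervals
    whose site choice is proportional to latent activity; regions ->
    scored regions, one per sampled UDHS site, scores = activity plus
    Gaussian noise (``region_score_noise_sd = 0`` gives noiseless scores).
    """
    udhs = reference.udhs
    a = reference.latent_activity
    if mode == "geneset":
        return GeneSet(species=config.species,
                       symbols=list(reference.target_genes),
                       source_label="fixture target-gene block")
    if mode == "reads":
        rng = np.random.default_rng([config.seed, 1])
        S = udhs.site_count
        sites = rng.choice(S, size=config.n_reads, p=a / a.sum())
        widths = udhs.ends[sites] - udhs.starts[sites]
        mids = udhs.starts[sites] + rng.integers(0, widths)
        half = config.read_length // 2
        starts = np.maximum(mids - half, 0)
        ends = starts + config.read_length
        return ReadInput(udhs.chroms[sites].copy(), starts, ends)
    if mode == "regions":
        rng = np.random.default_rng([config.seed, 2])
        S = udhs.site_count
        sites = np.sort(rng.choice(S, size=config.n_regions, replace=False))
        pad = 100
        starts = np.maximum(udhs.starts[sites] - pad, 0)
        ends = udhs.ends[sites] + pad
        scores = a[sites] + config.region_score_noise_sd * \
            rng.standard_normal(config.n_regions)
        return RegionInput(udhs.chroms[sites].copy(), starts, ends, scores)
    raise ValueError(f"unknown query mode: {mode}")
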