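"""Cis-regulatory profile inference.

A query gene set is modelled as the response of a logistic regression on
the regulatory-potential (RP) matrix P (genes x H3K27ac samples):

    E[y | P] = 1 / (1 + exp(-(beta_1 p_1 + ... + beta_m p_m)))

with the sparsity assumption that only a small subset of the compendium
samples (m0 << m) is informative about the gene set.  That subset is
identified by a generalized logistic *adaptive* lasso

    argmin_beta  sum_i [ -y_i (p_i' beta) + log(1 + exp(p_i' beta)) ]
                 + lambda * sum_j w_j |beta_j|

whose per-coefficient weights w_j are built iteratively: all ones in the
first round, then 1/|beta_j| from the previous round's fit (predictors
that were shrunk to zero get infinite weight, i.e. are removed).  The
selected coefficients are then projected onto the H3K27ac signal over
UDHS to give each candidate CRE a score; high scores mark elements likely
to regulate the query genes.

ChIP-seq read and scored-region queries bypass the model: their pile-up /
score vectors over UDHS are used as the profile directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .library_io import (
    GeneSet,
    ReadInput,
    RegionInput,
    UDHSIndex,
    map_regions_to_udhs,
    pileup_reads_on_udhs,
)

__all__ = [
    "RegulatoryPotentialMatrix",
    "ResponseVector",
    "AdaptiveLassoConfig",
    "AdaptiveLassoFit",
    "H3K27acSignalMatrix",
    "CisRegulatoryProfile",
    "build_response_vector",
    "logistic_lasso",
    "adaptive_lasso_select",
    "score_cres",
    "profile_from_input",
]


@dataclass
class RegulatoryPotentialMatrix:
    """Normalized genes x samples regulatory-potential predictor matrix."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # n x m, float64
    normalization: str = "column z-score"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n, m = self.values.shape
        if n != len(self.genes) or m != len(self.samples):
            raise ValueError("RP matrix shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RP matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ResponseVector:
    """Binary gene-set membership aligned to the RP matrix's gene order."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("response entries must be 0/1")
        ones = int(v.sum())
        if ones == 0 or ones == len(v):
            raise ValueError(
                "response must contain both classes (logistic fit undefined)")
        self.values = v.astype(np.float64)

    @property
    def n_ones(self) -> int:
        return int(self.values.sum())


def build_response_vector(gene_set: GeneSet,
                          rp: RegulatoryPotentialMatrix) -> ResponseVector:
    """y_i = 1 iff gene i of the RP matrix is in the query set."""
    members = {s.upper() for s in gene_set.symbols}
    y = np.fromiter(((g.upper() in members) for g in rp.genes),
                    dtype=np.float64, count=rp.n_genes)
    if y.sum() == 0:
        raise ValueError("gene set disjoint from RP matrix genes")
    return ResponseVector(y)


# ---------------------------------------------------------------------------
# Penalized logistic fits
# ---------------------------------------------------------------------------


@dataclass
class AdaptiveLassoConfig:
    """Knobs of the iterative selection.

    max_iterations counts lasso rounds: 2 = one plain-lasso round plus one
    adaptive round.  max_active truncates the lambda path once the active
    set exceeds it — under the sparsity assumption the optimum is far
    sparser, and the dense end of the path is never selected by BIC.
    """

    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    max_iterations: int = 2
    gamma: float = 1.0
    tol: float = 1e-7
    max_solver_iter: int = 10_000
    max_active: int | None = 50


@dataclass
class AdaptiveLassoFit:
    """Selected H3K27ac samples with coefficients and final weights."""

    sample_ids: list[str]
    coefficients: np.ndarray  # length m, zeros for unselected
    weights: np.ndarray  # length m, np.inf for removed predictors
    penalty: float
    intercept: float
    iterations: int
    selected_samples: list[str] = field(init=False)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        nz = np.flatnonzero(self.coefficients)
        self.selected_samples = [self.sample_ids[j] for j in nz]

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.coefficients)


def logistic_lasso(rp, y, weights, lam: float, *,
                   tol: float = 1e-7,
                   max_iter: int = 10_000) -> tuple[np.ndarray, float]:
    """Minimize the weighted-L1-penalized logistic negative log-likelihood.

    Solved by the standard adaptive-lasso reduction: with the
    substitution ``b_j = lam * w_j * beta_j`` the per-coefficient penalty
    ``lam * sum_j w_j |beta_j|`` becomes a plain unit L1 penalty on ``b``
    over the rescaled predictors ``X / (lam * w)``, so any (weights,
    lambda) pairs with equal products ``lam * w_j`` give bit-identical
    solver inputs.  ``lam = 0`` dispatches to an unpenalized fit.  The
    intercept is (effectively) unpenalized.

    Returns ``(beta, intercept)``.
    """
    X = rp.values if isinstance(rp, RegulatoryPotentialMatrix) else np.asarray(rp, float)
    yv = y.values if isinstance(y, ResponseVector) else np.asarray(y, float)
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in predictor matrix")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if lam < 0:
        raise ValueError("lambda must be >= 0")

    if lam == 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf = LogisticRegression(penalty=None, solver="lbfgs",
                                     tol=min(tol, 1e-9), max_iter=max_iter)
            clf.fit(X, yv)
        if clf.n_iter_[0] >= max_iter:
            raise RuntimeError("unpenalized logistic fit did not converge")
        return clf.coef_[0].copy(), float(clf.intercept_[0])

    # per-coefficient penalties lam*w_j; the free overall constant C is
    # set to their geometric mean so the rescaled predictors stay O(1)
    # (liblinear conditioning), while any (weights, lambda) pairs with
    # equal products lam*w_j still give identical solver inputs
    penalties = lam * w
    C = float(np.exp(np.mean(np.log(penalties))))
    scale = penalties / C
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        clf = LogisticRegression(l1_ratio=1.0, C=1.0 / C,
                                 solver="liblinear", tol=tol,
                                 max_iter=max_iter, intercept_scaling=100.0,
                                 random_state=0)
        clf.fit(X / scale, yv)
    if np.asarray(clf.n_iter_).max() >= max_iter:
        raise RuntimeError(
            f"L1 logistic solver hit max_iter={max_iter} at lambda={lam:g}")
    return clf.coef_[0] / scale, float(clf.intercept_[0])


def _nll(X: np.ndarray, y: np.ndarray, beta: np.ndarray, b0: float) -> float:
    eta = X @ beta + b0
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def _lambda_path(X: np.ndarray, y: np.ndarray,
                 config: AdaptiveLassoConfig) -> np.ndarray:
    # lambda_max = largest |gradient| of the null (intercept-only) model;
    # at or above it the L1 solution is all-zero
    lam_max = float(np.abs(X.T @ (y - y.mean())).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio,
                        config.n_lambdas)


def adaptive_lasso_select(rp: RegulatoryPotentialMatrix, y: ResponseVector,
                          config: AdaptiveLassoConfig | None = None,
                          ) -> AdaptiveLassoFit:
    """Iteratively-weighted sparse selection of informative H3K27ac samples.

    Round 0 runs a plain lasso (all weights 1); each later round reweights
    by ``1/|beta|**gamma`` from the previous round's fit and removes
    predictors whose coefficient was shrunk to zero (the infinite-weight
    limit).  Within each round, lambda is chosen on a log-spaced path by
    BIC = deviance + df*log(n).  Iteration stops when the selected set is
    unchanged or after ``config.max_iterations`` rounds.
    """
    config = config or AdaptiveLassoConfig()
    X_full = rp.values
    yv = y.values
    n, m = X_full.shape
    if m < 2:
        raise ValueError("need at least 2 predictors")

    active = np.arange(m)
    weights_active = np.ones(m)
    beta_full = np.zeros(m)
    final_weights = np.ones(m)
    intercept = 0.0
    penalty = 0.0
    rounds_run = 0

    for _ in range(config.max_iterations):
        Xa = X_full[:, active]
        wa = weights_active
        Xs = Xa / wa
        path = _lambda_path(Xs, yv, config)
        best_bic = np.inf
        best = None
        for lam in path:
            beta, b0 = logistic_lasso(Xa, yv, wa, lam, tol=config.tol,
                                      max_iter=config.max_solver_iter)
            k = int(np.count_nonzero(beta))
            bic = 2.0 * _nll(Xa, yv, beta, b0) + k * np.log(n)
            if bic < best_bic:
                best_bic = bic
                best = (beta, b0, lam)
            if config.max_active is not None and k > config.max_active:
                break
        beta, b0, lam = best
        rounds_run += 1
        new_full = np.zeros(m)
        new_full[active] = beta
        nz_local = np.flatnonzero(beta)
        new_active = active[nz_local]
        final_weights = np.full(m, np.inf)
        final_weights[active] = wa
        selection_unchanged = (
            new_active.size == active.size
            and np.array_equal(new_active, active)
        )
        beta_full, intercept, penalty = new_full, b0, float(lam)
        if new_active.size == 0:
            break
        active = new_active
        weights_active = 1.0 / np.abs(beta_full[active]) ** config.gamma
        if selection_unchanged and rounds_run > 1:
            break

    if not np.any(beta_full):
        raise ValueError("no informative H3K27ac samples")
    return AdaptiveLassoFit(sample_ids=list(rp.samples),
                            coefficients=beta_full,
                            weights=final_weights,
                            penalty=penalty,
                            intercept=intercept,
                            iterations=rounds_run)


# ---------------------------------------------------------------------------
# CRE scoring
# ---------------------------------------------------------------------------


@dataclass
class H3K27acSignalMatrix:
    """UDHS sites x samples H3K27ac signal, column-aligned to the RP matrix."""

    samples: list[str]
    values: np.ndarray  # site_count x m, non-negative

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[1] != len(self.samples):
            raise ValueError("signal matrix shape does not match sample ids")
        if np.any(self.values < 0):
            raise ValueError("H3K27ac signal must be non-negative")

    @property
    def site_count(self) -> int:
        return self.values.shape[0]


@dataclass
class CisRegulatoryProfile:
    """One score per UDHS site; all three input modes reduce to this."""

    scores: np.ndarray
    mode: str  # geneset | chipseq_reads | region_scores
    provenance: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile contains non-finite scores")
        if self.scores.size and np.ptp(self.scores) == 0:
            raise ValueError(
                "constant cis-regulatory profile cannot rank sites")

    def __len__(self) -> int:
        return len(self.scores)


def score_cres(fit: AdaptiveLassoFit,
               signals: H3K27acSignalMatrix) -> CisRegulatoryProfile:
    """Project selected-sample coefficients onto the UDHS H3K27ac signal.

    Site score = sum over selected samples j of beta_j * signal[site, j];
    higher scores mark candidate CREs more likely to regulate the query
    gene set.
    """
    if fit.sample_ids != signals.samples:
        raise ValueError("signal matrix sample ids do not match the fit")
    sel = fit.selected_indices
    if sel.size == 0:
        raise ValueError("empty fit: no selected samples")
    scores = signals.values[:, sel] @ fit.coefficients[sel]
    return CisRegulatoryProfile(
        scores=scores, mode="geneset",
        provenance=f"{sel.size} selected H3K27ac samples")


def profile_from_input(query, *, udhs: UDHSIndex | None = None,
                       rp: RegulatoryPotentialMatrix | None = None,
                       signals: H3K27acSignalMatrix | None = None,
                       config: AdaptiveLassoConfig | None = None,
                       ) -> CisRegulatoryProfile:
    """Dispatch a query of any supported type to its profile.

    GeneSet -> adaptive-lasso selection then CRE scoring (needs rp and
    signals); ReadInput -> read pile-up over UDHS; RegionInput -> region
    score assignment over UDHS.
    """
    if isinstance(query, GeneSet):
        if rp is None or signals is None:
            raise ValueError("gene-set input needs rp and signals")
        y = build_response_vector(query, rp)
        fit = adaptive_lasso_select(rp, y, config)
        prof = score_cres(fit, signals)
        prof.provenance = (f"gene set '{query.source_label}' "
                           f"({len(query)} genes); {prof.provenance}")
        return prof
    if isinstance(query, ReadInput):
        if udhs is None:
            raise ValueError("read input needs the UDHS index")
        counts = pileup_reads_on_udhs(query, udhs)
        return CisRegulatoryProfile(
            scores=counts.astype(float), mode="chipseq_reads",
            provenance=f"pile-up of {len(query)} reads")
    if isinstance(query, RegionInput):
        if udhs is None:
            raise ValueError("region input needs the UDHS index")
        scores = map_regions_to_udhs(query, udhs)
        return CisRegulatoryProfile(
            scores=scores, mode="region_scores",
            provenance=f"scores of {len(query)} regions")
    raise TypeError(f"unsupported query type: {type(query).__name__}")
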