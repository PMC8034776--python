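# Methods

`bartcore` ranks transcriptional regulators (TRs) by how well their
genome-wide binding, as captured by a compendium of ChIP-seq datasets,
matches a genomic *cis*-regulatory profile inferred from a user query.
This note records the model, the algorithmic and numerical choices made
where the design was open, what the synthetic benchmark does and does
not emulate, and the known limitations.

## The coordinate frame

Every genomic vector in the package — profiles, binding occupancy,
H3K27ac signal — is indexed on a fixed catalogue of candidate
*cis*-regulatory elements (CREs): the union of DNase I hypersensitive
sites (UDHS), a sorted, non-overlapping set of intervals treated as
given input. All interval I/O uses the BED convention (0-based,
half-open); overlap means non-empty intersection. Because the frame is
sorted and non-overlapping, interval assignment is done by binary
search rather than a tree structure; the test suite checks it against
quadratic brute-force oracles.

Two conventions the inputs do not force were fixed as follows:

* **Scored regions.** A UDHS site overlapped by several scored regions
  takes the **maximum** region score: it is order-independent and
  preserves peak-like semantics. Unscored sites score 0.
* **Read pile-up.** A read is assigned to the single site containing
  its midpoint `(start + end) // 2`, so no read is double-counted
  across adjacent or touching sites.

Input-size recommendations (≥100 genes, ≥1 million reads, ≥1000
regions) are warnings, not errors: they are recommendations about
statistical stability, not validity conditions.

## Profile inference from a gene set

Gene-set membership is modelled as a logistic regression on the
normalized regulatory-potential (RP) matrix **P** (genes × H3K27ac
samples):

    E[y | P] = 1 / (1 + exp(−(β₁p₁ + … + β_m p_m)))

with the working assumption that only m₀ ≪ m compendium samples are
informative. The informative subset is found by a generalized logistic
adaptive lasso,

    β̂ = argmin_β Σᵢ [ −yᵢ pᵢᵀβ + log(1 + exp(pᵢᵀβ)) ] + λ Σⱼ ŵⱼ |βⱼ|,

with iteratively constructed weights: ŵ = 1 in the first round, then
ŵⱼ = 1/|βⱼ|^γ (γ = 1, the standard adaptive-lasso exponent) from the
previous round's coefficients. Predictors shrunk exactly to zero are
removed from later rounds — the exact infinite-weight limit of the
penalty. The default is two rounds (one plain lasso, one adaptive),
configurable; iteration also stops early if the selected set stops
changing.

Numerical and selection choices:

* **Solver.** Each weighted problem is reduced to a plain unit-L1
  problem by the substitution bⱼ = λŵⱼβⱼ (rescaling predictor j by
  1/(λŵⱼ)), solved with scikit-learn's liblinear backend, and
  unscaled. The reduction makes the weight/penalty rescaling identity
  (weights c, penalty λ ≡ weights 1, penalty cλ) hold *exactly*, since
  both produce bit-identical solver inputs. λ = 0 dispatches to an
  unpenalized lbfgs fit. The intercept is effectively unpenalized
  (penalty weight 1/100 of any coefficient via the augmentation
  trick). Solver tolerance 1e-7, at most 10⁴ iterations; failure to
  converge raises.
* **λ selection.** Per round, λ runs over a 50-point log-spaced path
  from λ_max (the largest null-model gradient, above which the
  solution is all-zero) down to 10⁻³·λ_max, and the fit minimizing
  BIC = deviance + df·log(n) is kept. BIC is deterministic and costs
  one fit per grid point, in keeping with the method's avoidance of
  k-fold cross-validation. The path is truncated once the active set
  exceeds 50 predictors: under the sparsity assumption the BIC optimum
  is far sparser, and the dense tail is never selected.
* **Path monotonicity.** The number of nonzero coefficients is
  non-increasing in λ in well-conditioned regimes (and is tested
  there), but this is not a theorem of the lasso: variables can leave
  and re-enter the path, and solver tolerance adds jitter near
  saturation. Nothing in the algorithm relies on strict monotonicity.

The selected coefficients are projected onto the H3K27ac signal matrix
over UDHS: site score = Σⱼ βⱼ·signalⱼ. A constant profile (e.g. exact
cancellation) is rejected, since it cannot rank sites. ChIP-seq read
and scored-region queries skip the model entirely: their pile-up/score
vectors are the profile.

## Association scores

The association score of one binding dataset is the Mann–Whitney / ROC
AUC of the profile as a classifier of that dataset's UDHS occupancy:
P(score at a random occupied site > score at a random unoccupied site)
+ ½·P(tie), computed via the mid-rank rank-sum identity. This is the
standard reading of an "association AUC"; it is invariant under
strictly monotone transforms of the profile, so the profile is ranked
once and reused for every dataset. Datasets degenerate on the frame
(all or no sites occupied) are dropped with a warning. An all-tied
profile scores 0.5 by the same convention.

## The six per-TR statistics

1–2. **Wilcoxon rank-sum statistic and p-value.** The TR's dataset
AUCs against all other datasets' AUCs, one-sided (greater). The
reported statistic is the rank-sum standardized with mid-rank tie
correction and *no* continuity correction, so it negates exactly under
a group swap; the p-value applies the 0.5 continuity correction inside
the normal approximation. With distinct scores the approximation
tracks the exact permutation p to about 0.01 at group sizes (4, 6);
heavy ties coarsen the discrete null faster than any continuity rule
can follow, so only the statistic (not the p) is exact under ties.
TRs with a single dataset are allowed and flagged via
`dataset_count`.

3. **Z-score.** The Wilcoxon statistic standardized against a
background model: the mean/sd of that same TR's statistic across a
collection of unrelated background queries. The background is a
first-class input artifact (rebuildable from any collection of
background inputs by `build_background_models`), stored per TR because
the score measures how specific the enrichment is to *this* query
rather than a general property of that TR's datasets. A single global
model is also accepted; with no background, the standard-normal null
of the standardized rank-sum is used.

4. **Max AUC.** The TR's best single dataset.

5. **Relative rank.** Each of the three statistics above is ranked
descending across TRs (mid-rank ties); the mean of the three ranks is
divided by the number of TRs.

6. **Irwin-Hall p-value.** The sum of the three relative ranks is
referred to the Irwin-Hall(3) distribution — the null for three
*independent* uniform ranks — via its exact alternating closed form
(stable at k = 3; probabilities floored at 1e-300 to keep −log₁₀
plots finite). Tables are sorted by this p-value ascending, ties
broken deterministically by TR name; any column can be chosen as the
sort key instead.

**Known limitation — conservative null calibration.** The three ranks
are not independent under a null query: with an exchangeable library
the per-TR background means coincide, making the Z-score a nearly
monotone transform of the Wilcoxon statistic (identical ranks), and
the max-AUC rank is positively correlated with the rank-sum because
both derive from the same handful of AUCs. The summed rank therefore
behaves like 2U+V rather than U+V+W, and null Irwin-Hall p-values
deviate from uniformity (measured pooled Kolmogorov–Smirnov distance
≈ 0.19 on the synthetic null at 3 datasets/TR). The p-value is an
integrative ranking score, as intended, not a calibrated tail
probability; it should not be interpreted as a type-I error rate.

**Benchmark rule.** `call_true_prediction` implements the evaluation
convention for perturbation benchmarks: a factor counts as a true
prediction iff it ranks within the top fraction (default 10%,
optionally 1% or 0.5%) of TRs by Irwin-Hall p *and* its p-value is
below 0.01. A factor absent from the library raises a distinguishable
error, as such cases belong outside the benchmark denominator.

## The synthetic benchmark

`fixtures.generate_reference` builds a complete reference bundle from
one seeded integer-state generator (identical config + seed ⇒
bit-identical artifacts; no locale or threading dependence). A single
latent per-site activity vector ties together the three layers the
algorithm assumes are causally linked:

* **Genome/UDHS:** 5 synthetic chromosomes of 10 Mb; sites of width
  200–1000 bp with strictly positive gaps, so interval code is
  exercised across chromosome boundaries.
* **H3K27ac signal:** informative samples = activity × lognormal
  noise (sd 0.25 on the log scale); the rest are independent lognormal
  columns of the same marginal.
* **RP matrix:** standard-normal base with +`effect_size` (default
  2.0) added for target-block genes in informative samples only, then
  column z-scored. The RP construction of real compendia
  (decay-weighted read sums around TSS) is *not* recomputed — the
  matrix is a modelling input, and the fixture emulates only the
  statistical structure the selection step sees.
* **TR library:** `n_trs` = 50 TRs × 3 datasets. Decoys occupy sites
  i.i.d. at `peak_rate` = 0.15; the planted TR occupies the top 10%
  of sites by activity at `peak_rate × enrichment` (default 5, capped
  at 0.95). At the default 20 000 sites this gives ~3000 peaks per
  dataset, comfortably above the 2000-peak QC threshold (inclusive,
  matching the library's "at least 2000 peaks" rule).
* **Backgrounds:** 100 decoy runs with standard-normal profiles,
  giving each TR a background mean/sd of its Wilcoxon statistic.
* **Queries:** the gene-set query is the 200-gene target block; the
  read query samples 10⁶ read midpoints with probability proportional
  to activity; the region query scores 1000 site-anchored regions as
  activity plus Gaussian noise (sd 0.1).

Default counts and rates are the benchmark's study conditions;
repeated-run checks (rank uniformity under `enrichment = 1` across 50
seeds; 200-table null calibration) use proportionally reduced bundles
(e.g. 2000 genes / 50 samples / 4000 sites, QC threshold scaled with
the site count) because the properties under test are
size-independent, while the planted-recovery power check runs at the
full default sizes.

What passing these tests shows — and does not. The fixture
demonstrates that the pipeline recovers a regulator whose binding is
genuinely enriched at active elements linked to the query genes, and
that it does not hallucinate one under the null. It does not emulate
read-length/fragment structure, sequence content, mappability,
correlated TR families, heterogeneous dataset counts per TR, or the
real compendium's batch structure, so it cannot certify performance on
real Cistrome-scale libraries.

## Determinism and degenerate inputs

All randomness flows through `numpy.random.default_rng` seeds carried
in configs; liblinear is given a fixed `random_state`; result tables
are serialized with fixed `%.10g` formatting; SVG output pins the hash
salt and drops the date, so identical configs reproduce byte-identical
tables and plots. Degenerate inputs fail loudly with specific
messages: empty gene lists, gene sets matching nothing (or
everything), malformed intervals (reported by line), all-constant
profiles, degenerate occupancy vectors, empty post-QC libraries, and
empty adaptive-lasso selections.
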