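# bartcore

Transcriptional-regulator association analysis from ChIP-seq compendia.

Given a genomic query — a gene set, a mapped ChIP-seq read dataset, or a
scored region set — `bartcore` asks: **which transcriptional regulators
(TRs) are most likely behind it?** It answers by inferring a genomic
*cis*-regulatory profile over a fixed catalogue of candidate
*cis*-regulatory elements (the union of DNase I hypersensitive sites,
UDHS), scoring every TR ChIP-seq binding dataset in a library against
that profile, and ranking TRs with an integrative statistical
framework. It is aimed at computational biologists who have a
differential gene set or an epigenomic signal and want regulator
hypotheses ranked with transparent statistics.

## The method

**Profile inference (gene-set mode).** Gene-set membership y over the
genome is modelled as a logistic regression on the normalized
regulatory-potential matrix **P** derived from an H3K27ac ChIP-seq
compendium (genes × samples):

    E[y | P] = 1 / (1 + exp(−(β₁p₁ + … + β_m p_m)))

Only a sparse subset of compendium samples is assumed informative, and
it is selected by a generalized logistic **adaptive lasso**

    β̂ = argmin_β Σᵢ [ −yᵢ pᵢᵀβ + log(1 + exp(pᵢᵀβ)) ] + λ Σⱼ ŵⱼ|βⱼ|

whose weights ŵⱼ start at 1 and are then set to 1/|βⱼ| from the
previous round's fit (zeroed predictors are removed — the
infinite-weight limit); λ is chosen per round by BIC on a log-spaced
path. The selected coefficients are applied to the samples' H3K27ac
signal over UDHS, giving each candidate element a score; read and
region queries use their pile-up / score vectors directly.

**Association and ranking.** Each binding dataset gets an association
score: the ROC AUC of the profile as a classifier of its UDHS
occupancy (mid-rank ties). Per TR, the package then reports the six
statistics of the output table: the one-sided Wilcoxon rank-sum
statistic and p-value of that TR's AUCs against all others', a
Z-score against a background model of the same statistic over
unrelated queries, the maximum AUC, the relative rank (mean of the
three descending ranks / number of TRs), and the **Irwin-Hall
p-value** — the sum of the three relative ranks referred to the
distribution of a sum of three independent uniforms — by which the
table is sorted.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices, and known limitations (in particular: the Irwin-Hall p-value
is a ranking score, not a calibrated tail probability).

## Worked example

No external data are needed: the `fixtures` module generates a full
synthetic reference bundle — UDHS, RP and H3K27ac signal matrices, a
TR binding library with one *planted* regulator whose occupancy is
enriched at high-activity elements, and per-TR background models.

```python
import bartcore as bc

config = bc.FixtureConfig(seed=3, n_genes=2000, n_samples=50,
                          n_udhs_sites=4000, n_trs=20,
                          n_target_genes=120, n_background_runs=30,
                          min_peaks=300)
ref = bc.generate_reference(config)

genes = bc.generate_query(config, "geneset", ref)   # 120 target genes
profile = bc.profile_from_input(genes, rp=ref.rp, signals=ref.signals)
assoc = bc.score_library(profile, ref.library)
table = bc.assemble_results(assoc, ref.library, ref.backgrounds)
print(table.rows.head(3).to_string(index=False))
print("planted TR rank:", table.rank_of(config.planted_tr))
```

prints

```
tr_name  wilcoxon_statistic  wilcoxon_pvalue  z_score  max_auc  relative_rank  irwin_hall_pvalue  dataset_count
PLANTED            2.899972         0.001969 2.569461 0.663020       0.050000           0.000563              3
  TR011            1.204082         0.117590 1.187542 0.525405       0.183333           0.027729              3
  TR016            1.102328         0.138879 0.822815 0.529979       0.200000           0.036000              3
planted TR rank: 1
```

The adaptive lasso recovered the informative H3K27ac samples, the
resulting profile ranked the planted TR's occupied elements above
unoccupied ones (max AUC 0.66 vs ≈ 0.5 for decoys), and the planted TR
tops the table: rank 1 in each of the three statistics among 20 TRs
gives the smallest achievable relative rank 1/20 = 0.05, hence an
Irwin-Hall p-value of F₃(3 × 0.05) = 0.15³/6 ≈ 5.6e-4.

The same analysis runs from the shell against a reference directory
(`bc.write_reference(ref, "refdir")`):

```sh
bartcore geneset --species hg38 --library refdir \
    --input genes.txt --outdir out --min-peaks 300
bartcore plot --outdir out --tr PLANTED
```

The output directory contains the ranked table (`tr_results.tsv`), the
three intermediates (selected H3K27ac samples with coefficients, the
cis-regulatory profile, all dataset association scores), the serialized
run configuration, and a timestamped log; `plot` adds the per-TR
AUC-CDF and rank-dot figures.

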