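"""The six per-TR statistics and the Irwin-Hall ranking."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm, rankdata

from bartcore.association import AssociationTable
from bartcore.statistics import (
    BackgroundModel,
    FactorNotInLibraryError,
    assemble_results,
    build_background_models,
    call_true_prediction,
    irwin_hall_cdf,
    irwin_hall_pvalue,
    max_auc,
    relative_rank,
    wilcoxon_tr,
    z_score,
)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def exact_rank_sum_test(x, bg):
    """Exhaustive permutation oracle: observed mid-rank sum of the first
    group and the exact one-sided (greater) p-value."""
    pooled = np.concatenate([x, bg])
    ranks = rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    sums = [ranks[list(idx)].sum()
            for idx in itertools.combinations(range(len(pooled)), n1)]
    p_exact = np.mean([s >= observed for s in sums])
    return observed, p_exact


class TestWilcoxon:
    def test_extreme_ordering_gives_minimal_p(self):
        hi = [0.9, 0.92, 0.95, 0.99]
        lo = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        stat_hi, p_hi = wilcoxon_tr(hi, lo)
        # any other arrangement of the same pooled values has larger p
        for x in itertools.combinations(hi + lo, 4):
            rest = list(hi + lo)
            for v in x:
                rest.remove(v)
            _, p = wilcoxon_tr(list(x), rest)
            assert p >= p_hi

    def test_statistic_antisymmetric_under_group_swap(self, rng):
        x = rng.standard_normal(5)
        bg = rng.standard_normal(9)
        s1, _ = wilcoxon_tr(x, bg)
        s2, _ = wilcoxon_tr(bg, x)
        assert s1 == pytest.approx(-s2, abs=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty group"):
            wilcoxon_tr([], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_permutation_oracle(self, seed):
        # distinct integer scores: the normal approximation is only
        # expected to track the exact permutation p without ties
        rng = np.random.default_rng(seed)
        vals = rng.choice(100, 10, replace=False).astype(float)
        x, bg = vals[:4], vals[4:]
        stat, p = wilcoxon_tr(x, bg)
        observed, p_exact = exact_rank_sum_test(x, bg)
        # reconstruct the raw rank-sum from the standardized statistic
        N = 10
        mean = 4 * (N + 1) / 2
        sd = np.sqrt(4 * 6 / 12 * (N + 1))
        assert stat * sd + mean == pytest.approx(observed, abs=1e-9)
        assert abs(p - p_exact) <= 0.02

    @pytest.mark.parametrize("seed", range(4))
    def test_tied_scores_rank_sum_exact(self, seed):
        # with ties, the mid-rank sum must still invert exactly from the
        # tie-corrected standardized statistic
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 8, 4).astype(float)
        bg = rng.integers(0, 8, 6).astype(float)
        stat, _ = wilcoxon_tr(x, bg)
        observed, _ = exact_rank_sum_test(x, bg)
        pooled = np.concatenate([x, bg])
        N = 10
        mean = 4 * (N + 1) / 2
        _, counts = np.unique(pooled, return_counts=True)
        tie = ((counts ** 3) - counts).sum()
        sd = np.sqrt(4 * 6 / 12 * ((N + 1) - tie / (N * (N - 1))))
        assert stat * sd + mean == pytest.approx(observed, abs=1e-9)

    def test_singleton_group_allowed(self):
        stat, p = wilcoxon_tr([0.9], [0.1, 0.2, 0.3])
        assert stat > 0 and 0 < p < 0.5


# ---------------------------------------------------------------------------
# Z-score and max AUC
# ---------------------------------------------------------------------------


class TestZScore:
    def test_at_mean_and_two_sd(self):
        bg = BackgroundModel("w", mean=1.5, sd=0.5)
        assert z_score(1.5, bg) == 0.0
        assert z_score(2.5, bg) == 2.0

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            BackgroundModel("w", mean=0.0, sd=0.0)

    def test_matches_recomputation_from_background_runs(self, rng):
        stats = rng.standard_normal(100) * 2 + 1
        bg = BackgroundModel.from_stats(stats)
        x = 3.14
        want = (x - stats.mean()) / stats.std(ddof=1)
        assert z_score(x, bg) == pytest.approx(want, rel=1e-12)
        # the stored per-run statistics reproduce mean/sd
        arr = np.array(bg.per_background_stats)
        assert bg.mean == pytest.approx(arr.mean())
        assert bg.sd == pytest.approx(arr.std(ddof=1))


class TestMaxAuc:
    def test_examples(self):
        assert max_auc([0.4, 0.9, 0.6]) == 0.9
        assert max_auc([0.7]) == 0.7
        with pytest.raises(ValueError):
            max_auc([])

    def test_matches_sort_oracle(self, rng):
        for _ in range(200):
            vals = rng.random(int(rng.integers(1, 20)))
            assert max_auc(vals) == sorted(vals)[-1]


# ---------------------------------------------------------------------------
# relative rank
# ---------------------------------------------------------------------------


def rank_average_oracle(df):
    out = []
    cols = ["wilcoxon_statistic", "z_score", "max_auc"]
    for i in range(len(df)):
        ranks = []
        for c in cols:
            v = df[c].to_numpy()
            greater = (v > v[i]).sum()
            equal = (v == v[i]).sum()
            ranks.append(greater + (equal + 1) / 2)
        out.append(np.mean(ranks) / len(df))
    return np.array(out)


class TestRelativeRank:
    def test_best_in_all_three_of_ten(self):
        df = pd.DataFrame({
            "wilcoxon_statistic": np.r_[10.0, np.arange(9)],
            "z_score": np.r_[10.0, np.arange(9)],
            "max_auc": np.r_[1.0, np.linspace(0, 0.9, 9)]})
        assert relative_rank(df).iloc[0] == pytest.approx(0.1)

    def test_worst_in_all_three_is_one(self):
        df = pd.DataFrame({
            "wilcoxon_statistic": np.r_[np.arange(1, 7), 0.0],
            "z_score": np.r_[np.arange(1, 7), 0.0],
            "max_auc": np.r_[np.linspace(0.5, 1, 6), 0.1]})
        assert relative_rank(df).iloc[-1] == pytest.approx(1.0)

    def test_matches_independent_oracle(self, rng):
        df = pd.DataFrame({
            "wilcoxon_statistic": rng.standard_normal(20),
            "z_score": rng.standard_normal(20),
            "max_auc": rng.random(20)})
        got = relative_rank(df).to_numpy()
        assert np.allclose(got, rank_average_oracle(df), atol=1e-12)

    def test_missing_statistic_errors(self):
        df = pd.DataFrame({"wilcoxon_statistic": [1.0], "z_score": [1.0]})
        with pytest.raises(ValueError, match="max_auc"):
            relative_rank(df)


# ---------------------------------------------------------------------------
# Irwin-Hall
# ---------------------------------------------------------------------------


class TestIrwinHall:
    def test_support_endpoints(self):
        for k in (1, 2, 3, 5):
            assert irwin_hall_cdf(0.0, k) == 0.0
            assert irwin_hall_cdf(float(k), k) == 1.0
            assert irwin_hall_cdf(-1.0, k) == 0.0
            assert irwin_hall_cdf(k + 1.0, k) == 1.0

    def test_symmetry_point(self):
        assert irwin_hall_cdf(1.5, 3) == 0.5

    def test_cubic_closed_form_below_one(self):
        for s in (0.05, 0.3, 0.77, 1.0):
            assert irwin_hall_cdf(s, 3) == pytest.approx(s ** 3 / 6,
                                                         abs=1e-12)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            irwin_hall_cdf(0.5, 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0, 3), st.floats(0, 3))
    def test_monotone_and_symmetric(self, s1, s2):
        lo, hi = sorted([s1, s2])
        assert irwin_hall_cdf(lo, 3) <= irwin_hall_cdf(hi, 3)
        assert irwin_hall_cdf(s1, 3) + irwin_hall_cdf(3 - s1, 3) \
            == pytest.approx(1.0, abs=1e-9)


class TestIrwinHallPvalue:
    def test_closed_form_triplets(self):
        assert irwin_hall_pvalue((0.1, 0.1, 0.1)) == pytest.approx(
            0.3 ** 3 / 6, abs=1e-12)
        assert irwin_hall_pvalue((1.0, 1.0, 1.0)) == 1.0

    def test_composition_identity(self, rng):
        for _ in range(50):
            t = rng.uniform(0.01, 1.0, 3)
            assert irwin_hall_pvalue(t) == irwin_hall_cdf(t.sum(), 3)

    def test_component_out_of_range(self):
        with pytest.raises(ValueError):
            irwin_hall_pvalue((0.0, 0.5, 0.5))
        with pytest.raises(ValueError):
            irwin_hall_pvalue((1.2, 0.5, 0.5))


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------


def association_from(records):
    return AssociationTable(pd.DataFrame(
        records, columns=["dataset_id", "tr_name", "auc"]))


class TestAssembleResults:
    def test_two_tr_hand_worked_example(self):
        # TR A: aucs 0.9, 0.8; TR B: 0.3, 0.4.  Pooled ranks: 0.3->1,
        # 0.4->2, 0.8->3, 0.9->4, so A's rank-sum is 7.  With n1=n0=2:
        # mean 5, sd sqrt(4*5/12); statistic (7-5)/sd; the one-sided
        # normal p uses the 0.5 continuity correction.  Unit background
        # => z == statistic; both TRs tie-free so A ranks 1 in all three
        # statistics: relative rank 0.5, Irwin-Hall p = F3(1.5) = 0.5;
        # B ranks 2: relative rank 1.0, p = F3(3) = 1.
        table = assemble_results(association_from([
            ("a1", "A", 0.9), ("a2", "A", 0.8),
            ("b1", "B", 0.3), ("b2", "B", 0.4)]))
        rows = table.rows.set_index("tr_name")
        sd = np.sqrt(4 * 5 / 12)
        assert rows.loc["A", "wilcoxon_statistic"] == pytest.approx(2 / sd)
        assert rows.loc["A", "wilcoxon_pvalue"] == pytest.approx(
            float(norm.sf(1.5 / sd)))
        assert rows.loc["A", "z_score"] == pytest.approx(2 / sd)
        assert rows.loc["A", "max_auc"] == 0.9
        assert rows.loc["A", "relative_rank"] == pytest.approx(0.5)
        assert rows.loc["A", "irwin_hall_pvalue"] == pytest.approx(0.5)
        assert rows.loc["B", "wilcoxon_statistic"] == pytest.approx(-2 / sd)
        assert rows.loc["B", "max_auc"] == 0.4
        assert rows.loc["B", "relative_rank"] == pytest.approx(1.0)
        assert rows.loc["B", "irwin_hall_pvalue"] == pytest.approx(1.0)
        assert list(table.rows["tr_name"]) == ["A", "B"]
        assert rows.loc["A", "dataset_count"] == 2

    def test_invariant_to_dataset_order(self, rng):
        records = [(f"d{i}", f"TR{i % 6}", float(rng.random()))
                   for i in range(30)]
        t1 = assemble_results(association_from(records))
        shuffled = [records[i] for i in rng.permutation(30)]
        t2 = assemble_results(association_from(shuffled))
        pd.testing.assert_frame_equal(t1.rows, t2.rows)

    def test_fewer_than_two_trs_errors(self):
        with pytest.raises(ValueError, match="2 distinct TRs"):
            assemble_results(association_from(
                [("d1", "A", 0.5), ("d2", "A", 0.6)]))

    def test_sort_parameter(self, rng):
        records = [(f"d{i}", f"TR{i % 5}", float(rng.random()))
                   for i in range(20)]
        t = assemble_results(association_from(records), sort_by="max_auc")
        vals = t.rows["max_auc"].to_numpy()
        assert np.all(vals[:-1] >= vals[1:])

    def test_monotone_consistency_in_auc(self, rng):
        # raising every auc of one TR never worsens its final rank
        records = [(f"d{i}", f"TR{i % 6}", float(rng.uniform(0.3, 0.7)))
                   for i in range(24)]
        base = assemble_results(association_from(records))
        rank_before = base.rank_of("TR2")
        boosted = [(d, tr, min(a + 0.25, 0.99) if tr == "TR2" else a)
                   for d, tr, a in records]
        rank_after = assemble_results(
            association_from(boosted)).rank_of("TR2")
        assert rank_after <= rank_before

    def test_per_tr_background_mapping_used(self, rng):
        records = [(f"d{i}", f"TR{i % 3}", float(rng.random()))
                   for i in range(12)]
        backgrounds = {
            "TR0": BackgroundModel("w", mean=5.0, sd=2.0),
            "TR1": BackgroundModel("w", mean=0.0, sd=1.0),
            "TR2": BackgroundModel("w", mean=-1.0, sd=0.5)}
        t = assemble_results(association_from(records),
                             background=backgrounds)
        rows = t.rows.set_index("tr_name")
        for tr, bg in backgrounds.items():
            stat = rows.loc[tr, "wilcoxon_statistic"]
            assert rows.loc[tr, "z_score"] == pytest.approx(
                (stat - bg.mean) / bg.sd)


class TestCallTruePrediction:
    def _table(self, n=354, factor_rank=1, factor_p=1e-5):
        # ascending Irwin-Hall p column with KDFACTOR at the given rank
        p = np.empty(n)
        p[:factor_rank] = np.linspace(factor_p / 2, factor_p, factor_rank)
        lo = min(0.9, factor_p * 1.5 + 0.01)
        p[factor_rank:] = np.linspace(lo, 0.95, n - factor_rank)
        stats = -np.arange(n, dtype=float)
        names = [f"TR{i:03d}" for i in range(n)]
        names[factor_rank - 1] = "KDFACTOR"
        df = pd.DataFrame({
            "tr_name": names, "wilcoxon_statistic": stats,
            "wilcoxon_pvalue": p, "z_score": stats, "max_auc": 1 - p,
            "relative_rank": p, "irwin_hall_pvalue": p,
            "dataset_count": 1})
        from bartcore.statistics import TRResultTable
        return TRResultTable(df)

    def test_top_rank_small_p_is_true(self):
        assert call_true_prediction(self._table(), "KDFACTOR")

    def test_outside_top_fraction_is_false_regardless_of_p(self):
        t = self._table(factor_rank=36, factor_p=0.005)
        assert not call_true_prediction(t, "KDFACTOR")

    def test_large_p_in_top_fraction_is_false(self):
        t = self._table(factor_rank=1, factor_p=0.02)
        assert not call_true_prediction(t, "KDFACTOR")

    def test_stricter_cutoffs_callable(self):
        t = self._table()
        assert call_true_prediction(t, "KDFACTOR", top_fraction=0.005)
        assert call_true_prediction(t, "KDFACTOR", top_fraction=0.01)

    def test_absent_factor_distinguishable(self):
        with pytest.raises(FactorNotInLibraryError):
            call_true_prediction(self._table(), "NOT_THERE")


def test_background_builder_from_profiles(small_reference, rng):
    lib = small_reference.library
    profiles = [rng.standard_normal(lib.udhs.site_count) for _ in range(5)]
    models = build_background_models(lib, profiles)
    assert set(models) == set(lib.tr_names)
    for m in models.values():
        assert len(m.per_background_stats) == 5 and m.sd > 0
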