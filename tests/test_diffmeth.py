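import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methylearn as ml
from methylearn.diffmeth import (
    GroupError,
    SelectionError,
    bh_fdr,
    dichotomize_at_mean,
    pooled_selection,
    random_selection,
    select_by_significance,
    select_to_count,
    welch_t,
)
from methylearn.diffmeth import test_all_cpg as per_cpg_tests
from methylearn.io import MethylomeMatrix


def welch_oracle(a, b):
    """Textbook Welch's t: statistic, Welch-Satterthwaite df, two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def bh_oracle(p):
    """Step-up BH: p * m / rank with a reverse cumulative minimum, clipped."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


class TestWelch:
    def test_hand_example(self):
        t, df, p = welch_t([10, 20, 30], [40, 50, 60])
        assert t == pytest.approx(-3.674, abs=5e-4)
        assert df == pytest.approx(4.0, abs=1e-9)

    def test_identical_groups_give_zero(self):
        t, df, p = welch_t([5, 10, 15], [5, 10, 15])
        assert t == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(size=8)
        assert welch_t(a, b)[0] == pytest.approx(-welch_t(b, a)[0])

    def test_zero_variance_both_groups_undefined(self):
        with pytest.raises(GroupError, match="zero variance"):
            welch_t([5, 5, 5], [7, 7, 7])

    def test_small_groups_rejected(self):
        with pytest.raises(GroupError):
            welch_t([1], [2, 3])

    def test_matches_oracle_on_many_random_inputs(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            na, nb = rng.integers(2, 12, size=2)
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), nb)
            t, df, p = welch_t(a, b)
            to, dfo, po = welch_oracle(a, b)
            assert abs(t - to) <= 1e-10 * max(1, abs(to))
            assert abs(df - dfo) <= 1e-10 * max(1, abs(dfo))
            assert abs(p - po) <= 1e-10


class TestBH:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_empty(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])
        assert bh_fdr([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=50), st.randoms())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = bh_fdr(p)
        q_perm = bh_fdr([p[i] for i in perm])
        np.testing.assert_allclose(q_perm, [q[i] for i in perm], atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(5)
        p = rng.random(300)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()


class TestTestAllCpG:
    def test_single_column_q_equals_p(self):
        df = pd.DataFrame(
            {"Chr01.10": [10.0, 20, 30, 40, 50, 60]},
            index=list("ABCDEF"),
        )
        res = per_cpg_tests(MethylomeMatrix(df), ["A", "B", "C"], ["D", "E", "F"])
        assert res["q"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_overlapping_groups_rejected(self, null_study):
        mat = ml.impute_missing(null_study.matrix)
        ids = null_study.sample_ids
        with pytest.raises(GroupError, match="overlap"):
            per_cpg_tests(mat, ids[:4], ids[3:8])

    def test_type_one_calibration_at_05(self, null_study):
        mat = ml.impute_missing(null_study.matrix)
        ids = null_study.sample_ids
        res = per_cpg_tests(mat, ids[:10], ids[10:20])
        frac = (res["p"].dropna() < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_planted_cpg_beat_null_q(self, tiny_study):
        mat = ml.impute_missing(tiny_study.matrix)
        md = tiny_study.metadata.set_index("sample_id")
        res = per_cpg_tests(
            mat,
            md.index[md["tissue"] == "X"].tolist(),
            md.index[md["tissue"] == "L"].tolist(),
        )
        res = res.set_index("position_id")
        planted = tiny_study.truth["tissue"]
        null_pids = res.index.difference(
            sum(tiny_study.truth.values(), [])
        )
        assert res.loc[planted, "q"].max() < res.loc[null_pids, "q"].median()


class TestSelection:
    @pytest.fixture(scope="class")
    def results(self, tiny_study):
        mat = ml.impute_missing(tiny_study.matrix)
        md = tiny_study.metadata.set_index("sample_id")
        return per_cpg_tests(
            mat,
            md.index[md["tissue"] == "X"].tolist(),
            md.index[md["tissue"] == "L"].tolist(),
        )

    def test_vacuous_fdr_keeps_all_significant(self, results):
        sel = select_by_significance(results, alpha=0.01, fdr_cutoff=1.0)
        assert len(sel) == int((results["p"] <= 0.01).sum())

    def test_zero_cutoff_warns_empty(self, results):
        with pytest.warns(UserWarning, match="empty"):
            sel = select_by_significance(results, alpha=0.01, fdr_cutoff=0.0)
        assert len(sel) == 0

    def test_tightening_cutoff_monotone(self, results):
        sizes = [
            len(select_by_significance(results, 0.01, c))
            for c in (1e-1, 1e-2, 1e-3, 1e-4)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_select_to_count_hits_target(self, results):
        sel = select_to_count(results, target=30, tolerance=10)
        assert 20 <= len(sel) <= 40
        assert "fdr_cutoff" in sel.selection_params

    def test_select_all_with_zero_tolerance(self, results):
        n = int((results["p"] <= 0.01).sum())
        sel = select_to_count(results, target=n, tolerance=0)
        assert len(sel) == n

    def test_infeasible_target_errors(self, results):
        with pytest.raises(SelectionError):
            select_to_count(results, target=10**6, tolerance=0)

    def test_ordered_by_q_then_p(self, results):
        sel = select_to_count(results, target=30, tolerance=10)
        stats = results.set_index("position_id").loc[sel.position_ids]
        q = stats["q"].to_numpy()
        assert (np.diff(q) >= 0).all()


class TestDichotomize:
    def test_forced_split(self):
        high, low = dichotomize_at_mean(pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert set(high) == {"c", "d"} and set(low) == {"a", "b"}

    def test_value_at_mean_goes_low(self):
        high, low = dichotomize_at_mean(
            pd.Series([1, 2, 3, 2], index=list("abcd"))
        )
        assert "b" not in high and "d" not in high

    def test_constant_trait_rejected(self):
        with pytest.raises(GroupError):
            dichotomize_at_mean(pd.Series([5.0, 5, 5, 5]))


class TestPoolAndRandom:
    def _sel(self, pids):
        return ml.CpGSelection(position_ids=pids, origin="differential")

    def test_disjoint_pool_sums(self):
        a = self._sel([f"Chr01.{i}" for i in range(500)])
        b = self._sel([f"Chr02.{i}" for i in range(100)])
        pooled = pooled_selection([a, b], [500, 100])
        assert len(pooled) == 600 and pooled.origin == "pooled"

    def test_overlap_deduplicated_first_kept(self):
        a = self._sel(["Chr01.1", "Chr01.2"])
        b = self._sel(["Chr01.2", "Chr01.3"])
        pooled = pooled_selection([a, b], [2, 2])
        assert pooled.position_ids == ["Chr01.1", "Chr01.2", "Chr01.3"]

    def test_count_exceeding_size_errors(self):
        with pytest.raises(SelectionError):
            pooled_selection([self._sel(["Chr01.1"])], [5])

    def test_random_selection_deterministic(self):
        uni = [f"Chr01.{i}" for i in range(1000)]
        s1 = random_selection(uni, 14, seed=3)
        s2 = random_selection(uni, 14, seed=3)
        assert s1.position_ids == s2.position_ids
        assert random_selection(uni, 14, seed=4).position_ids != s1.position_ids

    def test_random_full_universe_is_permutation(self):
        uni = [f"Chr01.{i}" for i in range(20)]
        sel = random_selection(uni, 20, seed=0)
        assert sorted(sel.position_ids, key=lambda s: int(s.split(".")[1])) == uni

    def test_random_small_overlap_across_seeds(self):
        uni = [f"Chr01.{i}" for i in range(10_000)]
        sels = [set(random_selection(uni, 14, seed=s).position_ids) for s in range(3)]
        for i in range(3):
            for j in range(i + 1, 3):
                assert len(sels[i] & sels[j]) <= 2
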