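import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import comb, gammaln

from dbsi import (
    bonferroni_alpha,
    compare_groups,
    fisher_exact,
    make_cohort,
    table1_fixture,
    time_to_diagnosis,
    welch_t,
    wilcoxon_signed_rank,
)
from dbsi.synthetic import CohortSpec


# ---------- independent oracles ----------

def t_sf_by_integration(t, df):
    """P(T > t) from numerical integration of the t density."""

    def pdf(x):
        logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
        return np.exp(logc - (df + 1) / 2 * np.log1p(x * x / df))

    val, _ = quad(pdf, t, np.inf)
    return val


def wilcoxon_exact_enumeration(diffs):
    """Two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    cdf = np.mean(ws <= w_obs)
    sf = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(cdf, sf))


def fisher_exact_enumeration(tab):
    """Two-sided p: sum hypergeometric probabilities <= observed."""
    a, b = tab[0]
    c, d = tab[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return comb(r1, k, exact=True) * comb(r2, c1 - k, exact=True) / comb(n, c1, exact=True)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


# ---------- tests ----------

class TestWelch:
    def test_hand_computed_example(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_identical_groups(self):
        t, df, p = welch_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_antisymmetry(self):
        t1, _, p1 = welch_t([1.0, 2, 4], [3.0, 5, 9])
        t2, _, p2 = welch_t([3.0, 5, 9], [1.0, 2, 4])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_p_matches_t_density_integration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(2, 8))
        b = rng.normal(rng.uniform(-1, 1), 1.5, rng.integers(2, 8))
        t, df, p = welch_t(a, b)
        expected = 2 * t_sf_by_integration(abs(t), df)
        assert p == pytest.approx(expected, abs=1e-6)


class TestWilcoxon:
    def test_enumeration_example(self):
        w, p, nz = wilcoxon_signed_rank([1.0, 2, 3, 4], [0.0, 0, 0, 0])
        assert p == pytest.approx(0.125)
        assert nz == 0

    def test_all_zero_differences_degenerate(self):
        x = [1.0, 2.0, 3.0]
        w, p, nz = wilcoxon_signed_rank(x, x)
        assert p == 1.0 and nz == 3

    def test_sign_flip_preserves_p(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 1, 8)
        _, p1, _ = wilcoxon_signed_rank(d, np.zeros(8))
        _, p2, _ = wilcoxon_signed_rank(-d, np.zeros(8))
        assert p1 == pytest.approx(p2)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 10))
    def test_exact_path_matches_full_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.2, 1.0, n)
        _, p, _ = wilcoxon_signed_rank(d, np.zeros(n), exact=True)
        assert p == pytest.approx(wilcoxon_exact_enumeration(d), abs=1e-10)

    def test_zero_differences_dropped_and_counted(self):
        before = [1.0, 2.0, 3.0, 4.0, 5.0]
        after = [1.0, 1.5, 3.0, 3.0, 4.0]
        _, p, nz = wilcoxon_signed_rank(before, after)
        assert nz == 2
        _, p_ref, _ = wilcoxon_signed_rank([2.0, 4.0, 5.0], [1.5, 3.0, 4.0])
        assert p == pytest.approx(p_ref)


class TestFisher:
    def test_symmetric_table(self):
        assert fisher_exact([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert fisher_exact([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_transpose_invariance(self):
        tab = [[4, 1], [2, 5]]
        assert fisher_exact(tab) == pytest.approx(fisher_exact(np.transpose(tab)))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        a=st.integers(0, 8), b=st.integers(0, 8),
        c=st.integers(0, 8), d=st.integers(0, 8),
    )
    def test_matches_hypergeometric_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        tab = [[a, b], [c, d]]
        assert fisher_exact(tab) == pytest.approx(fisher_exact_enumeration(tab), abs=1e-9)


class TestBonferroni:
    def test_published_threshold(self):
        assert bonferroni_alpha(0.05, 9) == pytest.approx(0.0056, abs=5e-5)

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestCompareGroups:
    def degenerate_cohort(self):
        means = {m: ((0.5, 0.0), (0.5, 0.0)) for m in
                 ("restricted", "nonrestricted", "fiber", "adc", "fa",
                  "t1w_gd", "t2w", "flair")}
        means["hindered"] = ((0.17, 0.0), (0.08, 0.0))
        return make_cohort(CohortSpec(group_means=means, seed=0))[1]

    def test_only_separated_metric_is_flagged(self):
        met = self.degenerate_cohort()
        # zero-sd identical-mean metrics are dropped (Welch undefined);
        # jitter them to make variance positive without group difference
        rng = np.random.default_rng(0)
        for c in met.columns:
            if c not in ("Subject", "Diagnosis", "hindered"):
                met[c] = met[c] + rng.normal(0, 1e-3, len(met))
        met["hindered"] += rng.normal(0, 1e-6, len(met))
        res = compare_groups(met)
        assert res.adjusted_alpha == pytest.approx(0.05 / 9)
        assert bool(res.table.loc["hindered", "significant"])
        others = res.table.drop(index="hindered")
        assert not others["significant"].any()

    def test_row_permutation_invariance(self):
        _, met = make_cohort(CohortSpec(seed=3))
        res1 = compare_groups(met)
        shuffled = met.sample(frac=1.0, random_state=7).reset_index(drop=True)
        res2 = compare_groups(shuffled)
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_small_group_is_error(self):
        _, met = make_cohort(CohortSpec(n_treatment_effect=1, n_progression=5, seed=0))
        with pytest.raises(ValueError):
            compare_groups(met)


class TestTimeToDiagnosis:
    def test_published_table_summary(self):
        s = time_to_diagnosis(table1_fixture())
        assert s.n_analyzed == 9
        assert s.n_earlier == 6
        assert s.fraction_earlier == pytest.approx(2 / 3)
        assert s.median == pytest.approx(7.7)
        assert s.iqr == pytest.approx((0.0, 20.1))

    def test_progression_subgroup(self):
        s = time_to_diagnosis(table1_fixture())
        g = s.by_group["progression"]
        assert g["n"] == 5
        assert g["median"] == pytest.approx(7.7)
        assert g["iqr"] == pytest.approx((0.0, 15.0))

    def test_all_zero_differences(self):
        rec = pd.DataFrame(
            dict(Subject=["a", "b"], Diagnosis=["progression", "progression"],
                 SurgeryToDBSI_weeks=[10.0, 12.0], SurgeryToSOC_weeks=[10.0, 12.0])
        )
        s = time_to_diagnosis(rec)
        assert s.median == 0.0 and s.iqr == (0.0, 0.0) and s.n_earlier == 0

    def test_no_analyzed_records_is_error(self):
        rec = table1_fixture()
        rec = rec[rec["Diagnosis"] == "stable"]
        with pytest.raises(ValueError):
            time_to_diagnosis(rec)
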