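"""Agreement statistics: Bland-Altman, ICC(A,1), repeated-measures
correlation, and the distributional gates.

Independent oracles: hand-computed ANOVA tables for tiny examples, the
pingouin package for ICC and rm-correlation on random data, and values
frozen from R's stats package for the Shapiro-Wilk / F-test / paired-t
reference vectors.
"""

import numpy as np
import pandas as pd
import pytest

from igradient.agreement import (
    PairedObservations,
    bland_altman,
    icc_absolute_single,
    paired_t,
    r_squared_rm,
    rm_corr,
    shapiro_wilk,
    variance_f_test,
)


def pairs_of(subject, x, y):
    return PairedObservations(np.asarray(subject), np.asarray(x, float),
                              np.asarray(y, float))


class TestBlandAltman:
    def test_constant_difference_collapses_loa(self):
        p = pairs_of([1, 1, 2, 2], [1, 2, 3, 4], [4, 5, 6, 7])
        res = bland_altman(p)
        assert res.bias == 3.0
        assert res.loa_lower == res.loa_upper == 3.0

    def test_single_subject_classic_by_hand(self):
        p = pairs_of([1, 1, 1], [0, 0, 0], [-1, 0, 1])
        res = bland_altman(p)
        assert res.method == "classic"
        assert res.bias == 0.0
        assert res.sd_total == pytest.approx(1.0)
        assert res.loa_lower == pytest.approx(-1.96)
        assert res.loa_upper == pytest.approx(1.96)

    def test_two_subject_variance_components_by_hand(self):
        # d = {0, 0} and {2, 2}: within-subject MS = 0; between-subject
        # MS = 4 with n0 = 2, so sigma2_between = 2 and sd_total = sqrt(2)
        p = pairs_of([1, 1, 2, 2], [0, 0, 0, 0], [0, 0, 2, 2])
        res = bland_altman(p)
        assert res.method == "repeated-measures"
        assert res.bias == 1.0
        assert res.var_within == 0.0
        assert res.var_between == pytest.approx(2.0, abs=1e-12)
        assert res.sd_total == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_one_pair_per_subject_equals_classic(self, rng):
        x = rng.normal(0, 5, 12)
        y = x + rng.normal(1, 2, 12)
        p = pairs_of(np.arange(12), x, y)
        res = bland_altman(p)
        d = y - x
        assert res.bias == pytest.approx(d.mean())
        assert res.sd_total == pytest.approx(d.std(ddof=1), abs=1e-12)

    def test_loa_symmetry(self, rng):
        subj = np.repeat(np.arange(6), 4)
        x = rng.normal(0, 3, 24)
        y = x + rng.normal(0.5, 1, 24) + np.repeat(rng.normal(0, 1, 6), 4)
        res = bland_altman(pairs_of(subj, x, y))
        assert (res.loa_upper - res.bias) == pytest.approx(res.bias - res.loa_lower, abs=1e-12)

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            bland_altman(pairs_of([1, 1], [0, 1], [1, 2]))

    def test_ci_brackets_estimates(self, rng):
        subj = np.repeat(np.arange(8), 3)
        x = rng.normal(0, 2, 24)
        y = x + rng.normal(1, 1, 24)
        res = bland_altman(pairs_of(subj, x, y), ci=True)
        assert res.bias_ci[0] < res.bias < res.bias_ci[1]
        assert res.loa_lower_ci[0] < res.loa_lower < res.loa_lower_ci[1]
        assert res.loa_upper_ci[0] < res.loa_upper < res.loa_upper_ci[1]


class TestIcc:
    def test_perfect_agreement_is_one(self):
        p = pairs_of([1, 2, 3], [1, 2, 3], [1, 2, 3])
        for model in ("two-way random", "two-way mixed"):
            res = icc_absolute_single(p, model=model)
            assert res.icc == 1.0
            assert res.ci_upper == 1.0

    def test_offset_table_by_hand(self):
        # x = 1..4, y = x + 10: MSR = 10/3, MSC = 200, MSE = 0, so
        # ICC(A,1) = (10/3) / (10/3 + (2/4) * 200) = 10/310
        p = pairs_of([1, 2, 3, 4], [1, 2, 3, 4], [11, 12, 13, 14])
        res = icc_absolute_single(p)
        assert res.icc == pytest.approx(10 / 310, abs=1e-10)
        assert res.ms["MSR"] == pytest.approx(10 / 3, abs=1e-10)
        assert res.ms["MSC"] == pytest.approx(200.0, abs=1e-10)
        assert res.ms["MSE"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_pingouin_on_random_data(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(5):
            n = int(rng.integers(5, 15))
            x = rng.normal(0, 2, n)
            y = x + rng.normal(0.3, 0.8, n)
            res = icc_absolute_single(pairs_of(np.arange(n), x, y))
            df = pd.DataFrame({
                "targets": np.tile(np.arange(n), 2),
                "raters": np.repeat(["a", "b"], n),
                "ratings": np.concatenate([x, y]),
            })
            tab = pg.intraclass_corr(df, "targets", "raters", "ratings")
            ref = tab.loc[tab["Type"] == "ICC2"].iloc[0] if (tab["Type"] == "ICC2").any() \
                else tab.loc[tab["Type"] == "ICC(A,1)"].iloc[0]
            assert res.icc == pytest.approx(float(ref["ICC"]), abs=1e-8)
            lo, hi = ref["CI95"] if "CI95" in ref else ref["CI95%"]
            assert res.ci_lower == pytest.approx(float(lo), abs=5e-3)
            assert res.ci_upper == pytest.approx(float(hi), abs=5e-3)

    def test_repeated_pairs_rejected(self):
        p = pairs_of([1, 1, 2], [0, 1, 2], [0, 1, 2])
        with pytest.raises(ValueError, match="exactly one"):
            icc_absolute_single(p)


class TestRmCorr:
    def test_perfect_positive_within_subjects(self):
        subj = np.repeat([1, 2, 3], 4)
        x = np.tile(np.arange(4.0), 3)
        y = 2 * x + np.repeat([0.0, 10.0, -5.0], 4)
        res = rm_corr(pairs_of(subj, x, y))
        assert res.r_rm == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative(self):
        subj = np.repeat([1, 2], 3)
        x = np.tile([0.0, 1.0, 2.0], 2)
        y = -x + np.repeat([3.0, 8.0], 3)
        assert rm_corr(pairs_of(subj, x, y)).r_rm == pytest.approx(-1.0)

    def test_explicit_ancova_bookkeeping_oracle(self):
        # small two-subject dataset checked against the ANCOVA sums of
        # squares computed with an independent dummy-variable regression
        sm = pytest.importorskip("statsmodels.api")
        subj = np.array([1, 1, 1, 2, 2, 2])
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        y = np.array([0.0, 2.5, 3.0, 5.0, 7.0, 7.5])
        res = rm_corr(pairs_of(subj, x, y))
        X = np.column_stack([np.ones(6), subj == 2, x])
        fit = sm.OLS(y, X).fit()
        t_x = fit.tvalues[2]
        df = 6 - 2 - 1
        r_ref = np.sign(fit.params[2]) * np.sqrt(t_x**2 / (t_x**2 + df))
        assert res.r_rm == pytest.approx(r_ref, abs=1e-10)
        assert res.df == df

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        subj = np.repeat(np.arange(6), 5)
        x = rng.normal(0, 1, 30) + np.repeat(rng.normal(0, 3, 6), 5)
        y = 0.7 * x + rng.normal(0, 1, 30) + np.repeat(rng.normal(0, 3, 6), 5)
        res = rm_corr(pairs_of(subj, x, y))
        ref = pg.rm_corr(pd.DataFrame({"s": subj, "x": x, "y": y}), "x", "y", "s")
        assert res.r_rm == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.df == int(ref["dof"].iloc[0])
        assert res.p_value == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_invariant_to_per_subject_shifts(self, rng):
        subj = np.repeat(np.arange(4), 6)
        x = rng.normal(0, 1, 24)
        y = x + rng.normal(0, 0.5, 24)
        base = rm_corr(pairs_of(subj, x, y)).r_rm
        shifted = rm_corr(pairs_of(subj, x + np.repeat([5, -3, 0, 9], 6),
                                   y + np.repeat([-2, 4, 1, 0], 6))).r_rm
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_singleton_subjects_dropped_with_record(self):
        subj = np.array([1, 1, 1, 2, 2, 2, 3])
        x = np.array([0.0, 1, 2, 0, 1, 2, 5])
        y = np.array([0.0, 1, 2, 1, 2, 3, 9])
        res = rm_corr(pairs_of(subj, x, y))
        assert res.dropped_subjects == [3]
        assert res.n_subjects_used == 2

    def test_too_few_usable_subjects_errors(self):
        with pytest.raises(ValueError):
            rm_corr(pairs_of([1, 1, 2], [0, 1, 0], [0, 1, 0]))

    def test_r_squared_is_square(self, rng):
        subj = np.repeat(np.arange(4), 4)
        x = rng.normal(0, 1, 16)
        y = x + rng.normal(0, 1, 16)
        p = pairs_of(subj, x, y)
        assert r_squared_rm(p) == pytest.approx(rm_corr(p).r_rm ** 2)


class TestGates:
    # reference vectors with values frozen from R's stats package
    A = np.array([1.2, 2.3, 1.8, 2.9, 3.1, 2.0, 1.5])
    B = np.array([0.8, 1.1, 0.9, 1.4, 1.2, 1.0, 1.3])

    def test_paired_t_identical_vectors(self):
        p = pairs_of([1, 2, 3], [1.0, 2, 3], [1.0, 2, 3])
        res = paired_t(p)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_paired_t_zero_variance_flagged(self):
        p = pairs_of([1, 2, 3, 4], [0.0, 0, 0, 0], [1.0, 1, 1, 1])
        res = paired_t(p)
        assert np.isinf(res["t"]) and res["p"] == 0.0 and res["zero_variance"]

    def test_paired_t_matches_r(self):
        res = paired_t(pairs_of(np.arange(7), self.B, self.A))
        assert res["t"] == pytest.approx(4.5267946627, abs=1e-9)
        assert res["p"] == pytest.approx(0.0039886960, abs=1e-9)

    def test_shapiro_matches_r(self):
        v = [14.2, 15.1, 13.8, 16.0, 15.5, 14.9]
        res = shapiro_wilk(v)
        assert res["W"] == pytest.approx(0.9762065538, abs=1e-6)
        assert res["p"] == pytest.approx(0.9312230546, abs=1e-6)

    def test_f_test_matches_r(self):
        res = variance_f_test(self.A, self.B)
        assert res["F"] == pytest.approx(10.5306122449, abs=1e-9)
        assert res["p"] == pytest.approx(0.0114076218, abs=1e-9)

    def test_f_test_symmetric_p(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 3, 12)
        assert variance_f_test(a, b)["p"] == pytest.approx(variance_f_test(b, a)["p"])

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            variance_f_test([1.0, 2.0], [1.0, 2.0, 3.0])
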