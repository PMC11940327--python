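"""Cohort statistics: normality gate, exact tests, oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chemoreflex import (
    InsufficientDataError,
    ValidationError,
    delta_correlation,
    ks_normality,
    literature_compare,
    summary_table,
    wilcoxon_exact,
    within_subject_compare,
)
from chemoreflex.stats import holm_adjust


def wilcoxon_enum_oracle(diffs):
    """Brute-force two-sided p: all 2^n sign assignments of |d| ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws, dtype=float)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def spearman_enum_oracle(a, b):
    """Brute-force permutation p for |rho| via rank-Pearson."""
    ra, rb = sps.rankdata(a), sps.rankdata(b)

    def rho(x, y):
        x = x - x.mean()
        y = y - y.mean()
        return (x * y).sum() / math.sqrt((x**2).sum() * (y**2).sum())

    obs = abs(rho(ra, rb))
    hits = total = 0
    for perm in itertools.permutations(rb):
        total += 1
        if abs(rho(ra, np.asarray(perm))) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestKsNormality:
    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            ks_normality([1.0, 2.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_normality([3.0] * 10)

    def test_level_on_normal_data(self):
        rng = np.random.default_rng(17)
        hits = sum(ks_normality(rng.standard_normal(100)) > 0.05 for _ in range(100))
        assert hits >= 90

    def test_power_on_exponential_data(self):
        rng = np.random.default_rng(18)
        hits = sum(
            ks_normality(rng.exponential(size=100)) < 0.05 for _ in range(100)
        )
        assert hits >= 90


class TestWilcoxonExact:
    @pytest.mark.parametrize("n", range(4, 11))
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for trial in range(5):
            d = np.round(rng.normal(0.5, 1.0, size=n), 1)  # rounding makes ties
            if np.all(d == 0):
                continue
            _, p = wilcoxon_exact(d)
            assert p == pytest.approx(wilcoxon_enum_oracle(d), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.3, 1.0, size=12)  # continuous: no ties, no zeros
        w, p = wilcoxon_exact(d)
        ref = sps.wilcoxon(d, method="exact")
        # scipy reports min(W+, W-); the two statistics are complementary
        assert min(w, len(d) * (len(d) + 1) / 2 - w) == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_spec_fixture(self):
        _, p = wilcoxon_exact([1.0, 2.0, -1.0, 3.0, 4.0, 5.0])
        assert p == pytest.approx(wilcoxon_enum_oracle([1, 2, -1, 3, 4, 5]), abs=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_exact([0.0, 0.0, 0.0])


def _long_table(pre, post, variable="HVR"):
    rows = []
    for i, (a, b) in enumerate(zip(pre, post)):
        rows.append((f"S{i}", "pre", variable, a))
        rows.append((f"S{i}", "post", variable, b))
    return pd.DataFrame(rows, columns=["subject", "visit", "variable", "value"])


class TestWithinSubjectCompare:
    def test_identical_visits_degenerate_p1(self):
        table = _long_table([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        res = within_subject_compare(table, "HVR")
        assert res.p == 1.0
        assert res.test == "degenerate"

    def test_paired_t_hand_computation(self):
        pre = [1.0, 2.0, 3.0, 4.0, 5.0]
        post = [2.0, 4.0, 5.0, 7.0, 9.0]
        res = within_subject_compare(_long_table(pre, post), "HVR", force_test="t")
        d = np.array(post) - np.array(pre)
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.test == "paired t"
        assert res.statistic == pytest.approx(t_expected)
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_expected), df=4))

    def test_wilcoxon_branch_matches_oracle(self):
        pre = [0.0] * 6
        post = [1.0, 2.0, -1.0, 3.0, 4.0, 5.0]
        res = within_subject_compare(
            _long_table(pre, post), "HVR", force_test="wilcoxon"
        )
        assert res.test == "wilcoxon"
        assert res.p == pytest.approx(wilcoxon_enum_oracle(post), abs=1e-12)

    def test_gate_is_logged(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(10, 1, 20)
        post = pre + rng.normal(0.5, 1, 20)
        res = within_subject_compare(_long_table(pre, post), "HVR")
        assert np.isfinite(res.normality_p)
        assert res.test in ("paired t", "wilcoxon")

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            within_subject_compare(_long_table([1.0, 2.0], [2.0, 1.0]), "HVR")


class TestDeltaCorrelation:
    @staticmethod
    def _two_var_table(da, db):
        rows = []
        for i, (x, y) in enumerate(zip(da, db)):
            rows += [
                (f"S{i}", "pre", "A", 0.0),
                (f"S{i}", "post", "A", x),
                (f"S{i}", "pre", "B", 0.0),
                (f"S{i}", "post", "B", y),
            ]
        return pd.DataFrame(rows, columns=["subject", "visit", "variable", "value"])

    def test_perfect_monotone(self):
        rho, p, n = delta_correlation(
            self._two_var_table([1, 2, 3, 4, 5], [2, 4, 8, 16, 32]), "A", "B"
        )
        assert rho == pytest.approx(1.0)
        assert n == 5

    def test_perfect_reversal(self):
        rho, _, _ = delta_correlation(
            self._two_var_table([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]), "A", "B"
        )
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_oracle_with_tie(self):
        da = [1.0, 2.0, 2.0, 4.0, 5.0, 6.0]  # one tie
        db = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        rho, p, n = delta_correlation(self._two_var_table(da, db), "A", "B")
        assert n == 6
        assert p == pytest.approx(spearman_enum_oracle(da, db), abs=1e-12)
        assert rho == pytest.approx(sps.spearmanr(da, db).statistic)

    @pytest.mark.parametrize("n", [5, 7])
    def test_exact_p_random_fixtures(self, n):
        rng = np.random.default_rng(n)
        da, db = rng.normal(size=n), rng.normal(size=n)
        _, p, _ = delta_correlation(self._two_var_table(da, db), "A", "B")
        assert p == pytest.approx(spearman_enum_oracle(da, db), abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(9)
        da, db = rng.normal(size=15), rng.normal(size=15)
        rho, p, n = delta_correlation(self._two_var_table(da, db), "A", "B")
        ref = sps.spearmanr(da, db)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_delta_rejected(self):
        with pytest.raises(ValidationError):
            delta_correlation(
                self._two_var_table([1.0] * 5, [1, 2, 3, 4, 5]), "A", "B"
            )


class TestLiteratureCompare:
    def test_equal_groups_null(self):
        sample = [9.0, 10.0, 11.0]
        t, df, p = literature_compare(sample, 10.0, 1.0, 3)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_welch(self):
        x = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1])
        m2, s2, n2 = 21.0, 4.0, 10
        t, df, p = literature_compare(x, m2, s2, n2)
        v1 = x.var(ddof=1) / len(x)
        v2 = s2**2 / n2
        t_hand = (x.mean() - m2) / math.sqrt(v1 + v2)
        df_hand = (v1 + v2) ** 2 / (v1**2 / 7 + v2**2 / 9)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), df_hand), rel=1e-9)

    def test_zero_reference_sd_rejected(self):
        with pytest.raises(ValidationError):
            literature_compare([1.0, 2.0, 3.0], 2.0, 0.0, 5)


class TestSummaryTable:
    def test_gate_selects_presentation(self):
        rng = np.random.default_rng(12)
        n = 40
        normal_pre = rng.normal(50, 5, n)
        skew_pre = rng.lognormal(1.0, 1.0, n)
        rows = []
        for i in range(n):
            rows += [
                (f"S{i}", "pre", "LVEF", normal_pre[i]),
                (f"S{i}", "post", "LVEF", normal_pre[i] + rng.normal(2, 2)),
                (f"S{i}", "pre", "NTproBNP", skew_pre[i]),
                (f"S{i}", "post", "NTproBNP", skew_pre[i] * rng.lognormal(0, 0.5)),
            ]
        table = pd.DataFrame(rows, columns=["subject", "visit", "variable", "value"])
        report = summary_table(table)
        lvef = report[report["variable"] == "LVEF"].iloc[0]
        bnp = report[report["variable"] == "NTproBNP"].iloc[0]
        assert "±" in lvef["pre"]
        assert "[" in bnp["pre"]
        assert lvef["n"] == n and bnp["n"] == n

    def test_holm_adjustment_flag(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])
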