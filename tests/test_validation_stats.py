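"""QC filter, chi-square, rank tests, logistic regression, ROC analysis."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transnp.io_core import DataError, GenotypeMatrix
from transnp.validation_stats import (
    apply_qc,
    chi2_yates,
    compare_platforms,
    logistic_fit,
    mann_whitney_mc,
    roc_analysis,
    wilcoxon_signed_rank,
    yates_chi2,
)

from oracles import auc_pair_counting, chi2_yates_cellwise, logistic_grid_fit


class TestApplyQC:
    def _matrix(self, calls: dict) -> GenotypeMatrix:
        return GenotypeMatrix(pd.DataFrame(calls, index=["l1", "l2", "l3", "l4", "l5"]))

    def test_sample_below_call_rate_removed(self):
        gm = self._matrix(
            {
                "good": ["AA", "AB", "BB", "AA", "AB"],
                "bad": ["AA", None, None, "AA", "AB"],  # 60% < 80%
            }
        )
        out = apply_qc(gm)
        assert list(out.samples) == ["good"]

    def test_all_complete_samples_identity(self):
        gm = self._matrix({"s1": ["AA"] * 5, "s2": ["AB"] * 5})
        out = apply_qc(gm)
        pd.testing.assert_frame_equal(out.calls, gm.calls)

    def test_all_samples_removed_is_error(self):
        gm = self._matrix({"s1": ["AA", None, None, None, None]})
        with pytest.raises(DataError):
            apply_qc(gm)

    def test_random_missingness_matches_brute_force(self, rng):
        for _ in range(10):
            calls = pd.DataFrame(
                np.where(rng.random((8, 6)) < 0.3, None, "AA"),
                index=[f"l{i}" for i in range(8)],
                columns=[f"s{j}" for j in range(6)],
            )
            gm = GenotypeMatrix(calls)
            expected = [
                s for s in calls.columns if calls[s].notna().mean() >= 0.8
            ]
            if not expected:
                continue
            assert list(apply_qc(gm).samples) == expected


class TestChi2Yates:
    def test_polymorphism_rate_table(self):
        stat, p = chi2_yates((259, 150, 200, 96))
        assert round(stat, 2) == 1.18
        assert p == pytest.approx(0.272, abs=0.006)

    def test_conversion_rate_table_floors_to_zero(self):
        stat, p = chi2_yates((409, 535, 296, 388))
        assert stat == 0.0
        assert p == 1.0

    def test_identical_rows_give_zero(self):
        for k in (1, 5, 20):
            assert chi2_yates((k, k, k, k))[0] == 0.0

    def test_zero_marginal_warns_and_returns_null(self):
        stat, p = chi2_yates((0, 0, 5, 7))
        assert (stat, p) == (0.0, 1.0)

    def test_exhaustive_against_cellwise_formula_entries_up_to_30(self):
        """Cross-product formula == expected-count formula on every table."""
        grid = np.arange(31)
        a, b, c, d = np.meshgrid(grid, grid, grid, grid, indexing="ij")
        a, b, c, d = (x.ravel() for x in (a, b, c, d))
        keep = (a + b > 0) & (c + d > 0) & (a + c > 0) & (b + d > 0)
        a, b, c, d = a[keep], b[keep], c[keep], d[keep]
        mine, _ = yates_chi2(a, b, c, d)
        oracle = chi2_yates_cellwise(a, b, c, d)
        np.testing.assert_allclose(mine, oracle, atol=1e-9)

    def test_spot_check_against_scipy(self, rng):
        for _ in range(200):
            t = rng.integers(1, 30, size=4)
            mine, mp = chi2_yates(tuple(int(x) for x in t))
            res = stats.chi2_contingency(t.reshape(2, 2), correction=True)
            assert mine == pytest.approx(res.statistic, abs=1e-10)
            assert mp == pytest.approx(res.pvalue, abs=1e-10)


class TestMannWhitney:
    def test_identical_samples_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = mann_whitney_mc(x, list(x), n_perm=20_000, seed=1)
        assert res.p > 0.9

    def test_separated_samples_match_exact_enumeration(self):
        x = [10.0, 11.0, 12.0, 13.0, 14.0]
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = mann_whitney_mc(x, y, n_perm=200_000, seed=7)
        # exact two-sided p by enumerating all C(10,5) label assignments
        pooled = np.array(x + y)
        ranks = stats.rankdata(pooled)
        mu = 12.5
        obs = abs(res.u - mu)
        count = 0
        total = 0
        for idx in combinations(range(10), 5):
            u = ranks[list(idx)].sum() - 15
            total += 1
            if abs(u - mu) >= obs - 1e-12:
                count += 1
        exact = count / total
        assert res.p == pytest.approx(exact, abs=0.002)
        assert res.p_ci[0] <= exact <= res.p_ci[1]

    def test_u_plus_u_prime_identity(self, rng):
        for _ in range(10):
            x = rng.normal(size=rng.integers(3, 12))
            y = rng.normal(size=rng.integers(3, 12))
            u_xy = mann_whitney_mc(x, y, n_perm=10, seed=0).u
            u_yx = mann_whitney_mc(y, x, n_perm=10, seed=0).u
            assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    def test_seeded_reproducibility(self):
        x, y = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        a = mann_whitney_mc(x, y, n_perm=50_000, seed=42)
        b = mann_whitney_mc(x, y, n_perm=50_000, seed=42)
        assert a.p == b.p


class TestWilcoxon:
    def test_equal_pairs_dropped_p_one(self):
        x = [1.0, 2.0, 3.0]
        assert wilcoxon_signed_rank(x, list(x)) == (0.0, 1.0)

    def test_six_positive_differences_forced_maximum(self):
        x = [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        v, _ = wilcoxon_signed_rank(x, y)
        assert v == 21.0  # 1+2+...+6

    def test_small_n_p_matches_sign_flip_enumeration(self, rng):
        for _ in range(5):
            d = rng.normal(size=8)
            d = d[d != 0]
            x = np.abs(d)
            y = x - d
            v, p = wilcoxon_signed_rank(x, y)
            ranks = stats.rankdata(np.abs(d))
            n = len(d)
            mu = n * (n + 1) / 4
            obs = abs(v - mu)
            count = 0
            for mask in range(2**n):
                vv = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
                if abs(vv - mu) >= obs - 1e-12:
                    count += 1
            assert p == pytest.approx(count / 2**n, abs=1e-9)


class TestLogisticFit:
    def test_constant_predictor_removed_first(self, rng):
        n = 200
        x1 = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 + 1.5 * x1)))).astype(int)
        X = pd.DataFrame({"x1": x1, "flat": np.ones(n)})
        model = logistic_fit(X, y, mode="backward_wald")
        assert "flat" in model.removed
        assert "x1" in model.terms.index

    def test_six_row_fit_matches_grid_likelihood_maximization(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = np.array([0, 0, 1, 0, 1, 1])
        model = logistic_fit(pd.DataFrame({"x": x}), y, mode="enter")
        b0, b1 = logistic_grid_fit(x, y)
        assert model.intercept == pytest.approx(b0, abs=1e-3)
        assert model.terms.loc["x", "B"] == pytest.approx(b1, abs=1e-3)

    def test_wald_is_squared_coefficient_over_se(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        model = logistic_fit(pd.DataFrame({"x": x}), y)
        row = model.terms.loc["x"]
        assert row["wald"] == pytest.approx((row["B"] / row["se"]) ** 2)

    def test_backward_recovers_planted_coefficient(self):
        """Backward elimination keeps the real predictor, drops the noise one,
        and recovers its effect size with small bias across replicates."""
        biases = []
        kept_noise = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            n = 2000
            x1 = rng.normal(size=n)
            x2 = rng.normal(size=n)
            eta = -1.0 + 1.5 * x1
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            model = logistic_fit(
                pd.DataFrame({"x1": x1, "x2": x2}), y, mode="backward_wald"
            )
            assert "x1" in model.terms.index
            biases.append(model.terms.loc["x1", "B"] - 1.5)
            if "x2" in model.terms.index:
                kept_noise += 1
        assert abs(np.mean(biases)) < 0.15
        # null predictor survives the 0.10 stay threshold only rarely
        assert kept_noise <= 10

    def test_enter_loglik_at_least_backward_loglik(self, rng):
        n = 300
        X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(4)})
        y = (rng.random(n) < 1 / (1 + np.exp(-X["x0"]))).astype(int)
        full = logistic_fit(X, y, mode="enter")
        reduced = logistic_fit(X, y, mode="backward_wald")
        assert full.llf >= reduced.llf - 1e-9

    def test_categorical_expanded_with_last_level_reference(self, rng):
        n = 300
        cat = rng.choice(["lo", "mid", "hi"], size=n)
        y = (rng.random(n) < np.where(cat == "lo", 0.8, 0.3)).astype(int)
        model = logistic_fit(
            pd.DataFrame({"grp": cat}), y, mode="enter", categorical=["grp"]
        )
        dummy_rows = [t for t in model.terms.index if t.startswith("grp(")]
        assert len(dummy_rows) == 2
        group_row = model.terms.loc["grp"]
        assert group_row["df"] == 2


class TestRoc:
    def test_perfect_separation_auc_one(self):
        res = roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_constant_scores_auc_half(self):
        res = roc_analysis([1.0] * 6, [0, 1, 0, 1, 0, 1])
        assert res.auc == 0.5

    def test_auc_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            scores = rng.integers(0, 8, size=20).astype(float)
            labels = rng.integers(0, 2, size=20)
            if labels.sum() in (0, 20):
                continue
            res = roc_analysis(scores, labels)
            assert res.auc == pytest.approx(auc_pair_counting(scores, labels))

    def test_auc_equals_scaled_u_statistic(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        res = roc_analysis(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert res.auc == pytest.approx(u / (len(pos) * len(neg)))

    def test_youden_cutoff_maximizes_j_prefers_smaller(self):
        scores = [0, 0, 1, 1, 2, 2, 3, 3]
        labels = [0, 0, 0, 1, 1, 1, 1, 1]
        res = roc_analysis(scores, labels)
        js = {}
        for cut in sorted(set(scores)):
            sens = np.mean([s > cut for s, l in zip(scores, labels) if l == 1])
            spec = np.mean([s <= cut for s, l in zip(scores, labels) if l == 0])
            js[cut] = sens + spec - 1
        best_j = max(js.values())
        assert js[res.optimal_cutoff] == pytest.approx(best_j)
        assert res.optimal_cutoff == min(c for c, j in js.items() if j == best_j)

    def test_single_class_is_error(self):
        with pytest.raises(DataError):
            roc_analysis([1.0, 2.0], [1, 1])

    def test_hanley_and_delong_se_same_scale(self, rng):
        scores = rng.normal(size=200) + np.repeat([0, 0.8], 100)
        labels = np.repeat([0, 1], 100)
        d = roc_analysis(scores, labels, se_method="delong")
        h = roc_analysis(scores, labels, se_method="hanley")
        assert d.auc == h.auc
        assert d.se_auc == pytest.approx(h.se_auc, rel=0.3)


class TestComparePlatforms:
    def _table(self, rng, n=60, depth_scale=1.0):
        return pd.DataFrame(
            {
                "contig_length": rng.normal(400, 60, size=n),
                "depth": rng.normal(30 * depth_scale, 5 * depth_scale, size=n),
                "snp_assay_conversion": rng.integers(0, 2, size=n),
                "snp_genotype": rng.integers(0, 2, size=n),
                "ie_code": rng.choice(["1", "0", "no"], size=n),
                "ie_species_match": rng.integers(0, 6, size=n),
                "geosites": rng.integers(1, 5, size=n),
                "snp_score": rng.uniform(0.4, 1.0, size=n),
                "msaf": rng.uniform(0.05, 0.5, size=n),
            }
        )

    def test_identical_tables_all_p_near_one(self, rng):
        t = self._table(rng)
        report = compare_platforms(t, t.copy())
        assert (report["p"] > 0.95).all()

    def test_report_row_count_equals_declared_variables(self, rng):
        report = compare_platforms(self._table(rng), self._table(rng))
        assert len(report) == 9

    def test_missing_variable_skipped(self, rng):
        a = self._table(rng).drop(columns=["msaf"])
        report = compare_platforms(a, self._table(rng))
        assert "msaf" not in set(report["variable"])
        assert len(report) == 8

    def test_planted_depth_difference_detected(self):
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = self._table(rng, depth_scale=1.0)
            b = self._table(rng, depth_scale=5.0)
            report = compare_platforms(a, b).set_index("variable")
            if report.loc["depth", "p"] < 0.001:
                detected += 1
        assert detected >= 19

    def test_paired_rows_added(self, rng):
        t = self._table(rng)
        report = compare_platforms(
            t, self._table(rng),
            paired={"msaf_vs_maf": (t["msaf"], t["msaf"] * 0.8)},
        )
        row = report[report["variable"] == "msaf_vs_maf"].iloc[0]
        assert row["test"] == "wilcoxon"
        assert row["p"] < 0.01
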