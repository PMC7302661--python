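"""Ranking: symmetry, quintile categories, agreement testing, recovery."""

import numpy as np
import pandas as pd
import pytest

from tmbench.benchmark import (
    BenchmarkError,
    BenchmarkReport,
    _rank_ascending,
    categorize,
    category_agreement,
    compare_rankings,
    rank_matched,
    rank_regression,
)
from tmbench.diagnostics import chi_square_independence
from tmbench.matching import MatchResult
from tmbench.risk import fit_risk_model
from tmbench.synthetic import GeneratorConfig, generate_system


def _fake_results(hospitals, rng, n=200, effect=None):
    """Hand-built matched samples sharing one set of template slots."""
    out = {}
    base_p = rng.uniform(0.02, 0.3, n)
    for i, h in enumerate(hospitals):
        eff = 0.0 if effect is None else effect[i]
        logit = np.log(base_p / (1 - base_p)) + eff
        p = 1 / (1 + np.exp(-logit))
        df = pd.DataFrame({
            "died_30d": (rng.random(n) < p).astype(int),
            "predicted_mortality": base_p,
        })
        out[h] = MatchResult(
            hospital_id=h, feasible=True,
            pairs=[(slot, f"{h}_{slot}") for slot in range(n)],
            matched_rows=df)
    return out


class TestRankMatched:
    def test_identical_data_gives_equal_estimates(self):
        rng = np.random.default_rng(0)
        results = _fake_results(["H1", "H2", "H3", "H4"], rng)
        df = results["H1"].matched_rows
        for r in results.values():
            r.matched_rows = df.copy()
        report = rank_matched(results)
        est = report.frame["estimate"]
        assert est.abs().max() < 1e-6
        assert sorted(report.frame["rank"]) == [1, 2, 3, 4]
        # ties broken by hospital id: ascending ids get ascending ranks
        assert list(report.frame.sort_values("rank").index) == ["H1", "H2", "H3", "H4"]

    def test_large_effect_separates_hospitals(self):
        rng = np.random.default_rng(1)
        wins = 0
        for _ in range(20):
            results = _fake_results(["A", "B"], rng, n=300, effect=[0.0, 1.5])
            report = rank_matched(results)
            wins += report.frame.loc["B", "rank"] == 2
        assert wins >= 18

    def test_infeasible_hospitals_excluded(self):
        rng = np.random.default_rng(2)
        results = _fake_results(["A", "B", "C"], rng)
        results["C"] = MatchResult(hospital_id="C", feasible=False,
                                   reason="fine_balance_infeasible")
        report = rank_matched(results)
        assert report.hospitals == ["A", "B"]
        assert report.metadata["excluded_infeasible"] == ["C"]

    def test_all_survivor_hospital_triggers_ridge(self):
        rng = np.random.default_rng(3)
        results = _fake_results(["A", "B", "C"], rng, n=80)
        results["B"].matched_rows["died_30d"] = 0
        report = rank_matched(results)
        assert report.metadata["ridge_fallback"]
        assert report.frame.loc["B", "rank"] == 1  # zero deaths = best

    def test_too_few_hospitals_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(BenchmarkError):
            rank_matched(_fake_results(["A"], rng))


class TestRankRegression:
    def test_null_quality_shrinks_to_zero(self):
        cfg = GeneratorConfig(n_hospitals=8, volume_range=(1500, 1500),
                              heterogeneity=0.3, quality_sd=0.0)
        cohort, _ = generate_system(cfg, 19)
        fit_risk_model(cohort)
        report = rank_regression(cohort)
        b = report.frame["estimate"].to_numpy()
        sd = report.frame["se"].to_numpy()
        assert np.all(np.abs(b) <= 3 * sd + 1e-12)

    def test_single_hospital_rejected(self):
        cfg = GeneratorConfig(n_hospitals=2, volume_range=(300, 300))
        cohort, _ = generate_system(cfg, 1)
        fit_risk_model(cohort)
        solo = cohort.copy()
        solo.df = solo.df[solo.df.hospital_id == "H001"]
        with pytest.raises(BenchmarkError):
            rank_regression(solo)

    def test_recovers_strong_quality_signal(self):
        cfg = GeneratorConfig(n_hospitals=10, volume_range=(2000, 2000),
                              heterogeneity=0.3, quality_sd=0.6)
        cohort, profiles = generate_system(cfg, 23)
        fit_risk_model(cohort)
        report = rank_regression(cohort)
        truth = [p.quality_effect for p in profiles]
        from scipy.stats import spearmanr

        rho = spearmanr(truth, report.frame.loc[
            [p.hospital_id for p in profiles], "rank"]).statistic
        assert rho > 0.7


class TestCategorize:
    def _report(self, H):
        frame = pd.DataFrame({
            "estimate": np.arange(H, dtype=float), "se": 1.0,
        }, index=pd.Index([f"H{i:03d}" for i in range(H)], name="hospital_id"))
        frame["rank"] = _rank_ascending(frame)
        frame["category"] = None
        return BenchmarkReport(frame=frame, method="test")

    def test_ten_hospitals_2_6_2(self):
        rep = categorize(self._report(10))
        counts = rep.frame["category"].value_counts()
        assert counts.to_dict() == {"median": 6, "top": 2, "bottom": 2}

    def test_117_hospitals_24_69_24(self):
        rep = categorize(self._report(117))
        counts = rep.frame["category"].value_counts()
        assert counts.to_dict() == {"median": 69, "top": 24, "bottom": 24}

    def test_input_order_invariance(self):
        rep1 = categorize(self._report(10))
        rep2 = self._report(10)
        rep2.frame = rep2.frame.sample(frac=1.0, random_state=7)
        rep2.frame["rank"] = _rank_ascending(rep2.frame)
        rep2 = categorize(rep2)
        merged = rep1.frame["category"].sort_index()
        assert merged.equals(rep2.frame["category"].sort_index())

    def test_fewer_than_five_rejected(self):
        with pytest.raises(BenchmarkError):
            categorize(self._report(4))

    def test_rank_invariant_to_constant_shift(self):
        rep = self._report(9)
        shifted = self._report(9)
        shifted.frame["estimate"] += 17.5
        shifted.frame["rank"] = _rank_ascending(shifted.frame)
        assert (rep.frame["rank"] == shifted.frame["rank"]).all()


class TestCompareRankings:
    def _categorized(self, H, perm=None, seed=0):
        rep = categorize(TestCategorize._report(self, H))
        if perm is not None:
            cats = rep.frame["category"].to_numpy()
            rep.frame["category"] = cats[perm]
        return rep

    def test_identical_reports_diagonal_table(self):
        a = self._categorized(20)
        b = self._categorized(20)
        table, stat, p = compare_rankings(a, b)
        assert np.trace(table.to_numpy()) == 20
        assert category_agreement(a, b) == 1.0
        assert p < 0.01

    def test_delegates_to_pearson_chi_square(self):
        rng = np.random.default_rng(5)
        a = self._categorized(30)
        b = self._categorized(30, perm=rng.permutation(30))
        table, stat, p = compare_rankings(a, b)
        ref = chi_square_independence(table.to_numpy())
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_null_rejection_rate_near_nominal(self):
        """Independently shuffled category labels with fixed margins:
        the chi-square agreement test rejects at ~5%."""
        rng = np.random.default_rng(6)
        H, reps = 100, 400
        rejections = 0
        a = self._categorized(H)
        for _ in range(reps):
            b = self._categorized(H, perm=rng.permutation(H))
            _, _, p = compare_rankings(a, b)
            rejections += p < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3.5 * se

    def test_disjoint_hospital_sets_rejected(self):
        a = self._categorized(10)
        b = self._categorized(12)
        with pytest.raises(BenchmarkError):
            compare_rankings(a, b)
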