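"""Cross-match test exactness and univariate balance statistics."""

import numpy as np
import pandas as pd
import pytest

from tmbench.diagnostics import (
    DiagnosticsError,
    balance_table,
    chi_square_independence,
    crossmatch_null_pmf,
    crossmatch_pvalue,
    crossmatch_test,
    kruskal_wallis,
)


def enumerate_pairings(n_items):
    """All perfect pairings of range(n_items), as lists of index pairs."""
    if n_items == 0:
        return [[]]
    items = list(range(n_items))
    first = items[0]
    out = []
    for j in range(1, n_items):
        rest = [x for x in items[1:] if x != items[j]]
        for sub in _enumerate_rest(rest):
            out.append([(first, items[j])] + sub)
    return out


def _enumerate_rest(items):
    if not items:
        return [[]]
    first = items[0]
    out = []
    for j in range(1, len(items)):
        rest = [x for x in items[1:] if x != items[j]]
        for sub in _enumerate_rest(rest):
            out.append([(first, items[j])] + sub)
    return out


def null_pmf_by_enumeration(n1, n2):
    counts = {}
    labels = [0] * n1 + [1] * n2
    for pairing in enumerate_pairings(n1 + n2):
        a1 = sum(1 for i, j in pairing if labels[i] != labels[j])
        counts[a1] = counts.get(a1, 0) + 1
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()}


class TestCrossmatchNull:
    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (4, 4), (5, 5), (6, 6),
                                       (2, 4), (3, 5)])
    def test_closed_form_matches_full_enumeration(self, n1, n2):
        exact = crossmatch_null_pmf(n1, n2)
        enum = null_pmf_by_enumeration(n1, n2)
        assert set(exact) == set(enum)
        for a in exact:
            assert exact[a] == pytest.approx(enum[a], abs=1e-12)
        assert sum(exact.values()) == pytest.approx(1.0)
        # parity: a1 has the parity of the group size difference constraint
        for a in exact:
            assert (n1 - a) % 2 == 0 and (n2 - a) % 2 == 0

    def test_matches_random_pairing_simulation(self):
        n = 4
        rng = np.random.default_rng(12)
        labels = np.array([0] * n + [1] * n)
        reps = 100_000
        draws = np.array([
            (labels[rng.permutation(2 * n).reshape(n, 2)].sum(axis=1) == 1).sum()
            for _ in range(reps)])
        pmf = crossmatch_null_pmf(n, n)
        for a, p in pmf.items():
            emp = (draws == a).mean()
            se = np.sqrt(p * (1 - p) / reps)
            assert abs(emp - p) < 3.5 * se

    def test_odd_total_rejected(self):
        with pytest.raises(DiagnosticsError):
            crossmatch_null_pmf(2, 3)


class TestCrossmatchTest:
    def _frames(self, t_points, h_points):
        t = pd.DataFrame(np.asarray(t_points, float), columns=["x", "y"])
        h = pd.DataFrame(np.asarray(h_points, float), columns=["x", "y"])
        return t, h

    def test_two_tight_clusters_give_minimum_p(self):
        # two template points together, two hospital points far away:
        # optimal pairing is within-group, a1 = 0, p = P(A1=0) = 1/3
        t, h = self._frames([[0, 0], [0.1, 0]], [[10, 10], [10.1, 10]])
        res = crossmatch_test(t, h, ["x", "y"], cov=np.eye(2))
        assert res.a1 == 0
        assert res.p_value == pytest.approx(1 / 3)  # smallest attainable at n=2

    def test_interleaved_groups_give_full_crossing(self):
        n = 4
        t, h = self._frames([[2 * i, 0] for i in range(n)],
                            [[2 * i + 0.001, 0] for i in range(n)])
        res = crossmatch_test(t, h, ["x", "y"], cov=np.eye(2))
        assert res.a1 == n
        assert res.p_value == pytest.approx(1.0)
        assert not res.poorly_matched

    def test_subsampling_caps_group_size(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x", "y"])
        h = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x", "y"])
        res = crossmatch_test(t, h, ["x", "y"], max_group=10, seed=1)
        assert res.n_pairs == 10

    def test_unequal_groups_rejected_when_odd(self):
        t = pd.DataFrame({"x": [0.0], "y": [0.0]})
        h = pd.DataFrame({"x": [1.0, 2.0], "y": [0.0, 0.0]})
        with pytest.raises(DiagnosticsError):
            crossmatch_test(t, h, ["x", "y"])


class TestKruskalWallis:
    def test_hand_computed_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(27 / 7)

    def test_identical_groups_high_p(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.pvalue > 0.9

    def test_all_constant_degenerate(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.status == "degenerate" and res.statistic is None

    def test_relabelling_symmetry(self):
        a = kruskal_wallis([[1, 5, 9], [2, 6, 7]])
        b = kruskal_wallis([[2, 6, 7], [1, 5, 9]])
        assert a.statistic == pytest.approx(b.statistic)

    def test_bad_groups_rejected(self):
        with pytest.raises(DiagnosticsError):
            kruskal_wallis([[1, 2]])


class TestChiSquare:
    def test_perfectly_independent_table(self):
        res = chi_square_independence([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_hand_formula_2x2(self):
        # Pearson statistic, no continuity correction:
        # n (ad - bc)^2 / (r1 r2 c1 c2) = 60 * 300^2 / 30^4
        res = chi_square_independence([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(60 * 300**2 / 30**4)
        assert res.statistic == pytest.approx(20 / 3)

    def test_doubling_counts_doubles_statistic(self):
        t = np.array([[20, 10], [10, 20]])
        a = chi_square_independence(t)
        b = chi_square_independence(2 * t)
        assert b.statistic == pytest.approx(2 * a.statistic)

    def test_zero_marginal_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            res = chi_square_independence([[10, 0, 10], [12, 0, 8]])
        assert res.status == "ok"

    def test_negative_counts_rejected(self):
        with pytest.raises(DiagnosticsError):
            chi_square_independence([[1, -2], [3, 4]])


class TestBalanceTable:
    def _samples(self, shift_age=0.0, n=300, hospitals=4, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for i in range(hospitals):
            df = pd.DataFrame({
                "age": rng.normal(66, 12, n),
                "surgical": rng.integers(0, 2, n),
                "dx_category": rng.choice(["a", "b", "c"], n),
                "constant": 1.0,
            })
            if i == 0:
                df["age"] += shift_age
            out[f"H{i}"] = df
        return out

    def test_identical_samples_all_balanced(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame({"age": rng.normal(66, 12, 200),
                             "surgical": rng.integers(0, 2, 200)})
        report = balance_table({"H0": base, "H1": base.copy()},
                               ["age", "surgical"])
        assert report.n_unbalanced == 0

    def test_shifted_age_detected(self):
        report = balance_table(self._samples(shift_age=20.0),
                               ["age", "surgical", "dx_category"])
        row = report.table.set_index("variable").loc["age"]
        assert not row["balanced"]
        assert report.table.shape[0] == 3  # one row per roster variable

    def test_constant_variable_marked_degenerate_balanced(self):
        with pytest.warns(UserWarning, match="degenerate"):
            report = balance_table(self._samples(), ["constant"],
                                   continuous=["constant"])
        row = report.table.iloc[0]
        assert row["status"] == "degenerate" and row["balanced"]

    def test_single_hospital_rejected(self):
        with pytest.raises(DiagnosticsError):
            balance_table({"H0": pd.DataFrame({"age": [1.0]})}, ["age"])

    def test_balance_summary_plot_written(self, tmp_path):
        from tmbench.diagnostics import plot_balance_summary

        report = balance_table(self._samples(), ["age", "surgical"])
        out = tmp_path / "balance.png"
        plot_balance_summary({"run1": report}, out)
        assert out.stat().st_size > 0
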