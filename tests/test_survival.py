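import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from netsig.survival_stratification import (
    SurvivalError,
    collapse_probes,
    dynamic_hybrid_cut,
    hclust_complete,
    km_curve,
    km_survival_at,
    logrank_test,
    pearson_distance,
    quantile_normalize,
    signature_matrix,
    stratify,
)
from netsig.synthetic_data import CohortSpec, gen_cohort, gen_probe_map


# ---------------------------------------------------------------------------
# Oracles (independent re-implementations used only by tests)


def bruteforce_complete_linkage(d: np.ndarray) -> list[float]:
    """Naive O(n^3) complete-linkage agglomeration; returns sorted merge heights."""
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if h < best[0]:
                    best = (h, (i, j))
        h, (i, j) = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


def logrank_two_group_oracle(times, events, groups):
    """Hand O-E/V risk-table tabulation of the 2-group log-rank chi-square."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    g1 = np.unique(groups)[0]
    O1 = E1 = V1 = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == g1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == g1)).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V1 += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V1


# ---------------------------------------------------------------------------


class TestCollapseProbes:
    def test_single_probe_identity(self):
        expr = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["p1", "p2"], columns=["a", "b"])
        out = collapse_probes(expr, {"p1": "G1", "p2": "G2"})
        assert list(out.index) == ["G1", "G2"]
        assert np.allclose(out.to_numpy(), expr.to_numpy())

    def test_highest_mean_probe_wins(self):
        expr = pd.DataFrame(
            [[5.0, 5.0], [7.0, 7.0]], index=["p1", "p2"], columns=["a", "b"]
        )
        out = collapse_probes(expr, {"p1": "G", "p2": "G"})
        assert np.allclose(out.loc["G"], [7.0, 7.0])

    def test_tie_goes_to_lexicographically_smallest_probe(self):
        expr = pd.DataFrame(
            [[5.0, 1.0], [1.0, 5.0]], index=["p2", "p1"], columns=["a", "b"]
        )
        out = collapse_probes(expr, {"p1": "G", "p2": "G"})
        assert np.allclose(out.loc["G"], [1.0, 5.0])  # p1's row

    def test_no_mapped_probe_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["p1"], columns=["a"])
        with pytest.raises(SurvivalError):
            collapse_probes(expr, {"x": "G"})

    def test_planted_top_probe_recovered(self):
        gene = pd.DataFrame(
            np.random.default_rng(9).normal(size=(10, 6)),
            index=[f"G{i}" for i in range(10)],
            columns=[f"P{i}" for i in range(6)],
        )
        pmap, probe_expr, top = gen_probe_map(gene, (2, 4), seed=9)
        out = collapse_probes(probe_expr, pmap)
        for g in gene.index:
            assert np.allclose(out.loc[g], probe_expr.loc[top[g]])


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        expr = pd.DataFrame({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]})
        assert np.allclose(quantile_normalize(expr), expr)

    def test_two_column_hand_example(self):
        expr = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = quantile_normalize(expr)
        assert np.allclose(out["a"], [1.5, 3.5])
        assert np.allclose(out["b"], [1.5, 3.5])

    def test_sorted_columns_identical_after(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(30, 5)))
        out = quantile_normalize(expr).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(20, 3)))
        out = quantile_normalize(expr)
        for c in expr.columns:
            assert (expr[c].rank() == out[c].rank()).all()


class TestSignatureMatrix:
    def test_partial_mapping_counts(self):
        # 84-gene signature, 76 present: structural analog of a real mapping
        genes = [f"G{i:03d}" for i in range(76)]
        expr = pd.DataFrame(
            np.zeros((76, 3)), index=genes, columns=["a", "b", "c"]
        )
        signature = genes + [f"X{i}" for i in range(8)]
        sub, unmapped = signature_matrix(expr, signature)
        assert sub.shape[0] == 76 and len(unmapped) == 8

    def test_disjoint_signature_rejected(self):
        expr = pd.DataFrame(np.zeros((3, 2)), index=list("ABC"), columns=["a", "b"])
        with pytest.raises(SurvivalError):
            signature_matrix(expr, ["X", "Y"])


class TestPearsonDistance:
    def test_affine_profiles_have_zero_distance(self):
        base = np.array([1.0, 2.0, 5.0, 3.0])
        expr = pd.DataFrame({"i": base, "j": 2 * base + 1})
        d = pearson_distance(expr)
        assert d.loc["i", "j"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_have_distance_two(self):
        base = np.array([1.0, 2.0, 5.0, 3.0])
        expr = pd.DataFrame({"i": base, "j": -base})
        assert pearson_distance(expr).loc["i", "j"] == pytest.approx(2.0, abs=1e-12)

    def test_matches_textbook_covariance_formula(self):
        rng = np.random.default_rng(12)
        expr = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("wxyz"))
        d = pearson_distance(expr)
        v = expr.to_numpy()
        for i, a in enumerate("wxyz"):
            for j, b in enumerate("wxyz"):
                x, y = v[:, i], v[:, j]
                r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                    ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
                )
                assert d.loc[a, b] == pytest.approx(1 - r, abs=1e-12)

    def test_zero_variance_patient_named(self):
        expr = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(SurvivalError, match="flat"):
            pearson_distance(expr)


class TestHclustComplete:
    def test_two_points_single_merge(self):
        d = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        Z = hclust_complete(d)
        assert Z.shape == (1, 4) and Z[0, 2] == pytest.approx(3.0)

    def test_forced_merge_order(self):
        d = pd.DataFrame(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        Z = hclust_complete(d)
        assert Z[0, 2] == pytest.approx(1.0) and Z[1, 2] == pytest.approx(10.0)

    def test_matches_bruteforce_oracle_heights(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            m = rng.uniform(size=(n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            df = pd.DataFrame(d, index=range(n), columns=range(n))
            Z = hclust_complete(df)
            assert np.allclose(sorted(Z[:, 2]), bruteforce_complete_linkage(d))

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(SurvivalError):
            hclust_complete(d)


class TestDynamicHybridCut:
    @staticmethod
    def two_group_distance(n_per_group: int, seed: int) -> tuple[pd.DataFrame, np.ndarray]:
        expr, _, labels = gen_cohort(
            CohortSpec(
                n_patients=2 * n_per_group, n_genes=40, expression_effect=3.0,
                signature_genes=[f"G{i:04d}" for i in range(30)], seed=seed,
            )
        )
        d = pearson_distance(expr.iloc[:30])
        return d, labels.to_numpy()

    def test_small_cohort_collapses_to_single_cluster(self):
        # n = 3 with floor max(2, 1) = 2: no two disjoint clusters fit
        d, _ = self.two_group_distance(5, seed=1)
        d = d.iloc[:3, :3]
        labels = dynamic_hybrid_cut(hclust_complete(d), d, min_fraction=0.5)
        assert labels.nunique() == 1  # pigeonhole: no admissible split

    def test_planted_groups_recovered_exactly(self):
        d, truth = self.two_group_distance(20, seed=5)
        labels = dynamic_hybrid_cut(hclust_complete(d), d, min_fraction=0.25)
        assert labels.nunique() == 2
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_equal_distances_give_single_cluster(self):
        n = 12
        d = pd.DataFrame(1.0 - np.eye(n))
        labels = dynamic_hybrid_cut(hclust_complete(d), d, min_fraction=0.25)
        assert labels.nunique() == 1

    def test_size_floor_and_determinism(self):
        d, _ = self.two_group_distance(16, seed=8)
        Z = hclust_complete(d)
        l1 = dynamic_hybrid_cut(Z, d, min_fraction=0.125)
        l2 = dynamic_hybrid_cut(Z, d, min_fraction=0.125)
        assert (l1 == l2).all()
        floor = max(2, int(0.125 * len(d)))
        assert l1.value_counts().min() >= floor
        assert sorted(l1.unique()) == list(range(1, l1.nunique() + 1))

    def test_bad_fraction_rejected(self):
        d, _ = self.two_group_distance(5, seed=2)
        with pytest.raises(SurvivalError):
            dynamic_hybrid_cut(hclust_complete(d), d, min_fraction=0.7)


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        c = km_curve([1, 2, 3], [0, 0, 0])
        assert np.allclose(c.survival, 1.0)

    def test_hand_product_limit(self):
        c = km_curve([1, 2, 3], [1, 0, 1])
        assert km_survival_at(c, 1) == pytest.approx(2 / 3)
        assert km_survival_at(c, 2.5) == pytest.approx(2 / 3)
        assert km_survival_at(c, 3) == pytest.approx(0.0)

    def test_all_events_at_once(self):
        c = km_curve([1, 1, 1, 1], [1, 1, 1, 1])
        assert km_survival_at(c, 1) == pytest.approx(0.0)

    def test_survival_at_zero_and_before_first_event(self):
        c = km_curve([5, 6], [1, 1])
        assert km_survival_at(c, 0) == 1.0
        assert km_survival_at(c, 4.9) == 1.0

    def test_monotone_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            c = km_curve(rng.exponential(5, n), rng.integers(0, 2, n))
            assert c.survival[0] <= 1.0 + 1e-12
            assert np.all(np.diff(c.survival) <= 1e-12)
            assert np.all((c.survival >= 0) & (c.survival <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(SurvivalError):
            km_curve([-1.0], [1])


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4]
        e = [1, 0, 1, 1]
        res = logrank_test(t + t, e + e, [1] * 4 + [2] * 4)
        assert res.chi_square == pytest.approx(0.0, abs=1e-10)
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_hand_tabulation_on_four_subjects(self):
        t, e, g = [1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 2, 2]
        res = logrank_test(t, e, g)
        assert res.df == 1
        assert res.chi_square == pytest.approx(logrank_two_group_oracle(t, e, g), abs=1e-10)

    def test_matches_hand_tabulation_on_random_data(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(6, 25))
            t = rng.exponential(3, n).round(2)
            e = rng.integers(0, 2, n)
            g = rng.integers(0, 2, n)
            if e.sum() == 0 or len(set(g)) < 2:
                continue
            res = logrank_test(t, e, g)
            assert res.chi_square == pytest.approx(
                logrank_two_group_oracle(t, e, g), abs=1e-8
            )

    def test_subject_censored_before_first_event_changes_nothing(self):
        t, e, g = [2.0, 3.0, 4.0, 5.0], [1, 1, 1, 0], [1, 2, 1, 2]
        base = logrank_test(t, e, g)
        padded = logrank_test(t + [0.5], e + [0], g + [2])
        assert padded.chi_square == pytest.approx(base.chi_square, abs=1e-10)

    def test_requires_two_groups_and_an_event(self):
        with pytest.raises(SurvivalError):
            logrank_test([1, 2], [1, 1], [1, 1])
        with pytest.raises(SurvivalError):
            logrank_test([1, 2], [0, 0], [1, 2])


class TestStratify:
    def test_planted_prognosis_recovered(self):
        expr, surv, truth = gen_cohort(CohortSpec(seed=21))
        res = stratify(expr, surv, [f"G{i:04d}" for i in range(20)])
        assert res.logrank is not None and res.logrank.pvalue < 0.01
        assert adjusted_rand_score(truth.to_numpy(), res.assignment.to_numpy()) > 0.9
        assert set(res.survival_at_5y) == set(res.curves)
        assert res.subtype_composition["n"].sum() == len(surv)

    def test_absent_subtype_rejected(self):
        expr, surv, _ = gen_cohort(CohortSpec(seed=2))
        with pytest.raises(SurvivalError, match="NOSUCH"):
            stratify(expr, surv, [f"G{i:04d}" for i in range(20)], subtype_filter="NOSUCH")

    def test_deterministic(self):
        expr, surv, _ = gen_cohort(CohortSpec(seed=4))
        sig = [f"G{i:04d}" for i in range(20)]
        r1 = stratify(expr, surv, sig)
        r2 = stratify(expr, surv, sig)
        assert (r1.assignment == r2.assignment).all()
        assert r1.logrank.pvalue == r2.logrank.pvalue
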