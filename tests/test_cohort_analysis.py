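import itertools

import numpy as np
import pandas as pd
import pytest

from conncodec.family import (NetworkAssignment, RelationshipPairs,
                              bootstrap_performance, fdr_correct,
                              fit_demographic_models, mask_to_network,
                              match_unrelated_pairs,
                              permutation_compare_separability,
                              relationship_pairs_from_cohort, roc_separability,
                              similarity_by_relationship, zscore_by_unrelated)
from conncodec.flavors import (CohortTable, EdgeVectorSet, FlavorSpec,
                               ValidationError, count_edges, edge_index)


def cohort_frame(rows):
    cols = ["subject_id", "age", "sex", "cog_total", "cog_fluid", "cog_cryst",
            "cog_early", "family_id", "zygosity", "split", "retest_of"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df:
            df[c] = ""
    return CohortTable(df[cols])


class TestPairDerivation:
    def test_pairs_from_tiny_cohort(self, tiny_cohort):
        _, _, cohort, _ = tiny_cohort
        pairs = relationship_pairs_from_cohort(cohort)
        counts = pairs.table["relation"].value_counts()
        assert counts["MZ"] == 6 and counts["DZ"] == 4 and counts["sibling"] == 6
        assert counts["self-retest"] == 5

    def test_family_members_never_matched_as_unrelated(self, tiny_cohort):
        _, _, cohort, _ = tiny_cohort
        pairs = relationship_pairs_from_cohort(cohort)
        matched = match_unrelated_pairs(cohort, pairs)
        fam = dict(zip(cohort.table["subject_id"], cohort.table["family_id"]))
        for _, r in matched.table.iterrows():
            assert fam[r["subject_a"]] != fam[r["subject_b"]]

    def test_matched_pair_minimizes_age_gap(self):
        rows = [dict(subject_id="a1", age=30, sex="F", family_id="fA",
                     zygosity="sibling", split="test"),
                dict(subject_id="a2", age=33, sex="F", family_id="fA",
                     zygosity="sibling", split="test")]
        # unrelated candidates with various age gaps
        for i, ag in enumerate([20, 23, 25, 30, 40]):
            rows.append(dict(subject_id=f"u{i}", age=ag, sex="F",
                             family_id=f"u{i}", zygosity="none", split="test"))
        cohort = cohort_frame(rows)
        pairs = relationship_pairs_from_cohort(cohort)
        assert len(pairs.table) == 1 and pairs.table.iloc[0]["age_diff"] == 3
        matched = match_unrelated_pairs(cohort, pairs)
        got = matched.table.iloc[0]
        # exhaustive check: no unrelated same-sex pair has |gap - 3| smaller
        best = min(abs(abs(a - b) - 3)
                   for a, b in itertools.combinations([20, 23, 25, 30, 40, 30, 33], 2))
        assert abs(got["age_diff"] - 3) == pytest.approx(best)


class TestSimilarityGrouping:
    def test_identity_matrix_self_retest(self):
        ids = ["a", "b"]
        pairs = RelationshipPairs(pd.DataFrame(
            [dict(subject_a="a", subject_b="b", relation="self-retest")]))
        S = np.ones((2, 2))
        groups = similarity_by_relationship(S, ids, pairs)
        assert groups["self-retest"].tolist() == [1.0]

    def test_hand_set_matrix_lookup(self):
        S = np.array([[1.0, 0.2, 0.3, 0.4],
                      [0.2, 1.0, 0.5, 0.6],
                      [0.3, 0.5, 1.0, 0.7],
                      [0.4, 0.6, 0.7, 1.0]])
        ids = list("abcd")
        pairs = RelationshipPairs(pd.DataFrame([
            dict(subject_a="a", subject_b="b", relation="MZ"),
            dict(subject_a="c", subject_b="d", relation="unrelated"),
            dict(subject_a="b", subject_b="c", relation="DZ"),
        ]))
        groups = similarity_by_relationship(S, ids, pairs)
        assert groups["MZ"].tolist() == [0.2]
        assert groups["unrelated"].tolist() == [0.7]
        assert groups["DZ"].tolist() == [0.5]
        assert groups["sibling"].size == 0  # empty group, no crash

    def test_pair_outside_matrix_rejected(self):
        pairs = RelationshipPairs(pd.DataFrame(
            [dict(subject_a="a", subject_b="zz", relation="MZ")]))
        with pytest.raises(ValidationError):
            similarity_by_relationship(np.eye(2), ["a", "b"], pairs)


class TestZscore:
    def test_unrelated_group_maps_to_standard(self, rng):
        groups = {"unrelated": rng.standard_normal(100) * 3 + 5,
                  "MZ": rng.standard_normal(10)}
        z = zscore_by_unrelated(groups)
        assert z["unrelated"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["unrelated"].std() == pytest.approx(1.0, abs=1e-12)

    def test_location_invariance(self, rng):
        groups = {"unrelated": rng.standard_normal(50), "MZ": rng.standard_normal(8)}
        z1 = zscore_by_unrelated(groups)
        z2 = zscore_by_unrelated({k: v + 7.5 for k, v in groups.items()})
        assert np.allclose(z1["MZ"], z2["MZ"], atol=1e-10)

    def test_hand_arithmetic(self):
        groups = {"unrelated": np.array([0.0, 2.0]), "MZ": np.array([3.0])}
        z = zscore_by_unrelated(groups)
        assert z["MZ"][0] == pytest.approx((3.0 - 1.0) / 1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            zscore_by_unrelated({"unrelated": np.array([1.0, 1.0])})


class TestRocSeparability:
    def test_perfect_separation(self):
        assert roc_separability([0, 1, 2], [5, 6, 7]) == 1.0

    def test_identical_distributions_half(self):
        assert roc_separability([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_hand_rank_sum_oracle(self):
        # pairs: (1,1.5)+ (1,3)+ (2,1.5)- (2,3)+ -> 3/4
        assert roc_separability([1, 2], [1.5, 3]) == pytest.approx(0.75)

    def test_monotone_transform_invariance(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(15) + 0.5
        auc1 = roc_separability(a, b)
        f = lambda x: np.exp(3 * x) - 1  # strictly monotone
        assert roc_separability(f(a), f(b)) == pytest.approx(auc1)


class TestPermutationCompare:
    def test_identical_scores_p_near_one(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10) + 1
        out = permutation_compare_separability(a, b, a.copy(), b.copy(),
                                               n_perm=200, seed=0)
        assert out["statistic"] == 0.0
        assert out["p_value"] > 0.9

    def test_zero_permutations_rejected(self, rng):
        a = rng.standard_normal(4)
        with pytest.raises(ValidationError):
            permutation_compare_separability(a, a, a, a, n_perm=0)

    def test_exact_enumeration_matches_independent_oracle(self, rng):
        la = rng.standard_normal(3)
        lb = rng.standard_normal(3) + 2.0
        oa = rng.standard_normal(3)
        ob = rng.standard_normal(3) + 0.3
        out = permutation_compare_separability(la, lb, oa, ob, exact=True)

        def auc(x, y):
            return np.mean([(xi < yi) + 0.5 * (xi == yi)
                            for xi in x for yi in y])

        obs = auc(la, lb) - auc(oa, ob)
        count = total = 0
        for swaps in itertools.product([0, 1], repeat=6):
            sa, sb = np.array(swaps[:3], bool), np.array(swaps[3:], bool)
            la2 = np.where(sa, oa, la)
            oa2 = np.where(sa, la, oa)
            lb2 = np.where(sb, ob, lb)
            ob2 = np.where(sb, lb, ob)
            stat = auc(la2, lb2) - auc(oa2, ob2)
            count += abs(stat) >= abs(obs) - 1e-12
            total += 1
        assert out["p_value"] == pytest.approx(count / total)
        assert out["n_perm"] == total


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_correct([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        assert np.allclose(fdr_correct([0.2, 0.2, 0.2]), 0.2)

    def test_hand_applied_bh(self):
        adj = fdr_correct([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_matches_independent_stepup_oracle(self, rng):
        for _ in range(10):
            p = rng.uniform(size=rng.integers(2, 20))
            adj = fdr_correct(p)
            # independent step-up implementation
            m = p.size
            order = np.argsort(p)
            ranked = p[order] * m / (np.arange(m) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            oracle = np.empty(m)
            oracle[order] = np.minimum(ranked, 1.0)
            assert np.allclose(adj, oracle, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_correct([0.5, 1.2])


class TestDemographicModels:
    def test_exact_linear_target_recovered(self, rng):
        n, p = 120, 10
        X = rng.standard_normal((n, p))
        w = rng.standard_normal(p)
        targets = pd.DataFrame({"age": X @ w})
        groups = np.arange(n)  # all singleton families
        tr = np.arange(90)
        te = np.arange(90, n)
        res = fit_demographic_models(X, targets, groups, tr, te, seed=0)
        assert res["age"]["r"] > 0.99

    def test_permuted_targets_at_chance(self, rng):
        n, p = 120, 8
        X = rng.standard_normal((n, p))
        y = X @ rng.standard_normal(p)
        targets = pd.DataFrame({
            "age": rng.permutation(y),
            "sex": rng.permutation(np.array(["F", "M"] * (n // 2))),
        })
        res = fit_demographic_models(X, targets, np.arange(n),
                                     np.arange(90), np.arange(90, n), seed=0)
        assert abs(res["age"]["r"]) < 0.45
        assert 0.2 < res["sex"]["balanced_accuracy"] < 0.8

    def test_constant_target_degenerate(self, rng):
        X = rng.standard_normal((40, 4))
        targets = pd.DataFrame({"age": np.full(40, 31.0)})
        with pytest.warns(UserWarning, match="constant target"):
            res = fit_demographic_models(X, targets, np.arange(40),
                                         np.arange(30), np.arange(30, 40))
        assert np.isnan(res["age"]["r"])

    def test_sex_separable_classes(self, rng):
        n = 100
        sex = np.array(["F", "M"] * (n // 2))
        X = rng.standard_normal((n, 6))
        X[:, 0] += np.where(sex == "M", 2.0, -2.0)
        targets = pd.DataFrame({"sex": sex})
        res = fit_demographic_models(X, targets, np.arange(n),
                                     np.arange(80), np.arange(80, n), seed=0)
        assert res["sex"]["balanced_accuracy"] > 0.9


class TestBootstrap:
    def test_perfect_predictions_zero_width(self):
        y = np.arange(10.0)
        out = bootstrap_performance(y, y.copy(),
                                    lambda a, b: float(np.mean(a == b)),
                                    n_boot=50, seed=1)
        assert out["mean"] == 1.0
        assert out["interval90"] == (1.0, 1.0)

    def test_seeded_reproducibility(self, rng):
        y = rng.standard_normal(30)
        p = y + rng.standard_normal(30)
        fn = lambda a, b: float(np.corrcoef(a, b)[0, 1])
        o1 = bootstrap_performance(y, p, fn, n_boot=100, seed=5)
        o2 = bootstrap_performance(y, p, fn, n_boot=100, seed=5)
        assert np.array_equal(o1["scores"], o2["scores"])

    def test_interval_covers_sampling_noise(self, rng):
        # known-noise case: r ~ 0.7; the 90% interval should contain the
        # full-sample estimate and have sensible width
        y = rng.standard_normal(200)
        p = y + rng.standard_normal(200)
        fn = lambda a, b: float(np.corrcoef(a, b)[0, 1])
        full = fn(y, p)
        out = bootstrap_performance(y, p, fn, n_boot=200, seed=2)
        lo, hi = out["interval90"]
        assert lo < full < hi
        assert 0.01 < hi - lo < 0.3

    def test_too_few_boots_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_performance(np.ones(3), np.ones(3), lambda a, b: 0.0,
                                  n_boot=1)


class TestNetworkMasking:
    FL = FlavorSpec("M4_FC", "FC", "M4", 4, fc_variant="pearson")  # 6 edges

    def make_set(self, rng):
        return EdgeVectorSet(self.FL, ["s0", "s1"], rng.standard_normal((2, 6)))

    def test_all_regions_network_is_identity(self, rng):
        es = self.make_set(rng)
        a = NetworkAssignment(["net"] * 4)
        out = mask_to_network(es, a, "net", np.zeros(6))
        assert np.array_equal(out.data, es.data)

    def test_two_region_network_toy(self, rng):
        es = self.make_set(rng)
        a = NetworkAssignment(["A", "A", "B", "B"])
        mu = np.full(6, 99.0)
        out = mask_to_network(es, a, "A", mu)
        # edge (2,3) is the only edge with neither endpoint in A
        idx = edge_index(4).index((2, 3))
        for j in range(6):
            if j == idx:
                assert np.all(out.data[:, j] == 99.0)
            else:
                assert np.array_equal(out.data[:, j], es.data[:, j])

    def test_edges_kept_count_identity(self, rng):
        # edges_kept = n_edges - C(n_regions - |net|, 2), oracle by enumeration
        n_regions = 9
        fl = FlavorSpec("M9_FC", "FC", "M9", n_regions, fc_variant="pearson")
        es = EdgeVectorSet(fl, ["s"], rng.standard_normal((1, fl.n_edges)))
        labels = ["A"] * 3 + ["B"] * 6
        a = NetworkAssignment(labels)
        mu = np.full(fl.n_edges, -7.0)
        out = mask_to_network(es, a, "A", mu)
        kept = int(np.sum(out.data[0] != -7.0))
        oracle = sum(1 for i, j in edge_index(n_regions)
                     if labels[i] == "A" or labels[j] == "A")
        assert kept == oracle == fl.n_edges - count_edges(n_regions - 3)

    def test_empty_network_replaces_everything(self, rng):
        es = self.make_set(rng)
        a = NetworkAssignment(["A", "A", "B", "B"])
        mu = np.arange(6.0)
        out = mask_to_network(es, a, [], mu)
        assert np.array_equal(out.data, np.tile(mu, (2, 1)))

    def test_unknown_network_rejected(self, rng):
        es = self.make_set(rng)
        with pytest.raises(ValidationError):
            mask_to_network(es, NetworkAssignment(["A"] * 4), "Z", np.zeros(6))
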