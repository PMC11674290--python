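import numpy as np
import pandas as pd
import pytest

from conftest import genorm_greedy_oracle, pair_sd_oracle
from refstab.model import CtMatrix, ct_to_quantities
from refstab.stability import (
    bestkeeper_descriptives,
    bestkeeper_index_correlation,
    deltact_scores,
    genorm_m,
    genorm_pairwise_variation,
    genorm_ranking,
    m_threshold_classify,
    normfinder_stability,
    optimal_reference_count,
    pairwise_variation_matrix,
)

SQRT3 = float(np.sqrt(3.0))


class TestDeltaCt:
    def test_two_gene_pair_sd(self):
        ct = CtMatrix(
            pd.DataFrame([[20.0, 21, 22], [25.0, 25, 25]], index=["A", "B"], columns=["s1", "s2", "s3"]),
            pd.Series({"s1": "a", "s2": "a", "s3": "b"}),
        )
        scores = deltact_scores(ct)["value"]
        assert scores["A"] == pytest.approx(1.0) and scores["B"] == pytest.approx(1.0)

    def test_constant_offset_pair_scores_zero(self):
        ct = CtMatrix(
            pd.DataFrame([[20.0, 21, 22], [23.0, 24, 25]], index=["A", "B"], columns=["s1", "s2", "s3"]),
            pd.Series({"s1": "a", "s2": "a", "s3": "b"}),
        )
        assert deltact_scores(ct)["value"].max() == pytest.approx(0.0, abs=1e-12)

    def test_three_gene_hand_computation(self, toy_ct):
        table = deltact_scores(toy_ct)
        expected = {"A": (1 + 1 / SQRT3) / 2, "B": (1 + 1 / SQRT3) / 2, "C": 1 / SQRT3}
        for g, v in expected.items():
            assert table.loc[g, "value"] == pytest.approx(v, rel=1e-9)
        assert table.loc["C", "rank"] == 1
        assert table.loc["A", "rank"] == table.loc["B", "rank"] == 2  # dense tie

    def test_matches_pairwise_oracle_on_random_matrices(self, random_ct_factory):
        ct = random_ct_factory(6, 7, seed=5)
        table = deltact_scores(ct)
        for g in ct.gene_ids:
            expected = np.mean([pair_sd_oracle(ct, g, h) for h in ct.gene_ids if h != g])
            assert table.loc[g, "value"] == pytest.approx(expected, rel=1e-9)


class TestGeNorm:
    def test_identical_profiles_have_zero_m(self):
        ct = CtMatrix(
            pd.DataFrame([[20.0, 21, 22], [22.0, 23, 24]], index=["A", "B"], columns=["s1", "s2", "s3"]),
            pd.Series({"s1": "a", "s2": "a", "s3": "b"}),
        )
        m = genorm_m(ct_to_quantities(ct))
        assert float(m.abs().max()) == pytest.approx(0.0, abs=1e-12)

    def test_toy_m_values_match_pair_sd_enumeration(self, toy_ct):
        m = genorm_m(ct_to_quantities(toy_ct))
        assert m["C"] == pytest.approx(1 / SQRT3, rel=1e-9)
        assert m["A"] == pytest.approx((1 + 1 / SQRT3) / 2, rel=1e-9)

    def test_singleton_subset_is_an_error(self, toy_ct):
        with pytest.raises(ValueError, match="2 genes"):
            genorm_m(ct_to_quantities(toy_ct), subset=["A"])

    def test_ranking_pairs_the_covarying_genes_first(self, toy_ct):
        # C tracks A and B closely; B is flat while A drifts, so B goes first
        res = genorm_ranking(ct_to_quantities(toy_ct))
        assert set(res.ranking[:2]) == {"A", "C"}
        assert res.ranks["A"] == res.ranks["C"] == 1 and res.ranks["B"] == 2

    def test_ranking_matches_greedy_oracle_on_random_instances(self, random_ct_factory):
        for seed in range(20):
            ct = random_ct_factory(5, 8, seed=seed)
            res = genorm_ranking(ct_to_quantities(ct))
            excl, final_pair = genorm_greedy_oracle(ct)
            assert res.exclusion_order == excl
            assert sorted(res.ranking[:2]) == final_pair

    def test_all_identical_profiles_use_documented_tie_break(self):
        data = pd.DataFrame(
            np.tile([20.0, 21, 22, 23], (4, 1)), index=["d", "b", "a", "c"],
            columns=["s1", "s2", "s3", "s4"],
        )
        ct = CtMatrix(data, pd.Series(["x", "x", "y", "y"], index=data.columns))
        res = genorm_ranking(ct_to_quantities(ct))
        # all M tie at 0: lexicographically last id removed first
        assert res.exclusion_order == ["d", "c"]
        assert res.ranking[:2] == ["a", "b"]

    def test_v_series_zero_when_next_gene_is_proportional(self):
        # gene ranked n+1 proportional to NF_n across samples => V_n = 0
        base = np.array([20.0, 21.0, 23.0, 19.5])
        data = pd.DataFrame(
            [base, base + 1.0, base + 2.0], index=["A", "B", "C"], columns=["s1", "s2", "s3", "s4"]
        )
        ct = CtMatrix(data, pd.Series(["x", "x", "y", "y"], index=data.columns))
        q = ct_to_quantities(ct)
        v = genorm_pairwise_variation(q, ["A", "B", "C"])
        assert v[2] == pytest.approx(0.0, abs=1e-12)

    def test_v_series_matches_from_scratch_oracle(self, random_ct_factory):
        ct = random_ct_factory(4, 8, seed=9)
        q = ct_to_quantities(ct)
        ranking = genorm_ranking(q).ranking
        v = genorm_pairwise_variation(q, ranking)
        logq = np.log2(q.data.loc[ranking])
        for n in range(2, 4):
            nf_n = logq.iloc[:n].mean(axis=0)
            nf_n1 = logq.iloc[: n + 1].mean(axis=0)
            assert v[n] == pytest.approx(float((nf_n - nf_n1).std(ddof=1)), abs=1e-9)

    def test_v_series_invariant_to_gene_row_offset(self, random_ct_factory):
        ct = random_ct_factory(5, 6, seed=3)
        shifted_data = ct.data.copy()
        shifted_data.iloc[2] += 7.0
        shifted = CtMatrix(shifted_data, ct.groups)
        q0, q1 = ct_to_quantities(ct), ct_to_quantities(shifted)
        r0 = genorm_ranking(q0)
        np.testing.assert_allclose(
            r0.v_series, genorm_pairwise_variation(q1, r0.ranking), atol=1e-9
        )


class TestOptimalReferenceCount:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ({2: 0.087, 3: 0.12}, 2),  # published leading value => two references suffice
            ({2: 0.20, 3: 0.12, 4: 0.10}, 3),
            ({2: 0.20, 3: 0.18, 4: 0.15}, None),  # threshold is strict
        ],
    )
    def test_smallest_qualifying_n(self, series, expected):
        assert optimal_reference_count(series) == expected

    def test_bare_sequence_starts_at_two(self):
        assert optimal_reference_count([0.2, 0.12, 0.1]) == 3

    def test_empty_series_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            optimal_reference_count({})


class TestMThresholdClassify:
    def test_strictly_below_threshold_is_suitable(self):
        assert m_threshold_classify({"g": 1.2941}) == {"g"}
        assert m_threshold_classify({"g": 1.5}) == set()


class TestNormFinder:
    def test_centering_makes_residual_rows_sum_to_zero(self, random_ct_factory):
        # sample centering means the per-sample residuals z always sum to
        # zero over genes; with two genes the rows are exact mirror images,
        # so their stability values coincide
        data = pd.DataFrame([[20.0, 21, 22, 20], [25.0, 25.5, 24, 26]],
                            index=["A", "B"], columns=["s1", "s2", "s3", "s4"])
        ct = CtMatrix(data, pd.Series(["x", "x", "y", "y"], index=data.columns))
        q = ct_to_quantities(ct)
        z = np.log2(q.data) - np.log2(q.data).mean(axis=0)
        np.testing.assert_allclose(z.sum(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.loc["A"], -z.loc["B"], atol=1e-12)

    def test_toy_ungrouped_hand_computation(self, toy_ct):
        res = normfinder_stability(ct_to_quantities(toy_ct))
        s = res.table["value"]
        assert s["A"] == pytest.approx(np.sqrt(21 / 81), rel=1e-9)  # 0.5092
        assert s["B"] == pytest.approx(np.sqrt(21 / 81), rel=1e-9)
        assert s["C"] == pytest.approx(np.sqrt(3 / 81), rel=1e-9)  # 0.1925
        assert res.table.loc["C", "rank"] == 1

    def test_agrees_with_deltact_ordering_on_toy(self, toy_ct):
        nf = normfinder_stability(ct_to_quantities(toy_ct)).table
        dc = deltact_scores(toy_ct)
        assert (nf["rank"] == dc["rank"]).all()

    def test_grouped_mode_zero_intergroup_when_group_means_coincide(self, random_ct_factory):
        ct = random_ct_factory(4, 6, seed=7)
        # duplicate the first half of samples into the second so group means match
        data = ct.data.copy()
        data.iloc[:, 3:] = data.iloc[:, :3].to_numpy()
        sym = CtMatrix(data, ct.groups)
        res = normfinder_stability(ct_to_quantities(sym), sym.groups)
        assert res.grouped
        assert float(res.intergroup.abs().max().max()) == pytest.approx(0.0, abs=1e-12)

    def test_grouped_mode_rejects_singleton_group(self, toy_ct):
        with pytest.raises(ValueError, match="2 samples per group"):
            normfinder_stability(ct_to_quantities(toy_ct), toy_ct.groups)  # heat has 1 sample

    def test_grouped_formula_matches_direct_computation(self, random_ct_factory):
        ct = random_ct_factory(5, 8, seed=13)
        q = ct_to_quantities(ct)
        res = normfinder_stability(q, ct.groups)
        z = np.log2(q.data) - np.log2(q.data).mean(axis=0)
        for g in ct.gene_ids:
            per_group = []
            means = {a: z.loc[g, ct.samples_in(a)].mean() for a in ct.group_names}
            grand = np.mean(list(means.values()))
            for a in ct.group_names:
                d = means[a] - grand
                v = z.loc[g, ct.samples_in(a)].var(ddof=1)
                per_group.append(abs(d) + np.sqrt(v / len(ct.samples_in(a))))
            assert res.table.loc[g, "value"] == pytest.approx(np.mean(per_group), rel=1e-9)


class TestBestKeeper:
    def test_hand_computed_descriptives(self):
        data = pd.DataFrame([[20.0, 21, 22, 21], [25.0, 25, 25, 25]],
                            index=["X", "Y"], columns=["s1", "s2", "s3", "s4"])
        ct = CtMatrix(data, pd.Series(["a", "a", "b", "b"], index=data.columns))
        row = bestkeeper_descriptives(ct).loc["X"]
        assert row["arith_mean"] == pytest.approx(21.0)
        assert row["value"] == pytest.approx(0.5)  # mean absolute deviation
        assert row["cv"] == pytest.approx(100 * 0.5 / 21, rel=1e-9)
        assert row["geo_mean"] == pytest.approx((20 * 21 * 22 * 21) ** 0.25, rel=1e-12)
        assert row["min"] == 20 and row["max"] == 22

    def test_constant_gene_degenerates_cleanly(self):
        data = pd.DataFrame([[25.0, 25, 25], [20.0, 22, 24]], index=["Y", "X"],
                            columns=["s1", "s2", "s3"])
        ct = CtMatrix(data, pd.Series(["a", "a", "b"], index=data.columns))
        row = bestkeeper_descriptives(ct).loc["Y"]
        assert row["value"] == 0 and row["cv"] == 0
        assert row["geo_mean"] == pytest.approx(row["arith_mean"])

    def test_suitability_flag_follows_the_one_cycle_rule(self, random_ct_factory):
        ct = random_ct_factory(6, 9, seed=21)
        table = bestkeeper_descriptives(ct)
        assert (table["suitable"] == (table["value"] <= 1.0)).all()

    def test_sample_sd_switch(self):
        data = pd.DataFrame([[20.0, 21, 22, 21], [25.0, 25, 25, 25]],
                            index=["X", "Y"], columns=["s1", "s2", "s3", "s4"])
        ct = CtMatrix(data, pd.Series(["a", "a", "b", "b"], index=data.columns))
        row = bestkeeper_descriptives(ct, use_sample_sd=True).loc["X"]
        assert row["value"] == pytest.approx(data.loc["X"].std(ddof=1))

    def test_nonpositive_ct_is_an_error(self, toy_ct):
        data = toy_ct.data.copy()
        data.loc["A", "s1"] = -1.0
        with pytest.raises(ValueError, match="nonpositive"):
            bestkeeper_descriptives(CtMatrix(data, toy_ct.groups))

    def test_index_correlation_affine_gene_correlates_perfectly(self, random_ct_factory):
        ct = random_ct_factory(3, 8, seed=17)
        data = ct.data.copy()
        index_vals = np.exp(np.log(data.iloc[:2]).mean(axis=0))
        data.iloc[2] = index_vals + 3.0
        ct2 = CtMatrix(data, ct.groups)
        out = bestkeeper_index_correlation(ct2, subset=list(data.index[:2]))
        assert out.loc[data.index[2], "r"] == pytest.approx(1.0, abs=1e-9)

    def test_index_correlation_matches_direct_formula(self, random_ct_factory):
        ct = random_ct_factory(4, 8, seed=19)
        out = bestkeeper_index_correlation(ct)
        index = np.exp(np.log(ct.data).mean(axis=0))
        for g in ct.gene_ids:
            y = ct.data.loc[g]
            r = ((y - y.mean()) * (index - index.mean())).sum() / np.sqrt(
                ((y - y.mean()) ** 2).sum() * ((index - index.mean()) ** 2).sum()
            )
            assert out.loc[g, "r"] == pytest.approx(float(r), abs=1e-9)

    def test_zero_variance_gene_gets_undefined_r(self):
        data = pd.DataFrame([[25.0, 25, 25], [20.0, 22, 24]], index=["flat", "X"],
                            columns=["s1", "s2", "s3"])
        ct = CtMatrix(data, pd.Series(["a", "a", "b"], index=data.columns))
        out = bestkeeper_index_correlation(ct)
        assert np.isnan(out.loc["flat", "r"])


class TestCrossMethodIdentity:
    def test_pairwise_variation_equals_pair_sd_at_efficiency_two(self, random_ct_factory):
        for seed in range(10):
            ct = random_ct_factory(8, 9, seed=seed)
            v = pairwise_variation_matrix(ct_to_quantities(ct))
            for i, g in enumerate(ct.gene_ids):
                for h in ct.gene_ids[i + 1:]:
                    assert v.loc[g, h] == pytest.approx(pair_sd_oracle(ct, g, h), abs=1e-9)

    def test_single_pass_m_equals_deltact_scores(self, random_ct_factory):
        ct = random_ct_factory(8, 9, seed=42)
        m = genorm_m(ct_to_quantities(ct))
        dc = deltact_scores(ct)["value"]
        np.testing.assert_allclose(m.loc[dc.index], dc, atol=1e-9)
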