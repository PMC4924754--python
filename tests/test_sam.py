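"""SAM d-statistic, permutation FDR, Delta tuning and the auxiliary screens."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_matrix, make_metadata
from oracles import sam_oracle

from lncarray import (
    ValidationError,
    gradual_modulation_check,
    quartile_stratify,
    sam_two_class,
    subgroup_contrasts,
    variability_filter,
)
from lncarray.sam import SAMTwoClass


def two_group_labels(mat, n1):
    ids = mat.sample_ids
    return pd.Series(["A"] * n1 + ["B"] * (len(ids) - n1), index=ids)


class TestVariabilityFilter:
    def test_constant_row_excluded(self):
        x = np.vstack([np.zeros(6), np.array([0, 2, 0, 2, 0, 2.0])])
        mat = make_matrix(x)
        assert variability_filter(mat) == [mat.feature_ids[1]]

    def test_boundary_row_kept(self):
        dev = np.log2(1.5)
        x = (np.array([1, -1, 1, -1.0]) * dev)[None, :]
        kept = variability_filter(make_matrix(x))
        assert len(kept) == 1  # mean |deviation| exactly log2(1.5)

    def test_matches_definition(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 12))
        mat = make_matrix(x)
        kept = set(variability_filter(mat))
        dev = np.abs(x - x.mean(axis=1, keepdims=True)).mean(axis=1)
        want = {f for f, d in zip(mat.feature_ids, dev) if d >= np.log2(1.5)}
        assert kept == want

    def test_bad_fold_errors(self):
        with pytest.raises(ValidationError):
            variability_filter(make_matrix(np.ones((2, 3))), fold=1.0)


class TestSamStatistic:
    def test_equal_group_means_give_zero_d(self):
        x = np.tile(np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]), (4, 1))
        mat = make_matrix(x)
        res = sam_two_class(mat, two_group_labels(mat, 3), n_permutations=20, seed=0)
        assert np.allclose(res.d, 0.0)
        up, down = res.called_at(0.1)
        assert up == [] and down == []

    def test_s0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 12))
        mat = make_matrix(x)
        res = sam_two_class(mat, two_group_labels(mat, 6), n_permutations=100,
                            seed=0, s0_mode=0.0)
        t_stats = np.array(
            [stats.ttest_ind(x[f, :6], x[f, 6:], equal_var=True).statistic
             for f in range(30)]
        )
        assert np.allclose(res.d, t_stats, atol=1e-10)

    def test_label_swap_negates_d_preserves_q(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(25, 10))
        x[:4, :5] += 1.5
        mat = make_matrix(x)
        labels = two_group_labels(mat, 5)
        res_ab = sam_two_class(mat, labels, groups=("A", "B"), n_permutations=252, seed=0)
        res_ba = sam_two_class(mat, labels, groups=("B", "A"), n_permutations=252, seed=0)
        assert np.allclose(res_ab.d, -res_ba.d, atol=1e-10)
        assert np.allclose(res_ab.q_values, res_ba.q_values, atol=1e-10)

    def test_fold_change_is_antilogged_mean_difference(self):
        rng = np.random.default_rng(3)
        x = rng.normal(7, 1, size=(10, 8))
        mat = make_matrix(x)
        res = sam_two_class(mat, two_group_labels(mat, 4), n_permutations=70, seed=0)
        assert np.allclose(res.fold_change, 2.0**res.numerator)
        assert (res.fold_change > 0).all()

    def test_input_validation(self):
        mat = make_matrix(np.ones((5, 6)))
        with pytest.raises(ValidationError):
            sam_two_class(mat, two_group_labels(mat, 1))  # group of 1
        with pytest.raises(ValidationError):
            sam_two_class(mat, two_group_labels(mat, 3), n_permutations=5)


class TestPermutationOracle:
    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n1 = n2 = 3 + seed % 2
        m = 8 + 2 * seed
        x = rng.normal(7, 1, size=(m, n1 + n2))
        if seed % 2 == 0:
            x[:2, :n1] += 2.0
        mat = make_matrix(x)
        res = sam_two_class(mat, two_group_labels(mat, n1), n_permutations=10_000, seed=0)
        want = sam_oracle(x, n1)
        assert res.exhaustive
        assert np.allclose(res.d, want["d"], atol=1e-9)
        assert np.allclose(res.dbar, want["dbar"], atol=1e-9)
        assert res.s0 == pytest.approx(want["s0"], abs=1e-12)
        assert res.pi0 == pytest.approx(want["pi0"], abs=1e-12)
        assert np.allclose(res.q_values, want["q"], atol=1e-9)

    def test_exhaustive_count_is_binomial_coefficient(self):
        mat = make_matrix(np.random.default_rng(0).normal(size=(8, 6)))
        res = sam_two_class(mat, two_group_labels(mat, 3), n_permutations=20, seed=0)
        assert res.exhaustive and res.n_permutations == 20  # C(6,3)


class TestDeltaTuning:
    def test_n_called_non_increasing_in_delta(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(60, 14))
        x[:6, :7] += 2.0
        mat = make_matrix(x)
        res = sam_two_class(mat, two_group_labels(mat, 7), n_permutations=300, seed=1)
        grid = res.delta_grid.sort_values("delta")
        assert (grid["n_called"].diff().dropna() <= 0).all()

    def test_null_data_q_target_zero_calls_nothing(self):
        rng = np.random.default_rng(6)
        mat = make_matrix(rng.normal(size=(100, 16)))
        res = sam_two_class(mat, two_group_labels(mat, 8), n_permutations=200, seed=2)
        _, up, down = res.tune_delta(0.0)
        assert len(up) + len(down) <= 1

    def test_planted_large_effects_recovered_at_near_zero_q(self):
        # with the permutation-average false-call estimate the attainable
        # q floor is ~pi0/B per called feature, so "q-value 0" screening is
        # exercised at a near-zero target; sensitivity aggregated over seeds
        planted = {f"F{i:04d}" for i in range(5)}
        hits = false_calls = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            x = rng.normal(7, 1, size=(40, 20))
            x[:5, :10] += 3.0
            mat = make_matrix(x)
            res = sam_two_class(mat, two_group_labels(mat, 10),
                                n_permutations=200, seed=seed)
            _, up, down = res.tune_delta(0.01)
            called = set(up) | set(down)
            hits += len(called & planted)
            false_calls += len(called - planted)
        assert hits / (20 * 5) >= 0.9
        assert false_calls <= 5


class TestSubgroupContrasts:
    def test_planted_flag_effect_tops_ranking(self):
        rng = np.random.default_rng(7)
        meta = make_metadata({"MM": 30})
        flags = pd.DataFrame(
            {g: False for g in
             ["HD", "t_11_14_or_6_14", "t_4_14", "t_14_16_or_14_20", "other",
              "del13", "del17", "gain1q"]},
            index=meta.sample_ids,
        )
        flags.loc[meta.sample_ids[:12], "HD"] = True
        flags["other"] = ~flags["HD"]
        meta.table = meta.table.join(flags)
        x = rng.normal(7, 0.5, size=(30, 30))
        x[:3, :12] += 2.0  # HD effect on first 3 features
        mat = make_matrix(x)
        results = subgroup_contrasts(mat, meta, n_permutations=100, seed=0, top_k=3)
        assert set(results["HD"].top) == {"F0000", "F0001", "F0002"}

    def test_degenerate_flag_skipped(self):
        meta = make_metadata({"MM": 10})
        for g in ["HD", "t_11_14_or_6_14", "t_4_14", "t_14_16_or_14_20", "other",
                  "del13", "del17", "gain1q"]:
            meta.table[g] = False
        meta.table["HD"] = True  # all-true -> degenerate
        meta.table["other"] = False
        mat = make_matrix(np.random.default_rng(8).normal(size=(10, 10)))
        results = subgroup_contrasts(mat, meta, n_permutations=100, seed=0)
        assert "HD" not in results


class TestQuartiles:
    def test_eight_distinct_values_quartiles_of_two(self):
        x = np.zeros((2, 8))
        x[0] = [3, 1, 7, 5, 2, 8, 6, 4]
        mat = make_matrix(x)
        labels = quartile_stratify(mat, mat.feature_ids[0])
        sizes = labels.labels.value_counts()
        assert sizes.to_dict() == {"I": 2, "II": 2, "III": 2, "IV": 2}
        assert set(labels.samples_in("I")) == {mat.sample_ids[1], mat.sample_ids[4]}
        assert set(labels.samples_in("IV")) == {mat.sample_ids[2], mat.sample_ids[5]}

    def test_all_ties_broken_by_sample_order(self):
        mat = make_matrix(np.zeros((1, 8)))
        labels = quartile_stratify(mat, mat.feature_ids[0])
        assert labels.samples_in("I") == mat.sample_ids[:2]
        assert labels.samples_in("IV") == mat.sample_ids[6:]

    def test_129_samples_split_33_32_32_32(self):
        rng = np.random.default_rng(9)
        mat = make_matrix(rng.normal(size=(1, 129)))
        labels = quartile_stratify(mat, mat.feature_ids[0])
        sizes = [len(labels.samples_in(q)) for q in ("I", "II", "III", "IV")]
        assert sizes == [33, 32, 32, 32]

    def test_too_few_samples_errors(self):
        with pytest.raises(ValidationError):
            quartile_stratify(make_matrix(np.zeros((1, 3))), "F0000")


class TestGradualModulation:
    def _with_quartile_medians(self, medians):
        # 8 samples: two per quartile carrying the target medians exactly
        x = np.repeat(np.asarray(medians, dtype=float), 2)[None, :]
        ranking = np.arange(8, dtype=float)[None, :]
        mat = make_matrix(np.vstack([ranking, x]))
        labels = quartile_stratify(mat, mat.feature_ids[0])
        return mat, labels

    def test_strictly_monotone_true(self):
        mat, labels = self._with_quartile_medians([1, 2, 3, 4])
        out = gradual_modulation_check(mat, labels, features=[mat.feature_ids[1]])
        assert bool(out.iloc[0])

    def test_non_monotone_false(self):
        mat, labels = self._with_quartile_medians([1, 3, 2, 4])
        out = gradual_modulation_check(mat, labels, features=[mat.feature_ids[1]])
        assert not bool(out.iloc[0])

    def test_null_rate_matches_exchangeable_orderings(self):
        # under exchangeability all 4! median orderings are equally likely;
        # 2 of 24 are strictly monotone
        rng = np.random.default_rng(10)
        hits, trials = 0, 400
        for _ in range(trials):
            x = np.vstack([np.arange(8.0), rng.normal(size=8)])
            mat = make_matrix(x)
            labels = quartile_stratify(mat, mat.feature_ids[0])
            hits += int(
                gradual_modulation_check(mat, labels, [mat.feature_ids[1]]).iloc[0]
            )
        expected = 2 / 24
        se = np.sqrt(expected * (1 - expected) / trials)
        assert abs(hits / trials - expected) < 4 * se
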