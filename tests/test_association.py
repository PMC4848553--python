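import numpy as np
import pytest
from scipy import stats

from radscreen import (
    BinaryFeatureMatrix,
    ICEstimator,
    MutationRecord,
    NFE2L2_KEAP1_BINDING_SITES,
    NamedMatrix,
    RegionRestriction,
    StatisticalPreconditionError,
    correlation_rank,
    information_coefficient,
    mutation_matrix,
    permutation_pvalue,
    rank_associations,
)
from radscreen.association import rank_inverse_normal


class TestMutationMatrix:
    def test_hand_built_grid(self):
        records = [
            MutationRecord("A", "S1"),
            MutationRecord("A", "S3"),
            MutationRecord("B", "S2"),
        ]
        m = mutation_matrix(records, ["S1", "S2", "S3"])
        assert m.feature_ids == ["A", "B"]
        np.testing.assert_array_equal(m.calls, [[1, 0, 1], [0, 1, 0]])

    def test_keap1_binding_site_restriction(self):
        # Nrf2 degron motifs D29LG / E79TGE -> residue ranges 29-31 and 79-82
        records = [
            MutationRecord("NFE2L2", "S1", protein_position=80),
            MutationRecord("NFE2L2", "S2", protein_position=200),
            MutationRecord("NFE2L2", "S3", protein_position=29),
        ]
        m = mutation_matrix(records, ["S1", "S2", "S3"], [NFE2L2_KEAP1_BINDING_SITES])
        restricted = m.feature("NFE2L2.keap1_sites")
        np.testing.assert_array_equal(restricted, [1, 0, 1])
        # the unrestricted row still counts every record
        np.testing.assert_array_equal(m.feature("NFE2L2"), [1, 1, 1])

    def test_record_without_position_never_satisfies_restriction(self):
        records = [MutationRecord("NFE2L2", "S1", protein_position=None)]
        m = mutation_matrix(records, ["S1"], [NFE2L2_KEAP1_BINDING_SITES])
        assert m.feature("NFE2L2.keap1_sites")[0] == 0
        assert m.feature("NFE2L2")[0] == 1

    def test_restriction_on_absent_gene_gives_empty_row(self, caplog):
        restriction = RegionRestriction("KEAP1", ((1, 100),))
        with caplog.at_level("WARNING"):
            m = mutation_matrix([MutationRecord("TP53", "S1")], ["S1", "S2"], [restriction])
        assert m.feature("KEAP1.1-100").sum() == 0
        assert "KEAP1" in caplog.text


class TestRankInverseNormal:
    def test_antisymmetric_bitwise(self, rng):
        x = rng.normal(size=31)
        np.testing.assert_array_equal(rank_inverse_normal(-x), -rank_inverse_normal(x))

    def test_monotone_and_rank_only(self, rng):
        x = rng.normal(size=20)
        z = rank_inverse_normal(x)
        assert np.array_equal(np.argsort(z), np.argsort(x))
        np.testing.assert_array_equal(rank_inverse_normal(np.exp(x)), z)


class TestInformationCoefficient:
    def test_self_feature_is_near_one(self):
        y = np.random.default_rng(7).normal(size=200)
        assert information_coefficient(y, y) >= 0.95

    def test_antisymmetry_is_exact(self, rng):
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        assert information_coefficient(x, -y) == -information_coefficient(x, y)
        c = (rng.random(60) < 0.3).astype(float)
        assert information_coefficient(c, -y) == -information_coefficient(c, y)

    def test_independent_pair_scores_near_zero(self):
        rng = np.random.default_rng(123)
        ic = information_coefficient(rng.normal(size=200), rng.normal(size=200))
        assert abs(ic) <= 0.15

    def test_monotone_rescaling_leaves_ic_unchanged(self, rng):
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        base = information_coefficient(x, y)
        assert information_coefficient(x, 3.5 * y + 11.0) == base
        assert information_coefficient(x, np.exp(y)) == base

    def test_binary_carrier_shift_is_detected(self, rng):
        c = np.zeros(100)
        c[rng.choice(100, 25, replace=False)] = 1
        y = rng.normal(size=100) + 2.0 * c
        assert information_coefficient(c, y) > 0.4

    def test_constant_inputs_signalled(self, rng):
        y = rng.normal(size=50)
        with pytest.raises(StatisticalPreconditionError):
            information_coefficient(np.full(50, 1.3), y)
        with pytest.raises(StatisticalPreconditionError):
            information_coefficient(y, np.zeros(50))

    def test_too_few_carriers_signalled(self, rng):
        c = np.zeros(50)
        c[0] = 1
        with pytest.raises(StatisticalPreconditionError):
            information_coefficient(c, rng.normal(size=50))

    def test_too_few_observations_signalled(self):
        with pytest.raises(StatisticalPreconditionError):
            information_coefficient(np.arange(5.0), np.arange(5.0))

    def test_batch_agrees_with_scalar_magnitudes(self, rng):
        est = ICEstimator()
        y = rng.normal(size=80)
        calls = (rng.random((6, 80)) < 0.3).astype(np.int8)
        batch = est.binary_ic_batch(calls, y)
        for i in range(6):
            assert abs(batch[i]) == pytest.approx(abs(est.ic(calls[i].astype(float), y)), abs=1e-9)


class TestPermutationPvalue:
    def test_planted_effect_reaches_minimum_p(self, rng):
        c = np.zeros(100)
        c[rng.choice(100, 20, replace=False)] = 1
        y = rng.normal(size=100)
        y = y + 3.0 * y.std(ddof=1) * c
        _, p = permutation_pvalue(c, y, n_perm=999, seed=5)
        assert p == pytest.approx(1 / 1000)

    def test_p_is_never_zero(self, rng):
        c = np.zeros(50)
        c[:25] = 1
        y = np.concatenate([np.zeros(25), np.ones(25)]) + rng.normal(0, 0.01, 50)
        _, p = permutation_pvalue(c, y, n_perm=99, seed=1)
        assert p >= 1 / 100

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            y = rng.normal(size=60)
            c = np.zeros(60)
            c[rng.choice(60, int(rng.integers(8, 25)), replace=False)] = 1
            _, p = permutation_pvalue(c, y, n_perm=99, seed=rng)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_directional_variant_is_anticonservative_by_design(self):
        # choosing the direction after seeing the data doubles the null
        # rejection rate; documents why the two-sided form is the default
        rng = np.random.default_rng(3)
        rej_dir = rej_two = 0
        for _ in range(300):
            y = rng.normal(size=60)
            c = np.zeros(60)
            c[rng.choice(60, 15, replace=False)] = 1
            _, p1 = permutation_pvalue(c, y, n_perm=99, seed=rng, two_sided=False)
            _, p2 = permutation_pvalue(c, y, n_perm=99, seed=rng, two_sided=True)
            rej_dir += p1 < 0.05
            rej_two += p2 < 0.05
        assert rej_dir / 300 > rej_two / 300


class TestRankAssociations:
    def test_planted_feature_ranks_first(self, rng):
        n = 100
        planted = np.zeros(n)
        planted[rng.choice(n, 20, replace=False)] = 1
        y = rng.normal(size=n) + 2.5 * planted
        calls = (rng.random((200, n)) < 0.25).astype(np.int8)
        calls[0] = planted
        m = BinaryFeatureMatrix([f"F{i}" for i in range(200)], [f"S{i}" for i in range(n)], calls)
        results, _ = rank_associations(m, y, direction="resistance")
        assert results[0].feature_id == "F0"
        assert results[0].direction == "resistance"

    def test_sensitivity_direction_reverses_order(self, rng):
        n = 60
        planted = np.zeros(n)
        planted[:15] = 1
        y = rng.normal(size=n) - 2.5 * planted
        calls = (rng.random((50, n)) < 0.3).astype(np.int8)
        calls[0] = planted
        m = BinaryFeatureMatrix([f"F{i}" for i in range(50)], [f"S{i}" for i in range(n)], calls)
        results, _ = rank_associations(m, y, direction="sensitivity")
        assert results[0].feature_id == "F0" and results[0].ic < 0

    def test_identical_features_adjacent_in_id_order(self, rng):
        n = 40
        c = (np.arange(n) < 12).astype(np.int8)
        y = rng.normal(size=n) + c
        m = BinaryFeatureMatrix(["zeta", "alpha"], [f"S{i}" for i in range(n)],
                                np.vstack([c, c]))
        results, _ = rank_associations(m, y)
        assert [r.feature_id for r in results] == ["alpha", "zeta"]
        assert results[0].ic == results[1].ic

    def test_failing_features_listed_and_all_failing_is_error(self, rng):
        n = 40
        y = rng.normal(size=n)
        good = (rng.random(n) < 0.4).astype(np.int8)
        single = np.zeros(n, dtype=np.int8)
        single[0] = 1
        m = BinaryFeatureMatrix(["ok", "solo"], [f"S{i}" for i in range(n)],
                                np.vstack([good, single]))
        results, excluded = rank_associations(m, y)
        assert excluded == ["solo"] and [r.feature_id for r in results] == ["ok"]
        m_bad = BinaryFeatureMatrix(["solo"], [f"S{i}" for i in range(n)], single[None, :])
        with pytest.raises(StatisticalPreconditionError):
            rank_associations(m_bad, y)

    def test_permutation_p_attached_when_requested(self, rng):
        n = 60
        c = np.zeros(n, dtype=np.int8)
        c[rng.choice(n, 20, replace=False)] = 1
        y = rng.normal(size=n) + 3.0 * c
        m = BinaryFeatureMatrix(["hit"], [f"S{i}" for i in range(n)], c[None, :])
        results, _ = rank_associations(m, y, n_perm=199, seed=0)
        assert results[0].p_value == pytest.approx(1 / 200)
        assert results[0].n_permutations == 199


class TestCorrelationRank:
    def test_feature_equal_to_phenotype_ranks_first(self, rng):
        y = rng.normal(size=20)
        values = np.vstack([y, rng.normal(size=(4, 20))])
        m = NamedMatrix([f"F{i}" for i in range(5)], [f"S{i}" for i in range(20)], values)
        table, dropped = correlation_rank(m, y, method="spearman")
        assert table.loc[0, "feature_id"] == "F0"
        assert table.loc[0, "coefficient"] == pytest.approx(1.0)
        assert table.loc[0, "rank"] == 1

    def test_constant_feature_dropped(self, rng):
        y = rng.normal(size=10)
        m = NamedMatrix(["const", "ok"], [f"S{i}" for i in range(10)],
                        np.vstack([np.full(10, 2.0), rng.normal(size=10)]))
        table, dropped = correlation_rank(m, y)
        assert dropped == ["const"] and list(table["feature_id"]) == ["ok"]

    def test_matches_closed_form_spearman(self, rng):
        y = rng.normal(size=12)
        values = rng.normal(size=(10, 12))
        m = NamedMatrix([f"F{i}" for i in range(10)], [f"S{i}" for i in range(12)], values)
        table, _ = correlation_rank(m, y, method="spearman")
        yr = np.argsort(np.argsort(y)) + 1
        for fid, coef in zip(table["feature_id"], table["coefficient"]):
            x = values[int(fid[1:])]
            xr = np.argsort(np.argsort(x)) + 1
            rho = 1 - 6 * np.sum((xr - yr) ** 2) / (12 * (12**2 - 1))
            assert coef == pytest.approx(rho, abs=1e-12)

    def test_incomplete_pairs_dropped(self, rng):
        y = rng.normal(size=6)
        row = rng.normal(size=6)
        row[[0, 1, 2, 3]] = np.nan  # only 2 complete pairs
        m = NamedMatrix(["sparse", "full"], [f"S{i}" for i in range(6)],
                        np.vstack([row, rng.normal(size=6)]))
        table, dropped = correlation_rank(m, y)
        assert dropped == ["sparse"]
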