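import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radscreen import (
    GeneSet,
    NamedMatrix,
    StatisticalPreconditionError,
    ValidationError,
    signature_summary,
    signature_vs_phenotype,
    ssgsea_project,
    ssgsea_score,
)


def expr_vector(values, prefix="G"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float)


def hand_unrolled_ssgsea(values, member_index, alpha):
    """Independent oracle: explicit walk down the sorted gene list."""
    n = len(values)
    ranks = stats.rankdata(values)            # highest expression -> rank n
    order = sorted(range(n), key=lambda i: -values[i])
    in_set = [i in member_index for i in order]
    weights = [ranks[i] ** alpha for i in order]
    denom_in = sum(w for w, m in zip(weights, in_set) if m)
    n_out = n - sum(in_set)
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for w, m in zip(weights, in_set):
        if m:
            cum_in += w / denom_in
        else:
            cum_out += 1.0 / n_out
        score += cum_in - cum_out
    return score


class TestSsgseaScore:
    def test_top_genes_score_positive_bottom_negative(self):
        vec = expr_vector(np.arange(20.0))     # G19 highest
        top = GeneSet("top", "", frozenset({f"G{i}" for i in range(15, 20)}))
        bottom = GeneSet("bottom", "", frozenset({f"G{i}" for i in range(5)}))
        assert ssgsea_score(vec, top).score > 0
        assert ssgsea_score(vec, bottom).score < 0

    def test_rank_transform_invariance_is_exact(self, rng):
        values = rng.normal(size=30)
        vec = expr_vector(values)
        gs = GeneSet("s", "", frozenset({f"G{i}" for i in range(7)}))
        base = ssgsea_score(vec, gs).score
        for transform in (np.exp, lambda v: 100 * v + 3, lambda v: v**3):
            assert ssgsea_score(expr_vector(transform(values)), gs).score == base

    def test_matches_hand_unrolled_oracle(self, rng):
        values = rng.normal(size=10)
        vec = expr_vector(values)
        gs = GeneSet("s", "", frozenset({"G1", "G4", "G7"}))
        result = ssgsea_score(vec, gs, alpha=0.25, min_set_size=3)
        expected = hand_unrolled_ssgsea(values, {1, 4, 7}, alpha=0.25)
        assert result.score == pytest.approx(expected, abs=1e-12)
        assert result.n_set_genes_used == 3

    def test_small_overlap_rejected(self):
        vec = expr_vector(np.arange(10.0))
        gs = GeneSet("tiny", "", frozenset({"G1", "G2"}))
        with pytest.raises(StatisticalPreconditionError):
            ssgsea_score(vec, gs)

    def test_set_covering_all_genes_rejected(self):
        vec = expr_vector(np.arange(6.0))
        gs = GeneSet("all", "", frozenset({f"G{i}" for i in range(6)}))
        with pytest.raises(ValidationError):
            ssgsea_score(vec, gs, min_set_size=3)


class TestSsgseaProject:
    def make_matrix(self, rng, n_genes=30, n_samples=4):
        return NamedMatrix(
            [f"G{i}" for i in range(n_genes)],
            [f"S{j}" for j in range(n_samples)],
            rng.normal(size=(n_genes, n_samples)),
        )

    def test_single_set_matches_scalar_op(self, rng):
        m = self.make_matrix(rng)
        gs = GeneSet("s", "", frozenset({f"G{i}" for i in range(8)}))
        projected, rejected = ssgsea_project(m, [gs])
        assert rejected == []
        for j, sid in enumerate(m.column_ids):
            scalar = ssgsea_score(pd.Series(m.values[:, j], index=m.row_ids), gs)
            assert projected.values[0, j] == pytest.approx(scalar.score)

    def test_permuting_samples_permutes_scores(self, rng):
        m = self.make_matrix(rng)
        gs = GeneSet("s", "", frozenset({f"G{i}" for i in range(8)}))
        projected, _ = ssgsea_project(m, [gs])
        perm = [2, 0, 3, 1]
        m_perm = NamedMatrix(m.row_ids, [m.column_ids[j] for j in perm], m.values[:, perm])
        projected_perm, _ = ssgsea_project(m_perm, [gs])
        np.testing.assert_array_equal(projected_perm.values[0], projected.values[0][perm])

    def test_three_sets_by_four_samples_fixture(self, rng):
        m = self.make_matrix(rng)
        sets = [
            GeneSet("a", "", frozenset({f"G{i}" for i in range(6)})),
            GeneSet("b", "", frozenset({f"G{i}" for i in range(10, 18)})),
            GeneSet("c", "", frozenset({f"G{i}" for i in range(20, 27)})),
        ]
        projected, _ = ssgsea_project(m, sets)
        assert projected.row_ids == ["a", "b", "c"]
        members = [{int(g[1:]) for g in s.members} for s in sets]
        for i, idx in enumerate(members):
            for j in range(4):
                expected = hand_unrolled_ssgsea(m.values[:, j], idx, alpha=0.25)
                assert projected.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_rejected_sets_reported_and_all_rejected_is_error(self, rng):
        m = self.make_matrix(rng)
        tiny = GeneSet("tiny", "", frozenset({"G0"}))
        ok = GeneSet("ok", "", frozenset({f"G{i}" for i in range(8)}))
        _, rejected = ssgsea_project(m, [tiny, ok])
        assert rejected == ["tiny"]
        with pytest.raises(StatisticalPreconditionError):
            ssgsea_project(m, [tiny])

    def test_random_set_null_distribution(self, rng):
        # with uniform weights (alpha=0) the random-set score is exactly
        # mean-zero; rank weighting (alpha=0.25) adds a known positive
        # offset that stays small relative to the null spread
        values = rng.normal(size=200)
        flat, weighted = [], []
        for _ in range(2000):
            members = set(rng.choice(200, size=15, replace=False).tolist())
            flat.append(hand_unrolled_ssgsea_fast(values, members, 0.0))
            weighted.append(hand_unrolled_ssgsea_fast(values, members, 0.25))
        flat = np.asarray(flat)
        weighted = np.asarray(weighted)
        assert abs(flat.mean()) < 3 * flat.std(ddof=1) / np.sqrt(flat.size)
        assert weighted.mean() > 0  # intrinsic offset of the rank weighting


def hand_unrolled_ssgsea_fast(values, member_index, alpha):
    from radscreen.signatures import _ssgsea_from_arrays

    in_set = np.zeros(len(values), dtype=bool)
    in_set[list(member_index)] = True
    return _ssgsea_from_arrays(np.asarray(values), in_set, alpha)


class TestSignatureSummary:
    def make_expression(self, rng, n_genes=5, n_samples=10):
        return NamedMatrix(
            [f"G{i}" for i in range(n_genes)],
            [f"S{j}" for j in range(n_samples)],
            rng.normal(5.0, 2.0, size=(n_genes, n_samples)),
        )

    def test_cohort_median_is_zero(self, rng):
        m = self.make_expression(rng)
        summary = signature_summary(m, {"sig": [f"G{i}" for i in range(5)]})
        assert np.median(summary.scores) == pytest.approx(0.0, abs=1e-12)

    def test_affine_rescaling_of_raw_expression_is_removed(self, rng):
        m = self.make_expression(rng)
        genes = [f"G{i}" for i in range(5)]
        base = signature_summary(m, {"sig": genes}).scores
        slopes = rng.uniform(0.5, 4.0, size=5)
        offsets = rng.normal(size=5)
        rescaled = NamedMatrix(
            m.row_ids, m.column_ids, m.values * slopes[:, None] + offsets[:, None]
        )
        np.testing.assert_allclose(signature_summary(rescaled, {"sig": genes}).scores,
                                   base, atol=1e-10)

    def test_shifted_sample_attains_maximum(self, rng):
        m = NamedMatrix(
            [f"G{i}" for i in range(5)],
            [f"S{j}" for j in range(50)],
            rng.normal(size=(5, 50)),
        )
        sds = m.values.std(axis=1, ddof=1)
        m.values[:, 7] += 5.0 * sds
        summary = signature_summary(m, {"sig": [f"G{i}" for i in range(5)]})
        assert int(np.argmax(summary.scores)) == 7

    def test_step_by_step_hand_computation(self, rng):
        m = self.make_expression(rng)
        genes = [f"G{i}" for i in range(5)]
        summary = signature_summary(m, {"sig": genes})
        z = (m.values - np.median(m.values, axis=1, keepdims=True)) / m.values.std(
            axis=1, ddof=1, keepdims=True
        )
        per_sample = z.mean(axis=0)
        expected = (per_sample - np.median(per_sample)) / per_sample.std(ddof=1)
        np.testing.assert_allclose(summary.scores, expected, atol=1e-12)

    def test_multiple_signatures_average(self, rng):
        m = self.make_expression(rng, n_genes=8)
        sigs = {"a": ["G0", "G1", "G2"], "b": ["G4", "G5", "G6", "G7"]}
        summary = signature_summary(m, sigs)
        parts = [signature_summary(m, {k: v}).scores for k, v in sigs.items()]
        np.testing.assert_allclose(summary.scores, np.mean(parts, axis=0), atol=1e-12)

    def test_zero_sd_gene_excluded_with_warning(self, rng, caplog):
        m = self.make_expression(rng)
        m.values[2] = 1.0  # constant gene
        with caplog.at_level("WARNING"):
            summary = signature_summary(m, {"sig": [f"G{i}" for i in range(5)]})
        assert "zero-SD" in caplog.text
        z = np.delete(m.values, 2, axis=0)
        z = (z - np.median(z, axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        per_sample = z.mean(axis=0)
        expected = (per_sample - np.median(per_sample)) / per_sample.std(ddof=1)
        np.testing.assert_allclose(summary.scores, expected, atol=1e-12)

    def test_signature_with_no_usable_genes_is_error(self, rng):
        m = self.make_expression(rng)
        with pytest.raises(StatisticalPreconditionError):
            signature_summary(m, {"sig": ["MISSING1", "MISSING2"]})


class TestSignatureVsPhenotype:
    def test_identical_score_and_phenotype(self, rng):
        m = NamedMatrix(["G0"], [f"S{j}" for j in range(10)], rng.normal(size=(1, 10)))
        summary = signature_summary(m, {"sig": ["G0"]})
        phenotype = summary.as_mapping()
        r, r2, table = signature_vs_phenotype(summary, phenotype)
        assert r2 == pytest.approx(1.0)

    def test_independent_phenotype_has_small_r_squared(self):
        rng = np.random.default_rng(99)
        m = NamedMatrix(
            [f"G{i}" for i in range(5)],
            [f"S{j}" for j in range(200)],
            rng.normal(size=(5, 200)),
        )
        summary = signature_summary(m, {"sig": [f"G{i}" for i in range(5)]})
        phenotype = {s: float(v) for s, v in zip(summary.sample_ids, rng.normal(size=200))}
        _, r2, _ = signature_vs_phenotype(summary, phenotype)
        assert r2 < 0.05

    def test_planted_program_recovers_association(self, planted_cohort):
        cohort = planted_cohort
        program = [gs for gs in cohort.gene_sets if gs.name == "KEAP1L_program"][0]
        summary = signature_summary(cohort.expression, {program.name: sorted(program.members)})
        r, r2, _ = signature_vs_phenotype(summary, cohort.truth.true_scores)
        assert r > 0 and r2 > 0.1
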