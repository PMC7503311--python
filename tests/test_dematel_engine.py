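import numpy as np
import pytest

from fdematel import (
    DEFAULT_SCALE,
    FuzzyMatrix,
    LinguisticScale,
    TriangularFuzzyNumber,
    average_panel,
    classify_and_rank,
    defuzzify_matrix,
    initial_matrix,
    normalization_factor,
    normalize,
    prominence_relation,
    ranking_by_prominence,
    run_pipeline,
    total_relation,
)
from fdematel.panel_io import ExpertPanel


def hollow(n, value, dtype=float):
    A = np.full((n, n), value, dtype=dtype)
    np.fill_diagonal(A, 0)
    return A


def neumann_series(C, terms=200):
    """Independent oracle: truncated series C + C^2 + ... + C^terms."""
    acc = np.zeros_like(C)
    power = np.eye(C.shape[0])
    for _ in range(terms):
        power = power @ C
        acc += power
    return acc


def random_hollow_matrix(rng, n, rho_target):
    A = rng.random((n, n))
    np.fill_diagonal(A, 0)
    rho = np.abs(np.linalg.eigvals(A)).max()
    return A * (rho_target / rho)


class TestInitialMatrix:
    def test_high_influence_everywhere(self, scale):
        Z = initial_matrix([["High influence"] * 2] * 2, scale)
        assert np.array_equal(Z.L, [[0, 0.5], [0.5, 0]])
        assert np.array_equal(Z.M, [[0, 0.75], [0.75, 0]])
        assert np.array_equal(Z.U, [[0, 1.0], [1.0, 0]])

    def test_diagonal_forced_to_crisp_zero(self, scale):
        Z = initial_matrix(
            [
                ["Very high influence", "High influence"],
                ["High influence", "Very high influence"],
            ],
            scale,
        )
        assert np.diag(Z.L).sum() == np.diag(Z.M).sum() == np.diag(Z.U).sum() == 0

    def test_no_influence_everywhere(self, scale):
        Z = initial_matrix([["No influence"] * 3] * 3, scale)
        assert not Z.L.any() and not Z.M.any()
        assert np.array_equal(Z.U, hollow(3, 0.25))

    def test_unknown_term_propagates(self, scale):
        with pytest.raises(KeyError, match="moderate"):
            initial_matrix([["x", "moderate influence"], ["x", "x"]], scale)


class TestNormalization:
    def test_factor_all_very_high_n14(self, scale):
        Z = initial_matrix([["Very high influence"] * 14] * 14, scale)
        assert normalization_factor(Z) == pytest.approx(13.0)

    def test_factor_is_max_upper_row_sum(self):
        Z = FuzzyMatrix([[0, 0.5], [0.3, 0]], [[0, 0.6], [0.4, 0]], [[0, 0.8], [0.6, 0]])
        assert normalization_factor(Z) == pytest.approx(0.8)

    def test_factor_all_no_influence_3x3(self, scale):
        Z = initial_matrix([["No influence"] * 3] * 3, scale)
        assert normalization_factor(Z) == pytest.approx(0.5)

    def test_all_zero_matrix_rejected(self):
        Z = FuzzyMatrix(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            normalization_factor(Z)

    def test_self_normalization_caps_upper_at_one(self):
        Z = FuzzyMatrix([[0, 0.5], [0.3, 0]], [[0, 0.6], [0.4, 0]], [[0, 0.8], [0.6, 0]])
        X = normalize(Z, normalization_factor(Z))
        assert X.U[0, 1] == pytest.approx(1.0)
        assert X.U.sum(axis=1).max() == pytest.approx(1.0)

    def test_crispness_preserved(self):
        A = hollow(3, 0.4)
        X = normalize(FuzzyMatrix(A, A, A), 2.0)
        assert np.array_equal(X.L, X.M) and np.array_equal(X.M, X.U)

    def test_scale_invariance(self, scale):
        Z = initial_matrix([["High influence", "Low influence", "No influence"],
                            ["Very low influence", "High influence", "Low influence"],
                            ["No influence", "Very high influence", "Low influence"]], scale)
        Z2 = FuzzyMatrix(2 * Z.L, 2 * Z.M, 2 * Z.U)
        X1 = normalize(Z, normalization_factor(Z))
        X2 = normalize(Z2, normalization_factor(Z2))
        assert np.allclose(X1.U, X2.U) and np.allclose(X1.L, X2.L)

    def test_nonpositive_factor_rejected(self):
        Z = FuzzyMatrix(hollow(2, 0.1), hollow(2, 0.2), hollow(2, 0.3))
        with pytest.raises(ValueError):
            normalize(Z, 0.0)


class TestAveragePanel:
    def test_single_matrix_identity(self):
        X = FuzzyMatrix(hollow(3, 0.1), hollow(3, 0.2), hollow(3, 0.3), "normalized")
        A = average_panel([X])
        assert np.array_equal(A.L, X.L) and np.array_equal(A.U, X.U)

    def test_midpoint_of_two(self):
        X0 = FuzzyMatrix(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)))
        X1 = FuzzyMatrix(hollow(2, 0.5), hollow(2, 0.5), hollow(2, 0.5))
        A = average_panel([X0, X1])
        assert np.array_equal(A.M, hollow(2, 0.25))
        assert np.diag(A.M).sum() == 0

    def test_permutation_invariant_in_expert_order(self):
        rng = np.random.default_rng(3)
        mats = []
        for _ in range(4):
            base = random_hollow_matrix(rng, 5, 0.3)
            mats.append(FuzzyMatrix(base * 0.8, base, base * 1.2))
        fwd = average_panel(mats)
        rev = average_panel(mats[::-1])
        assert np.allclose(fwd.L, rev.L) and np.allclose(fwd.U, rev.U)

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            average_panel([])
        a = FuzzyMatrix(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)))
        b = FuzzyMatrix(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            average_panel([a, b])


class TestTotalRelation:
    def test_crisp_2x2_closed_form(self):
        A = hollow(2, 0.5)
        T = total_relation(FuzzyMatrix(A, A, A, "averaged"))
        expected = np.array([[1 / 3, 2 / 3], [2 / 3, 1 / 3]])
        for C in T.components():
            assert np.allclose(C, expected, atol=1e-12)

    def test_zero_matrix_maps_to_zero(self):
        Z = np.zeros((4, 4))
        T = total_relation(FuzzyMatrix(Z, Z, Z, "averaged"))
        assert not T.L.any() and not T.U.any()

    def test_agrees_with_truncated_neumann_series(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            C = random_hollow_matrix(rng, n, rho_target=float(rng.uniform(0.2, 0.9)))
            T = total_relation(FuzzyMatrix(C, C, C, "averaged"))
            assert np.abs(T.M - neumann_series(C)).max() < 1e-9

    def test_component_order_preserved(self):
        rng = np.random.default_rng(5)
        base = random_hollow_matrix(rng, 6, 0.5)
        T = total_relation(FuzzyMatrix(base * 0.5, base * 0.8, base, "averaged"))
        assert (T.L <= T.M + 1e-12).all() and (T.M <= T.U + 1e-12).all()

    def test_divergent_component_rejected(self):
        A = hollow(3, 0.6)  # spectral radius 1.2
        with pytest.raises(ValueError, match="spectral radius"):
            total_relation(FuzzyMatrix(A * 0.1, A * 0.5, A, "averaged"))

    def test_monotone_in_entries(self):
        rng = np.random.default_rng(8)
        C = random_hollow_matrix(rng, 5, 0.5)
        bumped = C.copy()
        bumped[1, 3] += 0.05
        T0 = defuzzify_matrix(total_relation(FuzzyMatrix(C, C, C, "averaged")))
        T1 = defuzzify_matrix(total_relation(FuzzyMatrix(bumped, bumped, bumped, "averaged")))
        assert (T1 - T0).min() > -1e-12
        assert T1[1, 3] > T0[1, 3]


class TestDefuzzifyAndIndices:
    def test_crisp_matrix_unchanged(self):
        A = hollow(3, 0.2)
        T = FuzzyMatrix(A, A, A, "total")
        assert np.array_equal(defuzzify_matrix(T), A)

    def test_fixture_total_relation_cells(self, bundle):
        T = total_relation(bundle.aggregated)
        tprime = defuzzify_matrix(T)
        assert tprime[0, 0] == pytest.approx(0.194, abs=0.01)
        assert tprime[0, 1] == pytest.approx(0.243, abs=0.01)

    def test_published_matrix_row_and_column_sums(self, bundle):
        D, R, prom, rel = prominence_relation(bundle.expected_tprime)
        assert D[0] == pytest.approx(3.367, abs=0.01)
        assert R[0] == pytest.approx(3.315, abs=0.01)

    def test_symmetric_matrix_has_zero_relation(self):
        rng = np.random.default_rng(2)
        A = rng.random((5, 5))
        A = (A + A.T) / 2
        _, _, _, rel = prominence_relation(A)
        assert np.abs(rel).max() < 1e-12

    def test_two_by_two_hand_sums(self):
        D, R, prom, rel = prominence_relation(np.array([[1 / 3, 2 / 3], [2 / 3, 1 / 3]]))
        assert np.allclose(D, [1, 1]) and np.allclose(R, [1, 1])
        assert np.allclose(prom, [2, 2]) and np.allclose(rel, [0, 0])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            prominence_relation(np.ones((2, 3)))


class TestClassifyAndRank:
    def test_signs_define_groups(self):
        tprime = np.array([[0.0, 1.0], [0.2, 0.0]])  # D-R = (+0.8, -0.8)
        res = classify_and_rank(["A", "B"], tprime)
        assert res.group == ("cause", "effect")
        assert res.cause_group == ("A",)

    def test_zero_relation_is_effect_with_boundary_flag(self):
        tprime = np.array([[0.0, 0.5], [0.5, 0.0]])
        res = classify_and_rank(["A", "B"], tprime)
        assert res.group == ("effect", "effect")
        assert set(res.boundary_flags) == {"A", "B"}

    def test_prominence_ties_flagged_and_label_ordered(self):
        tprime = np.array([[0.0, 0.5], [0.5, 0.0]])
        res = classify_and_rank(["B", "A"], tprime)
        assert res.ranking == ("B", "A")  # input label order breaks the tie
        assert set(res.tie_flags) == {"A", "B"}

    def test_display_precision_ranking_rounds_before_sorting(self):
        ranking, ties = ranking_by_prominence(["A", "B"], np.array([1.0004, 1.0001]), decimals=3)
        assert ranking == ("A", "B")
        assert set(ties) == {"A", "B"}

    def test_conservation_identities(self):
        rng = np.random.default_rng(4)
        tprime = rng.random((8, 8))
        res = classify_and_rank([f"C{i}" for i in range(8)], tprime)
        assert abs(res.relation.sum()) < 1e-9
        assert res.D.sum() == pytest.approx(res.R.sum(), abs=1e-9)
        assert res.D.sum() == pytest.approx(tprime.sum(), abs=1e-9)


class TestRunPipeline:
    def test_fixture_prominence_of_top_criterion(self, bundle):
        res = run_pipeline(bundle.aggregated, criteria=bundle.criteria)
        i = bundle.criteria.index("C3")
        assert res.prominence[i] == pytest.approx(6.868, abs=0.05)

    def test_fixture_cause_group_matches_published_signs(self, bundle):
        res = run_pipeline(bundle.aggregated, criteria=bundle.criteria)
        assert set(res.cause_group) == {"C1", "C2", "C4", "C5", "C6", "C12"}

    def test_identical_experts_equal_single_expert(self, scale):
        rows = [
            ["-", "High influence", "Low influence"],
            ["Very low influence", "-", "Very high influence"],
            ["No influence", "Low influence", "-"],
        ]
        rows = [[c if c != "-" else "No influence" for c in r] for r in rows]
        one = ExpertPanel(("C1", "C2", "C3"), (tuple(map(tuple, rows)),))
        three = ExpertPanel(("C1", "C2", "C3"), (tuple(map(tuple, rows)),) * 3)
        res1 = run_pipeline(one, scale)
        res3 = run_pipeline(three, scale)
        assert np.allclose(res1.tprime, res3.tprime, atol=1e-12)

    def test_crisp_scale_reduces_to_classic_dematel(self, scale):
        # crisp scale: every term collapses to its modal value
        crisp = LinguisticScale(
            [(t, TriangularFuzzyNumber(v.m, v.m, v.m)) for t, v in
             zip(scale.terms, scale.values)]
        )
        rng = np.random.default_rng(9)
        n = 6
        terms = scale.terms
        rows = tuple(
            tuple(terms[int(rng.integers(0, len(terms)))] for _ in range(n))
            for _ in range(n)
        )
        panel = ExpertPanel(tuple(f"C{i}" for i in range(n)), (rows,))
        res = run_pipeline(panel, crisp)
        T = res.audit["total"]
        assert np.allclose(T.L, T.M) and np.allclose(T.M, T.U)

        # independent crisp route: plain DEMATEL on the modal ratings
        Z = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    Z[i, j] = crisp[rows[i][j]].m
        X = Z / Z.sum(axis=1).max()
        expected = neumann_series(X, terms=4000)
        assert np.abs(res.tprime - expected).max() < 1e-9

    def test_permutation_equivariance(self, bundle):
        rng = np.random.default_rng(7)
        perm = rng.permutation(14)
        agg = bundle.aggregated
        permuted = FuzzyMatrix(
            agg.L[np.ix_(perm, perm)], agg.M[np.ix_(perm, perm)],
            agg.U[np.ix_(perm, perm)], "averaged",
        )
        labels = tuple(bundle.criteria[i] for i in perm)
        base = run_pipeline(agg, criteria=bundle.criteria)
        moved = run_pipeline(permuted, criteria=labels)
        assert np.allclose(moved.tprime, base.tprime[np.ix_(perm, perm)], atol=1e-12)
        for c in bundle.criteria:
            i, j = bundle.criteria.index(c), labels.index(c)
            assert moved.relation[j] == pytest.approx(base.relation[i], abs=1e-12)
            assert moved.group[j] == base.group[i]
        assert moved.ranking == base.ranking

    def test_component_order_holds_at_every_stage(self, scale):
        rng = np.random.default_rng(12)
        terms = scale.terms
        rows = tuple(
            tuple(terms[int(rng.integers(0, len(terms)))] for _ in range(5))
            for _ in range(5)
        )
        panel = ExpertPanel(tuple(f"C{i}" for i in range(5)), (rows, rows))
        res = run_pipeline(panel, scale)
        stages = res.audit["initial"] + res.audit["normalized"] + [
            res.audit["averaged"], res.audit["total"]
        ]
        for fm in stages:
            assert (fm.L <= fm.M + 1e-12).all() and (fm.M <= fm.U + 1e-12).all()

    def test_audit_trail_records_all_stages(self, scale):
        panel = ExpertPanel(
            ("C1", "C2"),
            ((("No influence", "High influence"), ("Low influence", "No influence")),),
        )
        res = run_pipeline(panel, scale)
        assert set(res.audit) == {"initial", "normalized", "averaged", "total"}

    def test_panel_requires_scale(self, scale):
        panel = ExpertPanel(
            ("C1", "C2"),
            ((("No influence", "High influence"), ("Low influence", "No influence")),),
        )
        with pytest.raises(ValueError, match="scale"):
            run_pipeline(panel)
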