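import numpy as np
import pytest

from orientq.errors import FactorError
from orientq.factors import (
    CorrelationMatrix,
    FactorSolution,
    consensus_statements,
    correlate,
    distinguishing_statements,
    explained_variance_percentages,
    extract,
    factor_arrays,
    factor_zscores,
    flag_defining,
    kaiser_guttman_screen,
    manual_rotate,
    reliability,
    significance_threshold,
    varimax,
    varimax_criterion,
)
from orientq.qsort import QGrid, QSortMatrix, SimilarityScores, build_qsort_matrix


def qsorts_from_scores(matrix, grid):
    n_inst, n_stmt = matrix.shape
    scores = SimilarityScores(
        matrix=np.tanh(matrix),  # squash into the cosine range; ranks preserved
        institution_ids=[f"i{j}" for j in range(n_inst)],
        statement_ids=[f"s{j}" for j in range(n_stmt)],
    )
    return build_qsort_matrix(scores, grid)


@pytest.fixture
def grid11():
    return QGrid(column_values=np.arange(-5, 6), column_counts=np.ones(11, dtype=int))


class TestCorrelate:
    def test_identical_and_negated_columns(self, grid11):
        rng = np.random.default_rng(0)
        row = rng.normal(size=11)
        qs = qsorts_from_scores(np.vstack([row, row, -row]), grid11)
        R = correlate(qs)
        assert R.values[0, 1] == pytest.approx(1.0)
        assert R.values[0, 2] == pytest.approx(-1.0)  # symmetric grid

    def test_hand_computed_pearson(self, grid11):
        rng = np.random.default_rng(1)
        qs = qsorts_from_scores(rng.normal(size=(2, 11)), grid11)
        x, y = qs.values[:, 0].astype(float), qs.values[:, 1].astype(float)
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
        )
        assert correlate(qs).values[0, 1] == pytest.approx(r_hand, abs=1e-12)

    def test_single_institution_rejected(self, grid11):
        qs = qsorts_from_scores(np.zeros((1, 11)), grid11)
        with pytest.raises(FactorError):
            correlate(qs)


class TestExtract:
    def test_identity_matrix(self):
        R = CorrelationMatrix(np.eye(4), [f"i{j}" for j in range(4)])
        sol = extract(R, 4, n_statements=54)
        assert np.allclose(sol.eigenvalues, 1.0)
        assert np.allclose(sol.explained_variance_pct(), 25.0)

    def test_all_ones_two_by_two(self):
        R = CorrelationMatrix(np.ones((2, 2)), ["a", "b"])
        sol = extract(R, 2, n_statements=54)
        assert np.allclose(sol.eigenvalues, [2.0, 0.0], atol=1e-12)

    def test_non_symmetric_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(FactorError, match="symmetric"):
            CorrelationMatrix(bad, ["a", "b", "c"])

    def test_loadings_reconstruct_eigenpairs(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(6, 6))
        R = A @ A.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        sol = extract(CorrelationMatrix(R, [f"i{j}" for j in range(6)]), 6, 54)
        assert np.allclose(sol.loadings @ sol.loadings.T, R, atol=1e-9)

    def test_published_style_variance_rounding(self):
        eigs = [187.302, 92.909, 39.265, 15.6638]
        pct, cum = explained_variance_percentages(eigs, 389)
        assert pct.tolist() == [48, 24, 10, 4]
        assert cum == 86


class TestThresholdAndScreen:
    @pytest.mark.parametrize(
        "n, z, expected",
        [(54, 2.58, 0.351), (36, 2.58, 0.43), (25, 1.96, 0.392)],
    )
    def test_significance_threshold(self, n, z, expected):
        assert significance_threshold(n, z) == pytest.approx(expected, abs=5e-4)

    def test_identity_admits_zero_factors(self):
        R = CorrelationMatrix(np.eye(5), [f"i{j}" for j in range(5)])
        sol = extract(R, 5, n_statements=54)
        assert kaiser_guttman_screen(sol) == 0  # eigenvalues exactly 1.0 fail strict >

    def test_perfect_clone_group_admits_one_factor(self):
        R = np.eye(5)
        R[:3, :3] = 1.0  # three identical sorts
        sol = extract(CorrelationMatrix(R, [f"i{j}" for j in range(5)]), 5, 54)
        assert sol.eigenvalues[0] == pytest.approx(3.0)
        assert kaiser_guttman_screen(sol) == 1


def planar_grid_max(L, step=1e-4):
    """Brute-force varimax oracle for 2 factors: scan the rotation angle."""
    thetas = np.arange(0.0, np.pi / 2, step)
    cos, sin = np.cos(thetas), np.sin(thetas)
    x, y = L[:, 0], L[:, 1]
    xr = x[:, None] * cos - y[:, None] * sin
    yr = x[:, None] * sin + y[:, None] * cos
    h = np.sqrt(x**2 + y**2)[:, None]
    xr, yr = xr / h, yr / h  # Kaiser normalization
    crit = ((xr**2).var(axis=0)) + ((yr**2).var(axis=0))
    return crit.max()


class TestVarimax:
    def test_single_factor_unchanged(self):
        L = np.array([[0.5], [0.7], [-0.2]])
        rotated, rot = varimax(L)
        assert np.allclose(rotated, L)
        assert np.allclose(rot, np.eye(1))

    def test_communalities_preserved(self):
        rng = np.random.default_rng(3)
        L = rng.normal(size=(12, 3))
        rotated, rot = varimax(L)
        assert np.allclose(
            np.sum(rotated**2, axis=1), np.sum(L**2, axis=1), atol=1e-9
        )
        assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-9)
        assert np.allclose(L @ rot, rotated, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_criterion_matches_planar_angle_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.normal(size=(8, 2))
        rotated, _ = varimax(L)
        assert varimax_criterion(rotated) == pytest.approx(
            planar_grid_max(L), abs=1e-6
        )

    def test_agrees_with_statsmodels_rotation(self):
        """Independent cross-check against statsmodels' varimax."""
        from statsmodels.multivariate.factor_rotation import rotate_factors

        rng = np.random.default_rng(4)
        L = rng.normal(size=(10, 3))
        ours, _ = varimax(L, kaiser=False)
        theirs, _ = rotate_factors(L, "varimax")
        assert varimax_criterion(ours, kaiser=False) == pytest.approx(
            varimax_criterion(theirs, kaiser=False), abs=1e-8
        )


class TestManualRotate:
    def test_zero_angle_is_identity(self):
        L = np.random.default_rng(0).normal(size=(6, 3))
        assert np.allclose(manual_rotate(L, 0, 1, 0.0), L)

    def test_rotation_inverse(self):
        L = np.random.default_rng(1).normal(size=(6, 4))
        back = manual_rotate(manual_rotate(L, 0, 3, 2.0), 0, 3, -2.0)
        assert np.allclose(back, L, atol=1e-12)

    def test_cw_direction_flips_sign(self):
        L = np.random.default_rng(2).normal(size=(5, 2))
        assert np.allclose(
            manual_rotate(L, 0, 1, 2.0, direction="cw"),
            manual_rotate(L, 0, 1, -2.0),
        )

    def test_communalities_invariant(self):
        L = np.random.default_rng(3).normal(size=(7, 3))
        rotated = manual_rotate(L, 1, 2, 37.5)
        assert np.allclose(
            np.sum(rotated**2, axis=1), np.sum(L**2, axis=1), atol=1e-12
        )

    def test_out_of_range_factor_rejected(self):
        L = np.zeros((4, 2))
        with pytest.raises(FactorError):
            manual_rotate(L, 0, 2, 2.0)
        with pytest.raises(FactorError):
            manual_rotate(L, 1, 1, 2.0)


class TestFlagDefining:
    def test_majority_communality_example(self):
        # h2 = 0.65; 0.64 > 0.325 -> defining on factor 1
        flags = flag_defining(np.array([[0.8, 0.1]]), threshold=0.351)
        assert flags.flags.tolist() == [[True, False]]

    def test_exact_half_communality_not_flagged(self):
        flags = flag_defining(np.array([[0.5, 0.5]]), threshold=0.351)
        assert not flags.flags.any()

    def test_below_threshold_not_flagged(self):
        flags = flag_defining(np.array([[0.3, 0.2]]), threshold=0.351)
        assert not flags.flags.any()

    def test_at_most_one_flag_per_row(self):
        rng = np.random.default_rng(5)
        flags = flag_defining(rng.normal(scale=0.5, size=(50, 4)), threshold=0.351)
        assert np.all(flags.flags.sum(axis=1) <= 1)


class TestFactorScores:
    def test_single_defining_sort_standardizes_raw_sort(self, grid11):
        rng = np.random.default_rng(0)
        qs = qsorts_from_scores(rng.normal(size=(3, 11)), grid11)
        loadings = np.array([[0.9], [0.1], [0.05]])
        from orientq.factors import FlagMatrix

        flags = FlagMatrix(np.array([[True], [False], [False]]))
        z = factor_zscores(qs, flags, loadings)
        raw = qs.values[:, 0].astype(float)
        assert np.allclose(z[:, 0], (raw - raw.mean()) / raw.std())

    def test_two_identical_defining_sorts_match_single(self, grid11):
        row = np.linspace(-1, 1, 11)
        qs = qsorts_from_scores(np.vstack([row, row]), grid11)
        from orientq.factors import FlagMatrix

        both = FlagMatrix(np.array([[True], [True]]))
        one = FlagMatrix(np.array([[True], [False]]))
        z_both = factor_zscores(qs, both, np.array([[0.9], [0.6]]))
        z_one = factor_zscores(qs, one, np.array([[0.9], [0.6]]))
        assert np.allclose(z_both, z_one)

    def test_brown_weight_formula(self):
        f = 0.707
        assert f / (1 - f**2) == pytest.approx(1.414, abs=5e-3)

    def test_no_defining_sorts_error_names_factor(self, grid11):
        qs = qsorts_from_scores(np.zeros((2, 11)), grid11)
        from orientq.factors import FlagMatrix

        flags = FlagMatrix(np.array([[False], [False]]))
        with pytest.raises(FactorError, match="factor 1"):
            factor_zscores(qs, flags, np.array([[0.2], [0.1]]))

    def test_zscores_standardized(self, grid11):
        rng = np.random.default_rng(1)
        qs = qsorts_from_scores(rng.normal(size=(6, 11)), grid11)
        from orientq.factors import FlagMatrix

        flags = FlagMatrix(
            np.array([[True, False]] * 3 + [[False, True]] * 3)
        )
        loadings = np.array([[0.8, 0.1]] * 3 + [[0.1, 0.8]] * 3)
        z = factor_zscores(qs, flags, loadings)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-9)


class TestFactorArrays:
    def test_grid_reimposed_with_ties_by_index(self, grid11):
        z = np.array([[2.0, 0.5], [2.0, 0.5]] + [[-v, 0.1 * v] for v in range(1, 10)])
        arrays = factor_arrays(z, grid11)
        # top two z tie -> statement 0 gets +5, statement 1 gets +4
        assert arrays[0, 0] == 5 and arrays[1, 0] == 4
        for f in range(2):
            assert sorted(arrays[:, f].tolist()) == list(range(-5, 6))

    def test_top_z_gets_top_level(self, grid11):
        z = np.linspace(1, -1, 11)[:, None]
        arrays = factor_arrays(z, grid11)
        assert arrays[0, 0] == 5 and arrays[-1, 0] == -5


class TestReliability:
    def test_single_sort_spearman_brown(self):
        r = reliability([1])
        assert r.composite_reliability[0] == pytest.approx(0.8)
        assert r.se_zscores[0] == pytest.approx(np.sqrt(0.2), abs=5e-4)

    def test_monotone_in_p(self):
        r = reliability(np.arange(1, 40))
        assert np.all(np.diff(r.composite_reliability_raw) > 0)
        assert np.all(np.diff(np.sqrt(1 - r.composite_reliability_raw)) < 0)

    def test_zero_defining_sorts_rejected(self):
        with pytest.raises(FactorError):
            reliability([3, 0])


class TestDistinguishingConsensus:
    def rel(self, p):
        return reliability(p)

    def test_identical_columns_no_distinguishing_all_consensus(self):
        z = np.tile(np.linspace(-1, 1, 11)[:, None], (1, 2))
        rel = self.rel([180, 180])
        dist = distinguishing_statements(z, rel)
        assert dist == [[], []]
        assert consensus_statements(z, rel) == list(range(11))

    def test_sed_arithmetic_boundary(self):
        """SE 0.032 each -> SED 0.04525; |dz|=0.10 is significant at 0.05
        (1.96*SED=0.0887) but not at 0.01 (2.58*SED=0.1168)."""
        rel = self.rel([180, 180])  # both SE 0.032
        z = np.zeros((3, 2))
        z[0, 0] = 0.10
        dist = distinguishing_statements(z, rel)
        assert (0, 0.05) in dist[0]
        assert (0, 0.01) not in dist[0]
        assert consensus_statements(z, rel) == [1, 2]

    def test_single_factor_consensus_undefined(self):
        with pytest.raises(FactorError):
            consensus_statements(np.zeros((5, 1)), self.rel([10]))


class TestEigenInvariants:
    def test_trace_conservation_for_correlation_matrices(self, grid11):
        rng = np.random.default_rng(9)
        qs = qsorts_from_scores(rng.normal(size=(8, 11)), grid11)
        R = correlate(qs)
        eigs = np.linalg.eigvalsh(R.values)
        assert eigs.sum() == pytest.approx(8.0, abs=1e-9)

    @pytest.mark.parametrize("dim", [3, 4, 5])
    def test_eigenvalues_match_characteristic_polynomial(self, dim):
        rng = np.random.default_rng(dim)
        A = rng.normal(size=(dim, dim))
        S = (A + A.T) / 2
        eigs = np.sort(np.linalg.eigvalsh(S))
        roots = np.sort(np.real(np.roots(np.poly(S))))
        assert np.allclose(eigs, roots, atol=1e-8)

    def test_rotation_preserves_retained_block_variance(self):
        rng = np.random.default_rng(10)
        L = rng.normal(size=(10, 3))
        sol = FactorSolution(
            loadings=L,
            eigenvalues=np.sort(np.sum(L**2, axis=0))[::-1],
            n_statements=54,
        )
        from orientq.factors import manual_rotate_solution, varimax_solution

        rotated = manual_rotate_solution(varimax_solution(sol), 0, 2, 13.0)
        assert np.sum(rotated.loadings**2) == pytest.approx(np.sum(L**2), abs=1e-9)
        assert rotated.rotation_log[0][0] == "varimax"
        assert rotated.rotation_log[1][0] == "manual"
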