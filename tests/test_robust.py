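import numpy as np
import pytest

from icasig.robust import (
    ComponentSet,
    SimilarityMatrix,
    cluster_components,
    medoid_of,
    robust_signatures_for_n,
    run_ica_once,
    sign_correct,
    similarity_matrix,
    stability_index,
)
from icasig.simulate import generate_mixture, match_signatures


def brute_force_stability(members, sim):
    """Literal double-loop evaluation of the cluster stability index."""
    members = set(members)
    outside = set(range(len(sim))) - members
    intra = sum(sim.values[i, j] for i in members for j in members)
    intra /= len(members) ** 2
    if not outside:
        return intra
    extra = sum(sim.values[i, j] for i in members for j in outside)
    extra /= len(members) * len(outside)
    return intra - extra


def brute_force_medoid(members, sim):
    members = sorted(members)
    best, best_sum = None, -np.inf
    for i in members:
        s = sum(sim.values[i, j] for j in members)
        if s > best_sum + 1e-15:
            best, best_sum = i, s
    return best


def random_similarity(rng, m):
    a = rng.uniform(0, 1, size=(m, m))
    s = (a + a.T) / 2
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(values=s)


@pytest.fixture(scope="module")
def planted():
    return generate_mixture(800, 40, r=3, noise_sd=0.0, sparsity=0.0, seed=5)


@pytest.fixture(scope="module")
def planted4():
    return generate_mixture(800, 40, r=4, noise_sd=0.0, sparsity=0.0, seed=9)


class TestRunIcaOnce:
    def test_same_seed_bitwise_identical(self, planted):
        a = run_ica_once(planted.expression, 3, seed=11)
        b = run_ica_once(planted.expression, 3, seed=11)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        np.testing.assert_array_equal(a.mixing, b.mixing)

    def test_recovers_planted_sources(self, planted):
        cs = run_ica_once(planted.expression, 3, seed=2)
        matches = match_signatures(cs.loadings, planted.true_loadings)
        assert (matches.abs_pearson > 0.99).all()
        assert matches.truth.nunique() == 3

    def test_noiseless_reconstruction(self, planted):
        cs = run_ica_once(planted.expression, 3, seed=2)
        assert cs.residual < 1e-6

    def test_unit_variance_loadings(self, planted):
        cs = run_ica_once(planted.expression, 3, seed=2)
        np.testing.assert_allclose(cs.loadings.std(axis=0), 1.0, rtol=1e-10)

    def test_invalid_n_rejected(self, planted):
        with pytest.raises(ValueError):
            run_ica_once(planted.expression, 1, seed=0)
        with pytest.raises(ValueError):
            run_ica_once(planted.expression, 40, seed=0)


class TestSignCorrect:
    def make_set(self, loadings, mixing):
        return ComponentSet(
            n_components=loadings.shape[1],
            loadings=loadings,
            mixing=mixing,
            run_seed=0,
            residual=0.0,
        )

    def test_negative_skew_flipped_product_unchanged(self, rng):
        col = -np.abs(rng.laplace(size=300))  # strongly negative skew
        loadings = np.column_stack([col, rng.laplace(size=300)])
        mixing = rng.standard_normal((2, 7))
        cs = self.make_set(loadings, mixing)
        out = sign_correct(cs)
        assert np.all(out.loadings[:, 0] == -loadings[:, 0])
        np.testing.assert_allclose(out.loadings @ out.mixing, loadings @ mixing)

    def test_idempotent(self, rng):
        cs = self.make_set(rng.laplace(size=(200, 4)), rng.standard_normal((4, 9)))
        once = sign_correct(cs)
        twice = sign_correct(once)
        np.testing.assert_array_equal(once.loadings, twice.loadings)
        np.testing.assert_array_equal(once.mixing, twice.mixing)

    def test_symmetric_column_tie_break(self):
        # perfectly symmetric values -> zero skew; max-|loading| is negative
        col = np.array([-5.0, 5.0, -1.0, 1.0, -5.0, 5.0, 0.0, -5.0, 5.0, 0.0])
        assert abs(float(np.mean(((col - col.mean()) / col.std()) ** 3))) < 1e-8
        cs = self.make_set(col[:, None].copy(), np.ones((1, 3)))
        out = sign_correct(cs)
        # largest-absolute entry must end up positive
        assert out.loadings[np.argmax(np.abs(out.loadings[:, 0])), 0] > 0


class TestSimilarityMatrix:
    def test_sign_invariance(self, rng):
        v = rng.standard_normal(100)
        sim = similarity_matrix([v, -v])
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_matches_textbook_pearson(self):
        vectors = [
            np.array([1.0, 2, 3, 4, 5, 6]),
            np.array([2.0, 1, 4, 3, 6, 5]),
            np.array([-1.0, 5, 2, 8, 0, 3]),
            np.array([6.0, 5, 4, 3, 2, 1]),
            np.array([1.5, -2, 0, 7, 7, -1]),
        ]
        sim = similarity_matrix(vectors)
        for i, vi in enumerate(vectors):
            for j, vj in enumerate(vectors):
                xm, ym = vi - vi.mean(), vj - vj.mean()
                r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
                assert sim.values[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_independent_vectors_near_zero(self, rng):
        sim = similarity_matrix(rng.standard_normal((10000, 4)))
        off = sim.values[np.triu_indices(4, k=1)]
        assert off.max() < 0.05

    def test_constant_vector_named(self, rng):
        with pytest.raises(ValueError, match="component 1"):
            similarity_matrix([rng.standard_normal(20), np.full(20, 2.0)])

    def test_bounds_and_symmetry(self, rng):
        sim = similarity_matrix(rng.standard_normal((50, 8)))
        assert np.all(sim.values >= 0) and np.all(sim.values <= 1)
        np.testing.assert_array_equal(sim.values, sim.values.T)
        np.testing.assert_array_equal(np.diag(sim.values), np.ones(8))


class TestClusterComponents:
    def bundles(self, rng, sizes, dim=500):
        cols, truth = [], []
        for b, size in enumerate(sizes):
            base = rng.standard_normal(dim)
            for _ in range(size):
                cols.append(base + 0.01 * rng.standard_normal(dim))
                truth.append(b)
        return np.column_stack(cols), np.array(truth)

    def test_planted_partition_recovered(self, rng):
        comps, truth = self.bundles(rng, [5, 7])
        clusters = cluster_components(similarity_matrix(comps), 2)
        got = {frozenset(c.member_indices) for c in clusters}
        expected = {frozenset(np.nonzero(truth == b)[0].tolist()) for b in (0, 1)}
        assert got == expected

    def test_all_singletons(self, rng):
        sim = similarity_matrix(rng.standard_normal((300, 6)))
        clusters = cluster_components(sim, 6)
        assert sorted(len(c.member_indices) for c in clusters) == [1] * 6

    def test_input_order_invariance(self, rng):
        comps, _ = self.bundles(rng, [4, 3, 5])
        perm = rng.permutation(comps.shape[1])
        direct = cluster_components(similarity_matrix(comps), 3)
        shuffled = cluster_components(similarity_matrix(comps[:, perm]), 3)
        direct_sets = {frozenset(c.member_indices) for c in direct}
        mapped = {
            frozenset(int(perm[i]) for i in c.member_indices) for c in shuffled
        }
        assert direct_sets == mapped


class TestMedoid:
    def test_singleton(self, rng):
        sim = random_similarity(rng, 5)
        assert medoid_of({3}, sim) == 3

    def test_three_member_hand_case(self):
        s = np.eye(4)
        s[0, 1] = s[1, 0] = 0.9
        s[0, 2] = s[2, 0] = 0.9
        s[1, 2] = s[2, 1] = 0.5
        assert medoid_of({0, 1, 2}, SimilarityMatrix(values=s)) == 0

    def test_agrees_with_brute_force(self, rng):
        for _ in range(50):
            sim = random_similarity(rng, 12)
            members = rng.choice(12, size=8, replace=False)
            assert medoid_of(set(members), sim) == brute_force_medoid(members, sim)


class TestStabilityIndex:
    def test_perfect_cluster_is_one(self):
        s = np.zeros((6, 6))
        s[:3, :3] = 1.0
        np.fill_diagonal(s, 1.0)
        assert stability_index({0, 1, 2}, SimilarityMatrix(values=s)) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # cluster {0,1}: intra (1+1+0.8+0.8)/4=0.9, extra 4*0.1/(2*2)=0.1
        s = np.eye(4)
        s[0, 1] = s[1, 0] = 0.8
        for i in (0, 1):
            for j in (2, 3):
                s[i, j] = s[j, i] = 0.1
        s[2, 3] = s[3, 2] = 0.4
        assert stability_index({0, 1}, SimilarityMatrix(values=s)) == pytest.approx(0.8)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            m = int(rng.integers(3, 15))
            sim = random_similarity(rng, m)
            size = int(rng.integers(1, m + 1))
            members = set(rng.choice(m, size=size, replace=False).tolist())
            assert stability_index(members, sim) == pytest.approx(
                brute_force_stability(members, sim), abs=1e-12
            )

    def test_never_exceeds_one(self, rng):
        for _ in range(50):
            sim = random_similarity(rng, 10)
            members = set(rng.choice(10, size=4, replace=False).tolist())
            assert stability_index(members, sim) <= 1.0 + 1e-12

    def test_whole_set_cluster_has_no_extra_term(self, rng):
        sim = random_similarity(rng, 6)
        expected = sim.values.sum() / 36
        assert stability_index(set(range(6)), sim) == pytest.approx(expected)


class TestRobustSignaturesForN:
    def test_planted_sources_recovered(self, planted4):
        sigs = robust_signatures_for_n(planted4.expression, 4, runs=20, base_seed=100)
        assert len(sigs) == 4
        assert all(s.stability > 0.95 for s in sigs)
        est = np.column_stack([s.gene_loadings for s in sigs])
        matches = match_signatures(est, planted4.true_loadings)
        assert (matches.abs_pearson > 0.95).all()
        assert matches.truth.nunique() == 4

    def test_threshold_one_empty(self, planted4):
        with pytest.warns(UserWarning, match="threshold"):
            sigs = robust_signatures_for_n(
                planted4.expression, 4, runs=5, threshold=1.0, base_seed=0
            )
        assert sigs == []

    def test_doubling_runs_keeps_matched_sources(self, planted4):
        matched = []
        for runs in (10, 20):
            sigs = robust_signatures_for_n(planted4.expression, 4, runs=runs, base_seed=7)
            est = np.column_stack([s.gene_loadings for s in sigs])
            m = match_signatures(est, planted4.true_loadings)
            matched.append(set(m.truth[m.abs_pearson > 0.9]))
        assert matched[0] == matched[1] == {0, 1, 2, 3}

    def test_scores_consistent_with_loading_projection(self, planted4):
        sigs = robust_signatures_for_n(planted4.expression, 4, runs=10, base_seed=3)
        centered = planted4.expression.values - planted4.expression.values.mean(
            axis=1, keepdims=True
        )
        for s in sigs:
            projection = s.gene_loadings @ centered
            r = np.corrcoef(projection, s.sample_scores)[0, 1]
            assert r > 0
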