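"""Odd-one-out prediction, RSA scoring, layer selection, variance
partitioning, and ridge attribute probes."""

import numpy as np
import pytest

from repalign import (
    EmbeddingSet,
    linear_probe,
    make_attributes,
    make_embeddings,
    make_world,
    ooo_accuracy,
    predict_odd_one_out,
    rank_correlation,
    rsa_alignment,
    rsm_from_embeddings,
    select_layer,
    similarity_to_rdm,
    simulate_judgments,
    variance_partition,
)
from repalign.geometry import cosine_similarity
from repalign.judgments import DissimilarityMatrix, SimilarityMatrix, ValidationError
from repalign.synthetic import SimulationConfig

from conftest import random_judgment_set


class TestPredictOddOneOut:
    def test_near_parallel_pair(self):
        E = EmbeddingSet(["a", "b", "c"], np.array([[1, 0], [1, 0.01], [0, 1.0]]))
        assert predict_odd_one_out(E, ("a", "b", "c")) == "c"

    def test_orthogonal_tie_lexicographic(self):
        E = EmbeddingSet(["a", "b", "c"], np.eye(3))
        assert predict_odd_one_out(E, ("a", "b", "c")) == "a"

    def test_unknown_item_rejected(self):
        E = EmbeddingSet(["a", "b"], np.eye(2))
        with pytest.raises(ValidationError):
            predict_odd_one_out(E, ("a", "b", "z"))

    def test_agrees_with_bruteforce_argmax(self, rng):
        items = [f"v{k}" for k in range(20)]
        E = EmbeddingSet(items, rng.standard_normal((20, 6)))
        for _ in range(100):
            a, b, c = (items[k] for k in rng.choice(20, 3, replace=False))
            sims = {
                c: cosine_similarity(E.vector(a), E.vector(b)),
                b: cosine_similarity(E.vector(a), E.vector(c)),
                a: cosine_similarity(E.vector(b), E.vector(c)),
            }
            best = max(sims.values())
            expect = min(k for k, v in sims.items() if v == best)
            assert predict_odd_one_out(E, (a, b, c)) == expect


class TestOooAccuracy:
    def test_perfect_on_deterministic_world(self):
        world = make_world(n_items=15, q=3, tau=1e-9, seed=2)  # deterministic choices
        js = simulate_judgments(world, SimulationConfig(n_triplets=500, seed=2))
        factors = EmbeddingSet(list(world.items), world.factors)
        assert ooo_accuracy(factors, js) == 1.0

    def test_chance_level_for_random_pairing(self, rng):
        js = random_judgment_set(np.random.default_rng(0), n_items=30, n_trials=10_000)
        E = EmbeddingSet(js.catalogue, rng.standard_normal((30, 8)))
        acc = ooo_accuracy(E, js)
        assert acc == pytest.approx(1 / 3, abs=0.02)

    def test_missing_embeddings_is_error_not_skip(self, rng):
        js = random_judgment_set(rng, 6, 20)
        E = EmbeddingSet(js.catalogue[:-1], np.eye(5))
        with pytest.raises(ValidationError):
            ooo_accuracy(E, js)

    def test_matches_per_triplet_predictions(self, rng):
        js = random_judgment_set(rng, 10, 200)
        E = EmbeddingSet(js.catalogue, rng.standard_normal((10, 4)))
        manual = np.mean(
            [predict_odd_one_out(E, j.items) == j.odd for j in js.judgments]
        )
        assert ooo_accuracy(E, js) == pytest.approx(manual)


class TestRsaAlignment:
    def _sm(self, values, items=None):
        n = values.shape[0]
        obs = ~np.eye(n, dtype=bool)
        return SimilarityMatrix(items or [f"v{k}" for k in range(n)], values, obs)

    def test_self_alignment_is_one(self, rng):
        v = rng.random((8, 8))
        v = (v + v.T) / 2
        S = self._sm(v)
        rep = rsa_alignment(S, S)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.r_squared == pytest.approx(1.0)

    def test_reversed_keeps_sign_in_rho(self, rng):
        v = rng.random((8, 8))
        v = (v + v.T) / 2
        rep = rsa_alignment(self._sm(1 - v), self._sm(v))
        assert rep.spearman_rho == pytest.approx(-1.0)
        assert rep.r_squared == pytest.approx(1.0)

    def test_shuffled_matrix_near_zero(self, rng):
        n = 46  # ~1000 pairs
        v = rng.random((n, n))
        v = (v + v.T) / 2
        perm = rng.permutation(n)
        rep = rsa_alignment(self._sm(v), self._sm(v[np.ix_(perm, perm)]))
        assert abs(rep.spearman_rho) < 0.1

    def test_item_mismatch_lists_difference(self, rng):
        v = rng.random((4, 4))
        v = (v + v.T) / 2
        a = self._sm(v, ["a", "b", "c", "d"])
        b = self._sm(v, ["a", "b", "c", "e"])
        with pytest.raises(ValidationError, match="e"):
            rsa_alignment(a, b)

    def test_joint_item_permutation_invariance(self, rng):
        world = make_world(n_items=12, q=3, tau=0.2, seed=0)
        js = simulate_judgments(world, SimulationConfig(n_triplets=800, seed=0))
        from repalign import estimate_similarity

        human = estimate_similarity(js)
        E = make_embeddings(world, SimulationConfig(n_triplets=1, seed=0, noise_scale=0.2, distractor_dims=4))
        model = rsm_from_embeddings(E)
        rep = rsa_alignment(model, human)
        perm = rng.permutation(12)

        def permute(sm):
            return SimilarityMatrix(
                [sm.items[k] for k in perm],
                sm.values[np.ix_(perm, perm)],
                sm.observed[np.ix_(perm, perm)],
            )

        rep_p = rsa_alignment(permute(model), permute(human))
        assert rep_p.spearman_rho == pytest.approx(rep.spearman_rho, abs=1e-12)


class TestSelectLayer:
    def test_recovers_informative_candidate(self):
        hits = 0
        for seed in range(10):
            world = make_world(n_items=30, q=3, tau=0.15, seed=seed)
            js = simulate_judgments(world, SimulationConfig(n_triplets=3000, seed=seed))
            good = EmbeddingSet(list(world.items), world.factors)
            rng = np.random.default_rng(seed + 500)
            bad = EmbeddingSet(list(world.items), rng.standard_normal((30, 3)))
            name = select_layer({"good": good, "bad": bad}, js, k_folds=5, seed=seed)
            hits += name == "good"
        assert hits >= 9

    def test_single_fold_rejected(self):
        world = make_world(n_items=20, q=2, tau=0.2, seed=0)
        js = simulate_judgments(world, SimulationConfig(n_triplets=500, seed=0))
        E = EmbeddingSet(list(world.items), world.factors)
        with pytest.raises(ValidationError):
            select_layer({"a": E, "b": E}, js, k_folds=1, seed=0)

    def test_deterministic_under_seed(self):
        world = make_world(n_items=25, q=3, tau=0.2, seed=1)
        js = simulate_judgments(world, SimulationConfig(n_triplets=2000, seed=1))
        rng = np.random.default_rng(7)
        cands = {
            "x": EmbeddingSet(list(world.items), rng.standard_normal((25, 4))),
            "y": EmbeddingSet(list(world.items), world.factors),
        }
        assert select_layer(cands, js, seed=3) == select_layer(cands, js, seed=3)


def _rdm_from_vec(items, vec, rng=None):
    n = len(items)
    v = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    v[iu, ju] = vec
    v = v + v.T
    return DissimilarityMatrix(items, v, ~np.eye(n, dtype=bool))


class TestVariancePartition:
    def test_duplicated_predictor(self, rng):
        items = [f"v{k}" for k in range(20)]
        n_pairs = 190
        a = np.abs(rng.standard_normal(n_pairs))
        h = a + 0.2 * np.abs(rng.standard_normal(n_pairs))
        rdm_a = _rdm_from_vec(items, a)
        vp = variance_partition(rdm_a, rdm_a, _rdm_from_vec(items, h))
        assert vp.unique_b == pytest.approx(0.0, abs=1e-10)
        assert vp.shared == pytest.approx(vp.total, abs=1e-10)
        assert vp.collinear

    def test_independent_noise_predictor(self, rng):
        items = [f"v{k:02d}" for k in range(33)]  # 528 pairs
        n_pairs = 33 * 32 // 2
        a = np.abs(rng.standard_normal(n_pairs))
        b = np.abs(rng.standard_normal(n_pairs))
        vp = variance_partition(
            _rdm_from_vec(items, a), _rdm_from_vec(items, b), _rdm_from_vec(items, a)
        )
        assert vp.unique_a == pytest.approx(vp.total, abs=0.05)
        assert abs(vp.unique_b) < 0.05
        assert abs(vp.shared) < 0.05

    def test_sum_identity_on_random_inputs(self, rng):
        items = [f"v{k}" for k in range(15)]
        n_pairs = 105
        for _ in range(5):
            vecs = [np.abs(rng.standard_normal(n_pairs)) for _ in range(3)]
            vp = variance_partition(*[_rdm_from_vec(items, v) for v in vecs])
            assert vp.unique_a + vp.unique_b + vp.shared == pytest.approx(vp.total, abs=1e-10)

    def test_suppressor_reports_negative_shared(self, rng):
        # b = a + noise; h correlates with the noise: adding b boosts a's fit
        items = [f"v{k}" for k in range(25)]
        n_pairs = 300
        noise = rng.standard_normal(n_pairs)
        a = np.abs(rng.standard_normal(n_pairs)) + 2
        b = a + noise + 3
        h = noise - 0.1 * a + 5
        vp = variance_partition(
            _rdm_from_vec(items, a), _rdm_from_vec(items, np.abs(b)), _rdm_from_vec(items, np.abs(h))
        )
        assert vp.shared < 0
        assert vp.suppression

    def test_too_few_pairs_rejected(self, rng):
        items = ["a", "b", "c"]
        v = np.abs(rng.standard_normal(3))
        with pytest.raises(ValidationError):
            variance_partition(*[_rdm_from_vec(items, v)] * 3)


class TestLinearProbe:
    def test_recovers_linear_target(self, rng):
        items = [f"v{k}" for k in range(60)]
        X = rng.standard_normal((60, 10))
        w = rng.standard_normal(10)
        y = X @ w
        E = EmbeddingSet(items, X)
        res = linear_probe(E, dict(zip(items, y)), items[:45], items[45:])
        assert res.pearson_r > 0.99

    def test_null_ratings_center_on_zero(self):
        rs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            items = [f"v{k}" for k in range(200)]
            E = EmbeddingSet(items, rng.standard_normal((200, 12)))
            y = rng.standard_normal(200)
            res = linear_probe(E, dict(zip(items, y)), items[:160], items[160:])
            rs.append(res.pearson_r)
        assert abs(np.mean(rs)) < 0.15

    def test_single_penalty_grid(self, rng):
        items = [f"v{k}" for k in range(30)]
        X = rng.standard_normal((30, 5))
        y = X[:, 0]
        res = linear_probe(EmbeddingSet(items, X), dict(zip(items, y)), items[:20], items[20:], penalty_grid=(0.5,))
        assert res.penalty == 0.5

    def test_contract_errors(self, rng):
        items = [f"v{k}" for k in range(20)]
        X = rng.standard_normal((20, 4))
        E = EmbeddingSet(items, X)
        ratings = dict(zip(items, np.arange(20.0)))
        with pytest.raises(ValidationError, match="disjoint"):
            linear_probe(E, ratings, items[:12], items[10:])
        with pytest.raises(ValidationError, match="10"):
            linear_probe(E, ratings, items[:5], items[15:])
        with pytest.raises(ValidationError, match="constant"):
            linear_probe(E, dict(zip(items, np.ones(20))), items[:12], items[12:])
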