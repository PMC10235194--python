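"""Negative sampling, BCE loss, analytic gradients and the optimization loop.

The backward pass is the package's own derivation; its oracle here is
central finite differences of the forward loss, checked parameter-by-
parameter for the Lorentz decoder, both encoders, and every Euclidean
baseline variant.
"""

import copy

import numpy as np
import pytest
from scipy import stats

from flone import data as dt
from flone import geometry as geo
from flone import model as fm
from flone import training as tr
from flone.data import DDTTriple, TripleStore
from flone.exceptions import ConfigurationError, SamplingError, TrainingError


class TestSampleNegatives:
    vocab = ["t1", "t2", "t3", "t4", "t5"]

    def test_never_collides_with_known(self):
        known = {("d", "k"): {"t1"}}
        rng = np.random.default_rng(0)
        trip = DDTTriple("d", "k", "t1")
        for _ in range(50):
            for neg in tr.sample_negatives(trip, self.vocab, known, 3, rng):
                assert neg.target in {"t2", "t3", "t4", "t5"}
                assert neg.drug == "d" and neg.disease == "k"

    def test_forced_single_admissible(self):
        known = {("d", "k"): {"t1"}}
        rng = np.random.default_rng(0)
        negs = tr.sample_negatives(DDTTriple("d", "k", "t1"), ["t1", "t2"], known, 4, rng)
        assert all(n.target == "t2" for n in negs)

    def test_no_admissible_target_raises(self):
        known = {("d", "k"): set(self.vocab)}
        with pytest.raises(SamplingError):
            tr.sample_negatives(DDTTriple("d", "k", "t1"), self.vocab, known, 1,
                                np.random.default_rng(0))

    def test_uniformity_chi_square(self):
        """10^4 draws over 4 admissible targets look uniform (chi-square)."""
        known = {("d", "k"): {"t1"}}
        rng = np.random.default_rng(7)
        draws = tr.sample_negatives(DDTTriple("d", "k", "t1"), self.vocab, known,
                                    10_000, rng)
        counts = np.array([sum(n.target == t for n in draws)
                           for t in ("t2", "t3", "t4", "t5")])
        assert stats.chisquare(counts).pvalue > 1e-4
        # 3-sigma binomial bound per cell
        assert np.all(np.abs(counts - 2500) < 3 * np.sqrt(10_000 * 0.25 * 0.75))


class TestBCELoss:
    def test_hand_case(self):
        """One positive at 0.5 and one negative at 0.5: loss = 2 log 2."""
        assert tr.bce_loss([0.5], [[0.5]]) == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_perfect_fit_limit(self):
        assert tr.bce_loss([1.0 - 1e-9], [[1e-9]]) == pytest.approx(0.0, abs=1e-5)

    def test_nonnegative_and_batch_consistency(self):
        rng = np.random.default_rng(0)
        p_pos = rng.uniform(0.01, 0.99, size=20)
        p_neg = rng.uniform(0.01, 0.99, size=(20, 5))
        batched = tr.bce_loss(p_pos, p_neg)
        assert batched >= 0
        per_triple = [tr.bce_loss([p_pos[i]], [p_neg[i]]) for i in range(20)]
        assert batched == pytest.approx(np.mean(per_triple), abs=1e-6)

    def test_empty_positives_raise(self):
        with pytest.raises(TrainingError):
            tr.bce_loss([], [])


def _numeric_grad(loss_fn, arr, eps=1e-6):
    g = np.zeros_like(np.atleast_1d(np.asarray(arr, dtype=float)))
    flat = g.reshape(-1)
    a = np.atleast_1d(arr).reshape(-1)
    for i in range(a.size):
        old = a[i]
        a[i] = old + eps
        lp = loss_fn()
        a[i] = old - eps
        lm = loss_fn()
        a[i] = old
        flat[i] = (lp - lm) / (2 * eps)
    return g.reshape(np.shape(arr))


class TestGradientsAgainstFiniteDifferences:
    d_idx = np.array([0, 1, 2, 3])
    k_idx = np.array([0, 1, 0, 1])
    t_pos = np.array([0, 1, 2, 3])
    t_neg = np.array([[4, 1], [0, 2], [3, 4], [0, 1]])

    def test_lorentz_base_gradients(self):
        params = fm.init_flone(num_drugs=4, num_targets=5, num_diseases=2,
                               dim=3, seed=1, dropout=0.0)

        def loss():
            l, _ = tr.flone_loss_and_grads(params, self.d_idx, self.k_idx,
                                           self.t_pos, self.t_neg, training=False)
            return l

        _, grads = tr.flone_loss_and_grads(params, self.d_idx, self.k_idx,
                                           self.t_pos, self.t_neg, training=False)
        for name in ("drug_points", "target_points", "disease_W", "disease_v",
                     "disease_b", "drug_bias", "target_bias"):
            num = _numeric_grad(loss, getattr(params, name))
            np.testing.assert_allclose(grads[name], num, rtol=1e-4, atol=1e-8,
                                       err_msg=name)

    def test_encoder_gradients(self):
        params = fm.init_flone(num_drugs=4, num_targets=5, num_diseases=2,
                               dim=3, seed=1, dropout=0.0,
                               drug_encoder_width=8, target_encoder_width=5)
        rng = np.random.default_rng(2)
        fp = (rng.random((4, 8)) < 0.3).astype(float)
        sim = rng.random((5, 5))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        lifted_fp = geo.exp_map_origin(fp)
        lifted_sim = geo.exp_map_origin(sim)

        def loss():
            l, _ = tr.flone_loss_and_grads(params, self.d_idx, self.k_idx,
                                           self.t_pos, self.t_neg,
                                           lifted_fp=lifted_fp, lifted_sim=lifted_sim,
                                           training=False)
            return l

        _, grads = tr.flone_loss_and_grads(params, self.d_idx, self.k_idx,
                                           self.t_pos, self.t_neg,
                                           lifted_fp=lifted_fp, lifted_sim=lifted_sim,
                                           training=False)
        for enc_name in ("drug_encoder", "target_encoder"):
            enc = getattr(params, enc_name)
            for field in ("W", "v"):
                num = _numeric_grad(loss, getattr(enc, field))
                denom = max(np.abs(num).max(), 1e-8)
                assert np.abs(grads[f"{enc_name}_{field}"] - num).max() / denom < 1e-3, \
                    f"{enc_name}.{field}"

    @pytest.mark.parametrize("variant", ["ddte", "ddte_bias", "fec"])
    def test_euclidean_gradients(self, variant):
        params = fm.init_euclidean([f"d{i}" for i in range(4)],
                                   [f"t{i}" for i in range(5)],
                                   [f"k{i}" for i in range(2)],
                                   dim=3, seed=1, variant=variant)

        def loss():
            l, _ = tr.euclidean_loss_and_grads(params, variant, self.d_idx,
                                               self.k_idx, self.t_pos, self.t_neg)
            return l

        _, grads = tr.euclidean_loss_and_grads(params, variant, self.d_idx,
                                               self.k_idx, self.t_pos, self.t_neg)
        for name, g in grads.items():
            num = _numeric_grad(loss, getattr(params, name))
            np.testing.assert_allclose(g, num, rtol=1e-5, atol=1e-9, err_msg=name)


class TestRiemannianUpdate:
    def test_zero_gradient_is_identity(self):
        table = geo.exp_map_origin(np.random.default_rng(0).normal(size=(6, 4)))
        new, state = tr.riemannian_update(table, np.zeros_like(table), lr=0.01)
        np.testing.assert_allclose(new, table, atol=1e-12)

    def test_step_lands_on_manifold(self):
        rng = np.random.default_rng(1)
        table = geo.exp_map_origin(rng.normal(size=(10, 5)))
        state = None
        for _ in range(5):
            grad = rng.normal(size=table.shape)
            table, state = tr.riemannian_update(table, grad, lr=0.05, state=state)
            ok, dev = geo.check_on_manifold(table, tol=1e-5)
            assert np.all(ok), np.max(dev)

    def test_large_gradients_cannot_blow_up(self):
        rng = np.random.default_rng(2)
        table = geo.exp_map_origin(rng.normal(size=(4, 4)))
        state = None
        for _ in range(20):
            table, state = tr.riemannian_update(table, rng.normal(size=table.shape) * 1e6,
                                                lr=0.5, state=state)
        assert np.all(np.isfinite(table))
        ok, _ = geo.check_on_manifold(table, tol=1e-5)
        assert np.all(ok)


class TestTrainLoop:
    def small_split(self, seed=0):
        cfgs = dict(n_drugs=12, n_targets=10, n_diseases=4, n_families=3,
                    mean_triangles_per_disease=6.0, fingerprint_width=32, seed=seed)
        from flone.synthetic import SynthConfig, generate_network
        net = generate_network(SynthConfig(**cfgs))
        store = net.planted
        return store, dt.split_by_pair(store, seed=seed, n_repeats=1)[0]

    def test_zero_epochs_returns_init_and_empty_history(self):
        store, (_, train, valid, _) = self.small_split()
        cfg = tr.TrainConfig(epochs=0, dim=4, seed=1)
        params, history = tr.train(train, valid, None, cfg, known_store=store)
        assert history == []
        ref = fm.init_flone(drug_ids=train.drugs, target_ids=train.targets,
                            disease_ids=train.diseases, dim=4, seed=1)
        np.testing.assert_array_equal(params.drug_points, ref.drug_points)

    def test_same_seed_identical_history(self):
        store, (_, train, valid, _) = self.small_split()
        cfg = tr.TrainConfig(epochs=5, dim=4, seed=3, learning_rate=5e-3)
        _, h1 = tr.train(train, valid, None, cfg, known_store=store)
        _, h2 = tr.train(train, valid, None, cfg, known_store=store)
        assert h1 == h2

    def test_loss_decreases_on_small_fixture(self):
        """Epoch-average loss drops substantially for >= 9/10 seeds."""
        store, (_, train, valid, _) = self.small_split()
        wins = 0
        for seed in range(10):
            cfg = tr.TrainConfig(epochs=50, dim=4, seed=seed, learning_rate=5e-3,
                                 dropout=0.0, patience=10**9)
            _, hist = tr.train(train, None, None, cfg, known_store=store)
            first = np.mean([h["loss"] for h in hist[:5]])
            last = np.mean([h["loss"] for h in hist[-5:]])
            wins += last < 0.8 * first
        assert wins >= 9

    def test_manifold_preserved_through_training(self):
        store, (_, train, valid, _) = self.small_split()
        cfg = tr.TrainConfig(epochs=10, dim=4, seed=0, learning_rate=5e-3)
        params, _ = tr.train(train, valid, None, cfg, known_store=store)
        for table in (params.drug_points, params.target_points):
            ok, dev = geo.check_on_manifold(table, tol=1e-5)
            assert np.all(ok), np.max(dev)

    def test_training_improves_over_untrained_mrr(self):
        from flone import evaluation as ev
        store, (_, train, valid, test) = self.small_split()
        cfg = tr.TrainConfig(epochs=120, dim=8, seed=0, learning_rate=5e-3,
                             patience=10**9, init_scale=0.3, dropout=0.2)
        init = fm.init_flone(drug_ids=train.drugs, target_ids=train.targets,
                             disease_ids=train.diseases, dim=8, seed=0, init_scale=0.3)
        before = ev.mrr(ev.rank_store(init, test))
        params, _ = tr.train(train, valid, None, cfg, known_store=store)
        after = ev.mrr(ev.rank_store(params, test))
        assert after > before

    def test_encoder_variant_requires_features(self):
        store, (_, train, valid, _) = self.small_split()
        cfg = tr.TrainConfig(epochs=1, variant="flone_ecfp_seq", dim=4)
        with pytest.raises(ConfigurationError):
            tr.train(train, valid, None, cfg)

    @pytest.mark.parametrize("variant", ["ddte", "ddte_bias", "fec",
                                         "flone_ecfp_seq"])
    def test_all_variants_run_and_are_finite(self, variant):
        from flone.synthetic import generate_features
        from flone.synthetic import SynthConfig, generate_network
        net = generate_network(SynthConfig(n_drugs=12, n_targets=10, n_diseases=4,
                                           n_families=3, mean_triangles_per_disease=6.0,
                                           fingerprint_width=32, seed=0))
        store = net.planted
        feats = generate_features(net)
        _, train, valid, _ = dt.split_by_pair(store, seed=0, n_repeats=1)[0]
        cfg = tr.TrainConfig(epochs=3, dim=4, seed=0, variant=variant)
        params, hist = tr.train(train, valid, feats, cfg, known_store=store)
        assert len(hist) == 3
        assert all(np.isfinite(h["loss"]) for h in hist)


def test_loss_batched_equals_looped():
    """Whole-batch loss equals the mean of per-triple losses (same negatives)."""
    params = fm.init_flone(num_drugs=4, num_targets=5, num_diseases=2, dim=3,
                           seed=1, dropout=0.0)
    d = np.array([0, 1, 2, 3])
    k = np.array([0, 1, 0, 1])
    tp = np.array([0, 1, 2, 3])
    tn = np.array([[4, 1], [0, 2], [3, 4], [0, 1]])
    full, _ = tr.flone_loss_and_grads(params, d, k, tp, tn, training=False)
    singles = [tr.flone_loss_and_grads(params, d[i:i+1], k[i:i+1], tp[i:i+1],
                                       tn[i:i+1], training=False)[0]
               for i in range(4)]
    assert full == pytest.approx(np.mean(singles), abs=1e-6)
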