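"""Decoder scoring, embedding tables, encoders and Euclidean baselines."""

import numpy as np
import pytest

from flone import geometry as geo
from flone import model as fm
from flone.exceptions import (ConfigurationError, CoverageError,
                              DimensionError, VocabularyError)


@pytest.fixture
def params():
    return fm.init_flone(num_drugs=4, num_targets=5, num_diseases=2, dim=6, seed=3)


class TestInit:
    def test_tables_on_manifold_and_deterministic(self, params):
        for table in (params.drug_points, params.target_points):
            ok, _ = geo.check_on_manifold(table)
            assert np.all(ok)
        again = fm.init_flone(num_drugs=4, num_targets=5, num_diseases=2, dim=6, seed=3)
        np.testing.assert_array_equal(params.drug_points, again.drug_points)
        np.testing.assert_array_equal(params.disease_W, again.disease_W)

    def test_zero_init_scale_puts_everything_at_origin(self):
        p = fm.init_flone(num_drugs=3, num_targets=3, num_diseases=1, dim=4,
                          seed=0, init_scale=0.0)
        np.testing.assert_array_equal(p.drug_points,
                                      np.tile(geo.origin(4), (3, 1)))

    def test_one_transform_per_disease(self, params):
        assert params.disease_W.shape[0] == len(params.diseases) == 2


class TestScoring:
    def test_probability_half_at_zero_logit(self):
        """d^2 = 0 (target equals translated drug) with zero biases and margin."""
        p = fm.init_flone(num_drugs=1, num_targets=1, num_diseases=1, dim=4,
                          seed=0, phi=0.0)
        y = fm.translate_drug(p, p.drugs[0], p.diseases[0])
        p.target_points[0] = y          # plant the target exactly at the translation
        assert fm.score_triple(p, p.drugs[0], p.diseases[0], p.targets[0]) \
            == pytest.approx(0.5, abs=1e-12)

    def test_score_strictly_decreases_with_distance(self, params):
        """Targets farther from the translated drug always score lower."""
        y = fm.translate_drug(params, params.drugs[0], params.diseases[0])
        params.drug_bias[:] = 0
        params.target_bias[:] = 0
        scores, d2 = [], []
        for r in (0.0, 0.5, 1.0, 2.0):
            t = geo.exp_map(y, r * geo.tangent_project(y, np.eye(7)[1]))
            t = t / np.sqrt(-geo.lorentz_inner(t, t))  # renormalize numerically
            d2.append(geo.sq_lorentz_distance(y, t, validate=False))
            inner = geo.lorentz_inner(y, t)
            scores.append(float(geo._sigmoid(-(-2 - 2 * inner) + params.phi)))
        assert np.all(np.diff(d2) > 0)
        assert np.all(np.diff(scores) < 0)

    def test_batch_equals_single_triple_scoring(self, params):
        all_scores = fm.score_all_targets(params, params.drugs[1], params.diseases[1])
        singles = [fm.score_triple(params, params.drugs[1], params.diseases[1], t)
                   for t in params.targets]
        np.testing.assert_allclose(all_scores, singles, atol=1e-6)

    def test_unknown_ids_raise(self, params):
        with pytest.raises(VocabularyError):
            fm.score_triple(params, "nope", params.diseases[0], params.targets[0])
        with pytest.raises(VocabularyError):
            fm.translate_drug(params, params.drugs[0], "nope")

    def test_translate_drug_on_manifold(self, params):
        rng = np.random.default_rng(0)
        for _ in range(100):
            d = params.drugs[rng.integers(0, 4)]
            k = params.diseases[rng.integers(0, 2)]
            ok, _ = geo.check_on_manifold(fm.translate_drug(params, d, k))
            assert ok

    def test_distinct_diseases_give_distinct_translations(self, params):
        a = fm.translate_drug(params, params.drugs[0], params.diseases[0])
        b = fm.translate_drug(params, params.drugs[0], params.diseases[1])
        assert not np.allclose(a, b)

    def test_permutation_equivariance(self, params):
        """Relabeling entities and permuting tables leaves scores unchanged."""
        ref = np.array([[fm.score_triple(params, d, k, t)
                         for t in params.targets]
                        for d in params.drugs for k in params.diseases])
        rng = np.random.default_rng(1)
        pd_, pt = rng.permutation(4), rng.permutation(5)
        perm = fm.FloneParams(
            drugs=[params.drugs[i] for i in pd_],
            targets=[params.targets[i] for i in pt],
            diseases=params.diseases, dim=params.dim, c=params.c,
            lam=params.lam, eps=params.eps, phi=params.phi, dropout=params.dropout,
            drug_points=params.drug_points[pd_], target_points=params.target_points[pt],
            disease_W=params.disease_W, disease_v=params.disease_v,
            disease_b=params.disease_b, drug_bias=params.drug_bias[pd_],
            target_bias=params.target_bias[pt])
        new = np.array([[fm.score_triple(perm, d, k, t)
                         for t in params.targets]
                        for d in params.drugs for k in params.diseases])
        np.testing.assert_allclose(new, ref, atol=1e-12)


def test_parameter_count_small_config():
    """n=4, 3 drugs, 2 targets, 2 diseases: hand-counted bookkeeping."""
    p = fm.init_flone(num_drugs=3, num_targets=2, num_diseases=2, dim=4, seed=0)
    counts = fm.parameter_count(p)
    assert counts["drug_embeddings"] == 3 * 5
    assert counts["target_embeddings"] == 2 * 5
    assert counts["entity_biases"] == 5
    assert counts["disease_transforms"] == 2 * (4 * 5 + 5 + 1)
    assert counts["total"] == 15 + 10 + 5 + 52


class TestEncoders:
    def make_encoder(self, width=16, dim=4, seed=0):
        p = fm.init_flone(num_drugs=2, num_targets=2, num_diseases=1, dim=dim,
                          seed=seed, drug_encoder_width=width)
        return p.drug_encoder

    def test_zero_fingerprint_goes_through_origin(self):
        enc = self.make_encoder()
        out = fm.encode_drug(np.zeros(16), enc)
        expected = geo.full_lorentz_linear(geo.origin(16), enc)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_identical_inputs_identical_embeddings(self):
        enc = self.make_encoder()
        fp = (np.random.default_rng(0).random(16) < 0.3).astype(float)
        np.testing.assert_array_equal(fm.encode_drug(fp, enc), fm.encode_drug(fp, enc))

    def test_width_mismatch(self):
        with pytest.raises(DimensionError):
            fm.encode_drug(np.zeros(8), self.make_encoder(width=16))

    def test_similarity_row_gives_manifold_point(self):
        enc = self.make_encoder(width=10)
        row = np.zeros(10)
        row[3] = 1.0
        ok, _ = geo.check_on_manifold(fm.encode_target(row, enc))
        assert ok

    def test_small_hamming_distance_embeds_closer(self):
        """Hamming-1 pairs land closer than Hamming-512 pairs for >= 95/100 inits."""
        rng = np.random.default_rng(42)
        width = 1024
        base = (rng.random(width) < 0.3).astype(float)
        near = base.copy()
        near[0] = 1.0 - near[0]
        far = base.copy()
        flip = rng.choice(width, size=512, replace=False)
        far[flip] = 1.0 - far[flip]
        wins = 0
        for seed in range(100):
            enc = self.make_encoder(width=width, dim=8, seed=seed)
            e0 = fm.encode_drug(base, enc)
            d_near = geo.sq_lorentz_distance(e0, fm.encode_drug(near, enc), validate=False)
            d_far = geo.sq_lorentz_distance(e0, fm.encode_drug(far, enc), validate=False)
            wins += d_near < d_far
        assert wins >= 95

    def test_identical_fingerprints_identical_scores(self, small_network, small_features):
        store = small_network.planted
        feats = small_features
        fp = feats.fingerprints.copy()
        fp.loc[store.drugs[1]] = fp.loc[store.drugs[0]]   # clone drug 0's fingerprint
        feats2 = fm.EncoderInputs(fingerprints=fp,
                                  target_similarity=feats.target_similarity)
        p = fm.init_flone(drug_ids=store.drugs, target_ids=store.targets,
                          disease_ids=store.diseases, dim=6, seed=0,
                          drug_encoder_width=fp.shape[1])
        s0 = fm.score_all_targets(p, store.drugs[0], store.diseases[0], features=feats2)
        s1 = fm.score_all_targets(p, store.drugs[1], store.diseases[0], features=feats2)
        # identical embeddings; only the per-drug bias could differ and both are 0
        np.testing.assert_allclose(s0, s1, atol=1e-12)


class TestMaterializeTables:
    def test_self_contained_passthrough(self, params):
        dt_, tt = fm.materialize_tables(params)
        assert dt_ is params.drug_points and tt is params.target_points

    def test_encoder_covers_unseen_entities(self, small_network, small_features):
        store = small_network.planted
        extra_drugs = store.drugs + ["DR_NEW"]
        fp = small_features.fingerprints.copy()
        fp.loc["DR_NEW"] = (np.random.default_rng(0).random(fp.shape[1]) < 0.2).astype(float)
        p = fm.init_flone(drug_ids=extra_drugs, target_ids=store.targets,
                          disease_ids=store.diseases, dim=6, seed=0,
                          drug_encoder_width=fp.shape[1])
        feats = fm.EncoderInputs(fingerprints=fp)
        drug_table, _ = fm.materialize_tables(p, feats)
        assert drug_table.shape[0] == len(extra_drugs)
        ok, _ = geo.check_on_manifold(drug_table)
        assert np.all(ok)

    def test_missing_features_raise_coverage_error(self, small_network, small_features):
        store = small_network.planted
        p = fm.init_flone(drug_ids=store.drugs, target_ids=store.targets,
                          disease_ids=store.diseases, dim=6, seed=0,
                          drug_encoder_width=small_features.fingerprints.shape[1])
        with pytest.raises(CoverageError):
            fm.materialize_tables(p, None)
        short = fm.EncoderInputs(fingerprints=small_features.fingerprints.iloc[:3])
        with pytest.raises(CoverageError):
            fm.materialize_tables(p, short)


class TestEuclideanBaselines:
    ids = (["da", "db"], ["ta", "tb", "tc"], ["ka", "kb"])

    def test_probability_half_when_translated_drug_hits_target(self):
        p = fm.init_euclidean(*self.ids, dim=3, seed=0, phi=0.0, variant="ddte")
        p.target_vecs[0] = p.drug_vecs[0] + p.disease_offsets[0]
        assert fm.score_triple_euclidean(p, "da", "ka", "ta", "ddte") \
            == pytest.approx(0.5, abs=1e-12)

    def test_bias_variant_reduces_to_plain_with_zero_biases(self):
        p = fm.init_euclidean(*self.ids, dim=3, seed=1, variant="ddte_bias")
        plain = fm.init_euclidean(*self.ids, dim=3, seed=1, variant="ddte")
        for d in p.drugs:
            for k in p.diseases:
                for t in p.targets:
                    assert fm.score_triple_euclidean(p, d, k, t, "ddte_bias") \
                        == pytest.approx(fm.score_triple_euclidean(plain, d, k, t, "ddte"))

    def test_fec_with_identity_map_matches_zero_offset_ddte_bias(self):
        fec = fm.init_euclidean(*self.ids, dim=3, seed=2, variant="fec")
        fec.disease_maps[:] = np.eye(3)
        fec.disease_map_bias[:] = 0.0
        db = fm.init_euclidean(*self.ids, dim=3, seed=2, variant="ddte_bias")
        db.drug_vecs = fec.drug_vecs.copy()
        db.target_vecs = fec.target_vecs.copy()
        db.disease_offsets = np.zeros_like(db.disease_offsets)
        for d in fec.drugs:
            for k in fec.diseases:
                for t in fec.targets:
                    assert fm.score_triple_euclidean(fec, d, k, t, "fec") \
                        == pytest.approx(fm.score_triple_euclidean(db, d, k, t, "ddte_bias"))

    def test_missing_variant_parameters(self):
        p = fm.init_euclidean(*self.ids, dim=3, seed=0, variant="ddte")
        with pytest.raises(ConfigurationError):
            fm.score_triple_euclidean(p, "da", "ka", "ta", "fec")
        with pytest.raises(ConfigurationError):
            fm.score_triple_euclidean(p, "da", "ka", "ta", "ddte_bias")


def test_checkpoint_round_trip(tmp_path, small_network, small_features):
    store = small_network.planted
    p = fm.init_flone(drug_ids=store.drugs, target_ids=store.targets,
                      disease_ids=store.diseases, dim=6, seed=0,
                      drug_encoder_width=small_features.fingerprints.shape[1])
    fm.save_checkpoint(p, tmp_path / "ckpt", "flone_ecfp_none")
    loaded, variant, cfg = fm.load_checkpoint(tmp_path / "ckpt")
    assert variant == "flone_ecfp_none"
    assert loaded.drugs == p.drugs
    np.testing.assert_array_equal(loaded.target_points, p.target_points)
    np.testing.assert_array_equal(loaded.drug_encoder.W, p.drug_encoder.W)
    e = fm.init_euclidean(store.drugs, store.targets, store.diseases, dim=4,
                          seed=1, variant="fec")
    fm.save_checkpoint(e, tmp_path / "eck", "fec")
    le, var2, _ = fm.load_checkpoint(tmp_path / "eck")
    assert var2 == "fec"
    np.testing.assert_array_equal(le.disease_maps, e.disease_maps)
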