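"""FLONE model parameters and scoring.

The decoder treats a triple (drug D, disease D', target T) as a
translation-based link prediction: the drug embedding ``x_D`` (a Lorentz
manifold point) is transformed by a *disease-specific* fully Lorentz linear
layer, and the transformed point is compared to the target embedding by the
squared Lorentzian distance,

    p(D, D', T) = sigmoid( -d_L^2( FLLinear_{D'}(x_D), x_T ) + b_D + b_T + phi ),

with per-entity scalar biases and a global margin ``phi``.  Drug and target
embeddings come either from self-contained look-up tables (one manifold point
per entity, trained directly with Riemannian updates) or from *hyperbolic
encoders*: a drug's binary ECFP fingerprint (or a target's row of a
0-1-normalized sequence-similarity matrix) is lifted to the manifold via the
exponential map at the origin and passed through one fully Lorentz linear
layer.  Encoders give any entity with features an embedding, including
entities never seen in training triples.

Euclidean baseline decoders mirror the same translation idea in flat space:
``ddte`` translates by a per-disease offset vector, ``ddte_bias`` adds the
entity biases, and ``fec`` replaces the vector offset by a per-disease linear
map (the fully Euclidean counterpart of the Lorentz decoder).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from .exceptions import (ConfigurationError, CoverageError, DimensionError,
                         VocabularyError)
from .geometry import FLLinearWeights

VARIANTS = ("flone_base", "flone_ecfp_seq", "flone_ecfp_none", "flone_none_seq",
            "ddte", "ddte_bias", "fec")
LORENTZ_VARIANTS = VARIANTS[:4]
EUCLIDEAN_VARIANTS = VARIANTS[4:]


# ---------------------------------------------------------------------------
# encoder feature inputs
# ---------------------------------------------------------------------------

@dataclass
class EncoderInputs:
    """Domain-knowledge features consumed by the hyperbolic encoders.

    ``fingerprints``: DataFrame indexed by drug id, binary entries (ECFP-style
    circular fingerprint bits).  ``target_similarity``: square DataFrame
    indexed by target id with values in [0, 1] and unit diagonal.
    """

    fingerprints: pd.DataFrame | None = None
    target_similarity: pd.DataFrame | None = None

    def __post_init__(self):
        if self.fingerprints is not None:
            arr = self.fingerprints.to_numpy(dtype=float)
            if not np.isin(arr, (0.0, 1.0)).all():
                raise ConfigurationError("fingerprint entries must be binary")
        if self.target_similarity is not None:
            sim = self.target_similarity
            arr = sim.to_numpy(dtype=float)
            if arr.shape[0] != arr.shape[1] or list(sim.index) != list(sim.columns):
                raise ConfigurationError("target similarity must be square with matching ids")
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise ConfigurationError("similarity entries must lie in [0, 1]")
            if not np.allclose(np.diag(arr), 1.0):
                raise ConfigurationError("similarity diagonal must be 1")

    def fingerprint_matrix(self, drug_ids) -> np.ndarray:
        if self.fingerprints is None:
            raise ConfigurationError("no fingerprints attached")
        missing = [d for d in drug_ids if d not in self.fingerprints.index]
        if missing:
            raise CoverageError(f"drugs lacking fingerprints: {missing[:5]}")
        return self.fingerprints.loc[list(drug_ids)].to_numpy(dtype=float)

    def similarity_matrix(self, target_ids) -> np.ndarray:
        if self.target_similarity is None:
            raise ConfigurationError("no target similarity attached")
        missing = [t for t in target_ids if t not in self.target_similarity.index]
        if missing:
            raise CoverageError(f"targets lacking similarity rows: {missing[:5]}")
        return self.target_similarity.loc[list(target_ids)].to_numpy(dtype=float)

    @staticmethod
    def load(fingerprints_tsv=None, similarity_tsv=None) -> "EncoderInputs":
        fp = sim = None
        if fingerprints_tsv is not None:
            fp = pd.read_csv(fingerprints_tsv, sep="\t", index_col=0)
        if similarity_tsv is not None:
            sim = pd.read_csv(similarity_tsv, sep="\t", index_col=0)
        return EncoderInputs(fingerprints=fp, target_similarity=sim)

    def save(self, fingerprints_tsv=None, similarity_tsv=None) -> None:
        if fingerprints_tsv is not None and self.fingerprints is not None:
            self.fingerprints.to_csv(fingerprints_tsv, sep="\t")
        if similarity_tsv is not None and self.target_similarity is not None:
            self.target_similarity.to_csv(similarity_tsv, sep="\t")


def ecfp_from_smiles(smiles: dict[str, str], width: int = 1024,
                     radius: int = 3) -> pd.DataFrame:
    """Morgan circular fingerprints (diameter 2*radius, default ECFP6) via RDKit."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=width)
    rows, ids = [], []
    for drug_id, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ConfigurationError(f"unparsable SMILES for {drug_id}: {smi!r}")
        fp = gen.GetFingerprint(mol)
        rows.append(np.array(fp, dtype=float))
        ids.append(drug_id)
    return pd.DataFrame(rows, index=ids, columns=[f"bit_{i}" for i in range(width)])


# ---------------------------------------------------------------------------
# Lorentz model parameters
# ---------------------------------------------------------------------------

@dataclass
class FloneParams:
    """All trainable state of a Lorentz decoder plus its hyperparameters.

    Embedding tables store full (dim+1)-coordinate manifold points (time +
    spatial); ``dim`` is the manifold dimension.  When an encoder is attached
    the corresponding table is ``None`` and embeddings are materialized fresh
    from features.  Disease transforms are per-disease FLLinear weights
    (shared ``lam``/``eps``/``dropout``); gates use one bias per disease.
    """

    drugs: list[str]
    targets: list[str]
    diseases: list[str]
    dim: int
    c: float = -1.0
    lam: float = 10.0
    eps: float = 1.0
    phi: float = 2.0
    dropout: float = 0.1
    drug_points: np.ndarray | None = None        # (n_drugs, dim+1)
    target_points: np.ndarray | None = None      # (n_targets, dim+1)
    disease_W: np.ndarray = None                 # (n_diseases, dim, dim+1)
    disease_v: np.ndarray = None                 # (n_diseases, dim+1)
    disease_b: np.ndarray = None                 # (n_diseases,)
    drug_bias: np.ndarray = None                 # (n_drugs,)
    target_bias: np.ndarray = None               # (n_targets,)
    drug_encoder: FLLinearWeights | None = None
    target_encoder: FLLinearWeights | None = None

    def __post_init__(self):
        self.drug_index = {d: i for i, d in enumerate(self.drugs)}
        self.target_index = {t: i for i, t in enumerate(self.targets)}
        self.disease_index = {k: i for i, k in enumerate(self.diseases)}

    def disease_weights(self, k_idx: int) -> FLLinearWeights:
        return FLLinearWeights(W=self.disease_W[k_idx], v=self.disease_v[k_idx],
                               b=float(self.disease_b[k_idx]), lam=self.lam,
                               eps=self.eps, dropout_rate=self.dropout)

    def _idx(self, table: dict, kind: str, entity: str) -> int:
        try:
            return table[entity]
        except KeyError:
            raise VocabularyError(f"unknown {kind} id {entity!r}") from None


def init_flone(num_drugs=None, num_targets=None, num_diseases=None, dim: int = 16,
               seed: int = 0, init_scale: float = 0.5, *, drug_ids=None,
               target_ids=None, disease_ids=None, c: float = -1.0,
               lam: float = 10.0, eps: float = 1.0, phi: float = 2.0,
               dropout: float = 0.1, drug_encoder_width: int | None = None,
               target_encoder_width: int | None = None) -> FloneParams:
    """Initialize FLONE parameters deterministically from a seed.

    Entity tables: spatial coordinates drawn N(0, init_scale^2) and lifted to
    the manifold by the exponential map at the origin (init_scale = 0 puts
    every entity at the origin).  Disease transforms start near the identity:
    W = [0 | I] + small noise, v = 0, and the gate bias set so the initial
    gate roughly matches the typical embedding radius.  Biases start at zero.

    Passing ``drug_encoder_width`` (fingerprint width) or
    ``target_encoder_width`` (number of targets, the similarity-row length)
    attaches the corresponding encoder and drops the self-contained table.
    """
    drug_ids = list(drug_ids) if drug_ids is not None else [f"DR{i:04d}" for i in range(num_drugs)]
    target_ids = list(target_ids) if target_ids is not None else [f"TG{i:04d}" for i in range(num_targets)]
    disease_ids = list(disease_ids) if disease_ids is not None else [f"DS{i:04d}" for i in range(num_diseases)]
    n_d, n_t, n_k = len(drug_ids), len(target_ids), len(disease_ids)
    if min(n_d, n_t, n_k, dim) < 1:
        raise ConfigurationError("entity counts and dim must be positive")
    rng = np.random.default_rng(seed)

    def table(n):
        return geo.exp_map_origin(rng.normal(0.0, init_scale, size=(n, dim)) if init_scale > 0
                                  else np.zeros((n, dim)), c)

    drug_points = table(n_d)
    target_points = table(n_t)

    # near-identity transform init: spatial rows of W pick out x_s, tiny noise
    # breaks symmetry between diseases; gate bias tuned so the initial gate
    # a = lam*sigmoid(b) + eps sits near the typical spatial radius.
    W0 = np.zeros((dim, dim + 1))
    W0[:, 1:] = np.eye(dim)
    disease_W = W0[None, :, :] + rng.normal(0.0, 0.01, size=(n_k, dim, dim + 1))
    disease_v = np.zeros((n_k, dim + 1))
    radius = max(init_scale * np.sqrt(dim), eps + 1e-3)
    gate_b = _inverse_sigmoid(np.clip((radius - eps) / lam, 1e-4, 1 - 1e-4))
    disease_b = np.full(n_k, gate_b)

    def encoder(width):
        W = rng.normal(0.0, 1.0 / np.sqrt(width + 1), size=(dim, width + 1))
        return FLLinearWeights(W=W, v=np.zeros(width + 1), b=gate_b, lam=lam,
                               eps=eps, dropout_rate=dropout)

    drug_enc = encoder(drug_encoder_width) if drug_encoder_width else None
    target_enc = encoder(target_encoder_width) if target_encoder_width else None
    return FloneParams(
        drugs=drug_ids, targets=target_ids, diseases=disease_ids, dim=dim, c=c,
        lam=lam, eps=eps, phi=phi, dropout=dropout,
        drug_points=None if drug_enc else drug_points,
        target_points=None if target_enc else target_points,
        disease_W=disease_W, disease_v=disease_v, disease_b=disease_b,
        drug_bias=np.zeros(n_d), target_bias=np.zeros(n_t),
        drug_encoder=drug_enc, target_encoder=target_enc)


def _inverse_sigmoid(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


# ---------------------------------------------------------------------------
# embedding materialization and scoring
# ---------------------------------------------------------------------------

def encode_drug(fingerprint, encoder_weights: FLLinearWeights, c: float = -1.0,
                training: bool = False, rng=None) -> np.ndarray:
    """Lift a binary fingerprint to the manifold and pass it through the encoder."""
    fingerprint = np.asarray(fingerprint, dtype=float)
    if fingerprint.shape[-1] != encoder_weights.n_in:
        raise DimensionError(
            f"fingerprint width {fingerprint.shape[-1]} != encoder input {encoder_weights.n_in}")
    lifted = geo.exp_map_origin(fingerprint, c)
    return geo.full_lorentz_linear(lifted, encoder_weights, c, training=training, rng=rng)


def encode_target(similarity_row, encoder_weights: FLLinearWeights, c: float = -1.0,
                  training: bool = False, rng=None) -> np.ndarray:
    """Lift a target-similarity row to the manifold and encode it (same path as drugs)."""
    return encode_drug(similarity_row, encoder_weights, c, training=training, rng=rng)


def materialize_tables(params: FloneParams, features: EncoderInputs | None = None,
                       training: bool = False, rng=None):
    """Return the (drug_table, target_table) actually used for scoring.

    Self-contained tables are returned unchanged; attached encoders recompute
    embeddings from features for every entity in the vocabulary (entities
    absent from training triples included — the unseen-entity contract).
    """
    if params.drug_encoder is not None:
        if features is None or features.fingerprints is None:
            raise CoverageError("drug encoder attached but no fingerprints supplied")
        fp = features.fingerprint_matrix(params.drugs)
        drug_table = encode_drug(fp, params.drug_encoder, params.c, training, rng)
    else:
        drug_table = params.drug_points
    if params.target_encoder is not None:
        if features is None or features.target_similarity is None:
            raise CoverageError("target encoder attached but no similarity matrix supplied")
        sim = features.similarity_matrix(params.targets)
        target_table = encode_target(sim, params.target_encoder, params.c, training, rng)
    else:
        target_table = params.target_points
    return drug_table, target_table


def translate_drug(params: FloneParams, drug: str, disease: str,
                   training: bool = False, rng=None,
                   features: EncoderInputs | None = None) -> np.ndarray:
    """Disease-specific Lorentz translation of one drug embedding."""
    d = params._idx(params.drug_index, "drug", drug)
    k = params._idx(params.disease_index, "disease", disease)
    drug_table, _ = materialize_tables(params, features, training, rng)
    return geo.full_lorentz_linear(drug_table[d], params.disease_weights(k),
                                   params.c, training=training, rng=rng)


def score_triple(params: FloneParams, drug: str, disease: str, target: str,
                 training: bool = False, rng=None,
                 features: EncoderInputs | None = None) -> float:
    """Similarity probability of one DDT triple (strictly inside (0, 1))."""
    d = params._idx(params.drug_index, "drug", drug)
    k = params._idx(params.disease_index, "disease", disease)
    j = params._idx(params.target_index, "target", target)
    drug_table, target_table = materialize_tables(params, features, training, rng)
    y = geo.full_lorentz_linear(drug_table[d], params.disease_weights(k),
                                params.c, training=training, rng=rng)
    d2 = geo.sq_lorentz_distance(y, target_table[j], params.c, validate=False)
    logit = -d2 + params.drug_bias[d] + params.target_bias[j] + params.phi
    return float(geo._sigmoid(logit))


def score_all_targets(params: FloneParams, drug: str, disease: str,
                      features: EncoderInputs | None = None,
                      tables=None) -> np.ndarray:
    """Scores of every target in the vocabulary for one (drug, disease) query.

    ``tables`` may carry pre-materialized (drug_table, target_table) to avoid
    re-encoding per query during evaluation.
    """
    d = params._idx(params.drug_index, "drug", drug)
    k = params._idx(params.disease_index, "disease", disease)
    drug_table, target_table = tables if tables is not None \
        else materialize_tables(params, features, training=False)
    y = geo.full_lorentz_linear(drug_table[d], params.disease_weights(k), params.c)
    inner = geo.lorentz_inner(y[None, :], target_table)
    d2 = np.maximum(2.0 / params.c - 2.0 * inner, 0.0)
    logit = -d2 + params.drug_bias[d] + params.target_bias + params.phi
    return geo._sigmoid(logit)


def parameter_count(params: FloneParams) -> dict:
    """Exact trainable-parameter bookkeeping (tables/encoders, biases, transforms)."""
    n_d, n_t, n_k = len(params.drugs), len(params.targets), len(params.diseases)
    dim = params.dim
    counts = {}
    counts["drug_embeddings"] = (params.drug_encoder.W.size + params.drug_encoder.v.size + 1
                                 if params.drug_encoder else n_d * (dim + 1))
    counts["target_embeddings"] = (params.target_encoder.W.size + params.target_encoder.v.size + 1
                                   if params.target_encoder else n_t * (dim + 1))
    counts["entity_biases"] = n_d + n_t
    counts["disease_transforms"] = n_k * (dim * (dim + 1) + (dim + 1) + 1)
    counts["total"] = sum(counts.values())
    return counts


# ---------------------------------------------------------------------------
# Euclidean baselines
# ---------------------------------------------------------------------------

@dataclass
class EuclideanParams:
    """Parameters of the Euclidean translation baselines (ddte / ddte_bias / fec)."""

    drugs: list[str]
    targets: list[str]
    diseases: list[str]
    dim: int
    phi: float = 2.0
    drug_vecs: np.ndarray = None                 # (n_drugs, dim)
    target_vecs: np.ndarray = None               # (n_targets, dim)
    disease_offsets: np.ndarray | None = None    # (n_diseases, dim)   ddte / ddte_bias
    disease_maps: np.ndarray | None = None       # (n_diseases, dim, dim)   fec
    disease_map_bias: np.ndarray | None = None   # (n_diseases, dim)        fec
    drug_bias: np.ndarray | None = None
    target_bias: np.ndarray | None = None

    def __post_init__(self):
        self.drug_index = {d: i for i, d in enumerate(self.drugs)}
        self.target_index = {t: i for i, t in enumerate(self.targets)}
        self.disease_index = {k: i for i, k in enumerate(self.diseases)}


def init_euclidean(drug_ids, target_ids, disease_ids, dim: int = 16, seed: int = 0,
                   init_scale: float = 0.5, phi: float = 2.0,
                   variant: str = "ddte") -> EuclideanParams:
    if variant not in EUCLIDEAN_VARIANTS:
        raise ConfigurationError(f"unknown Euclidean variant {variant!r}")
    rng = np.random.default_rng(seed)
    n_d, n_t, n_k = len(drug_ids), len(target_ids), len(disease_ids)
    p = EuclideanParams(
        drugs=list(drug_ids), targets=list(target_ids), diseases=list(disease_ids),
        dim=dim, phi=phi,
        drug_vecs=rng.normal(0, init_scale, (n_d, dim)),
        target_vecs=rng.normal(0, init_scale, (n_t, dim)))
    if variant == "fec":
        p.disease_maps = np.eye(dim)[None] + rng.normal(0, 0.01, (n_k, dim, dim))
        p.disease_map_bias = np.zeros((n_k, dim))
    else:
        p.disease_offsets = rng.normal(0, init_scale, (n_k, dim))
    if variant in ("ddte_bias", "fec"):
        p.drug_bias = np.zeros(n_d)
        p.target_bias = np.zeros(n_t)
    return p


def translate_drug_euclidean(params: EuclideanParams, d_idx: int, k_idx: int,
                             variant: str) -> np.ndarray:
    e = params.drug_vecs[d_idx]
    if variant == "fec":
        if params.disease_maps is None:
            raise ConfigurationError("fec variant requires disease_maps")
        return params.disease_maps[k_idx] @ e + params.disease_map_bias[k_idx]
    if params.disease_offsets is None:
        raise ConfigurationError(f"{variant} variant requires disease_offsets")
    return e + params.disease_offsets[k_idx]


def score_triple_euclidean(params: EuclideanParams, drug: str, disease: str,
                           target: str, variant: str) -> float:
    """Euclidean translation score sigmoid(-||t - e_T||^2 [+ b_D + b_T] + phi)."""
    if variant not in EUCLIDEAN_VARIANTS:
        raise ConfigurationError(f"unknown Euclidean variant {variant!r}")
    d = params.drug_index.get(drug)
    k = params.disease_index.get(disease)
    j = params.target_index.get(target)
    if None in (d, k, j):
        raise VocabularyError(f"unknown id among ({drug}, {disease}, {target})")
    t = translate_drug_euclidean(params, d, k, variant)
    q = t - params.target_vecs[j]
    logit = -float(q @ q) + params.phi
    if variant in ("ddte_bias", "fec"):
        if params.drug_bias is None or params.target_bias is None:
            raise ConfigurationError(f"{variant} variant requires entity biases")
        logit += float(params.drug_bias[d] + params.target_bias[j])
    return float(geo._sigmoid(logit))


def score_all_targets_euclidean(params: EuclideanParams, drug: str, disease: str,
                                variant: str) -> np.ndarray:
    d = params.drug_index.get(drug)
    k = params.disease_index.get(disease)
    if None in (d, k):
        raise VocabularyError(f"unknown id among ({drug}, {disease})")
    t = translate_drug_euclidean(params, d, k, variant)
    q = params.target_vecs - t[None, :]
    logit = -np.sum(q * q, axis=1) + params.phi
    if variant in ("ddte_bias", "fec"):
        logit = logit + params.drug_bias[d] + params.target_bias
    return geo._sigmoid(logit)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(params, out_dir, variant: str, extra: dict | None = None) -> None:
    """Write a checkpoint directory: config.json + arrays.npz."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {}
    if isinstance(params, FloneParams):
        cfg = dict(kind="lorentz", variant=variant, drugs=params.drugs,
                   targets=params.targets, diseases=params.diseases, dim=params.dim,
                   c=params.c, lam=params.lam, eps=params.eps, phi=params.phi,
                   dropout=params.dropout)
        for name in ("drug_points", "target_points", "disease_W", "disease_v",
                     "disease_b", "drug_bias", "target_bias"):
            val = getattr(params, name)
            if val is not None:
                arrays[name] = val
        for enc_name in ("drug_encoder", "target_encoder"):
            enc = getattr(params, enc_name)
            if enc is not None:
                arrays[f"{enc_name}_W"] = enc.W
                arrays[f"{enc_name}_v"] = enc.v
                arrays[f"{enc_name}_b"] = np.array(enc.b)
    else:
        cfg = dict(kind="euclidean", variant=variant, drugs=params.drugs,
                   targets=params.targets, diseases=params.diseases,
                   dim=params.dim, phi=params.phi)
        for name in ("drug_vecs", "target_vecs", "disease_offsets", "disease_maps",
                     "disease_map_bias", "drug_bias", "target_bias"):
            val = getattr(params, name)
            if val is not None:
                arrays[name] = val
    if extra:
        cfg["extra"] = extra
    (out / "config.json").write_text(json.dumps(cfg, indent=1))
    np.savez(out / "arrays.npz", **arrays)


def load_checkpoint(ckpt_dir):
    """Load a checkpoint directory; returns (params, variant, config dict)."""
    ckpt = Path(ckpt_dir)
    cfg = json.loads((ckpt / "config.json").read_text())
    arr = np.load(ckpt / "arrays.npz")
    if cfg["kind"] == "lorentz":
        params = FloneParams(
            drugs=cfg["drugs"], targets=cfg["targets"], diseases=cfg["diseases"],
            dim=cfg["dim"], c=cfg["c"], lam=cfg["lam"], eps=cfg["eps"],
            phi=cfg["phi"], dropout=cfg["dropout"],
            drug_points=arr["drug_points"] if "drug_points" in arr else None,
            target_points=arr["target_points"] if "target_points" in arr else None,
            disease_W=arr["disease_W"], disease_v=arr["disease_v"],
            disease_b=arr["disease_b"], drug_bias=arr["drug_bias"],
            target_bias=arr["target_bias"])
        for enc_name in ("drug_encoder", "target_encoder"):
            if f"{enc_name}_W" in arr:
                setattr(params, enc_name, FLLinearWeights(
                    W=arr[f"{enc_name}_W"], v=arr[f"{enc_name}_v"],
                    b=float(arr[f"{enc_name}_b"]), lam=cfg["lam"], eps=cfg["eps"],
                    dropout_rate=cfg["dropout"]))
    else:
        def _opt(key):
            return arr[key] if key in arr.files else None

        params = EuclideanParams(
            drugs=cfg["drugs"], targets=cfg["targets"], diseases=cfg["diseases"],
            dim=cfg["dim"], phi=cfg["phi"],
            drug_vecs=arr["drug_vecs"], target_vecs=arr["target_vecs"],
            disease_offsets=_opt("disease_offsets"),
            disease_maps=_opt("disease_maps"),
            disease_map_bias=_opt("disease_map_bias"),
            drug_bias=_opt("drug_bias"), target_bias=_opt("target_bias"))
    return params, cfg["variant"], cfg
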