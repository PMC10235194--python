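"""Training: negative sampling, BCE ranking loss, analytic gradients, optimizers.

Positives are contrasted against N' corrupted triples obtained by replacing
the target with a uniformly sampled target that does not form a known triple
with the same (drug, disease).  The loss is binary cross entropy normalized
by the number of positives,

    L = -(1/N) sum_N [ log p(D,D',T) + sum_{N'} log(1 - p(D,D',T')) ].

Gradients are derived analytically (see ``_fll_backward`` for the fully
Lorentz linear layer) and verified against central finite differences in the
test suite.  Euclidean parameters (layer weights, gates, biases, baseline
embeddings) are updated with Adam; manifold-valued embedding tables are
updated with a Riemannian Adam whose moments live in ambient coordinates:
the Euclidean gradient is converted to a Riemannian one (time coordinate
flipped, projected onto the tangent space), Adam-rescaled, re-projected, and
the step is retracted onto the hyperboloid with the exponential map.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry as geo
from . import model as fm
from .data import TripleStore
from .exceptions import (ConfigurationError, SamplingError, TrainingError)

#: probability clamp for numerical stability of the BCE loss
P_CLAMP = 1e-7


@dataclass
class TrainConfig:
    """Hyperparameters of one training run (all defaults configurable)."""

    dim: int = 16
    lam: float = 10.0
    eps: float = 1.0
    phi: float = 2.0
    dropout: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 512
    epochs: int = 300
    n_negatives: int = 10
    seed: int = 0
    variant: str = "flone_base"
    patience: int = 30
    init_scale: float = 0.5
    c: float = -1.0

    def __post_init__(self):
        if self.n_negatives < 1:
            raise ConfigurationError("n_negatives must be >= 1")
        if min(self.dim, self.batch_size) < 1 or self.epochs < 0:
            raise ConfigurationError("dim/batch_size must be positive, epochs >= 0")
        if self.variant not in fm.VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")


# ---------------------------------------------------------------------------
# negative sampling and loss
# ---------------------------------------------------------------------------

def sample_negatives(triple, target_vocab, known_index, n_neg: int, rng):
    """N' corrupted triples for one positive, never colliding with known positives.

    ``known_index`` maps (drug, disease) to the set of known-positive targets;
    sampling is uniform with replacement over the admissible targets.
    """
    known = known_index.get((triple.drug, triple.disease), set())
    admissible = [t for t in target_vocab if t not in known]
    if not admissible:
        raise SamplingError(
            f"no admissible negative target for ({triple.drug}, {triple.disease})")
    picks = rng.choice(len(admissible), size=n_neg, replace=True)
    return [replace(triple, target=admissible[i]) for i in picks]


def bce_loss(p_pos, p_neg) -> float:
    """Binary cross entropy over positives and their negatives, normalized by N.

    ``p_pos``: length-N array of positive-triple probabilities; ``p_neg``:
    (N, N') array (or flat list) of negative probabilities.  Probabilities
    are clamped to [1e-7, 1 - 1e-7].
    """
    p_pos = np.clip(np.asarray(p_pos, dtype=float), P_CLAMP, 1.0 - P_CLAMP)
    if p_pos.size == 0:
        raise TrainingError("bce_loss needs at least one positive probability")
    p_neg = np.clip(np.asarray(p_neg, dtype=float), P_CLAMP, 1.0 - P_CLAMP)
    n = p_pos.size
    return float(-(np.sum(np.log(p_pos)) + np.sum(np.log1p(-p_neg))) / n)


def _admissible_index(store: TripleStore, extra_known: TripleStore | None = None):
    """Per-(drug_idx, disease_idx) arrays of admissible negative target indices."""
    n_t = len(store.targets)
    all_t = np.arange(n_t)
    known: dict[tuple[int, int], set[int]] = {}
    for src in (store, extra_known):
        if src is None:
            continue
        for t in src:
            key = (store.drug_index[t.drug], store.disease_index[t.disease])
            known.setdefault(key, set()).add(store.target_index[t.target])
    out = {}
    for key, tset in known.items():
        adm = np.setdiff1d(all_t, np.fromiter(tset, dtype=np.int64), assume_unique=False)
        if adm.size == 0:
            raise SamplingError(f"no admissible negative target for pair index {key}")
        out[key] = adm
    return out


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _fll_backward(dY, cache):
    """Analytic gradients of one fully Lorentz linear layer.

    Returns ``(dX, dW, dv, db)`` for upstream gradient ``dY`` on the output
    points, using the intermediates cached by the forward pass.
    """
    X, Xd, mask = cache["X"], cache["Xd"], cache["mask"]
    s, a, nh, Hh, yt = cache["s"], cache["a"], cache["nh"], cache["Hh"], cache["yt"]
    w = cache["weights"]
    dyt = dY[:, 0]
    dYs = dY[:, 1:]
    da = dyt * a / yt + np.sum(dYs * Hh, axis=1)
    dHh = a[:, None] * dYs
    dH = (dHh - np.sum(dHh * Hh, axis=1, keepdims=True) * Hh) / nh[:, None]
    du = da * w.lam * s * (1.0 - s)
    dv = X.T @ du
    db = float(np.sum(du))
    dW = dH.T @ Xd
    dX = du[:, None] * w.v[None, :] + dH @ w.W
    if mask is not None:
        dX = du[:, None] * w.v[None, :] + (dH @ w.W) * mask
    return dX, dW, dv, db


def _flip_time(x):
    out = np.array(x, copy=True)
    out[..., 0] = -out[..., 0]
    return out


def flone_loss_and_grads(params: fm.FloneParams, d_idx, k_idx, t_pos, t_neg,
                         lifted_fp=None, lifted_sim=None, training: bool = True,
                         rng=None):
    """Batched BCE loss and analytic gradients for the Lorentz decoder.

    ``t_neg`` has shape (B, N'); ``lifted_fp``/``lifted_sim`` are the
    exp-map-lifted feature matrices when encoders are attached.  Returns
    ``(loss, grads)`` with gradient arrays keyed like the parameter fields.
    """
    c = params.c
    B = len(d_idx)
    n_neg = t_neg.shape[1]
    grads: dict[str, np.ndarray] = {}

    # drug embeddings for the batch
    if params.drug_encoder is not None:
        Xd, cache_de = geo.full_lorentz_linear(
            lifted_fp[d_idx], params.drug_encoder, c, training=training, rng=rng,
            _cache=True)
    else:
        Xd = params.drug_points[d_idx]

    # disease-specific translation, grouped by disease
    dimp1 = Xd.shape[1]
    Y = np.empty((B, params.dim + 1))
    k_caches = {}
    for k in np.unique(k_idx):
        rows = np.flatnonzero(k_idx == k)
        Y[rows], k_caches[int(k)] = geo.full_lorentz_linear(
            Xd[rows], params.disease_weights(int(k)), c, training=training,
            rng=rng, _cache=True)

    # target table
    if params.target_encoder is not None:
        Ttab, cache_te = geo.full_lorentz_linear(
            lifted_sim, params.target_encoder, c, training=training, rng=rng,
            _cache=True)
    else:
        Ttab = params.target_points
    Tp = Ttab[t_pos]
    Tn = Ttab[t_neg]

    inner_p = geo.lorentz_inner(Y, Tp)
    inner_n = geo.lorentz_inner(Y[:, None, :], Tn)
    logit_p = -2.0 / c + 2.0 * inner_p + params.drug_bias[d_idx] \
        + params.target_bias[t_pos] + params.phi
    logit_n = -2.0 / c + 2.0 * inner_n + params.drug_bias[d_idx][:, None] \
        + params.target_bias[t_neg] + params.phi
    p_pos = geo._sigmoid(logit_p)
    p_neg = geo._sigmoid(logit_n)
    loss = bce_loss(p_pos, p_neg)

    dlogit_p = (p_pos - 1.0) / B
    dlogit_n = p_neg / B
    dinner_p = 2.0 * dlogit_p
    dinner_n = 2.0 * dlogit_n

    dY = dinner_p[:, None] * _flip_time(Tp) \
        + np.sum(dinner_n[:, :, None] * _flip_time(Tn), axis=1)
    dTtab = np.zeros_like(Ttab)
    GY = _flip_time(Y)
    np.add.at(dTtab, t_pos, dinner_p[:, None] * GY)
    np.add.at(dTtab, t_neg.ravel(),
              (dinner_n[:, :, None] * GY[:, None, :]).reshape(-1, Ttab.shape[1]))

    grads["drug_bias"] = np.zeros_like(params.drug_bias)
    np.add.at(grads["drug_bias"], d_idx, dlogit_p + np.sum(dlogit_n, axis=1))
    grads["target_bias"] = np.zeros_like(params.target_bias)
    np.add.at(grads["target_bias"], t_pos, dlogit_p)
    np.add.at(grads["target_bias"], t_neg.ravel(), dlogit_n.ravel())

    # back through the disease transforms
    dXd = np.empty_like(Xd)
    grads["disease_W"] = np.zeros_like(params.disease_W)
    grads["disease_v"] = np.zeros_like(params.disease_v)
    grads["disease_b"] = np.zeros_like(params.disease_b)
    for k, cache in k_caches.items():
        rows = np.flatnonzero(k_idx == k)
        dXk, dWk, dvk, dbk = _fll_backward(dY[rows], cache)
        dXd[rows] = dXk
        grads["disease_W"][k] = dWk
        grads["disease_v"][k] = dvk
        grads["disease_b"][k] = dbk

    # drug path
    if params.drug_encoder is not None:
        _, dWe, dve, dbe = _fll_backward(dXd, cache_de)
        grads["drug_encoder_W"], grads["drug_encoder_v"], grads["drug_encoder_b"] = dWe, dve, dbe
    else:
        grads["drug_points"] = np.zeros_like(params.drug_points)
        np.add.at(grads["drug_points"], d_idx, dXd)

    # target path
    if params.target_encoder is not None:
        _, dWt, dvt, dbt = _fll_backward(dTtab, cache_te)
        grads["target_encoder_W"], grads["target_encoder_v"], grads["target_encoder_b"] = dWt, dvt, dbt
    else:
        grads["target_points"] = dTtab
    return loss, grads


def euclidean_loss_and_grads(params: fm.EuclideanParams, variant: str,
                             d_idx, k_idx, t_pos, t_neg):
    """Batched BCE loss and gradients for the Euclidean baseline decoders."""
    B = len(d_idx)
    use_bias = variant in ("ddte_bias", "fec")
    E = params.drug_vecs[d_idx]
    if variant == "fec":
        M = params.disease_maps[k_idx]
        T = np.einsum("bij,bj->bi", M, E) + params.disease_map_bias[k_idx]
    else:
        T = E + params.disease_offsets[k_idx]
    Qp = T - params.target_vecs[t_pos]
    Qn = T[:, None, :] - params.target_vecs[t_neg]
    logit_p = -np.sum(Qp * Qp, axis=1) + params.phi
    logit_n = -np.sum(Qn * Qn, axis=2) + params.phi
    if use_bias:
        logit_p = logit_p + params.drug_bias[d_idx] + params.target_bias[t_pos]
        logit_n = logit_n + params.drug_bias[d_idx][:, None] + params.target_bias[t_neg]
    p_pos = geo._sigmoid(logit_p)
    p_neg = geo._sigmoid(logit_n)
    loss = bce_loss(p_pos, p_neg)

    dlogit_p = (p_pos - 1.0) / B
    dlogit_n = p_neg / B
    dQp = -2.0 * dlogit_p[:, None] * Qp
    dQn = -2.0 * dlogit_n[:, :, None] * Qn
    dT = dQp + np.sum(dQn, axis=1)
    grads = {"target_vecs": np.zeros_like(params.target_vecs),
             "drug_vecs": np.zeros_like(params.drug_vecs)}
    np.add.at(grads["target_vecs"], t_pos, -dQp)
    np.add.at(grads["target_vecs"], t_neg.ravel(), -dQn.reshape(-1, params.dim))
    if variant == "fec":
        grads["disease_maps"] = np.zeros_like(params.disease_maps)
        grads["disease_map_bias"] = np.zeros_like(params.disease_map_bias)
        np.add.at(grads["disease_maps"], k_idx, np.einsum("bi,bj->bij", dT, E))
        np.add.at(grads["disease_map_bias"], k_idx, dT)
        dE = np.einsum("bij,bi->bj", M, dT)
    else:
        grads["disease_offsets"] = np.zeros_like(params.disease_offsets)
        np.add.at(grads["disease_offsets"], k_idx, dT)
        dE = dT
    np.add.at(grads["drug_vecs"], d_idx, dE)
    if use_bias:
        grads["drug_bias"] = np.zeros_like(params.drug_bias)
        grads["target_bias"] = np.zeros_like(params.target_bias)
        np.add.at(grads["drug_bias"], d_idx, dlogit_p + np.sum(dlogit_n, axis=1))
        np.add.at(grads["target_bias"], t_pos, dlogit_p)
        np.add.at(grads["target_bias"], t_neg.ravel(), dlogit_n.ravel())
    return loss, grads


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam on named Euclidean parameter arrays (in-place updates)."""

    def __init__(self, lr: float, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.state: dict[str, dict] = {}

    def step(self, name: str, param: np.ndarray, grad) -> np.ndarray:
        grad = np.asarray(grad, dtype=float)
        st = self.state.setdefault(name, {"m": np.zeros_like(param, dtype=float),
                                          "v": np.zeros_like(param, dtype=float),
                                          "t": 0})
        st["t"] += 1
        st["m"] = self.b1 * st["m"] + (1 - self.b1) * grad
        st["v"] = self.b2 * st["v"] + (1 - self.b2) * grad * grad
        mh = st["m"] / (1 - self.b1 ** st["t"])
        vh = st["v"] / (1 - self.b2 ** st["t"])
        param -= self.lr * mh / (np.sqrt(vh) + self.eps)
        return param


class RiemannianAdam:
    """Adam on Lorentz-manifold point tables with exp-map retraction.

    Moments are tracked per ambient coordinate of the Riemannian gradient
    (Euclidean gradient with the time coordinate sign flipped, projected onto
    the tangent space).  The rescaled step is re-projected onto the tangent
    space and retracted with the exponential map; the time coordinate is then
    recomputed from the spatial ones to pin the point to the hyperboloid.
    """

    def __init__(self, lr: float, c: float = -1.0, b1: float = 0.9,
                 b2: float = 0.999, eps: float = 1e-8, max_step_norm: float = 0.5):
        self.lr, self.c, self.b1, self.b2, self.eps = lr, c, b1, b2, eps
        self.max_step_norm = max_step_norm
        self.state: dict[str, dict] = {}

    def step(self, name: str, table: np.ndarray, egrad: np.ndarray) -> np.ndarray:
        rgrad = geo.tangent_project(table, _flip_time(egrad), self.c)
        st = self.state.setdefault(name, {"m": np.zeros_like(table),
                                          "v": np.zeros_like(table), "t": 0})
        st["t"] += 1
        st["m"] = self.b1 * st["m"] + (1 - self.b1) * rgrad
        st["v"] = self.b2 * st["v"] + (1 - self.b2) * rgrad * rgrad
        mh = st["m"] / (1 - self.b1 ** st["t"])
        vh = st["v"] / (1 - self.b2 ** st["t"])
        step = geo.tangent_project(table, mh / (np.sqrt(vh) + self.eps), self.c)
        step = -self.lr * step
        # the tangent projection scales with the base point's coordinate
        # magnitude, so raw steps can explode for points far from the origin;
        # cap each point's geodesic step length for stability
        nrm = np.sqrt(np.maximum(geo.lorentz_inner(step, step), 0.0))
        scale = np.where(nrm > self.max_step_norm,
                         self.max_step_norm / np.maximum(nrm, 1e-300), 1.0)
        new = geo.exp_map(table, step * scale[..., None], self.c)
        # numerical hygiene: recompute time coordinate from spatial ones
        return geo.from_spatial(new[..., 1:], self.c)


def riemannian_update(table: np.ndarray, egrad: np.ndarray, lr: float,
                      state: RiemannianAdam | None = None,
                      c: float = -1.0) -> tuple[np.ndarray, RiemannianAdam]:
    """One Riemannian Adam step on a table of manifold points.

    Functional wrapper around :class:`RiemannianAdam`; pass the returned
    optimizer back in to keep the moment state across steps.
    """
    if state is None:
        state = RiemannianAdam(lr, c)
    return state.step("table", np.array(table, copy=True), egrad), state


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _check_variant_features(variant: str, features: fm.EncoderInputs | None):
    needs_fp = variant in ("flone_ecfp_seq", "flone_ecfp_none")
    needs_sim = variant in ("flone_ecfp_seq", "flone_none_seq")
    if needs_fp and (features is None or features.fingerprints is None):
        raise ConfigurationError(f"variant {variant} requires drug fingerprints")
    if needs_sim and (features is None or features.target_similarity is None):
        raise ConfigurationError(f"variant {variant} requires target similarity")


def train(train_store: TripleStore, valid_store: TripleStore | None = None,
          features: fm.EncoderInputs | None = None,
          config: TrainConfig | None = None, known_store: TripleStore | None = None,
          verbose: bool = False):
    """Fit a FLONE (or Euclidean baseline) decoder on known triples.

    Runs mini-batched positive + negative scoring with the BCE loss,
    re-drawing negatives every epoch, and evaluates validation MRR after each
    epoch.  Negative targets are drawn uniformly among targets that do not
    form a triple in the *known* set with the query's (drug, disease):
    ``known_store`` should be the full extracted triple store when available
    (the convention here — it keeps held-out positives from being trained as
    negatives, which matters greatly for small target vocabularies); when
    omitted, train + valid positives are used.

    Returns ``(best_params, history)`` where ``best_params`` is the
    checkpoint with the highest validation MRR (final parameters when no
    validation store is given) and ``history`` is a list of per-epoch dicts.
    Fully reproducible given ``config.seed`` (single-threaded).
    """
    from .evaluation import mrr, rank_store   # deferred: avoid import cycle at module load

    config = config or TrainConfig()
    _check_variant_features(config.variant, features)
    if len(train_store) == 0:
        raise ConfigurationError("training store is empty")
    rng = np.random.default_rng(config.seed)
    lorentz = config.variant in fm.LORENTZ_VARIANTS

    lifted_fp = lifted_sim = None
    if lorentz:
        enc_fp_width = enc_sim_width = None
        if config.variant in ("flone_ecfp_seq", "flone_ecfp_none"):
            fp = features.fingerprint_matrix(train_store.drugs)
            lifted_fp = geo.exp_map_origin(fp, config.c)
            enc_fp_width = fp.shape[1]
        if config.variant in ("flone_ecfp_seq", "flone_none_seq"):
            sim = features.similarity_matrix(train_store.targets)
            lifted_sim = geo.exp_map_origin(sim, config.c)
            enc_sim_width = sim.shape[1]
        params = fm.init_flone(
            drug_ids=train_store.drugs, target_ids=train_store.targets,
            disease_ids=train_store.diseases, dim=config.dim, seed=config.seed,
            init_scale=config.init_scale, c=config.c, lam=config.lam,
            eps=config.eps, phi=config.phi, dropout=config.dropout,
            drug_encoder_width=enc_fp_width, target_encoder_width=enc_sim_width)
    else:
        params = fm.init_euclidean(
            train_store.drugs, train_store.targets, train_store.diseases,
            dim=config.dim, seed=config.seed, init_scale=config.init_scale,
            phi=config.phi, variant=config.variant)

    adam = Adam(config.learning_rate)
    radam = RiemannianAdam(config.learning_rate, config.c)
    if known_store is not None:
        admissible = _admissible_index(train_store, known_store)
    else:
        admissible = _admissible_index(train_store, valid_store)
    d_all, k_all, t_all = train_store.indices()
    n = len(train_store)

    history: list[dict] = []
    best = copy.deepcopy(params)
    best_mrr = -np.inf
    stall = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            d_idx, k_idx, t_pos = d_all[sel], k_all[sel], t_all[sel]
            t_neg = np.empty((len(sel), config.n_negatives), dtype=np.int64)
            for row, (di, ki) in enumerate(zip(d_idx, k_idx)):
                adm = admissible[(int(di), int(ki))]
                t_neg[row] = adm[rng.integers(0, adm.size, size=config.n_negatives)]
            if lorentz:
                loss, grads = flone_loss_and_grads(
                    params, d_idx, k_idx, t_pos, t_neg, lifted_fp=lifted_fp,
                    lifted_sim=lifted_sim, training=True, rng=rng)
            else:
                loss, grads = euclidean_loss_and_grads(
                    params, config.variant, d_idx, k_idx, t_pos, t_neg)
            for g in grads.values():
                if not np.all(np.isfinite(g)):
                    raise TrainingError(
                        f"non-finite gradient at epoch {epoch}, batch {start // config.batch_size}")
            _apply_grads(params, grads, adam, radam, lorentz)
            losses.append(loss)
        record = {"epoch": epoch, "loss": float(np.mean(losses))}
        if valid_store is not None and len(valid_store) > 0:
            results = rank_store(params, valid_store, features=features,
                                 variant=config.variant)
            record["valid_mrr"] = mrr(results)
            if record["valid_mrr"] > best_mrr:
                best_mrr = record["valid_mrr"]
                best = copy.deepcopy(params)
                stall = 0
            else:
                stall += 1
        history.append(record)
        if verbose:
            print(f"epoch {epoch}: " + ", ".join(f"{k}={v:.4f}" for k, v in record.items()
                                                 if k != "epoch"))
        if valid_store is not None and stall > config.patience:
            break
    if valid_store is None or best_mrr == -np.inf:
        best = params
    return best, history


def _apply_grads(params, grads, adam: Adam, radam: RiemannianAdam, lorentz: bool):
    if lorentz:
        for name in ("disease_W", "disease_v", "disease_b", "drug_bias", "target_bias"):
            adam.step(name, getattr(params, name), grads[name])
        if "drug_points" in grads:
            params.drug_points = radam.step("drug_points", params.drug_points,
                                            grads["drug_points"])
        if "target_points" in grads:
            params.target_points = radam.step("target_points", params.target_points,
                                              grads["target_points"])
        for enc_name in ("drug_encoder", "target_encoder"):
            enc = getattr(params, enc_name)
            if enc is not None:
                adam.step(f"{enc_name}_W", enc.W, grads[f"{enc_name}_W"])
                adam.step(f"{enc_name}_v", enc.v, grads[f"{enc_name}_v"])
                b = np.array([enc.b])
                adam.step(f"{enc_name}_b", b, np.array([grads[f"{enc_name}_b"]]))
                enc.b = float(b[0])
    else:
        for name, g in grads.items():
            adam.step(name, getattr(params, name), g)
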