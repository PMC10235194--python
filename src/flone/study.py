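"""The self-contained scaled-down study on the synthetic DDT fixture.

These functions define one reproducible protocol — fixture, splits, training
schedule — used both by the acceptance script and by the learning tests, so
the numbers they report are produced by the same code path.

The fixture is the default :class:`flone.synthetic.SynthConfig` network
(60 drugs, 50 targets, 25 diseases, seed 0): triples are extracted from the
emitted edge list by triangle closure and split by drug-target pair
(60/20/20, five independent repeats).  Models are 16-dimensional, trained
with the BCE loss, N' = 10 negatives filtered against the full extracted
triple set, Riemannian Adam on the embedding tables, and selected by
validation MRR.  The training schedule (learning rate 2e-3, dropout 0.2,
drug/target tables initialized at spatial scale 0.3, at most 400 epochs
with patience 120) was fixed as part of the protocol; problem sizes keep a
full train-and-evaluate cycle around a few seconds on one CPU.
"""

from __future__ import annotations

import numpy as np

from . import data as dt
from . import evaluation as ev
from . import model as fm
from . import training as tr
from .synthetic import SynthConfig, generate_features, generate_network

#: training schedule of the scaled-down study (16-dim models)
STUDY_TRAIN_KW = dict(
    dim=16, learning_rate=2e-3, dropout=0.2, init_scale=0.3,
    n_negatives=10, epochs=400, patience=120, batch_size=512,
)

#: fraction of drugs forced out of training in the unseen-drug study
HOLDOUT_FRACTION = 0.15


def build_fixture(seed: int = 0, config: SynthConfig | None = None):
    """Generate the study network and extract its triple store from the edges.

    Returns ``(store, features, network)``; the store is the triangle-closed
    extraction over the emitted edge list (a superset of the planted
    triples), carrying the full entity vocabulary.
    """
    config = config or SynthConfig(seed=seed)
    network = generate_network(config)
    extracted = dt.extract_triples(network.edges)
    store = dt.TripleStore(extracted.triples, vocab=network.planted.vocab)
    features = generate_features(network, config)
    return store, features, network


def train_variant(store, split, variant: str, features=None, seed: int = 0,
                  **overrides):
    """Train one variant on a (manifest, train, valid, test) split tuple."""
    _, train_store, valid_store, _ = split
    cfg = tr.TrainConfig(variant=variant, seed=seed,
                         **{**STUDY_TRAIN_KW, **overrides})
    feats = features if variant in ("flone_ecfp_seq", "flone_ecfp_none",
                                    "flone_none_seq") else None
    params, history = tr.train(train_store, valid_store, feats, cfg,
                               known_store=store)
    return params, history


def run_base_study(seed: int = 0, n_repeats: int = 5, ks=(1, 3, 10)):
    """Train flone_base on each pair-grouped repeat and evaluate the test MRR.

    ``seed`` offsets both the split shuffling and the per-repeat training
    seeds.  Returns a dict with per-repeat test reports, their mean, and the
    random-ranking reference H_n / n for the target vocabulary size.
    """
    store, features, _ = build_fixture()
    splits = dt.split_by_pair(store, seed=seed, n_repeats=n_repeats)
    reports = []
    for rep_idx, split in enumerate(splits):
        params, _ = train_variant(store, split, "flone_base",
                                  seed=seed + rep_idx)
        _, train_store, _, test_store = split
        reports.append(ev.evaluate(params, test_store, train_store, ks=ks))
    agg = ev.aggregate_reports(reports)
    return {
        "per_repeat_mrr": [r["overall"]["mrr"] for r in reports],
        "mean": agg["overall"],
        "reports": reports,
        "random_mrr": ev.expected_random_mrr(len(store.targets)),
        "n_candidates": len(store.targets),
    }


def run_unseen_drug_study(seed: int = 0, n_repeats: int = 5, ks=(1, 3, 10)):
    """Compare flone_base and flone_ecfp_seq on triples of held-out drugs.

    For each repeat, 15 % of drugs are removed from train/valid entirely
    (their pairs moved to test), both variants are trained on the remaining
    triples, and MRR is evaluated on the ``unseen_drug`` test partition.
    """
    store, features, _ = build_fixture()
    splits = dt.split_by_pair(store, seed=seed, n_repeats=n_repeats)
    out = {"base_unseen_mrr": [], "encoder_unseen_mrr": [],
           "base_reports": [], "encoder_reports": []}
    for rep_idx, split in enumerate(splits):
        manifest = split[0]
        held = dt.hold_out_drugs(manifest, store, HOLDOUT_FRACTION,
                                 seed=seed + rep_idx)
        _, train_store, valid_store, test_store = held
        for variant, key in (("flone_base", "base"), ("flone_ecfp_seq", "encoder")):
            params, _ = train_variant(store, held, variant, features=features,
                                      seed=seed + rep_idx)
            report = ev.evaluate(params, test_store, train_store, ks=ks,
                                 features=features if key == "encoder" else None,
                                 variant=variant)
            part = report["per_partition"].get("unseen_drug")
            out[f"{key}_unseen_mrr"].append(part["mrr"] if part else float("nan"))
            out[f"{key}_reports"].append(report)
    out["wins"] = int(np.sum(np.asarray(out["encoder_unseen_mrr"]) >
                             np.asarray(out["base_unseen_mrr"])))
    return out
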