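"""Model / Results facade.

``FLONEModel`` is built from triple stores (plus optional encoder features),
``fit()`` runs the optimization and returns a ``FLONEResults`` object that
carries the fitted parameters, the per-epoch history, evaluation helpers,
the Poincare projection of the embedding space and a ``summary()`` table.

    >>> model = FLONEModel(train, valid, variant="flone_base", dim=16, seed=0)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> report = res.evaluate(test)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import geometry as geo
from . import model as fm
from . import training as tr
from .data import TripleStore
from .exceptions import ConfigurationError


class FLONEModel:
    """Translation-based DDT triple completion model (Lorentz or Euclidean).

    Parameters
    ----------
    train_store, valid_store : TripleStore
        Known triples for fitting and for epoch-wise model selection
        (validation MRR).  Both should share the parent store's vocabulary.
    variant : str
        One of ``flone_base``, ``flone_ecfp_seq``, ``flone_ecfp_none``,
        ``flone_none_seq`` (Lorentz) or ``ddte``, ``ddte_bias``, ``fec``
        (Euclidean baselines).
    features : EncoderInputs, optional
        Drug fingerprints / target similarity; required by encoder variants.
    **config
        Any :class:`flone.training.TrainConfig` field (dim, learning_rate,
        epochs, n_negatives, seed, ...).
    """

    def __init__(self, train_store: TripleStore, valid_store: TripleStore | None = None,
                 variant: str = "flone_base", features: fm.EncoderInputs | None = None,
                 known_store: TripleStore | None = None, **config):
        self.train_store = train_store
        self.valid_store = valid_store
        self.features = features
        self.known_store = known_store
        self.config = tr.TrainConfig(variant=variant, **config)
        tr._check_variant_features(variant, features)

    @classmethod
    def from_files(cls, train_tsv, valid_tsv=None, fingerprints_tsv=None,
                   similarity_tsv=None, **kwargs):
        """Build from split TSVs.

        The entity vocabulary is taken from a ``manifest.json`` next to the
        training file when one exists (written by ``split``, it records the
        parent store's full entity universe); otherwise the union of the
        entities in the given files is used.
        """
        import json
        from pathlib import Path

        from .data import SplitManifest, TripleStore, load_triples
        train = load_triples(train_tsv)
        valid = load_triples(valid_tsv) if valid_tsv else None
        manifest_path = Path(train_tsv).parent / "manifest.json"
        if manifest_path.exists():
            vocab = SplitManifest.from_json(json.loads(manifest_path.read_text())).vocab
        else:
            stores = [train] + ([valid] if valid else [])
            vocab = tuple(sorted(set().union(*(set(s.vocab[i]) for s in stores)))
                          for i in range(3))
        train = TripleStore(train.triples, vocab=vocab)
        if valid is not None:
            valid = TripleStore(valid.triples, vocab=vocab)
        features = None
        if fingerprints_tsv or similarity_tsv:
            features = fm.EncoderInputs.load(fingerprints_tsv, similarity_tsv)
        return cls(train, valid, features=features, **kwargs)

    def fit(self, verbose: bool = False) -> "FLONEResults":
        params, history = tr.train(self.train_store, self.valid_store,
                                   self.features, self.config,
                                   known_store=self.known_store, verbose=verbose)
        return FLONEResults(self, params, history)


class FLONEResults:
    """Fitted model state: parameters, history, evaluation and projection."""

    def __init__(self, model: FLONEModel, params, history):
        self.model = model
        self.params = params
        self.history = history
        self.config = model.config
        self.variant = model.config.variant

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, test_store: TripleStore, train_store: TripleStore | None = None,
                 ks=(1, 3, 10), filtered: bool = False) -> dict:
        """MRR / Hits@K report, overall and per seen/unseen partition."""
        return ev.evaluate(self.params, test_store,
                           train_store or self.model.train_store, ks=ks,
                           features=self.model.features, variant=self.variant,
                           filtered=filtered)

    def rank_targets(self, drug: str, disease: str) -> pd.Series:
        """All candidate targets scored for one query, best first."""
        if self.variant in fm.EUCLIDEAN_VARIANTS:
            scores = fm.score_all_targets_euclidean(self.params, drug, disease,
                                                    self.variant)
        else:
            scores = fm.score_all_targets(self.params, drug, disease,
                                          features=self.model.features)
        return pd.Series(scores, index=self.params.targets).sort_values(ascending=False)

    # -- embedding geometry ---------------------------------------------------
    def project_targets(self) -> pd.DataFrame:
        """Poincare-ball coordinates of every target embedding (Lorentz variants)."""
        if self.variant in fm.EUCLIDEAN_VARIANTS:
            raise ConfigurationError("Poincare projection applies to Lorentz variants only")
        _, table = fm.materialize_tables(self.params, self.model.features)
        coords = geo.lorentz_to_poincare(table, self.params.c)
        cols = [f"coord_{i + 1}" for i in range(coords.shape[1])]
        return pd.DataFrame(coords, index=self.params.targets, columns=cols)

    # -- presentation ---------------------------------------------------------
    @property
    def best_valid_mrr(self) -> float | None:
        vals = [h["valid_mrr"] for h in self.history if "valid_mrr" in h]
        return max(vals) if vals else None

    def summary(self) -> str:
        cfg = self.config
        lines = ["FLONE triple-completion results",
                 "=" * 46,
                 f"{'variant':<28}{self.variant}",
                 f"{'embedding dim':<28}{cfg.dim}",
                 f"{'curvature c':<28}{cfg.c:g}" if self.variant in fm.LORENTZ_VARIANTS else
                 f"{'space':<28}Euclidean",
                 f"{'drugs / targets / diseases':<28}"
                 f"{len(self.params.drugs)} / {len(self.params.targets)} / {len(self.params.diseases)}",
                 f"{'training triples':<28}{len(self.model.train_store)}",
                 f"{'epochs run':<28}{len(self.history)}",
                 ]
        if self.variant in fm.LORENTZ_VARIANTS:
            counts = fm.parameter_count(self.params)
            lines.append(f"{'trainable parameters':<28}{counts['total']}")
        if self.history:
            lines.append(f"{'final training loss':<28}{self.history[-1]['loss']:.4f}")
        if self.best_valid_mrr is not None:
            lines.append(f"{'best validation MRR':<28}{self.best_valid_mrr:.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------
    def save(self, out_dir) -> None:
        out = Path(out_dir)
        fm.save_checkpoint(self.params, out, self.variant,
                           extra={"config": dataclasses.asdict(self.config)})
        (out / "history.jsonl").write_text(
            "\n".join(json.dumps(h) for h in self.history) + "\n")
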