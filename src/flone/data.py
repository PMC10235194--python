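"""Drug-disease-target (DDT) triple stores.

A heterogeneous DDT network is given as a typed, undirected edge list with
edge types ``drug_disease``, ``drug_target`` and ``disease_target``.  A triple
(D, D', T) is *known* iff all three edges (D, D'), (D, T) and (D', T) exist —
i.e. the three entities form a closed triangle in the network.

Two leakage controls from knowledge-graph-completion practice are provided:

* **Disease de-duplication** — diseases whose drug-target pair sets are nearly
  identical act like synonymous predicates and inflate test scores.  A greedy
  pass keeps a disease only if its Jaccard similarity with every already-kept
  disease is at or below a threshold (default 0.6, i.e. remove > 60 %
  overlap).
* **Pair-grouped splitting** — all triples sharing a (drug, target) pair are
  assigned to the same train/valid/test split, so the model never sees an
  implicit (drug, target) association of a test query during training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ParseError, SplitError

EDGE_TYPES = ("drug_disease", "drug_target", "disease_target")


@dataclass(frozen=True, order=True)
class DDTTriple:
    """One known (drug, disease, target) association."""

    drug: str
    disease: str
    target: str

    def __post_init__(self):
        if not (self.drug and self.disease and self.target):
            raise ParseError(f"triple ids must be non-empty, got {self!r}")


class TripleStore:
    """Indexed collection of DDT triples with entity vocabularies.

    Vocabularies default to exactly the ids occurring in the triples; an
    explicit (drugs, targets, diseases) vocabulary may be supplied to embed a
    split inside its parent store's entity universe (entities absent from the
    split — the unseen-entity scenario — then stay in the vocabulary).
    """

    def __init__(self, triples, vocab=None, strict: bool = True):
        seen = set()
        uniq = []
        for t in triples:
            if t in seen:
                if strict:
                    raise ParseError(f"duplicate triple {t}")
                continue
            seen.add(t)
            uniq.append(t)
        self.triples: list[DDTTriple] = sorted(uniq)
        occ_d = sorted({t.drug for t in self.triples})
        occ_t = sorted({t.target for t in self.triples})
        occ_k = sorted({t.disease for t in self.triples})
        if vocab is None:
            self.drugs, self.targets, self.diseases = occ_d, occ_t, occ_k
        else:
            drugs, targets, diseases = vocab
            self.drugs = sorted(drugs)
            self.targets = sorted(targets)
            self.diseases = sorted(diseases)
            missing = (set(occ_d) - set(self.drugs)) | (set(occ_t) - set(self.targets)) \
                | (set(occ_k) - set(self.diseases))
            if missing:
                raise ParseError(f"vocabulary does not cover triple ids: {sorted(missing)[:5]}")
        self.drug_index = {d: i for i, d in enumerate(self.drugs)}
        self.target_index = {t: i for i, t in enumerate(self.targets)}
        self.disease_index = {k: i for i, k in enumerate(self.diseases)}
        self.known: dict[tuple[str, str], set[str]] = {}
        for t in self.triples:
            self.known.setdefault((t.drug, t.disease), set()).add(t.target)

    # -- container protocol -------------------------------------------------
    def __len__(self):
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)

    def __contains__(self, triple: DDTTriple):
        return triple.target in self.known.get((triple.drug, triple.disease), ())

    @property
    def vocab(self):
        return (self.drugs, self.targets, self.diseases)

    def positives(self, drug: str, disease: str) -> set[str]:
        """Targets known to associate with (drug, disease)."""
        return set(self.known.get((drug, disease), set()))

    def pairs(self) -> list[tuple[str, str]]:
        """Sorted distinct (drug, target) pairs."""
        return sorted({(t.drug, t.target) for t in self.triples})

    def disease_pair_sets(self) -> dict[str, frozenset]:
        """Per-disease set of (drug, target) pairs it annotates."""
        out: dict[str, set] = {}
        for t in self.triples:
            out.setdefault(t.disease, set()).add((t.drug, t.target))
        return {k: frozenset(v) for k, v in out.items()}

    def indices(self):
        """Triples as (drug_idx, disease_idx, target_idx) int arrays."""
        d = np.array([self.drug_index[t.drug] for t in self.triples], dtype=np.int64)
        k = np.array([self.disease_index[t.disease] for t in self.triples], dtype=np.int64)
        j = np.array([self.target_index[t.target] for t in self.triples], dtype=np.int64)
        return d, k, j


# ---------------------------------------------------------------------------
# triple extraction
# ---------------------------------------------------------------------------

def extract_triples(edges, strict: bool = True) -> TripleStore:
    """Close triangles in a typed edge list into DDT triples.

    ``edges`` is an iterable of ``(a, b, edge_type)`` rows; endpoint order is
    irrelevant (edges are undirected).  A triple (D, D', T) is emitted iff the
    drug-disease edge {D, D'}, the drug-target edge {D, T} and the
    disease-target edge {D', T} are all present.  Entity roles are implied by
    the edge types; ids are assumed consistently typed.
    """
    dd_nbrs: dict[str, set[str]] = {}   # partner -> drugs, via drug_disease
    dt_nbrs: dict[str, set[str]] = {}   # partner -> drugs, via drug_target
    kt_pairs: list[tuple[str, str]] = []
    for line_no, row in enumerate(edges, start=1):
        try:
            a, b, et = row
        except (TypeError, ValueError) as exc:
            raise ParseError(f"edge row {line_no}: expected (head, tail, type), got {row!r}") from exc
        if not (a and b):
            raise ParseError(f"edge row {line_no}: empty endpoint id")
        if et == "drug_disease":
            dd_nbrs.setdefault(a, set()).add(b)
            dd_nbrs.setdefault(b, set()).add(a)
        elif et == "drug_target":
            dt_nbrs.setdefault(a, set()).add(b)
            dt_nbrs.setdefault(b, set()).add(a)
        elif et == "disease_target":
            kt_pairs.append((a, b))
        else:
            raise ParseError(
                f"edge row {line_no}: unknown edge type {et!r} (expected one of {EDGE_TYPES})"
            )
    triples = set()
    for u, v in kt_pairs:
        # try both role assignments of the disease-target edge; with
        # consistently typed ids only the correct one yields closed triangles
        for disease, target in ((u, v), (v, u)):
            drugs = dd_nbrs.get(disease, set()) & dt_nbrs.get(target, set())
            for drug in drugs:
                triples.add(DDTTriple(drug, disease, target))
    return TripleStore(sorted(triples), strict=strict)


# ---------------------------------------------------------------------------
# disease de-leakage filter
# ---------------------------------------------------------------------------

def jaccard(pair_set_a, pair_set_b) -> float:
    """Jaccard similarity |A n B| / |A u B|; 0 when both sets are empty."""
    a, b = set(pair_set_a), set(pair_set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def filter_diseases(store: TripleStore, threshold: float = 0.6):
    """Greedily drop diseases whose drug-target pair sets overlap too much.

    Diseases are visited in descending pair-set size (ties broken by
    lexicographic id, so richer annotations survive); one is kept iff its
    Jaccard similarity with every already-kept disease is <= ``threshold``.
    Returns ``(filtered_store, removed_report)`` where the report maps each
    removed disease to the kept disease that displaced it and their Jaccard.
    """
    if not (0.0 < threshold <= 1.0):
        raise SplitError(f"threshold must be in (0, 1], got {threshold}")
    sets = store.disease_pair_sets()
    order = sorted(sets, key=lambda k: (-len(sets[k]), k))
    kept: list[str] = []
    removed: dict[str, dict] = {}
    for k in order:
        clash = None
        for other in kept:
            j = jaccard(sets[k], sets[other])
            if j > threshold:
                clash = (other, j)
                break
        if clash is None:
            kept.append(k)
        else:
            removed[k] = {"kept_disease": clash[0], "jaccard": clash[1]}
    kept_set = set(kept)
    filtered = TripleStore([t for t in store if t.disease in kept_set])
    return filtered, removed


# ---------------------------------------------------------------------------
# pair-grouped splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitManifest:
    """Record of one train/valid/test split of (drug, target) pairs.

    Carries the parent store's entity vocabulary so that split files written
    to disk can be reloaded into the full entity universe (split TSVs alone
    cannot know about entities they do not mention).
    """

    ratios: tuple[float, float, float]
    seed: int
    repeat: int
    train_pairs: list[tuple[str, str]]
    valid_pairs: list[tuple[str, str]]
    test_pairs: list[tuple[str, str]]
    vocab: tuple[list[str], list[str], list[str]] | None = None

    def to_json(self) -> dict:
        return {
            "ratios": list(self.ratios),
            "seed": self.seed,
            "repeat": self.repeat,
            "train_pairs": [list(p) for p in self.train_pairs],
            "valid_pairs": [list(p) for p in self.valid_pairs],
            "test_pairs": [list(p) for p in self.test_pairs],
            "vocab": [list(v) for v in self.vocab] if self.vocab else None,
        }

    @classmethod
    def from_json(cls, d: dict) -> "SplitManifest":
        return cls(
            ratios=tuple(d["ratios"]), seed=d["seed"], repeat=d["repeat"],
            train_pairs=[tuple(p) for p in d["train_pairs"]],
            valid_pairs=[tuple(p) for p in d["valid_pairs"]],
            test_pairs=[tuple(p) for p in d["test_pairs"]],
            vocab=tuple(list(v) for v in d["vocab"]) if d.get("vocab") else None,
        )


def split_by_pair(store: TripleStore, ratios=(0.6, 0.2, 0.2), seed: int = 0,
                  n_repeats: int = 5):
    """Split triples into train/valid/test grouped by (drug, target) pair.

    Distinct pairs are shuffled per repeat (generator seeded ``seed + repeat``)
    and partitioned by count — floor(ratio * n) pairs to train and valid, the
    remainder to test — and every triple follows its pair, so no pair ever
    spans two splits.  The three split stores of a repeat share the parent
    store's vocabulary (entities may be absent from train: the unseen-entity
    scenario is preserved by design).

    Returns a list of ``(manifest, train_store, valid_store, test_store)``.
    """
    if len(ratios) != 3 or any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise SplitError(f"ratios must be three positives summing to 1, got {ratios}")
    pairs = store.pairs()
    if len(pairs) < 3:
        raise SplitError(f"need at least 3 drug-target pairs to split, got {len(pairs)}")
    by_pair: dict[tuple[str, str], list[DDTTriple]] = {}
    for t in store:
        by_pair.setdefault((t.drug, t.target), []).append(t)
    out = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(seed + rep)
        perm = list(rng.permutation(len(pairs)))
        shuffled = [pairs[i] for i in perm]
        n_train = int(np.floor(ratios[0] * len(pairs)))
        n_valid = int(np.floor(ratios[1] * len(pairs)))
        groups = (shuffled[:n_train],
                  shuffled[n_train:n_train + n_valid],
                  shuffled[n_train + n_valid:])
        manifest = SplitManifest(tuple(ratios), seed, rep,
                                 sorted(groups[0]), sorted(groups[1]), sorted(groups[2]),
                                 vocab=store.vocab)
        stores = tuple(
            TripleStore([t for p in g for t in by_pair[p]], vocab=store.vocab)
            for g in groups
        )
        out.append((manifest, *stores))
    return out


def hold_out_drugs(manifest: SplitManifest, store: TripleStore, fraction: float,
                   seed: int = 0):
    """Force a fraction of drugs to be entirely unseen during training.

    Selects ``round(fraction * n_drugs)`` drugs (at least 1) uniformly at
    random among drugs present in the parent store and moves every one of
    their pairs from train/valid into test.  Emulates the prospective
    scenario where a query drug has no known triples at all; used to probe
    feature-based encoders.  Returns ``(manifest, train, valid, test)``.
    """
    if not (0.0 < fraction < 1.0):
        raise SplitError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    drugs = sorted({t.drug for t in store})
    n_hold = max(1, int(round(fraction * len(drugs))))
    held = set(rng.choice(drugs, size=n_hold, replace=False).tolist())

    def _move(pairs):
        kept = [p for p in pairs if p[0] not in held]
        moved = [p for p in pairs if p[0] in held]
        return kept, moved

    train_p, m1 = _move(manifest.train_pairs)
    valid_p, m2 = _move(manifest.valid_pairs)
    test_p = sorted(manifest.test_pairs + m1 + m2)
    if not train_p or not valid_p:
        raise SplitError("drug hold-out emptied the train or valid split")
    new_manifest = SplitManifest(manifest.ratios, manifest.seed, manifest.repeat,
                                 sorted(train_p), sorted(valid_p), test_p,
                                 vocab=manifest.vocab or store.vocab)
    by_pair: dict[tuple[str, str], list[DDTTriple]] = {}
    for t in store:
        by_pair.setdefault((t.drug, t.target), []).append(t)
    stores = tuple(
        TripleStore([t for p in g for t in by_pair[p]], vocab=store.vocab)
        for g in (new_manifest.train_pairs, new_manifest.valid_pairs, new_manifest.test_pairs)
    )
    return (new_manifest, *stores)


# ---------------------------------------------------------------------------
# TSV / JSON I/O
# ---------------------------------------------------------------------------

_EDGE_HEADER = ["head_id", "tail_id", "edge_type"]
_TRIPLE_HEADER = ["drug_id", "disease_id", "target_id"]


def load_edges(path) -> list[tuple[str, str, str]]:
    """Read a typed edge list TSV with columns head_id, tail_id, edge_type."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EDGE_HEADER:
            raise ParseError(f"{path}: expected header {_EDGE_HEADER}, got {header}")
        edges = []
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ParseError(f"{path}:{line_no}: expected 3 columns, got {len(cols)}")
            if cols[2] not in EDGE_TYPES:
                raise ParseError(f"{path}:{line_no}: unknown edge type {cols[2]!r}")
            edges.append(tuple(cols))
    return edges


def save_edges(edges, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for a, b, et in sorted(edges):
            fh.write(f"{a}\t{b}\t{et}\n")


def load_triples(path, vocab=None, strict: bool = True) -> TripleStore:
    """Read a triples TSV (drug_id, disease_id, target_id) into a TripleStore."""
    path = Path(path)
    triples = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRIPLE_HEADER:
            raise ParseError(f"{path}: expected header {_TRIPLE_HEADER}, got {header}")
        seen = set()
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ParseError(f"{path}:{line_no}: expected 3 columns, got {len(cols)}")
            t = DDTTriple(*cols)
            if t in seen:
                if strict:
                    raise ParseError(f"{path}:{line_no}: duplicate triple {t}")
                warnings.warn(f"{path}:{line_no}: duplicate triple {t} dropped")
                continue
            seen.add(t)
            triples.append(t)
    return TripleStore(triples, vocab=vocab)


def save_triples(store: TripleStore, path) -> None:
    """Write a TripleStore as TSV in canonical (lexicographic) row order."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_TRIPLE_HEADER) + "\n")
        for t in store.triples:
            fh.write(f"{t.drug}\t{t.disease}\t{t.target}\n")


def save_split(result, out_dir) -> None:
    """Write one (manifest, train, valid, test) tuple into a directory."""
    manifest, train, valid, test = result
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_triples(train, out / "train.tsv")
    save_triples(valid, out / "valid.tsv")
    save_triples(test, out / "test.tsv")
    (out / "manifest.json").write_text(json.dumps(manifest.to_json(), indent=1))


def load_split(out_dir, vocab=None):
    out = Path(out_dir)
    manifest = SplitManifest.from_json(json.loads((out / "manifest.json").read_text()))
    vocab = vocab or manifest.vocab
    return (manifest,
            load_triples(out / "train.tsv", vocab=vocab),
            load_triples(out / "valid.tsv", vocab=vocab),
            load_triples(out / "test.tsv", vocab=vocab))
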