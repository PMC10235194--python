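"""Ranking evaluation and network hyperbolicity.

Each test triple (D, D', T) is scored against *every* candidate target in
the vocabulary and the true target's 1-based rank is recorded.  Ranking is
raw by default — other known positives of (D, D') are not removed from the
candidate list — with a clearly-labeled filtered mode as an option (the two
modes give different numbers).  Ties are broken pessimistically: the true
target is ranked after every equal-scored competitor.

Summary metrics are the mean reciprocal rank, MRR = mean(1/rank_i), and
Hits@K, the fraction of queries ranked within the top K.  Test triples are
partitioned into ``unseen_drug`` (drug absent from training triples),
``unseen_target`` and ``seen_both`` to separate structural generalization
from feature-based generalization; when a triple's drug and target are both
unseen, the drug label takes precedence.

Gromov hyperbolicity delta measures how tree-like the DDT network is via the
four-point condition on hop distances: for each node quadruple the three
pairwise-sum matchings sorted descending give (S_max - S_mid)/2, and delta
is the maximum over quadruples (0 for trees, large for grids).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from . import model as fm
from .data import TripleStore
from .exceptions import EvaluationError

PARTITIONS = ("unseen_drug", "unseen_target", "seen_both")

#: component size up to which the exact quadruple enumeration is used
EXACT_DELTA_NODES = 300


@dataclass(frozen=True)
class RankingResult:
    """Rank of one test triple's true target among all candidates."""

    drug: str
    disease: str
    target: str
    rank: int
    n_candidates: int
    partition: str = "seen_both"

    def __post_init__(self):
        if not (1 <= self.rank <= self.n_candidates):
            raise EvaluationError(
                f"rank {self.rank} outside [1, {self.n_candidates}]")


def rank_from_scores(scores: np.ndarray, true_idx: int) -> int:
    """1-based pessimistic rank of ``true_idx`` within a score vector."""
    s = np.asarray(scores, dtype=float)
    s_true = s[true_idx]
    higher = int(np.sum(s > s_true))
    tied = int(np.sum(s == s_true)) - 1
    return 1 + higher + tied


def rank_targets(params, drug: str, disease: str, true_target: str,
                 candidates=None, features=None, variant: str = "flone_base",
                 partition: str = "seen_both", tables=None) -> RankingResult:
    """Score candidates for one (drug, disease) query and rank the true target."""
    if variant in fm.EUCLIDEAN_VARIANTS:
        scores = fm.score_all_targets_euclidean(params, drug, disease, variant)
        vocab = params.targets
    else:
        scores = fm.score_all_targets(params, drug, disease, features=features,
                                      tables=tables)
        vocab = params.targets
    if candidates is not None:
        cand = list(candidates)
        if true_target not in cand:
            raise EvaluationError(f"true target {true_target!r} not among candidates")
        idx = [params.target_index[t] for t in cand]
        scores = scores[idx]
        true_idx = cand.index(true_target)
    else:
        if true_target not in params.target_index:
            raise EvaluationError(f"true target {true_target!r} not in vocabulary")
        true_idx = params.target_index[true_target]
        cand = vocab
    return RankingResult(drug, disease, true_target, rank_from_scores(scores, true_idx),
                         len(cand), partition)


def rank_store(params, store: TripleStore, train_store: TripleStore | None = None,
               features=None, variant: str = "flone_base",
               filtered: bool = False) -> list[RankingResult]:
    """Rank every triple of a store; raw candidates by default.

    ``filtered=True`` removes the query's *other* known positives (from the
    evaluated store and, when given, the training store) from the candidate
    scores before ranking — the alternative convention in the KGC literature.
    """
    labels = partition_test(store, train_store) if train_store is not None \
        else {t: "seen_both" for t in store}
    lorentz = variant in fm.LORENTZ_VARIANTS
    tables = fm.materialize_tables(params, features, training=False) if lorentz else None
    out = []
    for t in store:
        if lorentz:
            scores = fm.score_all_targets(params, t.drug, t.disease, tables=tables)
        else:
            scores = fm.score_all_targets_euclidean(params, t.drug, t.disease, variant)
        true_idx = params.target_index[t.target]
        if filtered:
            others = store.positives(t.drug, t.disease)
            if train_store is not None:
                others |= train_store.positives(t.drug, t.disease)
            others.discard(t.target)
            scores = np.array(scores, copy=True)
            for o in others:
                scores[params.target_index[o]] = -np.inf
        out.append(RankingResult(t.drug, t.disease, t.target,
                                 rank_from_scores(scores, true_idx),
                                 scores.size, labels[t]))
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mrr(results) -> float:
    """Mean reciprocal rank, in (0, 1]."""
    ranks = [r.rank for r in results]
    if not ranks:
        raise EvaluationError("mrr of empty result list")
    return float(np.mean(1.0 / np.asarray(ranks, dtype=float)))


def hits_at_k(results, k: int) -> float:
    """Fraction of results whose true target ranks within the top k."""
    if k < 1:
        raise EvaluationError(f"k must be >= 1, got {k}")
    ranks = [r.rank for r in results]
    if not ranks:
        raise EvaluationError("hits_at_k of empty result list")
    return float(np.mean(np.asarray(ranks) <= k))


def expected_random_mrr(n_candidates: int) -> float:
    """MRR of a uniformly random ranking over n candidates: H_n / n."""
    return float(np.sum(1.0 / np.arange(1, n_candidates + 1)) / n_candidates)


def partition_test(test_store: TripleStore, train_store: TripleStore) -> dict:
    """Label each test triple unseen_drug / unseen_target / seen_both.

    Drug precedence: a triple whose drug and target are both unseen is
    labeled ``unseen_drug``.
    """
    seen_drugs = {t.drug for t in train_store}
    seen_targets = {t.target for t in train_store}
    labels = {}
    for t in test_store:
        if t.drug not in seen_drugs:
            labels[t] = "unseen_drug"
        elif t.target not in seen_targets:
            labels[t] = "unseen_target"
        else:
            labels[t] = "seen_both"
    return labels


def summarize(results, ks=(1, 3, 10)) -> dict:
    """Overall and per-partition MRR / Hits@K report (valid JSON structure)."""
    if not results:
        raise EvaluationError("summarize of empty result list")
    def block(rs):
        out = {"mrr": mrr(rs), "n": len(rs)}
        for k in ks:
            out[f"hits@{k}"] = hits_at_k(rs, k)
        return out
    report = {"overall": block(results), "per_partition": {}}
    for part in PARTITIONS:
        rs = [r for r in results if r.partition == part]
        if rs:
            report["per_partition"][part] = block(rs)
    if "hits@1" in report["overall"]:
        # 1/rank >= indicator(rank == 1) pointwise, so MRR >= Hits@1 always
        assert report["overall"]["mrr"] + 1e-12 >= report["overall"]["hits@1"]
    return report


def evaluate(params, test_store: TripleStore, train_store: TripleStore | None = None,
             ks=(1, 3, 10), features=None, variant: str = "flone_base",
             filtered: bool = False) -> dict:
    """Full ranking evaluation of a checkpoint on a test store."""
    results = rank_store(params, test_store, train_store, features=features,
                         variant=variant, filtered=filtered)
    return summarize(results, ks=ks)


def aggregate_reports(reports) -> dict:
    """Triple-count-weighted mean of several evaluation reports (over repeats)."""
    if not reports:
        raise EvaluationError("no reports to aggregate")
    out = {"per_repeat": list(reports)}
    keys = [k for k in reports[0]["overall"] if k != "n"]
    total = sum(r["overall"]["n"] for r in reports)
    out["overall"] = {
        k: float(sum(r["overall"][k] * r["overall"]["n"] for r in reports) / total)
        for k in keys}
    out["overall"]["n"] = total
    out["per_partition"] = {}
    for part in PARTITIONS:
        blocks = [r["per_partition"][part] for r in reports if part in r.get("per_partition", {})]
        if blocks:
            n_part = sum(b["n"] for b in blocks)
            out["per_partition"][part] = {
                k: float(sum(b[k] * b["n"] for b in blocks) / n_part) for k in keys}
            out["per_partition"][part]["n"] = n_part
    return out


# ---------------------------------------------------------------------------
# Gromov hyperbolicity
# ---------------------------------------------------------------------------

def ddt_graph(store: TripleStore) -> nx.Graph:
    """Undirected heterogeneous graph of a triple store (all three edge kinds)."""
    g = nx.Graph()
    for t in store:
        g.add_edge(("drug", t.drug), ("disease", t.disease))
        g.add_edge(("drug", t.drug), ("target", t.target))
        g.add_edge(("disease", t.disease), ("target", t.target))
    return g


def _distance_matrix(graph: nx.Graph) -> np.ndarray:
    comp = max(nx.connected_components(graph), key=len)
    sub = graph.subgraph(comp)
    adj = nx.to_scipy_sparse_array(sub, format="csr")
    return shortest_path(adj, method="D", unweighted=True)


def gromov_delta(obj, mode: str = "auto", n_samples: int = 100_000,
                 seed: int = 0) -> float:
    """Gromov four-point hyperbolicity of a graph or triple store.

    Computed on hop distances over the largest connected component.  In
    ``exact`` mode every node quadruple is enumerated (used automatically up
    to 300 nodes); ``sampled`` draws ``n_samples`` uniform quadruples and is
    a lower bound on the exact value.  Graphs with fewer than 4 nodes return
    0 with a warning.
    """
    graph = obj if isinstance(obj, nx.Graph) else ddt_graph(obj)
    if graph.number_of_nodes() < 4:
        warnings.warn("fewer than 4 nodes: Gromov delta is trivially 0")
        return 0.0
    D = _distance_matrix(graph)
    n = D.shape[0]
    if n < 4:
        warnings.warn("largest component has fewer than 4 nodes: delta 0")
        return 0.0
    if mode == "auto":
        mode = "exact" if n <= EXACT_DELTA_NODES else "sampled"
    if mode == "exact":
        return _delta_exact(D)
    if mode == "sampled":
        return _delta_sampled(D, n_samples, seed)
    raise EvaluationError(f"unknown mode {mode!r}")


def _quad_delta(s1, s2, s3):
    stacked = np.stack([s1, s2, s3])
    stacked.sort(axis=0)
    return (stacked[2] - stacked[1]) / 2.0


def _delta_exact(D: np.ndarray) -> float:
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    best = 0.0
    # for each pair (i, j), sweep all pairs (k, l): the three matching sums of
    # the quadruple {i, j, k, l}; degenerate overlaps contribute 0 and are harmless
    for i in range(n - 1):
        for j in range(i + 1, n):
            s1 = D[i, j] + D[iu, ju]
            s2 = D[i, iu] + D[j, ju]
            s3 = D[i, ju] + D[j, iu]
            best = max(best, float(np.max(_quad_delta(s1, s2, s3))))
    return best


def _delta_sampled(D: np.ndarray, n_samples: int, seed: int) -> float:
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    q = rng.integers(0, n, size=(n_samples, 4))
    distinct = ((q[:, 0] != q[:, 1]) & (q[:, 0] != q[:, 2]) & (q[:, 0] != q[:, 3])
                & (q[:, 1] != q[:, 2]) & (q[:, 1] != q[:, 3]) & (q[:, 2] != q[:, 3]))
    q = q[distinct]
    a, b, c_, d = q.T
    s1 = D[a, b] + D[c_, d]
    s2 = D[a, c_] + D[b, d]
    s3 = D[a, d] + D[b, c_]
    if q.shape[0] == 0:
        return 0.0
    return float(np.max(_quad_delta(s1, s2, s3)))
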