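# Methods

## Model

A known association is a triple *(drug D, disease D′, target T)* whose three
pairwise edges all exist in the heterogeneous DDT network.  The decoder
treats the disease as a relation acting on the drug embedding:

* Drugs and targets are points of the Lorentz model `L^n_c`
  (`⟨x,x⟩_L = 1/c`, positive time coordinate; `c = −1` throughout, carried as
  a parameter only for testability).
* Each disease owns one **fully Lorentz linear layer**: gate
  `a = λ·σ(vᵀx + b) + ε`, spatial image `a·Wx̃/‖Wx̃‖` with `x̃ = dropout(x)`,
  time coordinate `√(a² − 1/c)`.  The time term is the unique choice for
  which the output satisfies the manifold constraint exactly, given that the
  spatial norm is `a`; with this convention any gate floor `ε > 0` is
  admissible.  Dropout applies to the full (n+1)-coordinate input of the
  `W` branch, training mode only.  If the mask happens to zero a sparse
  input row's entire image (possible for one-hot-like similarity rows), the
  undropped row is used for that sample; a zero image with dropout off
  raises a degenerate-transform error.
* Score: `p = σ(−d²_L(FLLinear_{D′}(x_D), x_T) + b_D + b_T + φ)` with
  squared Lorentzian distance `d²_L = 2/c − 2⟨·,·⟩_L`, scalar per-entity
  biases, and margin `φ`.

Embeddings come from self-contained look-up tables (one manifold point per
entity, stored as all n+1 coordinates so Riemannian optimization is natural)
or from **hyperbolic encoders**: the drug's binary circular fingerprint
(ECFP6-style, radius 3; computed from SMILES via RDKit or supplied
precomputed) or the target's 0–1 normalized similarity row is lifted to the
manifold by the exponential map at the origin, `(0, u) ↦ exp_O((0, u))`, and
passed through one fully Lorentz linear layer down to dimension n.  Encoders
give every featured entity an embedding, trained or not — the mechanism for
unseen-entity prediction.  Exactly one layer per encoder; stacking is
configurable but off by default.

Euclidean baselines mirror the same translation structure in flat space:
`ddte` scores `σ(−‖e_D + V_{D′} − e_T‖² + φ)`, `ddte_bias` adds the entity
biases, and `fec` replaces the vector offset with a per-disease linear map —
the fully Euclidean counterpart of the Lorentz decoder.  Baseline
embeddings are not norm-constrained; the margin `φ` is included in all
variants for parity (set 0 to disable).

### Defaults

| parameter | default | meaning |
|---|---|---|
| `dim` | 16 | manifold dimension (spatial coordinates) |
| `λ` | 10 | gate scale; spatial norm of any layer output lies in (ε, λ+ε] |
| `ε` | 1.0 | gate floor |
| `φ` | 2.0 | score margin |
| `dropout` | 0.1 | layer input dropout, training only |
| `τ_manifold` | 1e−5 | tolerance on the constraint `|⟨x,x⟩_L − 1/c|` |
| `N′` | 10 | negatives per positive |
| learning rate / batch / epochs / patience | 1e−3 / 512 / 300 / 30 | Adam-family defaults, all configurable |

## Training

Negatives corrupt the target: for each positive `(D, D′, T)`, `N′` targets
are drawn uniformly with replacement among targets that do **not** form a
known triple with `(D, D′)`, re-drawn every epoch.  The known set used for
this check should be the full extracted triple set when available
(`known_store=`): with a small target vocabulary, filtering against the
training positives only would repeatedly train each held-out positive as a
negative for exactly its own future query, which measurably caps test
ranking quality; with hundreds of targets the distinction is minor.  The
loss is binary cross entropy normalized by the positive count, probabilities
clamped at 1e−7.

Euclidean parameters (layer weights, gates, biases, baseline tables) use
Adam.  Manifold tables use a Riemannian Adam: the Euclidean gradient's time
coordinate is sign-flipped (Minkowski metric), projected onto the tangent
space, moments are kept per ambient coordinate (no parallel transport — a
standard simplification), the rescaled step is re-projected and applied by
exponential-map retraction, and the time coordinate is recomputed from the
spatial ones to pin the point to the hyperboloid.  Because the tangent
projection scales with the base point's coordinates, raw steps can overflow
`cosh` once points sit far from the origin; each point's geodesic step
length is therefore clipped at 0.5.  Model selection is by validation MRR
with early-stopping patience; training is single-threaded and bit-for-bit
reproducible from the seed.  The analytic backward pass is verified against
central finite differences in the test suite for every parameter group and
every variant.

## Evaluation

Each test triple is scored against **all** targets in the vocabulary; the
true target's 1-based rank uses pessimistic tie-breaking (ranked after every
equal-scored competitor).  Ranking is raw by default — other known positives
of the query are *not* removed from the candidates; a filtered mode is
provided and clearly labeled, as the two conventions give different numbers
and published work is not always explicit about which was used.  Metrics are
MRR (main) and Hits@{1,3,10}; multiple repeats are aggregated by
triple-count-weighted means.  Test triples are partitioned into
`unseen_drug` / `unseen_target` / `seen_both` relative to the training
triples, with drug precedence when both are unseen (a convention; the
choice only affects labeling, not ranks).

Gromov hyperbolicity δ is computed on hop distances of the largest connected
component of the undirected DDT graph, by the four-point condition: for a
quadruple, sort the three pairwise-sum matchings descending and take
(S_max − S_mid)/2; δ is the maximum over quadruples.  Exact enumeration is
used up to 300 nodes, uniform sampling (a lower bound) beyond.  Trees give
δ = 0, the 4-cycle gives 1.

## Synthetic data

The generator emulates the structural properties that make real DDT
networks learnable, at desk scale (defaults: 60 drugs, 50 targets, 25
diseases, seed 0):

* Targets belong to 10 latent **families** (receptor subtypes, kinase
  subfamilies).  A drug binds `1 + Poisson(3)` targets drawn by preferential
  attachment (`(deg+1)^1.5`) weighted 1 inside its primary family and 0.15
  outside — so hub targets emerge (tree-like backbone, measured δ = 2 on the
  default fixture) and a typical drug spans 2–3 families.
* A disease is the pathology of one target family: it annotates
  `Poisson(12)` backbone drug–target edges of that family (capped by the
  pool), sampled without replacement.  Every planted triple closes a
  triangle by construction; triangle extraction over the emitted edges
  returns a superset (accidental triangles are possible and reported).
  The per-disease budget stays below the family pool so that same-family
  diseases keep distinguishable pair sets and survive the 0.6-Jaccard
  disease filter in the majority.
* Features: each target gets a random bit mask (density 0.08, width 256); a
  drug's fingerprint is the OR of its targets' masks with 5 % bit flips; a
  target pair's similarity is the Jaccard of their drug-neighbor sets, unit
  diagonal.  Feature–structure correlation is monotone in (1 − noise rate).

Two design points deserve emphasis.  First, the family structure is not
decoration: with independent per-drug target draws, a held-out drug–target
pair is statistically independent of the training triples beyond target
popularity, and *no* model could beat a popularity ranking on a
pair-grouped split — related drugs binding related target families is
precisely the regularity that makes association prediction possible.
Second, diseases annotate a single family because disease conditioning must
genuinely narrow the candidate set for translation-based completion to show
its value; a disease that mirrors its drugs' full target repertoires cannot
prune a drug's other targets from the top ranks under raw ranking.

What the generator does **not** emulate: real chemistry (fingerprints are
abstract bit masks, not molecules), realistic degree distributions of any
specific database, disease ontology structure, and annotation noise other
than fingerprint bit flips.  Passing tests on this fixture show the
machinery is correct and that the method exploits hierarchy and
similarity-predicts-interaction signals; they do not certify accuracy
levels on any real database.

## The scaled-down study

`flone.study` fixes one protocol used by both the tests and
`scripts/acceptance.py`: extract triples from the default fixture's edges,
split by drug–target pair 60/20/20 five times, train 16-dimensional models
(learning rate 2e−3, dropout 0.2, tables initialized at spatial scale 0.3,
N′ = 10 filtered against the full extracted set, at most 400 epochs,
patience 120 — a few seconds per fit on one CPU), and evaluate raw-ranking
MRR/Hits@K on the test split.  The two headline outcomes:

* the trained Lorentz decoder's test MRR exceeds three times the random
  expectation H₅₀/50 ≈ 0.09 on every repeat (typically 0.45–0.7);
* with 15 % of drugs held out of training entirely, the
  fingerprint+similarity encoder variant beats the self-contained model on
  the unseen-drug partition in every repeat (typically ~0.75 vs ~0.5).

Note that with only 50 candidate targets the self-contained model's
unseen-drug MRR remains well above the random expectation even though its
embedding for such a drug is untrained noise: the disease transform alone
narrows the field to a handful of family targets.  The near-zero unseen-
entity baselines reported for real networks are a large-candidate-set
effect (with ~400 targets, disease-only information still leaves dozens of
candidates) and do not survive this scale-down; the encoder-vs-baseline
*ordering* does.

## Known limitations

* Curvature is fixed at −1; no curvature learning.
* CPU/NumPy implementation sized for networks of hundreds to a few thousand
  entities; no GPU path, no minibatch parallelism.
* Exact δ is O(n⁴) and switches to sampled (lower-bound) mode above 300
  nodes.
* Riemannian Adam omits parallel transport of moments; with the step-norm
  clip this is stable and accurate at these scales but is not a geodesically
  exact Adam.
* The filtered-ranking mode exists but all shipped numbers use raw ranking.
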