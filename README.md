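# flone

Fully Lorentzian embedding of drug–disease–target (DDT) networks for ranking
candidate protein targets.

## The problem

Given a drug and a disease, which protein is the drug most likely to act on?
Known drug–disease, drug–target and disease–target relationships form a
heterogeneous DDT network; whenever all three edges close a triangle, the
triple *(drug D, disease D′, target T)* is a known association.  Completing
such triples — drug as subject, disease as relation, target as object — is a
knowledge-graph-completion (KGC) ranking task: score every candidate target
for the query *(D, D′)* so that true targets rank at the top of the list a
screening campaign would work through.

DDT networks are hierarchically organized (hub targets, drug classes,
disease families), and hierarchies embed with low distortion in hyperbolic
rather than Euclidean space.  `flone` therefore embeds drugs and targets as
points of the Lorentz (hyperboloid) model

```
L^n_c = { x ∈ R^(n+1) : ⟨x,x⟩_L = 1/c, x_t > 0 },   ⟨x,y⟩_L = −x_t y_t + x_sᵀ y_s,
```

with curvature c = −1, and scores a triple with a disease-specific *fully
Lorentz linear* translation of the drug embedding:

```
p(D, D′, T) = σ( −d²_L( FLLinear_{D′}(x_D), x_T ) + b_D + b_T + φ ),
d²_L(x, y)  = 2/c − 2⟨x,y⟩_L,
FLLinear(x) = ( √(a² − 1/c),  a·Wx̃/‖Wx̃‖ ),   a = λσ(vᵀx + b) + ε,  x̃ = dropout(x).
```

All operations stay on the manifold — no round trips through tangent space —
and the embedding tables are trained with Riemannian Adam (tangent-space
steps, exponential-map retraction).  Where a drug or target was never seen
in training triples, *hyperbolic encoders* produce its embedding from domain
knowledge instead: an ECFP6 circular fingerprint (drugs) or a row of a 0–1
normalized sequence-similarity matrix (targets), lifted to the manifold via
the exponential map at the origin and passed through one fully Lorentz
linear layer.  Euclidean translation baselines (vector offset, vector offset
plus entity biases, and a fully Euclidean matrix-offset counterpart) are
included for comparison.

The package also ships the data handling this task needs to be honest:
triangle-rule triple extraction from typed edge lists, removal of diseases
whose drug–target pair sets overlap by Jaccard > 0.6 (near-duplicate
predicates leak information), train/valid/test splits grouped by drug–target
pair (so no pair spans two splits), ranking evaluation (MRR, Hits@K, raw or
filtered, with seen/unseen partitions), Gromov δ-hyperbolicity of the
network, Poincaré-disk projection of embeddings, and a synthetic generator
that produces triangle-closed, family-structured DDT networks with
correlated fingerprint/similarity features so everything is testable without
downloads.

## Worked example

```python
from flone import study, data as dt
from flone.api import FLONEModel

# synthetic study fixture: 60 drugs, 50 targets, 25 diseases, seed 0
store, features, network = study.build_fixture()
_, train, valid, test = dt.split_by_pair(store, seed=0, n_repeats=1)[0]

model = FLONEModel(train, valid, variant="flone_base", known_store=store,
                   dim=16, learning_rate=2e-3, dropout=0.2, init_scale=0.3,
                   epochs=400, patience=120, seed=0)
res = model.fit()
print(res.summary())
```

```
FLONE triple-completion results
==============================================
variant                     flone_base
embedding dim               16
curvature c                 -1
drugs / targets / diseases  60 / 50 / 25
training triples            190
epochs run                  400
trainable parameters        9230
final training loss         0.1892
best validation MRR         0.6112
==============================================
```

```python
print(res.evaluate(test)["overall"])
# {'mrr': 0.5191, 'n': 62, 'hits@1': 0.4032, 'hits@3': 0.5806, 'hits@10': 0.6452}
print(res.rank_targets("DR0007", "DS0012").head(3))
# TG0022    0.906649
# TG0034    0.041634
# TG0046    0.037968
```

Test MRR 0.52 means the true target of a held-out drug–target pair sits at
reciprocal rank ~2 on average among all 50 candidates; a random ranking
would give H₅₀/50 ≈ 0.09.  `res.rank_targets` returns every candidate's
similarity probability for one (drug, disease) query, best first — the list
a virtual screen would triage.  `res.project_targets()` yields Poincaré-ball
coordinates of the target embeddings for inspecting the learned hierarchy.

The same pipeline is scriptable from the shell:

```bash
flone simulate --out data/ --seed 0
flone extract  --edges data/edges.tsv --out data/triples.tsv
flone filter   --triples data/triples.tsv --out data/filtered.tsv --threshold 0.6
flone split    --triples data/filtered.tsv --out data/splits --seed 0 --repeats 5
flone train    --train data/splits/repeat_0/train.tsv --valid data/splits/repeat_0/valid.tsv \
               --out runs/base --variant flone_base --seed 0
flone eval     --checkpoint runs/base --test data/splits/repeat_0/test.tsv \
               --train data/splits/repeat_0/train.tsv --out runs/base/metrics.json
flone delta    --triples data/filtered.tsv
flone project  --checkpoint runs/base --out runs/base/poincare.tsv
```

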