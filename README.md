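# essnet

Essential-protein prediction from protein–protein interaction (PPI)
networks and periodic gene-expression profiles.

Essential proteins are those whose loss is lethal to the organism; in a
PPI network they are a minority class (roughly one protein in five in the
classic *S. cerevisiae* compendia), and the long-standing
centrality–lethality observation says hubs tend to be essential.  `essnet`
implements a deep-learning predictor that replaces hand-picked centrality
scalars with learned features, together with the eight classic centrality
baselines and the full evaluation protocol, all runnable end-to-end on
seeded synthetic data — no database downloads required.

## The model

Each protein *v* contributes two feature sources:

* **Topology.** node2vec: second-order biased random walks (return
  parameter *p*, in–out parameter *q*) generate a corpus of node
  sequences; a skip-gram model with negative sampling trained on the
  corpus yields a 64-dimensional vector per protein.
* **Expression.** The 36-point profile (three metabolic cycles × 12 time
  points) is reshaped cycle-major into a 1×3×12 image and passed through
  parallel 2-D convolutions with kernel sizes 1, 3 and 5 (8 channels
  each, zero same-padding), concatenated (24×3×12) and max-pooled with
  window (1,2) to 24×3×6 = 432 values.

The concatenated 432 + 64 = 496 features feed a 312-unit fully connected
ReLU layer with dropout 0.1 and a 2-way softmax head giving
P(essential | v).  Training uses Adam (lr 0.001, batch 32) with
cross-entropy loss.

**Balanced epoch sampling.** With M essential and N ≫ M non-essential
training proteins, every epoch trains on all M positives plus M
negatives drawn uniformly without replacement, so no batch is biased
toward the majority class.  A given negative is missed in all k epochs
with probability

    p_miss = (1 − M/N)^k

and the epoch count is the smallest k with p_miss < α (default
α = 0.001), so with high probability every negative is seen at least
once.

**Baselines.** DC, BC, CC, EC (degree, betweenness, closeness,
eigenvector), NC (sum of edge clustering coefficients, ECC), LAC (mean
neighbor degree inside the neighbor-induced subgraph), and the
expression-hybrid PeC (Σ ECC·PCC) and WDC (Σ λ·ECC + (1−λ)·PCC), with the
top-K candidate protocol: rank, call the top K essential, report
accuracy/precision/recall/F.

The neural network (forward, analytic backward, Adam) and the skip-gram
trainer are self-contained NumPy implementations, so the whole package is
deterministic per seed and has no deep-learning framework dependency.

## Worked example

```python
from essnet import (EssentialityModel, SyntheticSpec, WalkConfig,
                    SkipGramConfig)

model = EssentialityModel.from_synthetic(
    SyntheticSpec(),                        # 1000-node scale-free study
    walk_cfg=WalkConfig(walk_length=40, walks_per_node=10, seed=0),
    sg_cfg=SkipGramConfig(window=5, epochs=3, seed=0))
res = model.fit(seed=0)
print(res.summary())
```

```
Essential-protein prediction results
====================================================
Nodes: 1000    Edges: 3984    Essential: 247 (24.7%)
Split: 800 train / 200 test (fraction 0.8, seed 0)
Sampling plan: M=198  N=602  alpha=0.001  k=18 epochs
Strategy: balanced    Features: embedding
Final-epoch mean loss: 0.1510
----------------------------------------------------
Held-out test metrics
  accuracy     0.7450
  precision    0.4808
  recall       0.5102
  F-measure    0.4950
  AUC          0.8182
  AP           0.4918
```

The synthetic study plants essentiality with probability
logistic(−3.2 + 1.1·log degree) on a preferential-attachment network
(prevalence 24.7% here), plus a weaker phase-coherence signal in the
expression profiles.  An AUC of 0.82 and an AP nearly twice the
prevalence mean the pipeline recovers the planted signal well above the
degree-only floor; recall ≈ 0.51 at threshold 0.5 reflects the balanced
sampler (training on the raw imbalanced split drops recall markedly —
see `fit(strategy="raw")`).

Ablations: `model.fit(features="DC")` swaps the node2vec vector for a
single degree scalar; `model.rank_centralities()` runs all eight
baselines under the top-K protocol.  The same workflows are available
from the shell:

```bash
essnet simulate --n-nodes 1000 --seed 42 --out data/
essnet train --synthetic --seed 0 --out run/
essnet rank-centrality --synthetic --methods DC,NC,PeC --out ranks/
```

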