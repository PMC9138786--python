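# ddifuse

Drug–drug interaction (DDI) prediction by attention fusion of three
per-drug information channels.  Co-administered drugs can interfere with
each other's mechanisms of action; screening all candidate pairs
experimentally is infeasible, so link-prediction models over the known
interaction network are used to prioritise pairs for the wet lab.  This
package is aimed at computational researchers who want a tested,
self-contained (fully offline) implementation of a multi-channel DDI
pipeline, including a synthetic-data generator with planted, recoverable
signal so every stage can be exercised and validated without external
databases.

## The model

Every drug *d* gets three 64-dimensional channel vectors:

* **chemical sequence** — the SMILES string is tokenised into chemical
  symbols, embedded token-by-token with a CBOW model
  (`h = mean(ω_context)`, exact softmax over the vocabulary), stacked
  into a 64×64 matrix (zero-padded/truncated), and reduced by one 2-D
  convolution layer (64 kernels) with global average pooling;
* **network structure** — the training-fold interaction graph is
  embedded with second-order LINE,
  `O₂ = −Σ_{(i,j)∈E} w_ij log p₂(v_j|v_i)`, inside a
  coarsen/embed/refine hierarchy (star + edge collapsing), then passed
  through a 64-unit dense layer; unseen drugs inherit a neighbour's
  vector or zeros;
* **biological function** — per receptor type (carrier, target, enzyme,
  transporter, …) a binary drug×receptor profile gives a Euclidean
  distance view; similarity network fusion (SNF) cross-diffuses the
  views into one consensus N×N similarity, and the drug's row goes
  through dense 300 → 64 layers.

The three channel tokens are fused per drug by scaled dot-product
attention, `θ̃ = softmax(QKᵀ/√d_k)V` with learned 64×64 projections, and
concatenated (192 dims).  A pair (a, b) is the concatenation
[θ̃_a ‖ θ̃_b]; a three-hidden-layer feed-forward head (256/128/64,
dropout 0.3, sigmoid) is trained end-to-end with binary cross-entropy
and Adam on balanced positive/negative pairs, with both pair orderings
during training and the mean of both orderings at prediction, so scores
are symmetric.  Evaluation implements balanced negative sampling,
70/20/10 and 5-fold cross-validation protocols (the training graph is
rebuilt per fold from training positives only), Acc/Prec/Sen/F1/MCC at
threshold 0.5, rank-statistic AUC and step-integrated AUPR, and
case-study-style candidate ranking.

Everything is NumPy; no deep-learning framework is required.  See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from ddifuse import gen_world
from ddifuse.pipeline import RunConfig, train_test_val

world = gen_world(seed=7)          # 200 drugs, 4 planted communities
result = train_test_val(world.drugs, world.edges, world.associations,
                        RunConfig(), seed=7)
r = result["report"]
print(f"AUC {r.auc:.4f}  AUPR {r.aupr:.4f}  ACC {r.acc:.4f}  "
      f"MCC {r.mcc:.4f}")
```

prints

```
AUC 0.8032  AUPR 0.7950  ACC 0.7787  MCC 0.5549
```

The held-out AUC of ~0.80 is essentially the best achievable on this
synthetic world: its interactions are independent Bernoulli draws given
the planted communities, and the true-community oracle itself measures
AUC ≈ 0.78 (see `docs/methods.md`).  On the permutation-null world
(labels shuffled) the same pipeline scores ≈ 0.5, confirming that
nothing leaks.

The same pipeline is scriptable from the shell:

```sh
ddifuse simulate --n-drugs 200 --seed 7 --out-dir world/
ddifuse evaluate --drugs world/drugs.tsv --edges world/edges.tsv \
    --associations world/associations.tsv --protocol cv5 --seed 7 \
    --out-dir run/
ddifuse rank --drugs world/drugs.tsv --edges world/edges.tsv \
    --associations world/associations.tsv --query D0007 --out-dir rank/
```

`run/metrics.json` holds per-fold metrics with mean ± sd, and every
command writes its fully resolved configuration next to its outputs.

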