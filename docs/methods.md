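# Methods

`ddifuse` predicts unobserved drug–drug interactions (DDIs) by learning a
binary classifier over unordered drug pairs.  Each drug is described by
three information channels that are computed once per experiment and then
held fixed while the fusion network trains end-to-end.

## Channels

**Chemical sequence.**  A SMILES string is treated as a sentence whose
words are chemical symbols.  Two tokenisers are available: `char`
(single characters) and the default `atomwise`, which keeps bracket atoms
(`[nH]`) and the two-letter halogens `Cl`/`Br` intact; in both modes the
token concatenation reconstructs the input exactly.  A CBOW model with an
exact softmax output is trained over the whole corpus: the hidden state is
the arithmetic mean of the context tokens' input embeddings, and the
negative log-likelihood of the centre token is minimised by mini-batch
gradient descent with a linearly decaying step size.  SMILES vocabularies
are tiny (tens of symbols), so the exact softmax is both tractable and
free of the estimator noise of sampled objectives.  Defaults: dimension
64, window 5, `min_count` 1, 8 epochs.  Each drug becomes a fixed 64×64
matrix: the first rows are its token vectors in order, zero-padded, and
sequences longer than 64 tokens are truncated.  Out-of-vocabulary tokens
map to zero rows, consistent with the padding semantics.

A property worth knowing when testing this channel: CBOW stores
*syntagmatic* association (tokens that co-occur) across the input/output
matrices — a context token's input vector aligns with its neighbour's
*output* vector — while input–input similarity reflects interchangeable
usage.  Tests of co-occurrence therefore read the input–output cosine.

**Network structure.**  The training-fold positive pairs form an
undirected, simple, weighted interaction graph; test edges never enter
it.  Nodes are embedded with the second-order LINE objective

    O2 = − Σ_{(i,j)∈E} w_ij · log p2(v_j | v_i),
    p2(v_j | v_i) = exp(u′_j·u_i) / Σ_k exp(u′_k·u_i),

optimised by edge-sampling SGD with `neg_k = 5` negative samples drawn
∝ degree^0.75 and a learning rate decaying linearly to 1e-4 of its start
(0.025).  Batches are capped at half the edge count so one batch cannot
re-sample an edge many times against stale vectors, which would inflate
the effective step size on small graphs.  The exact softmax objective is
kept as a test oracle on small graphs.

For global structure the graph is first coarsened: each level applies a
star-collapsing pass (degree-1 neighbours of a hub merged in pairs) and
an edge-collapsing pass (a random matching of edges, endpoints merged),
with merged-edge weights summed, until at most
`max(100, ⌈|V|/32⌉)` nodes remain or a level stops shrinking.  The
coarsest graph is embedded from scratch; each finer level initialises
every node from its supernode's vertex and context vectors and refines.
A hierarchy of length one is exactly a plain LINE run with the same seed.
On graphs with clean multiscale structure (e.g. a barbell) the warm start
beats a cold start at equal budget; on dense noisy community graphs the
quotient graph blurs communities and the warm start can trap refinement
in a slightly worse optimum — a known trade-off of the hierarchy, not a
bug, and the coarsening threshold is config-exposed.

Drugs absent from the training graph fall back to the vector of their
lexicographically smallest embedded neighbour, or to the zero vector when
fully isolated.

Second-order proximity has a geometry worth remembering: nodes are close
when they share *neighbourhoods*, not when they are adjacent.  On a
cycle, distance-2 nodes (which share a neighbour) embed closer than
adjacent nodes.

**Biological function.**  Per receptor function type (carrier, target,
enzyme, transporter, …) a binary drug×receptor incidence matrix is built;
pairwise Euclidean row distances give one view per type.  Distances are
converted to affinities with the scaled-exponential kernel
`W_ij = exp(−d²_ij / (μ ε_ij))`, `ε_ij = (mean_knn(i)+mean_knn(j)+d_ij)/3`,
and the views are fused by similarity network fusion: per view a full
row-stochastic kernel `P` (off-diagonal mass ½, diagonal ½) and a K-NN
sparse kernel `S`; then T rounds of cross-diffusion
`P_v ← S_v · mean(P_other) · S_vᵀ` with renormalisation, and the
symmetrised mean of the final `P_v`.  With a single view the diffusion
runs against the view itself, which makes M identical copies an exact
fixed point of the M-view update — a convenient invariant for testing.
Defaults K = 20 (clamped to N−1), T = 20, μ = 0.5.  The kernel's local
scaling makes the result insensitive to a global rescaling of the
distances, so no prior normalisation is applied.

A drug's descriptor is its row of the fused matrix.  Before entering the
network the diagonal is dropped (self-similarity carries no pair
information and is an order of magnitude larger than everything else)
and the rows are divided by the off-diagonal mean, purely for numerical
conditioning — SNF entries scale like 1/N.

## Fusion model

The three channels are reduced to 64 dimensions each: the 64×64 sequence
matrix by one 2-D convolution layer (64 kernels, 3×3, stride 1, zero
padding, ReLU) followed by global average pooling; the network embedding
by a 64-unit dense layer; the N-dim fused row by dense layers of 300 and
64 units.  The three 64-vectors form a 3-token sequence fused by scaled
dot-product attention `softmax(QKᵀ/√d_k)V` with learned 64×64
projections and d_k = 64; the three enhanced tokens are concatenated into
a 192-vector per drug.  A pair is the concatenation of its two drug
vectors (384); the head has three hidden dense layers (256/128/64, ReLU,
dropout 0.3) and a sigmoid output.  Training minimises binary
cross-entropy with Adam (initial 1e-3), includes both orderings of every
pair, and stops early on a 10% validation split (patience 8, best weights
restored); prediction averages score(a,b) and score(b,a), so reported
scores are symmetric by construction.  Defaults: 40 epochs, batch 1024 —
sized so a full run finishes in about half a minute on one CPU; both are
config values recorded with every run.

Everything is plain NumPy (float64 parameters; the convolution pass uses
float32 patch matrices and cached ReLU masks so its intermediate stays
cache-resident).  Runs are bit-reproducible for a fixed seed in
single-threaded mode.

Ablation hooks: any channel can be replaced by a zero token and the
attention block by plain concatenation, via config flags.  The ablation
study runs all arms on one shared split and feature set per seed with a
fixed reduced budget (10 epochs, batch 2048, no early stopping) so the
arms differ only in the ablated component; note that at a fixed small
budget the measured per-channel "importance" also reflects how quickly
each reducer trains, not only how much information its channel carries.

## Evaluation protocol

Known interactions are positives; an equal number of negatives is drawn
uniformly without replacement from unordered non-interacting, non-self
pairs, once per experiment, before splitting — so folds partition a fixed
balanced set.  Two protocols are implemented: a 70/20/10
train/test/validation split and 5-fold cross-validation; in both, each
training portion's positives alone build the interaction graph, so
held-out edges are never visible to the network channel.  Metrics are
computed from the confusion counts at threshold 0.5 (accuracy, precision,
sensitivity, F1, Matthews correlation), plus AUC as the Mann–Whitney rank
statistic (ties half) — exactly the pairwise-comparison definition — and
AUPR by step integration of the precision–recall curve.  Single-class
inputs report AUC/AUPR/MCC as undefined.  Case-study ranking retrains
with the query drug's pairs removed from the training samples and ranks
all non-excluded partners by score.

## Synthetic worlds and what they can show

The generator plants a community structure: `n_drugs = 200` drugs in 4
balanced communities; interactions are independent Bernoulli draws with
`p_in = 0.2` within and `p_out = 0.02` across communities; each community
is enriched for its own receptor block (association probability 0.8
in-block, 0.05 off-block; 3 types × 50 receptors); SMILES-like strings
come from a 20-symbol alphabet with community-biased frequencies (a 4×
boost on 5 community-specific symbols, a choice made once to give the
chemical channel a weak but real signal).  All three tables are
reproducible byte-for-byte from the master seed.

This design makes the channels *partially redundant by construction*,
and that has a hard consequence: conditional on the two drugs'
communities, a held-out pair's label is independent of every feature the
model can see, so the Bayes-optimal score depends only on community
match.  At the default parameters that caps the achievable held-out AUC
at ≈ 0.78 (the true-community oracle measures 0.782 ± 0.008 over 10
seeds).  The trained model reaches ≈ 0.77, i.e. it recovers essentially
all the information the generator plants.  Two corollaries for reading
the test suite: (i) absolute AUC on this synthetic world says nothing
about real-data performance, where pair-specific structure (shared
neighbourhoods of genuinely dependent edges, heterogeneous degree) breaks
the cap; (ii) because the network and receptor channels both recover the
community labels almost perfectly, removing either one barely moves AUC,
so channel-ablation *ordering* on this world is close to seed noise even
though each channel is individually strong.  The permutation-null world
(labels shuffled over the balanced set) is immune to these caveats and
must score at chance.

## Numerical choices and degenerate inputs

- Self-pairs are dropped (with a warning) when building graphs; duplicate
  and reversed edges merge.
- Unknown drugs in similarity lookups yield zero vectors with a warning;
  an edgeless training graph zeroes the network channel.
- K-NN selection in SNF breaks ties by stable sort order; permutation
  equivariance is exact only for tie-free distances.
- MCC with a zero denominator (degenerate confusion matrix) is reported
  as 0; AUC ties count one half.
- The coarsening representative of a merged pair is the smaller node id,
  and the unseen-node fallback picks the lexicographically smallest
  neighbour, making both deterministic under relabelling.

## Known limitations

- The CBOW and LINE optimisers are plain NumPy; they are sized for
  hundreds of drugs and thousands of edges, not for DrugBank-scale
  corpora.
- First-order LINE proximity is not implemented.
- The hierarchical warm start can underperform a cold start on dense
  noisy community graphs (see above); set the coarsening threshold above
  |V| to disable coarsening.
- Chemically valid molecule generation is out of scope for the synthetic
  worlds; strings exercise the tokeniser and embedding machinery only.
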