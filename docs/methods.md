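# Methods

## Problem and model

`smireg` treats SM–miRNA regulation prediction as link classification on an
attributed multiplex heterogeneous bipartite network. The two node types are
small molecules and miRNAs; each regulation direction (up / down) is one
edge layer; every vertex carries an attribute vector derived from a
self-similarity network. The pipeline has five stages: (1) build the
regulation layers; (2) build Tanimoto self-similarity networks and sample
balanced negatives; (3) embed each similarity network into node attributes;
(4) embed the attributed regulation graph; (5) classify concatenated pair
embeddings under stratified fivefold cross-validation. By default each
regulation direction is modelled as its own single-relation network
(mirroring the separate up/down datasets); a joint two-layer mode falls out
of the same code by passing both layers, in which case the self-attention
over relations becomes non-trivial.

## Representations and similarity

Small molecules: the 166 public MACCS structural keys (RDKit's 167-bit
vector with the unused bit 0 stripped). miRNAs: binary presence vectors over
all 4^k k-mers of the U-normalised sequence, k = 4 by default — the natural
binary sequence analogue of structural keys; the underlying study never
fixes a miRNA representation, so this is a documented package choice.
Similarity is the Tanimoto coefficient; both empty sets give 0 by
convention. Self-similarity graphs keep every pair with S_ij > min_weight
(default 0: the graphs are dense, which is fine at a few hundred vertices;
`min_weight` exists for scale).

## Negative sampling

For an unlabelled pair, the regulation-proximity score is the arithmetic
mean of Tanimoto similarities between the candidate SM and the miRNA's
known regulators within the same relation layer. Pairs scoring strictly
below 0.1 form the eligible pool; exactly |positives| negatives are drawn
uniformly without replacement with a logged seed. Pairs whose miRNA has no
known regulator in the layer are unscorable and excluded (the mean is
undefined for them). The pool is enumerated exhaustively, which the tests
check against an independent brute-force oracle.

One consequence worth knowing: because negatives are *defined* by
fingerprint dissimilarity to the regulator set, the labels are partially a
function of the attributes by construction. A null network therefore still
yields above-chance separation if the threshold rule is applied; the
package's negative-control protocol (null latent model) disables the filter
(threshold > 1) so that labels are genuinely independent of features, and
then scores AUC ≈ 0.5. The routine positive control is label shuffling,
which uses the standard threshold.

## Attribute embedding (proximity preserving)

First- and second-order proximity objectives are trained separately and
concatenated (order-1 block first), 64 dimensions each, giving 128-dim
attributes to match the downstream base dimension. The optimiser is the
canonical one: weighted edge sampling through an alias table, K = 5 noise
vertices per positive from the degree^{3/4} distribution, learning rate
linearly decayed from 0.025, initialisation uniform in [−0.5/d, 0.5/d],
order-2 context vectors initialised at zero, 50 epochs (one epoch = one
pass worth of directed-edge samples), minibatch 128 with summed updates.
Isolated vertices keep a zero vector and a logged warning. The exact
objectives (full softmax for order 2) are implemented separately as the
reference the trainer is tested against; training must strictly decrease
them relative to initialisation. Vertices with identical similarity
profiles embed with cosine ≳ 0.98 at these defaults; very long training can
let the order-2 blocks of such duplicates drift apart (their context
distributions differ by self-exclusion), which is why the defaults are
moderate.

## Multiplex embedding

The fused embedding is v_{i,r} = h_z(x_i) + α M_rᵀ U_i c_{i,r} + β D_zᵀ x_i
with h_z, g_{z,r}, D_z single linear maps without bias (the simplest
transforms satisfying the model; Xavier-initialised, seeded) and α = β = 1.
Edge embeddings use K = 1 round of plain mean aggregation over the layer
neighbourhood; a vertex with no neighbours in a layer keeps its own
previous-level vector (avoids division by zero). Aggregation is linear, so
the trainer precomputes the K-step row-normalised adjacency power once per
graph and backpropagates through it exactly; a per-vertex recursive
implementation of the same operator exists for clarity and cross-checking.

Contexts come from meta-path random walks (default SM→miRNA alternating,
length 10, 20 walks per start vertex, window 5), next vertex uniform over
the neighbours of the prescribed next type, truncating when none exists.
The skip-gram loss uses L = 5 negatives drawn from the unigram^{3/4}
distribution restricted to the centre vertex's type. Optimisation is seeded
minibatch SGD at fixed learning rate 0.01 with mean-gradient steps (summed
batch gradients divided by batch size; per-pair updates at this rate
diverge). All gradients are analytic and checked against central
differences to 1e-4 relative error. The attention hidden size is a = 20;
base dimension d = 128 and edge dimension s = 64 by default, following the
sensitivity analysis's preferred settings, with s = 32 appropriate for the
smaller down-regulation dataset.

The transductive variant replaces h_z(x_i) and g_{z,r}(x_i) with free
per-vertex tables and drops the attribute term — an ablation that embeds
structure only.

## Classification and evaluation

Pair features are [v_miRNA ; v_SM] (miRNA block first, frozen for
reproducibility). The default classifier is LightGBM with 500 boosting
rounds, 31 leaves, learning rate 0.05, single-threaded and deterministic;
logistic regression, Gaussian naive Bayes, SVM (with probabilities) and
random forest sit behind the same interface. Calls use score ≥ 0.5 with
ties counted positive (the threshold is a package convention; none is
prescribed upstream). Sensitivity is TP/(TP+FN); a printed variant with
denominator FP+FN in the source study is treated as a typesetting error,
since its reported tables are only consistent with the standard form. Any
zero denominator in Sen/Spec/MCC yields 0. ROC/AUC and PR/AUPR come from
scikit-learn and are verified against an exhaustive concordance-count
oracle (0.5 credit per tie).

Cross-validation splits positives and negatives independently into five
near-equal folds. For each fold the test positives are removed from the
embedding graph before walk generation — keeping them would leak labels
through the walks — and the multiplex embedding is retrained; the
similarity-network attributes depend only on fingerprints, not on edges, so
they are trained once and shared across folds (retraining them per fold
would reproduce the identical result from the same seed and graph).

## Synthetic studies

The generator emulates a curated regulation database at desk scale:
60 SMs, 40 miRNAs, latent dimension 4, 400 positive edges per relation,
4 fingerprint blocks, bit-flip noise 0.05, seed 7. SMs in a block share a
disjoint structural-key template (~60 % of a 41-bit span set) with
independent bit flips; miRNAs in a block are rotations of one tiled 8-mer
core, so their k-mer fingerprints are identical within a block. Every
entity has a latent regulatory-class vector (class centroid + 0.15
Gaussian spread); the SM's class is its fingerprint block, while the
miRNA's class is drawn independently of its sequence block — sequence
similarity deliberately does not reveal which chemicals regulate a miRNA,
as in real regulation data, so recovering held-out links requires the
network. Edges are drawn per relation without replacement with probability
∝ σ(2 z_SM·z_miRNA). The null model decouples latents from blocks and
places edges uniformly.

What passing tests on this fixture do show: the full pipeline recovers
planted structure well above chance (fivefold mean AUC ≈ 0.96–0.99,
Acc ≈ 0.93–0.96 at the defaults) and collapses to AUC ≈ 0.5 under label
shuffling or the null model. What they do not show: behaviour under real
chemistry's fingerprint diversity, long-tailed degree distributions, or
database-scale entity counts. One scale artifact is documented prominently:
with only ~20 labelled pairs per miRNA, attribute vectors act as entity
keys that let a strong tree ensemble memorise each miRNA's regulator
profile, so the attributes-only ablation performs on par with the full
model here, whereas at database scale (hundreds of entities, a few pairs
each) structure-only embeddings outperform raw attributes. The
structure-vs-full ordering (full ≥ structure-only) does hold on the
fixture.

## Determinism and artifacts

Every random operation draws from a named seed derived from the config
seed. Pipeline runs write report JSON, ROC/PR point CSV, negatives TSV,
embeddings in word2vec text format (keys `vertex@relation`), per-pair
predictions TSV, the resolved YAML config and a run log; two runs from one
resolved config are byte-identical. Fold-independent stages (attributes)
are cached content-addressed under the output directory; cached tables are
always read back through the 6-decimal text format so cached and fresh
runs agree exactly.

## Known limitations

- The miRNA k-mer representation is a package choice, not an upstream
  specification; alternatives (secondary structure, expression profiles)
  are out of scope.
- Single-CPU NumPy training only; the dense similarity graphs and the
  dense K-step aggregation operator are comfortable to a few thousand
  vertices, not beyond.
- The eligible negative pool can be smaller than the positive count when
  regulator sets are chemically diverse; the sampler then reports the pool
  size rather than silently unbalancing.
- Case-study ranking against curated literature requires the external
  database export; only the mechanism (hold out one SM, retrain, rank) is
  implemented and tested on synthetic data.
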