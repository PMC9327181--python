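# Methods

This note records the model, the choices made where the design was genuinely
open, the synthetic benchmark's assumptions, and the numerical details that
matter for reproducing results.

## Model and losses

Entities and relations carry triples of K-dimensional parts (default K = 100).
The score of (s, p, o) is the cross-paired trilinear form
φ = Σ_k e_s¹w_p¹e_o³ + e_s²w_p²e_o² + e_s³w_p³e_o¹; it is multilinear, so a
zero entity annihilates the score and scaling any factor scales φ linearly.

The side-effect training loss per positive triple is

    L = −φ_spo + log Σ_{o'} exp(φ_spo') − φ_spo + log Σ_{s'} exp(φ_s'po)
        + (λ/3) Σ_k Σ_m (|e_s^m|³ + |w_p^m|³ + |e_o^m|³)

with the candidate sets {true entity} ∪ {sampled corruptions}.  The positive
score is subtracted once per side; written this way the expression is exactly
the sum of two softmax cross-entropies, and we keep that form.  The N3
regularization weight λ is not fixed by the method description; the default is
0.01, exposed in configuration.

Candidate sets are passed as fixed-width index arrays (column 0 = true entity)
with a boolean validity mask, so ragged negative sets batch cleanly and a
candidate set containing only the true entity collapses the softmax terms to
zero — a property the tests rely on.

**Gradients.**  No autodiff framework is used: the model is multilinear and
the softmax gradient has the standard expected-embedding form, so all
gradients are closed-form numpy expressions (d|x|³/dx = 3·sign(x)·x²).  Every
loss term is verified against central finite differences at 1e-4 relative
tolerance.  Updates use Adam (β₁ = 0.9, β₂ = 0.999) over dense embedding
tables; at the graph sizes this package targets, dense updates are cheaper
than sparse bookkeeping.

**Similarity-edge loss.**  Each auxiliary drug–drug edge contributes
weight(h,t) · L(h, r_sim, t) under a single shared similarity relation
embedding.  The similarity graph is (near-)complete, so a "filtered"
corruption of r_sim barely exists; step-2 corruptions are therefore drawn
uniformly over drugs without filtering, contrasting each weighted pair against
random pairs.

**Weak-node anchor loss.**  For each weak drug the anchors are the
n_sim_neighbors = 6 non-weak drugs with the largest mono-side-effect overlap
(ties by external id).  The loss is the mean squared difference between the
weak drug's concatenated parts and the element-wise mean of its anchors'
parts.  Anchors are treated as constants: well-trained strong embeddings are
targets, not co-trained, so the anchor step cannot drag them toward the weak
nodes.  Comparing to the anchor *mean* (rather than each anchor separately)
was chosen because it makes the 6-neighbour trade-off explicit — the target
interpolates between the single most similar drug and a broad average.

**"Weak" at training time.**  The held-out split defines weakness only for
evaluation; during training the anchor step and the strong-neighbour sampler
need their own notion.  Default: the bottom 1/6 of drugs by training drug–drug
degree (mirroring the split's N ≈ 1/6 of drugs), ties broken by external id.

## Graph enhancement

InvDeg uses training-split drug–drug degrees only — the enhancement exists to
help nodes weak *in training*, and using full-graph degrees would leak
held-out edges.  Window-weighting bounds default to l_bound = 1, u_bound = 4
on standardized descriptor space (distances there are O(√K)); both are
config-exposed, as is a `min_weight` pruning threshold (default 0 = complete
graph) added purely for scalability.  Similarity edges are excluded from all
degree computations and from evaluation.

## Chemical profiles

Three 100-dimensional profile families with matched similarity metrics:
Morgan fingerprints (radius 3, folded to 100 bits) with Tanimoto; RDKit
molecular descriptors — ranked by number of distinct values over the drug set,
top 100 kept, standardized — with the Gaussian kernel exp(−‖X−Y‖²/σ²),
σ defaulting to √K on standardized columns so typical distances are O(σ);
and externally computed hyperbolic embeddings with the Lorentz-distance
similarity (max_pair lor_dist − lor_dist(X,Y))/max_pair lor_dist.  The Lorentz
similarity is reported exactly as defined, unclipped: on a hyperboloid the
self-distance is −1, so values above 1 are possible.  tanimoto(0, 0) is
defined as 1 (two unknown drugs are indistinguishable), and drugs with
unresolvable SMILES get the zero vector (the column mean after
standardization for descriptors), logged.

Structured initialization copies a drug's profile into all three embedding
parts, rescales it to the Xavier standard deviation 1/√K, and adds 1% Gaussian
jitter so chemically identical twins can still diverge during training.  The
mono-side-effect initialization uses the indicator over the K most frequent
single side effects (ties by id).

## Negative sampling

All training samplers are filtered against every known positive (both
orientations for symmetric relations) and reject self-loop corruptions, with a
bounded retry budget (50) after which fewer negatives are emitted with a
warning.  Bernoulli head/tail odds are tph/(tph+hpt) from training
cardinalities.  Cache-based samplers keep per-(h,r) tail and per-(r,t) head
caches (size N1 = 30, refresh budget N_random = 30 by default — N1 is not
fixed by the method description); refreshes score cache ∪ fresh candidates
with the current model and retain cache_size entries by Gumbel-top-k, i.e.
sampling without replacement proportional to softmax(score) at temperature 1,
so hard corruptions persist without the cache collapsing to a deterministic
top-k.  The strong variant uses p(h) = 1/ln(deg_h)^α with natural log, degree
clamped to ≥ 2 and p capped at 1 (degree-1 nodes would otherwise divide by
log 1 = 0); both the head- and tail-cache keys are redirected when the weak
drug occupies the corrupted slot.

## Training and evaluation protocol

One epoch = minibatch passes over side-effect/PPI/target triples, then over
similarity edges (if enabled), then one anchor step (if enabled); cache-based
samplers refresh once per epoch.  Early stopping watches validation macro
ROC AUC with ε = 0.001 and patience k = 7; the best-validation checkpoint is
returned.  Learning rate defaults to 0.001 (0.005 for the plain baseline,
where it works best); batch size defaults to 512.

Evaluation pairs each held-out positive with **one** filtered uniform
corruption, generated once per (split, seed) and frozen, so reported AUCs are
reproducible.  ROC AUC and average precision are computed per side-effect
relation and macro-averaged with equal weight per relation (not weighted by
triple count).  FPR/FNR are pooled over relations at the sigmoid(φ) > 0.5
threshold (φ > 0), which is config-exposed.

In the weak-nodes split, drugs are sorted by ascending drug–drug degree (ties
by external id, then entity id); the M triples touching the first N drugs are
shuffled and alternately assigned to test and validation, test receiving the
extra triple when M is odd.  PPI and drug–target triples never leave the
training set — only drug–drug side-effect links are evaluated.  The split
records the realized M rather than enforcing a target value.

## Synthetic benchmark

The generator emulates the structure of the Decagon-style inputs at desk
scale: 60 drugs, 200 proteins, 8 side-effect relations, 20 mono side effects,
uniform random PPI (300) and drug–target (150) edges.  Drugs belong to latent
chemotypes (one per relation) with prototype binary feature vectors (bit
density 0.2, 5% flip noise) standing in for fingerprints.  Expected drug–drug
degrees are a floor of 6 plus a Pareto tail (exponent 2.0) scaled to mean 14:
the floor reflects that even new drugs carry a handful of known assertions —
and gives the held-out weak set a measurable size (M ≈ 30–40 for N = 10) —
while the tail produces hubs.  Pair probabilities follow a Chung–Lu model
tilted by (1−s) + 2s·Tanimoto, the side-effect type of an edge is the
chemotype-pair relation with probability s (uniform otherwise), and mono
side effects are drawn at rate 0.85/0.05 (preferred/other, interpolated to a
flat 0.25 at s = 0), every drug keeping at least one.  `signal_strength` s
therefore moves the generator continuously from pure noise to a strongly
planted chemistry→side-effect signal; the benchmark default is s = 0.9.

What passing on this benchmark shows — and does not.  The planted signal is
exactly the structure the enhancements exploit (chemistry predicts both
interactions and mono-side-effect profiles), so the weak-node gain certifies
the machinery end to end: initialization, edge weighting, anchoring and
evaluation.  Real chemical space is far messier: descriptor redundancy,
activity cliffs, biased ascertainment of side effects and a 963-relation
long tail are all absent, so desk-scale numbers say nothing quantitative
about performance on the real deposit.

## Problem sizes used in checks

The packaged comparison (test suite and `scripts/acceptance.py`) trains at
embedding dimension 64 for up to 40 epochs on the 60-drug benchmark, five
seeds, full model vs. baseline on both split types — about 30 s on one CPU.
These sizes are the package's desk-scale defaults for a reproducible,
quick-to-verify comparison; the estimator default remains K = 100.

## Known limitations

- Dense Adam updates scale linearly with the entity table; very large graphs
  would need sparse optimizer state.
- The complete similarity graph is quadratic in the number of drugs;
  `min_weight` pruning is the only sparsification offered.
- The "stay positive" regularization approach (training without negative
  sampling) is intentionally out of scope.
- External hyperbolic embeddings are consumed from a table; training the
  hyperbolic VAE that produces them is out of scope.
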