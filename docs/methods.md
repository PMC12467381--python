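# Methods

This note records the modelling assumptions, parameter choices, numerical
details and known limitations of the package, in the order the pipeline
runs.

## Featurisation

Compounds are encoded as hashed circular-substructure (Morgan) binary
fingerprints, radius 2 and 2048 bits by default — the community-standard
ECFP4-like configuration; both are configurable. Fingerprinting runs on the
molecular graph, so any SMILES spelling of the same molecule yields the same
vector.

Proteins are encoded by the k-mer skip-gram scheme: each sequence is split
into non-overlapping 3-mers in 3 shifted reading frames, skip-gram vectors
(dimension 100, window 5, negative sampling with 5 noise words from the
unigram^0.75 distribution) are trained on that corpus with a linearly
decaying learning rate, and a sequence embeds as the **sum** of its k-mer
vectors over all frames. Sum rather than mean is the default aggregation
(mean is available by flag); the embedding is therefore linear in the k-mer
count vector, which the tests exploit. k-mers unseen in training contribute
the zero vector rather than raising — at inference time novel sequences are
expected. Sequences are upper-cased and non-standard residue letters are
kept as literal symbols, so synthetic alphabets work unchanged. The trainer
is plain NumPy, fully seeded, and bit-reproducible on one machine; tables
round-trip through the plain-text word2vec format. Pre-trained tables can be
loaded instead of training.

## Interaction model

Two independent 3-layer ReLU projection stacks (hidden widths default to the
latent width *p*; *p* = 64 in the test preset, 1024 in the paper-shape
preset) map the two modality embeddings into a shared non-negative latent
space. All parameters are float64 NumPy arrays initialised with seeded
He-style fan-in uniform draws; forward and backward passes are hand-written
and validated against central finite differences (relative error ≤ 1e-3 on
sampled parameters) and against an independently coded straight-line
matrix-algebra oracle (100 random instances, 1e-5).

The cross-modal attention block deserves a note. Each entity is a *single*
latent vector, not a token sequence, so a softmax over the key axis would be
the constant 1 and would erase the query/key parameters entirely. The
default semantics therefore uses a scalar sigmoid gate per head:
head output = sigmoid(⟨q, k⟩/√(p/2)) · v, with queries from one modality and
keys/values from the other, roles reversed in the second head, and the
concatenated heads mixed by the global p×p weight. A second semantics
("tokens" mode) reshapes each per-head projection into a short token
sequence (8 tokens by default) and applies standard softmax attention; both
modes are config-visible and both have verified gradients. The classifier
head adds the two projections and the attention output residually,
layer-normalises with the vector's own empirical mean/variance (ε = 1e-5,
learned gain and shift — the conventional reading of a layer-norm affine),
and reads out one logit.

Binary cross-entropy is computed in the log-sum-exp form
max(z,0) − z·y + log(1+e^(−|z|)), exact for logits of any magnitude. The
triplet loss is mean over negatives of max(0, d(a,p) − d(a,n) + margin) with
Euclidean d on the projection outputs and margin 1.0 by default.

## Training

Pre-training minimises BCE with Adam (lr 1e-3, batch 64) over shuffled
mini-batches; fine-tuning runs Adam at 1e-4. The reduced fine-tuning rate
matters: the fine-tune starts from a converged classifier, and at the
pre-training rate the contrastive gradients drag the classification head off
its optimum (held-out ranking quality collapses); a tenth of the rate is the
conventional transfer-learning choice and preserves both objectives.

Fine-tuning turns every positive pair into an anchor and contrasts it
against 50 decoy compounds sampled uniformly without replacement (excluding
the active compound and anything positively paired with the anchor target),
re-sampled every epoch from epoch-derived seeds — fresh augmentation rather
than a frozen decoy set, the stronger regulariser. The triplet term is mixed
with BCE on the same anchor/positive/decoy pairs by a weight λ (default
0.5).

The triplet objective is **bidirectional** by default. The classical
direction (target anchor, compound positive, decoy-compound negatives) only
constrains compound-side geometry: it pushes decoy compounds away but says
nothing about where *non-binding proteins* sit relative to a compound. The
screening stage, however, compares a compound's distances to adverse-effect
targets against a control proteome the model never trained on — precisely
the axis the one-directional loss leaves unconstrained, and in practice that
comparison came out at chance level. The symmetric second direction
(compound anchor, its target as positive, target-side decoys sampled with
the same sampler, margin and count, excluding targets positively paired with
the compound) closes the gap: after fine-tuning, a compound's latent
nearest neighbours among proteins are almost exclusively its true
interactors (≈97% across independent benchmark worlds, vs ≈33% chance). The
one-directional form is available via a config flag. The target-decoy count
is capped by the least-eligible anchor so decoy blocks stay rectangular.

Validation splits are 85/15 stratified by label, seeded. A full
pretrain+fine-tune under one master seed is bit-reproducible.

## Latent screening

The per-entity "model embedding" is the projection-stack output — the only
representation defined for an entity in isolation; the post-attention fused
vector exists only for pairs and is not used for screening.

Distances are measured in a 2-D projection of the latent space, not in the
full latent: high-dimensional Euclidean distances concentrate, and the 2-D
plane is also the natural visual artefact. The projection is a
neighbour-graph manifold embedding (UMAP) with a deliberately **wide
neighbourhood (n_neighbors = 100)**: the screening statistic reads
*between-cluster* distances out of the plane, and small neighbourhoods are
well known to scramble the global arrangement of clusters (we observed
arbitrary sign flips of the adverse-effect-vs-control comparison at the
default neighbourhood of 15). A wide neighbourhood makes the embedding
honour global geometry — the property this method needs. Below 30 points
the neighbour graph is unreliable and the projection falls back to centred
principal axes (deterministic and seed-independent). Distances are only
comparable within one projection run; the API enforces matching projection
seeds. A config flag exposes full-latent distances for diagnostics.

Ranking is ascending by distance with lexicographic entity-id tie-breaks,
so ranks are a deterministic permutation of 1..N. The control comparison is
a one-sided Welch t-test (unequal variances, H₁: adverse-effect targets
closer); if both samples are exactly constant and equal the p-value is 0.5
by convention. Control proteins are sampled uniformly from the proteome id
list after excluding the adverse-effect accessions *and their isoforms*
(exclusion matches the base accession, so "P00742-2" leaves with "P00742").

What varies across the five repetitions of the organ aggregation is the
projection seed (master seed + repetition index) — the only stochastic stage
after training. Per (compound, target) the mean and SE = sd/√n of the
repeated distances are reported once per organ group of the target; a
target annotated to two organs contributes identical statistics to both. A
target missing from the organ map goes to "unmapped" with a warning.

## Knowledge base

Annotation sets merge by accession: adverse-effect terms union
(case-insensitively, first-seen casing kept), per-organ term lists union,
source labels union; conflicting sequence references under one accession
raise. Narrative curation edits are expressed as a declarative JSON patch
(add_term/remove_term per accession) applied after merging, never
hard-coded. Organ sources rank by descending per-organ term count, ties
alphabetical, joined with "/" — "Lung/Heart/Kidney" means most lung terms.

Targets cluster by the Levenshtein distance between canonical
adverse-effect profiles (terms lower-cased, sorted, ";"-joined — fixed for
determinism), under average linkage by default (single/complete available),
with the dendrogram cut to exactly k clusters. Edit distances are computed
by edlib (unit-cost NW alignment); a pure dynamic-programming oracle in the
test suite cross-checks it.

## Term normalisation and evaluation

The normaliser is deterministic: clean the text (lower-case, trim,
punctuation to spaces, collapse whitespace), try an exact synonym/preferred
lookup, then take the nearest dictionary surface form by edit distance,
accepted when the distance is at most `max_edit_fraction` (default 0.2) of
the longer string; ties break on (distance, surface form). It sits behind a
one-callable interface so a learned normaliser can be swapped in. The
shipped vocabulary is a small openly composed list of generic clinical
terms; the reader accepts any preferred-term/synonym CSV export.

Predicted term sets are built by a control-quantile rule: a target counts as
a predicted interactor when its distance falls strictly below the
`threshold_quantile` (default 0.05) quantile of the control-protein
distances, and the prediction is the union of interactors' terms. This is a
documented bridging rule of this package, configurable and recorded in the
output metadata — not a claim about any published procedure. Precision and
recall are set-based on normalised preferred terms; an empty prediction
leaves precision *absent* (not zero), an empty truth set leaves recall
absent, keeping averages honest.

## Synthetic benchmark

The generator builds a world with the statistical shape the framework
assumes, at desk scale: compound SMILES come from a grammar over C/N/O
chains, branches and rings (guaranteed parseable; verified by RDKit);
actives carry a planted fragment ("OCCN"), decoys the same atoms permuted
and verified fragment-free — property-matched hard negatives in miniature.
Proteins are uniform random 20-letter sequences of length 60–100; half the
targets carry a planted 6-residue motif; control proteins never do. A pair
interacts iff fragment AND motif are present, so the label is learnable
only from both modalities jointly; the pair table is balanced (positives =
motif-target × sampled actives; negatives split between decoy/motif-target
and active/non-motif-target pairs). The default conditions are 200
compounds, 100 targets, 100 controls, 6 positives per motif target, seed 7.
Each adverse-effect target gets 2–8 vocabulary terms over 1–3 organ groups;
per-compound ground-truth lists union the terms of the compound's
positively paired targets, with a `variant_rate` (default 0.2) fraction
replaced by generated misspellings (deletion, swap, duplication,
substitution, pluralisation, British/American swaps). A null world keeps
all entities and shuffles the labels, severing the rule — the leakage
control.

What the benchmark does *not* emulate: real chemistry or binding physics,
realistic proteome sequence composition, correlated adverse-effect
co-occurrence, or dose effects. Passing tests therefore demonstrate that
the pipeline recovers planted statistical structure end to end — not
clinical validity on real compounds.

## Problem sizes and numerics

The shipped test preset uses p = 64, 30 pre-training and 10 fine-tuning
epochs on the default world — minutes on one CPU; the paper-shape preset
(p = 1024, ≈118 adverse-effect targets, 1000 controls, 6 screened
compounds) reproduces the published proportions for users with more time.
Float64 throughout; ε = 1e-5 in layer norm; zero-distance anchors get a
zero (sub)gradient in the triplet loss; the BCE uses the stable log-sum-exp
form. All seeds derive from one master seed and stay below 2³¹.

## Known limitations

- The attention semantics on single-vector entities is an interpretation
  (gate vs token-reshape); both are provided, neither is claimed canonical.
- The control-proteome comparison depends on the 2-D projection
  configuration; the wide-neighbourhood default is required for stable
  global geometry and is documented above.
- The deterministic normaliser handles spelling variants, not semantic
  synonymy beyond the dictionary's explicit synonym rows.
- Precision on the synthetic benchmark is structurally diluted: every
  active truly interacts with every motif target, while ground-truth lists
  only cover the sampled pairs.
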