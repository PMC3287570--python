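# Methods

## Problem and model

A rooted binary phylogeny produced by a distance-based builder (e.g.
neighbor joining) resolves *every* divergence into bifurcations. When
three or more lineages actually diverged simultaneously — or the data
cannot order their divergences — that resolution is an artifact: the
builder inserts internal stems of near-zero length in an arbitrary order.
`polytomize` treats the detection of these artifacts as binary
classification of *two-level bifurcations* (triplets): patterns
`((A,B),C)` in which an internal node `u` has a two-leaf cherry `v=(A,B)`
and a leaf `C` as children, with `u` below the root so the stem above it
exists. Triplets whose parent is the root have no `S5`, leave `InterR`
undefined, and are excluded from training and classification (they are
counted in the extraction report).

Each triplet is described by three scale-free features computed from the
five branch lengths `S1..S5` and three pairwise distances `X1..X3`
(`X1 = d(A,C)`, `X2 = d(B,C)`, `X3 = d(A,B)`):

* `LR = (X1 + X2 − 2·X3) / ((X1 + X2 + X3)/3)` — the excess of the
  outgroup distances over twice the cherry distance, normalized by the
  mean distance. At a genuine dichotomy the divergence of `C` precedes
  that of `A` from `B` by a real time gap, so `LR` is bounded away from
  zero; at a resolved polytomy all three pairwise divergences coincide
  and `LR → 0`.
* `IntraR = (min(S1,S2)/max(S1,S2)) / (min(S3,S4)/max(S3,S4))` — cherry
  balance over outgroup/stem balance. The arbitrary resolution stem
  `S4 ≈ ε` makes the denominator collapse, so `IntraR` explodes at
  polytomies.
* `InterR = max(S1,S2,S3,S4)/S5` — the largest within-triplet branch
  against the stem above the triplet. Under the long-branch-retraction
  picture a radiation sits at the end of a long stem, giving polytomies
  systematically smaller `InterR`.

Branch lengths entering ratios are floored at `ε = 1e-9` first, because
consensus and NJ trees legitimately contain zero-length edges; features
must stay finite. With several distance sources, the three features are
computed per source and concatenated (three sources → nine features); an
instance is dropped, with a logged reason, if a source tree does not
contain the identical `((A,B),C)` two-level pattern — cross-tree triplet
correspondence is otherwise undefined, and dropping is the conservative
choice.

Gold-standard labels come from a reference taxonomy: `+1` when the
reference resolves `{A,B,C}` as `((A,B),C)` (MRCA of `A,B` strictly below
the three-taxon MRCA), `-1` when the three taxa form one polytomy *or*
when the reference resolves them conflictingly, `None` (excluded) when a
taxon is absent. Labeling conflicting resolutions `-1` follows the rule
that only reference-confirmed dichotomies count as the positive
dichotomy class; everything else is treated as a polytomy candidate.

## Classifier

The classifier is logistic regression fitted to its MAP point. Labels are
`+1` (dichotomy) / `-1` (polytomy); the model scores `P(dichotomy)`.
Two priors on the weights, both parameterized by a variance `V`:

* Gaussian: penalty `Σ w_j²/(2V)`;
* Laplace: penalty `λ Σ|w_j|` with `λ = √(2/V)`, so that the prior
  variance of a Laplace(0, b) density (2b²) equals `V`.

The intercept is unpenalized. Fitting is cyclic coordinate descent with a
per-coordinate trust region and an upper bound on the logistic-loss
curvature over the trust interval; each coordinate step cannot increase
the objective (asserted per sweep in tests), and the Laplace update parks
weights exactly at zero when the subgradient interval contains zero —
giving true sparsity, not numerically-small weights. Convergence requires
the largest coordinate step ≤ `tol` (default 1e-6) and, for the Gaussian
prior, gradient norm ≤ `tol`; the Gaussian solution matches a generic
quasi-Newton optimizer to ≤ 1e-4 on random problems (tested).

Features are standardized (mean 0, variance 1, computed on the training
portion only) by default, which makes fits invariant to affine feature
rescaling — important because `IntraR` spans four orders of magnitude.

### Model selection

`cv_select` grid-searches the prior variance ladder
`V = 0.002·2^i, i = 0..19` jointly with the error-tuning criterion
`t ∈ {0..5}` by stratified, seeded 3-fold cross-validation. For each
`(V,t)`: fit on two folds, tune the decision threshold θ on those
*training* folds under criterion `t` (never on held-out data, to avoid
selection leakage), and record the held-out F-measure with the polytomy
class positive. The pair with the best mean held-out F-measure wins (ties
prefer smaller `V`, then smaller `t`); the model is refit on all data.
The mean held-out log-likelihood per `V` — the alternative selection rule
— is recorded in the CV report alongside the F-measure surface, but
F-measure decides, being the protocol's headline metric.

Threshold tuning enumerates midpoints between consecutive distinct scores
plus one candidate below the minimum and one above the maximum; `t = 0`
fixes θ = 0.5. Ties between equally good thresholds go to the candidate
closest to 0.5 (then the smaller). The criteria are: 1 minimize FP+FN,
2 maximize (sensitivity+specificity)/2, 3 maximize T11U = 2·TP − FP,
4 maximize F1 = 2TP/(2TP+FP+FN), 5 maximize T13U = 20·TP − FP. The codes
follow this printed order throughout the package.

Reported metrics (precision, recall, F1, balanced accuracy, ROC AUC by
midrank Mann–Whitney, T11U, T13U) treat **polytomy as the positive
class** by default — detection of polytomies is the task — with a
`positive_class` parameter to flip the convention.

## Multifurcation generation

Collapsing a predicted polytomy deletes the stem `S4` and reattaches
`A, B` as siblings of `C` under `u`, setting all three child edges to
`(S1+S2+S3)/3`. `S4`'s length is discarded by default (an `add_stem`
flag adds it back onto the averaged edges for ultrametric-minded users).
Collapsing is single-pass over the triplets of the *input* tree: edits
never create new classifiable triplets, so re-running the classifier on
its own output is a no-op (idempotence, tested). Triplets are pairwise
node-disjoint below their parent nodes, so collapse order is immaterial.

Agreement between a tree and a reference taxonomy is scored on leaf
*triples*, not bipartitions, because triples are polytomy-aware: each
shared triple induces one of three resolutions or an unresolved star in
each tree, and the score is the fraction of identical outcomes (seeded
subsampling above 20 000 triples).

## Tree building and resampling

Neighbor joining is the standard agglomeration with deterministic
tie-breaking (equal Q-values resolved by the lexicographically smallest
pair of cluster labels, a cluster labeled by its smallest leaf), negative
estimated branch lengths clamped to zero, and rooting on the named
outgroup's pendant edge or at the midpoint otherwise — triplet
extraction needs a rooted tree. On additive matrices NJ recovers the
generating topology and branch lengths exactly (tested on random trees).

The jackknife builds replicate trees by retaining `⌊k%·m⌋` of each
genome's `m` orthologs per replicate (sampled without replacement,
chromosome order preserved; defaults k = 60, R = 50), computing a genome
distance matrix and running NJ. The genome distance is pluggable; the
built-in stand-in is `0.5·(1 − Jaccard(content)) + 0.5·(normalized
unsigned breakpoint count on the shared-ortholog orderings)` — symmetric,
0 for identical genomes, 1 for disjoint ones.

Majority-rule consensus counts rooted clades over consistently rooted
replicates and keeps those occurring in strictly more than the threshold
fraction (default 0.5; values below 0.5 are rejected since incompatible
clades then become possible). Supports are percentage occurrence; a
retained clade's branch length is the mean over the trees containing it.

## Synthetic data generator

The generator emulates the study conditions end to end: a multifurcating
"true" taxonomy, its arbitrary binary resolution, and a noisy distance
matrix.

Reference trees are **clock-like**: the root sits at age 1, leaves at age
0, and each internal child diverges at a uniform fraction of its parent's
age. Clock-like generation is a deliberate design choice: for ultrametric
trees the cherry distance is never larger than the outgroup distances, so
`LR ≥ 0` holds exactly on noise-free data and zero-noise recovery of the
planted polytomies is well defined — with independently drawn branch
lengths a long cherry pendant can exceed the outgroup distance and the
dichotomy/polytomy classes genuinely overlap. It is also the natural
model for a taxonomy, where branching order reflects divergence time.

With probability `polytomy_fraction` (default 0.35) an internal node is a
multifurcation of 3–5 children. Multifurcations draw their age from
`polytomy_age_fraction` (default 0.1–0.4 of the parent's age: a radiation
at the end of a long stem, which is what gives `InterR` its class
signal), dichotomies from `dichotomy_age_fraction` (default 0.45–0.8).
Binary resolution joins random pairs of children under new nodes stacked
at distinct offsets of `ε = polytomy_stem_scale · age` (default 1e-4)
below the polytomy age, keeping the tree ultrametric and every resolution
stem within a sliver of width ≤ 3ε. The truth label of each resulting
triplet is `-1` exactly when its cherry node and parent stem from the same
original multifurcation; this provenance labeling is asserted to agree
with reference-MRCA labeling for every instance.

Distance noise is multiplicative — `d = patristic · (1+e)`,
`e ~ N(0, sd²)` truncated above −0.9, default sd 0.05 — which keeps
distances positive and respects the features' scale invariance. With
`balance_classes` the majority class is downsampled (seeded) to a 50/50
split. The default `n_taxa = 3000` yields ≥ 300 balanced labeled triplets
per dataset (measured 330–370 across seeds); smaller problem sizes
(300–600 taxa) are used in unit tests and the end-to-end checks, where a
few dozen triplets suffice.

What the generator does *not* emulate: rate variation across lineages
(real trees are not ultrametric), estimation noise in branch lengths
(only the distance matrix is perturbed, so `IntraR`/`InterR` are
noise-free), horizontal transfer, and correlated distance errors.
Passing tests therefore demonstrate that the features and classifier
recover arbitrary resolutions planted by the stated mechanism — near-zero
ordering stems at simultaneous divergences — not performance on any
particular empirical dataset.

## Numerical choices and degenerate inputs

* Branch-length ε-floor 1e-9 before ratios; all-zero distance triplets
  are an error (`LR` undefined).
* PHYLIP square matrices: asymmetries ≤ 1e-6 (relative) are averaged
  away; larger ones are an error, as are negative entries.
* Newick internal labels that parse as numbers in [0, 100] are read as
  clade supports; others are kept as names.
* The model file is versioned JSON; loading refuses a mismatched format
  version, and classification refuses a feature-dimension mismatch.
* One seed per run fans out to per-stage generators through
  `numpy.random.SeedSequence`, so every pipeline stage is reproducible
  bit for bit.

## Known limitations

* Only two-level leaf triplets are classified. Arbitrary resolutions
  deeper in the tree (polytomy children that are internal subtrees) are
  not collapsible by this pattern, which is why taxonomy agreement of a
  classified tree stays below 1 even under exact triplet recovery.
* Single-pass collapsing never cascades, by design; a polytomy of many
  leaves regains at most three children per classified triplet.
* The jackknife's built-in genome distance is a simple content+breakpoint
  stand-in; serious use should plug in a domain-specific distance.
* Multi-source (e.g. nine-feature) mode requires the identical resolved
  pattern in every source tree; discordant sources reduce the usable
  instance count.
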