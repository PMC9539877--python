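# Methods

## The model

`finnet` treats feature–feature association as a prediction problem.  For a
gene × feature matrix **X**, each feature *t* in turn is the target of a
random forest fitted on all genes with bootstrap sampling, the remaining
features being the predictors.  Association between two features A and B is
then read off the fitted models symmetrically: A and B are linked when each
carries high importance for predicting the other.  This captures any
relationship the forest can exploit — linear or not, between any mix of
binary and continuous columns — at the price of being a *predictive*
association, not a causal or even a marginal-correlation statement: a
feature can earn importance through interactions with third features.

### Out-of-bag scoring

Every gene is used for training, so performance cannot be measured on a
held-out split.  Instead each gene is predicted only by the trees whose
bootstrap sample excluded it (on average ~37% of trees).  Vote tallies are
collected per tree from the forest's bootstrap indices; the per-gene
prediction is the majority vote, with ties going to the positive class
(deterministic, and recall-favouring for the minority class that F1
scores).  Genes that were never out of bag are excluded from scoring and
counted in `n_oob_scored`.  Categorical targets are scored with the F1 of
the positive class (annotations are minority-class, so accuracy would be
vacuous), continuous targets with R² = 1 − SS_res/SS_tot, which goes
negative when the model is worse than predicting the mean.

### Leakage control

Two mechanisms keep the scores honest:

* **Ontology leakage.** Membership columns of ontology terms are logically
  nested: parent ⊇ child.  When an ontology feature is the target, every
  feature mapped to a transitive ancestor or descendant (following `is_a`
  edges; `part_of` optional, off by default) is removed from the predictor
  set.  Siblings are deliberately *not* removed — they share no logical
  implication with the target.  Ontology terms with < 10 member genes are
  not used as targets at all (their F1 is dominated by noise); they remain
  available as predictors.
* **Shuffled-column control.** Independently permuting every column across
  genes preserves all marginal distributions while destroying every
  association; the mean OOB score on shuffled data is the no-signal
  baseline against which real scores are judged.

### Mutual ranks and the network

Raw importances are not comparable across models (they sum to 1 within a
model), so they are reduced to ranks: within each model scoring ≥ 0.4, the
nonzero importances get descending ranks (1 = largest; ties averaged;
exact zeros dropped — a feature the forest never split on has no rank).
For a pair (A, B) with both directional ranks present,

    MR(AB) = sqrt( Rank(A→B) · Rank(B→A) ),

the geometric mean familiar from reciprocal-rank coexpression measures.
Pairs missing either direction are excluded rather than given a fallback
rank: importance vectors, unlike complete similarity matrices, define no
natural worst rank.

The top 10% smallest MRs (ties at the boundary broken by lexicographic
pair order, making the edge count exactly ⌊0.1·N⌋ and the build
deterministic) become the network.  Edge weight is the integer inversion of
the ascending MR order — the i-th strongest of k edges weighs k − i + 1 —
which preserves exactly the MR ordering while being reproducible across
platforms, unlike a floating reciprocal.  Edge sign is the sign of the
Spearman rank correlation between the endpoint columns; Spearman is robust
to the mixed 0/1-continuous column types.  A numerically zero or undefined
correlation (constant column) gives sign 0 and a flag.

### Category associations

Whether two feature categories are connected more or less than chance is
tested by permutation: node→category labels are shuffled over the fixed
graph (default 10,000 times) and edges between every unordered category
pair are recounted.  Holding the graph fixed conditions on the degree
structure; rewiring edges instead would confound category structure with
topology.  Labels are permuted globally across all nodes, so each pair's
null accounts for competition from every other category.  Empirical
p-values use add-one smoothing, p = (1 + #extreme)/(n_perm + 1), the
standard Monte-Carlo correction that avoids p = 0.  Enrichment and
depletion are two separate one-sided families, each Benjamini–Hochberg
corrected on its own; the verdict at α = 0.05 gives enrichment precedence
(both directions significant is impossible for n_perm > 1).  Permutations
iterate over nodes in sorted order, so p-values do not depend on how the
graph object was assembled.

### Degree distribution

The power-law exponent is the negated slope of an ordinary least-squares
fit of log(count) on log(degree) over degrees with nonzero counts.  This
estimator is simple and matches common practice for visual scale-free
claims, but it is known to be biased downward by the noisy count-1 tail;
it needs ≥ 3 distinct degrees and should be read as descriptive, not as a
rigorous power-law test.

## Preprocessing

Features missing in more than half of the genes (strictly; denominator =
total gene count) are dropped.  Missing categorical entries become 0 — the
annotation-absent convention.  Missing continuous entries are filled with
the column mean, and continuous columns are then z-scored.  The statistics
are computed in the fill-then-standardise order: the mean over non-missing
values, the sample sd (n − 1) over the *imputed* column.  This makes
preprocessing exactly idempotent and leaves every non-constant continuous
column with mean 0 and sd 1; for fully observed columns it is the ordinary
sample sd.  Constant columns (sd = 0) map to all zeros instead of dividing
by zero.  Missing values are carried as an explicit NaN mask until
imputation; declared feature kinds win over inference, and a declared
categorical column containing non-{0,1} values is an error, not a
coercion.  The default statistics source is all genes — the OOB workflow
trains on everything — but a gene-subset API exists for users who add a
held-out evaluation and must compute statistics on training genes only.

## Hyperparameters

| parameter | default | role |
|---|---|---|
| `ccp_alpha` | 0.001 | cost-complexity pruning; nonzero keeps trees small on weak targets |
| `max_features` | 0.2 | fraction of predictors per split, mapped to ⌈0.2·p⌉; decorrelates trees |
| `n_estimators` | 50 | trees per forest; the main cost knob, 50 suffices for stable OOB scores |
| `max_depth` | 200 | effectively unlimited at desk scale; a guard at corpus scale |
| `score_cutoff` | 0.4 | minimum OOB F1/R² for a feature to enter mutual ranks |
| `top_fraction` | 0.1 | fraction of smallest MRs kept as edges |
| `min_ontology_positives` | 10 | smallest ontology term usable as a target |
| `n_perm` | 10,000 | permutations for the category test |
| `alpha` | 0.05 | FDR level for verdicts |

The calibration module reproduces the selection procedure behind the fixed
values: random search (20 draws without replacement from the grid's
Cartesian product) per calibration target, stratification of best scores
into high (≥ 0.7) / medium (≥ 0.5) / low groups, then consensus over the
high group either per-hyperparameter (`individual` mode) or as complete
configurations (`group` mode), with ties broken by grid declaration order.
`max_features = "sqrt"` maps to the square-root-of-predictor-count rule;
fractions map to ⌈fraction · p⌉.

Per-target seeds are a 64-bit BLAKE2 hash of (base seed, target name)
reduced below 2³¹, so results are identical across reruns, scheduling
orders and `n_jobs` settings.

## The synthetic generator

The generator emulates the statistical shape of an assembled feature
matrix at desk scale.  Per block, a latent factor z ~ N(0,1) is drawn per
gene; continuous block features are `loading·z + noise_sd·ε` and
categorical ones Bernoulli(σ(2·loading·z − 1)), the −1 intercept giving
~30–35% prevalence, the minority-class regime typical of binary annotation
features.  Independent standard-normal noise features model unpredictable
columns.  Each synthetic parent term is the union of two disjoint random
child gene sets, guaranteeing a leakage back door unless ontology removal
is applied.  Missingness is MCAR.  Within-block pairwise correlation is
loading²/(loading² + noise_sd²) by construction — 0.9 at the defaults —
and is verified against theory in the tests.

Defaults (500 genes; 5 blocks × 6 features, half continuous; loading 0.9,
noise sd 0.3; 20 noise features; 3 parent terms × 2 children × 40 genes;
10% missing) are sized so the full pipeline runs in seconds on one CPU
while every stage — eligibility, leakage removal, score cutoff,
thresholding, signing, permutation testing — is exercised.

What the generator does **not** emulate: the real data's 37 feature
categories and their marginal distributions, missingness that is informative
rather than MCAR, deep ontology hierarchies (one parent level only), and
corpus scale (tens of thousands of genes, ~10⁴ features).  Passing tests
therefore demonstrate the correctness and calibration of the machinery on
data satisfying the generative assumptions, not the biological yield of the
method on any real organism.

## Problem sizes used in the checks

The acceptance checks run the bookkeeping quantities at full feature width
(11,801 features; top 10% of 53,080 pairs), the end-to-end recovery on the
default 500-gene configuration over 5 seeds, the leakage-gap check over 10
seeds, the shuffled-control gap over 21 planted categorical targets at 400
genes, Monte-Carlo-vs-exhaustive agreement on a 6-node graph at 50,000
permutations, and the null calibration on a fixed 200-node / 2,000-edge
graph with 3 random labels × 200 replicates at 999 permutations — the
graph is sized so that edge-count ties (which make discrete permutation
p-values conservative) are negligible.

## Known limitations

* Impurity (mean-decrease) importances are biased toward high-cardinality
  and high-variance predictors; only their *ordering* enters the network,
  which blunts but does not remove the bias.  Permutation importance would
  be preferable in principle and is out of scope.
* OOB F1 on very small positive classes is noisy; the 10-positive floor is
  a pragmatic cutoff, not a power calculation.
* The bidirectionality requirement drops genuinely asymmetric
  relationships (A predicts B, B ignores A).
* The log–log degree fit is descriptive; no likelihood-based power-law
  inference is attempted.
* Edge signs summarise a marginal monotone association and may disagree
  with the (conditional, interaction-driven) relationship the forest
  actually used.
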