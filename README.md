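# finnet — feature importance networks

`finnet` infers relationships between heterogeneous gene-level features
(ontology-term memberships, expression levels and specificity, differential
expression calls, evolutionary ages, domain annotations, ...) by asking a
simple question of each feature in turn: *how well can it be predicted from
all the others?*  Features that are mutually top predictors of each other are
linked into a **feature importance network (FIN)** whose structure can be
mined for biological associations — which kinds of information about a gene
travel together, and which are independent.

It is aimed at computational biologists who have assembled a gene × feature
matrix for an organism and want a systematic, model-driven map of
feature–feature association that works across mixed categorical/continuous
data, respects ontology structure, and comes with honest statistical
controls.

## Method

Given a matrix **X** (genes × features, categorical features coded 0/1,
continuous features z-scored after mean imputation):

1. **Per-feature models.** Every eligible feature *t* becomes the target of
   a random forest trained on all genes with bootstrap sampling (classifier
   for 0/1 targets, regressor for continuous).  Performance is scored
   *out of bag*: each gene is predicted only by trees whose bootstrap sample
   excluded it — OOB F1 of the positive class for categorical targets, OOB
   R² for continuous ones.  Ontology-term targets with fewer than 10 member
   genes are skipped, and for an ontology target every feature mapped to an
   ancestor or descendant term is removed from the predictors (a parent term
   is a near-perfect — and biologically vacuous — predictor of its child).
   Production hyperparameters: `ccp_alpha = 0.001`, `max_features = 0.2`,
   `n_estimators = 50`, `max_depth = 200`; a random-search calibration
   procedure over the declared grid is also provided.

2. **Mutual ranks.** For features scoring ≥ 0.4, the nonzero impurity
   importances of each model are converted to ranks (1 = most important).
   For a feature pair (A, B) with Rank(A→B) the rank of A in B's model,

       MR(AB) = √( Rank(A→B) · Rank(B→A) )

   A pair exists only if both directional ranks exist.  Small MR = the two
   features are mutually top predictors.

3. **Network.** The top 10% smallest MRs become edges.  Edge weight inverts
   the ascending MR order (the strongest pair gets the largest weight), and
   each edge carries the sign of the Spearman correlation between its
   endpoint columns.

4. **Analysis.** Degree / betweenness / clustering per node, a log–log OLS
   fit of the degree histogram (power-law exponent), and a permutation test
   for category-level structure: node→category labels are shuffled 10,000
   times over the fixed graph, giving one-sided empirical p-values for
   enrichment and depletion of edges between every category pair, each
   family corrected by Benjamini–Hochberg.

A synthetic-data generator produces matrices with known planted structure —
latent-factor feature blocks, an ontology-like parent/child hierarchy
(parent gene set = union of its children's), and MCAR missingness — so every
stage of the pipeline is testable without external data.

## Worked example

```python
from finnet import (FeatureImportanceNetwork, SynthConfig,
                    evaluate_recovery, generate_synthetic_dataset)

matrix, truth = generate_synthetic_dataset(SynthConfig(seed=1))
fin = FeatureImportanceNetwork(random_state=1).fit(matrix, dag=truth.to_dag())

print(f"network: {fin.network_.n_nodes} nodes, {fin.network_.n_edges} edges")
rec = evaluate_recovery(fin.network_, truth)
print(f"planted-pair precision {rec.precision:.2f}, recall {rec.recall:.2f}")
enriched = [(r.cat_a, r.cat_b) for r in fin.category_test(n_perm=999)
            if r.verdict == "enriched"]
print(f"enriched category pairs: {enriched}")
```

Output:

```
network: 30 nodes, 43 edges
planted-pair precision 1.00, recall 0.57
enriched category pairs: [('block0', 'block0'), ('block1', 'block1'),
 ('block2', 'block2'), ('block3', 'block3'), ('block4', 'block4')]
```

The default synthetic configuration plants five blocks of six correlated
features in a 500-gene matrix.  All 59 per-feature forests fit; the 30 block
features pass the 0.4 score cutoff, the top 10% of their 435 mutual-rank
pairs form 43 edges, and every edge connects two features from the same
planted block (precision 1.00).  The permutation test recovers exactly the
five within-block enrichments and nothing else.

The same pipeline is scriptable from the shell:

```bash
finnet simulate --outdir data --seed 1
finnet run --values data/matrix.tsv --meta data/meta.tsv \
           --obo data/ontology.obo --outdir results --seed 1
```

which writes per-target scores, sparse importances, the edge list, a
GraphML export for Cytoscape, node metrics and the category-association
table, plus a resolved-configuration manifest that reproduces the run.

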