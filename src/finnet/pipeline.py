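"""End-to-end estimator: matrix in, feature importance network out.

:class:`FeatureImportanceNetwork` is the fit-shaped front door of the
package.  ``fit`` runs the whole chain — preprocessing (optional),
eligibility filtering, one OOB-scored random forest per target with
ontology leakage removal, mutual-rank computation, thresholding, edge
signing — and exposes the intermediate products as fitted attributes.
"""

from __future__ import annotations

import logging

from sklearn.base import BaseEstimator

from finnet.dataset import FeatureMatrix, preprocess
from finnet.fin import assign_edge_signs, build_fin, mutual_ranks
from finnet.models import DEFAULT_HP, HPSet, run_all_targets
from finnet.netstats import category_permutation_test, node_metrics
from finnet.ontology import OntologyDAG

logger = logging.getLogger(__name__)


class FeatureImportanceNetwork(BaseEstimator):
    """Build a mutual-rank feature network from a gene x feature matrix.

    Parameters
    ----------
    hp : random-forest hyperparameters used for every target model.
    score_cutoff : minimum OOB score (F1 or R²) for a feature to enter
        mutual-rank computation.
    top_fraction : fraction of the smallest mutual ranks kept as edges.
    min_ontology_positives : ontology terms with fewer member genes are
        not used as prediction targets.
    random_state : base seed; per-target seeds are derived from it.
    n_jobs : parallelism for per-target model fits.

    Attributes (after ``fit``)
    --------------------------
    results_ : list of per-target model results (score + importances).
    failures_ : map of target -> error for targets that could not be fit.
    pairs_ : all mutual-rank pairs above the score cutoff.
    network_ : the thresholded, weighted, signed feature network.
    """

    def __init__(
        self,
        hp: HPSet = DEFAULT_HP,
        score_cutoff: float = 0.4,
        top_fraction: float = 0.1,
        min_ontology_positives: int = 10,
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.hp = hp
        self.score_cutoff = score_cutoff
        self.top_fraction = top_fraction
        self.min_ontology_positives = min_ontology_positives
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X: FeatureMatrix, y=None, dag: OntologyDAG | None = None):
        """Run the full pipeline on a (possibly unpreprocessed) matrix."""
        if not isinstance(X, FeatureMatrix):
            raise TypeError("FeatureImportanceNetwork operates on FeatureMatrix inputs")
        matrix = X if X.preprocessed else preprocess(X)
        self.matrix_ = matrix
        self.results_, self.failures_ = run_all_targets(
            matrix,
            dag=dag,
            hp=self.hp,
            base_seed=self.random_state,
            n_jobs=self.n_jobs,
            min_ontology_positives=self.min_ontology_positives,
        )
        self.pairs_ = mutual_ranks(self.results_, score_cutoff=self.score_cutoff)
        self.network_ = build_fin(
            self.pairs_,
            top_fraction=self.top_fraction,
            results=self.results_,
            meta=matrix.categories(),
        )
        assign_edge_signs(self.network_, matrix)
        return self

    def node_metrics(self):
        self._check_fitted()
        return node_metrics(self.network_)

    def category_test(self, n_perm: int = 10_000, alpha: float = 0.05, seed: int | None = None):
        self._check_fitted()
        return category_permutation_test(
            self.network_,
            n_perm=n_perm,
            alpha=alpha,
            seed=self.random_state if seed is None else seed,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("FeatureImportanceNetwork is not fitted")
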