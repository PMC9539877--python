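"""Ontology DAG handling: leakage removal and target eligibility.

Ontology-term membership columns are not independent: a gene annotated
to a term is implicitly annotated to every ancestor of that term, so
when a term is the prediction target its ancestors (and descendants) are
near-perfect predictors.  Before training a model for an ontology
feature, every feature mapped to a related term is removed from the
predictor set.  Ontology terms with fewer than ``min_ontology_positives``
member genes are additionally excluded as prediction targets; all other
features are unconditionally eligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import obonet

from finnet.dataset import CATEGORICAL, FeatureMatrix, ValidationError

logger = logging.getLogger(__name__)

#: edge relations considered for ancestry; is_a always, part_of optional
DEFAULT_RELATIONS = ("is_a",)


@dataclass
class OntologyDAG:
    """A directed acyclic graph of ontology terms (edges point child -> parent)."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValidationError(f"ontology contains a cycle: {cycle[:3]}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @classmethod
    def from_edges(cls, child_parent_pairs) -> "OntologyDAG":
        """Build a DAG from (child, parent) pairs, e.g. synthetic hierarchies."""
        g = nx.DiGraph()
        for child, parent in child_parent_pairs:
            g.add_edge(child, parent, relation="is_a")
        return cls(graph=g)


def load_ontology(obo_path, include_part_of: bool = False) -> OntologyDAG:
    """Parse an OBO file into an :class:`OntologyDAG`.

    Obsolete terms are excluded.  ``is_a`` edges are always kept;
    ``part_of`` relationships only when ``include_part_of`` is set.
    A cyclic file raises :class:`ValidationError`.
    """
    relations = set(DEFAULT_RELATIONS) | ({"part_of"} if include_part_of else set())
    multi = obonet.read_obo(obo_path, ignore_obsolete=True)
    g = nx.DiGraph()
    g.add_nodes_from(multi.nodes(data=True))
    for child, parent, key in multi.edges(keys=True):
        if key in relations:
            g.add_edge(child, parent, relation=key)
    dag = OntologyDAG(graph=g)
    logger.info("loaded ontology %s: %d terms, %d edges", obo_path, len(dag), g.number_of_edges())
    return dag


def related_terms(dag: OntologyDAG, term: str) -> set[str]:
    """Transitive ancestors plus transitive descendants of ``term`` (exclusive).

    With child -> parent edge orientation, graph-descendants are ontology
    ancestors and vice versa; the union is orientation-independent.
    """
    if term not in dag:
        raise KeyError(f"unknown ontology term {term!r}")
    return nx.descendants(dag.graph, term) | nx.ancestors(dag.graph, term)


@dataclass(frozen=True)
class TargetSpec:
    """One prediction task: a target feature and its admissible predictors.

    ``predictors`` excludes the target itself and, for ontology-term
    targets, every feature mapped to an ancestor or descendant term.
    ``n_positive`` is the 0/1 column sum for categorical targets.
    """

    target: str
    predictors: tuple[str, ...]
    n_positive: int | None = None
    removed_related: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.target in self.predictors:
            raise ValidationError(f"target {self.target!r} appears among its predictors")


def build_target_spec(
    matrix: FeatureMatrix, target: str, dag: OntologyDAG | None = None
) -> TargetSpec:
    """Predictor set for one target, with ontology leakage removal applied."""
    meta = matrix.meta(target)  # raises KeyError if absent
    removed: set[str] = set()
    if meta.ontology_id is not None:
        if dag is None:
            logger.warning(
                "target %r is an ontology feature but no DAG was given; "
                "parent/child leakage removal skipped", target
            )
        elif meta.ontology_id in dag:
            related = related_terms(dag, meta.ontology_id)
            removed = {
                f.name
                for f in matrix.features
                if f.ontology_id is not None and f.ontology_id in related
            }
    predictors = tuple(
        n for n in matrix.feature_names if n != target and n not in removed
    )
    n_positive = None
    if meta.kind == CATEGORICAL:
        n_positive = int(matrix.values[target].fillna(0).sum())
    return TargetSpec(
        target=target,
        predictors=predictors,
        n_positive=n_positive,
        removed_related=tuple(sorted(removed)),
    )


def eligible_targets(matrix: FeatureMatrix, min_ontology_positives: int = 10) -> list[str]:
    """Features usable as prediction targets, in metadata order.

    Every non-ontology feature is eligible.  Ontology features must have
    at least ``min_ontology_positives`` member genes (strict '< threshold'
    exclusion), counted on the loaded matrix with missing entries as 0 —
    consistent with the categorical zero-fill rule.
    """
    out = []
    for meta in matrix.features:
        if meta.ontology_id is None:
            out.append(meta.name)
            continue
        positives = int(matrix.values[meta.name].fillna(0).sum())
        if positives >= min_ontology_positives:
            out.append(meta.name)
    n_removed = matrix.n_features - len(out)
    if n_removed:
        logger.info(
            "%d ontology features below %d positives excluded as targets",
            n_removed, min_ontology_positives,
        )
    return out
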