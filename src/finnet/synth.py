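"""Synthetic gene x feature matrices with known planted structure.

The generator emulates the statistical shape of a real mixed feature
matrix at desk scale: blocks of correlated features driven by shared
latent factors (continuous features load linearly on the factor,
categorical ones through a logistic link), independent noise features,
a small ontology-like hierarchy in which each parent term's gene set is
the union of its children's (so the parent leaks the child label unless
removed), and missing-completely-at-random entries.  The returned
ground truth lists the same-block feature pairs an ideal network should
recover and the planted parent/child term structure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from finnet.dataset import (
    CATEGORICAL,
    CONTINUOUS,
    FeatureMatrix,
    FeatureMeta,
    ValidationError,
)
from finnet.fin import FeatureNetwork
from finnet.ontology import OntologyDAG

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic dataset.

    Defaults are sized for desk-scale pipeline runs: 500 genes, five
    blocks of six features (three continuous, three categorical) with
    strong loadings, twenty independent noise features and three
    two-child parent terms of 40 genes per child.
    """

    n_genes: int = 500
    n_blocks: int = 5
    continuous_per_block: int = 3
    categorical_per_block: int = 3
    loading: float = 0.9
    noise_sd: float = 0.3
    categorical_intercept: float = -1.0
    n_noise_features: int = 20
    n_term_parents: int = 3
    children_per_parent: int = 2
    genes_per_child: int = 40
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_blocks, self.continuous_per_block,
               self.categorical_per_block, self.n_noise_features,
               self.n_term_parents, self.children_per_parent,
               self.genes_per_child) < 0:
            raise ValidationError("counts must be non-negative")
        if not (0 < self.loading <= 1):
            raise ValidationError("loading must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 <= self.missing_rate <= 0.7):
            raise ValidationError("missing_rate must be in [0, 0.7]")
        if self.children_per_parent * self.genes_per_child > self.n_genes:
            raise ValidationError(
                "children_per_parent * genes_per_child exceeds n_genes "
                "(child gene sets are disjoint within a parent)"
            )


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring.

    ``block_of`` maps each block feature to its block index; the
    ontology edges are (child, parent) pairs whose gene sets satisfy
    parent = union of children.
    """

    block_of: dict[str, int]
    same_block_pairs: set[tuple[str, str]]
    ontology_edges: list[tuple[str, str]]
    term_genes: dict[str, list[str]]

    def to_dag(self) -> OntologyDAG:
        """The planted hierarchy as an ontology DAG (child -> parent)."""
        return OntologyDAG.from_edges(self.ontology_edges)

    def to_json(self, path) -> None:
        payload = {
            "block_of": self.block_of,
            "same_block_pairs": sorted(list(p) for p in self.same_block_pairs),
            "ontology_edges": [list(e) for e in self.ontology_edges],
            "term_genes": self.term_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            block_of={k: int(v) for k, v in payload["block_of"].items()},
            same_block_pairs={tuple(p) for p in payload["same_block_pairs"]},
            ontology_edges=[tuple(e) for e in payload["ontology_edges"]],
            term_genes=payload["term_genes"],
        )

    def write_obo(self, path) -> None:
        """Minimal OBO rendering of the planted hierarchy (synthetic terms)."""
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\nontology: finnet-synthetic\n")
            terms = sorted(self.term_genes)
            parents = {c: p for c, p in self.ontology_edges}
            for term in terms:
                fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
                if term in parents:
                    fh.write(f"is_a: {parents[term]} ! parent\n")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_synthetic_dataset(config: SynthConfig) -> tuple[FeatureMatrix, GroundTruth]:
    """Draw one synthetic matrix plus its ground truth (unpreprocessed).

    Per block b, a latent factor z_b ~ N(0, 1) is drawn per gene;
    continuous block features are ``loading * z_b + noise_sd * eps`` and
    categorical ones are Bernoulli(sigmoid(2 * loading * z_b + intercept)),
    the negative default intercept giving the minority-class prevalence
    typical of binary annotation features.  Noise
    features are independent standard normals.  Each parent term is the
    union of its children's disjoint random gene sets.  Missingness is
    applied MCAR at ``missing_rate`` after generation.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]

    columns: dict[str, np.ndarray] = {}
    metas: list[FeatureMeta] = []
    block_of: dict[str, int] = {}

    for b in range(config.n_blocks):
        z = rng.standard_normal(n)
        for j in range(config.continuous_per_block):
            name = f"blk{b}_cont{j}"
            columns[name] = config.loading * z + config.noise_sd * rng.standard_normal(n)
            metas.append(FeatureMeta(name=name, category=f"block{b}", kind=CONTINUOUS))
            block_of[name] = b
        for j in range(config.categorical_per_block):
            name = f"blk{b}_cat{j}"
            p = _sigmoid(2.0 * config.loading * z + config.categorical_intercept)
            columns[name] = (rng.random(n) < p).astype(float)
            metas.append(FeatureMeta(name=name, category=f"block{b}", kind=CATEGORICAL))
            block_of[name] = b

    ontology_edges: list[tuple[str, str]] = []
    term_genes: dict[str, list[str]] = {}
    for i in range(config.n_term_parents):
        parent = f"SYN:P{i:03d}"
        pool = rng.choice(n, size=config.children_per_parent * config.genes_per_child,
                          replace=False)
        parent_col = np.zeros(n)
        parent_members: list[str] = []
        for j in range(config.children_per_parent):
            child = f"SYN:C{i:03d}_{j}"
            members = pool[j * config.genes_per_child:(j + 1) * config.genes_per_child]
            col = np.zeros(n)
            col[members] = 1.0
            cname = f"term_c{i}_{j}"
            columns[cname] = col
            metas.append(FeatureMeta(name=cname, category="ontology",
                                     kind=CATEGORICAL, ontology_id=child))
            parent_col = np.maximum(parent_col, col)
            child_genes = [genes[g] for g in sorted(members)]
            term_genes[child] = child_genes
            parent_members.extend(child_genes)
            ontology_edges.append((child, parent))
        pname = f"term_p{i}"
        columns[pname] = parent_col
        metas.append(FeatureMeta(name=pname, category="ontology",
                                 kind=CATEGORICAL, ontology_id=parent))
        term_genes[parent] = sorted(parent_members)

    for j in range(config.n_noise_features):
        name = f"noise{j:03d}"
        columns[name] = rng.standard_normal(n)
        metas.append(FeatureMeta(name=name, category="noise", kind=CONTINUOUS))

    values = pd.DataFrame({m.name: columns[m.name] for m in metas}, index=genes)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.mask(mask)

    same_block_pairs = {
        tuple(sorted((a, b)))
        for a in block_of
        for b in block_of
        if a < b and block_of[a] == block_of[b]
    }
    truth = GroundTruth(
        block_of=block_of,
        same_block_pairs=same_block_pairs,
        ontology_edges=ontology_edges,
        term_genes=term_genes,
    )
    matrix = FeatureMatrix(values=values, features=metas, preprocessed=False)
    logger.info("generated synthetic matrix: %d genes x %d features (seed %d)",
                matrix.n_genes, matrix.n_features, config.seed)
    return matrix, truth


@dataclass(frozen=True)
class RecoveryResult:
    """Precision/recall of planted same-block pairs in a built network."""

    precision: float
    recall: float
    n_edges: int
    n_true_pairs: int
    flagged: bool = False


def evaluate_recovery(network: FeatureNetwork, truth: GroundTruth) -> RecoveryResult:
    """Score a network against the planted block structure.

    Precision is the fraction of network edges whose two endpoints
    belong to the same planted block (edges touching noise or ontology
    features count against it); recall is the fraction of planted
    same-block pairs recovered.  With no planted pairs recall is
    undefined and reported as NaN with a flag.
    """
    edges = {tuple(sorted(e)) for e in network.graph.edges}
    n_edges = len(edges)
    hits = sum(1 for e in edges if e in truth.same_block_pairs)
    precision = hits / n_edges if n_edges else 0.0
    if not truth.same_block_pairs:
        return RecoveryResult(precision=precision, recall=float("nan"),
                              n_edges=n_edges, n_true_pairs=0, flagged=True)
    recall = hits / len(truth.same_block_pairs)
    return RecoveryResult(precision=precision, recall=recall,
                          n_edges=n_edges, n_true_pairs=len(truth.same_block_pairs))
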