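"""Topology metrics and category-association statistics on the network.

The feature importance network is analysed on its undirected, unweighted
skeleton: degree, normalised betweenness centrality and local clustering
coefficient per node, and a log-log least-squares fit of the degree
histogram (biological networks typically show a power-law tail).

Category-level structure is tested by permutation: node -> category
labels are shuffled over the fixed graph and the number of edges inside
every unordered category pair is recounted, yielding one-sided empirical
p-values for enrichment and depletion, each family corrected by
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from finnet.dataset import ValidationError
from finnet.fin import FeatureNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoryAssociationResult:
    """Permutation-test outcome for one unordered category pair.

    ``p_enriched`` asks whether the observed edge count is high compared
    with random labellings, ``p_depleted`` whether it is low; both use
    add-one smoothing so p is in (0, 1].  ``verdict`` is decided on the
    BH-adjusted q-values at the chosen alpha, enrichment first.
    """

    cat_a: str
    cat_b: str
    observed: int
    p_enriched: float
    p_depleted: float
    q_enriched: float
    q_depleted: float
    verdict: str  # enriched / depleted / ns


@dataclass(frozen=True)
class DegreeFit:
    """Power-law fit of the degree distribution on log-log axes."""

    exponent: float
    r_squared: float
    degrees: tuple[int, ...]
    counts: tuple[int, ...]


def node_metrics(network: FeatureNetwork) -> pd.DataFrame:
    """Degree, normalised betweenness and clustering coefficient per node.

    Computed on the undirected unweighted skeleton.  Betweenness uses
    the standard normalisation by the number of non-incident ordered
    pairs; clustering is 0 for nodes of degree < 2.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")
    betweenness = nx.betweenness_centrality(g, normalized=True)
    clustering = nx.clustering(g)
    rows = {
        node: {
            "category": g.nodes[node].get("category", "unknown"),
            "degree": g.degree[node],
            "betweenness": betweenness[node],
            "clustering": clustering[node],
        }
        for node in g.nodes
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "node"
    return df


def degree_powerlaw_fit(network: FeatureNetwork) -> DegreeFit:
    """OLS of log(count) on log(degree) over degrees with nonzero counts.

    Returns the negated slope as the power-law exponent and the R² of
    the log-log regression.  Needs at least three distinct degrees.
    """
    degs = np.array([d for _, d in network.graph.degree()])
    uniq, counts = np.unique(degs[degs > 0], return_counts=True)
    if len(uniq) < 3:
        raise ValidationError("insufficient degree diversity for a power-law fit")
    x = np.log(uniq.astype(float))
    y = np.log(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DegreeFit(
        exponent=float(-slope),
        r_squared=r2,
        degrees=tuple(int(d) for d in uniq),
        counts=tuple(int(c) for c in counts),
    )


def _edge_arrays(network: FeatureNetwork, meta: Mapping[str, str]):
    """Node category codes and edge endpoint index arrays.

    Nodes are taken in sorted order so that permutation streams — and
    hence Monte-Carlo p-values — do not depend on how the graph object
    happened to be assembled.
    """
    nodes = sorted(network.graph.nodes)
    missing = [n for n in nodes if n not in meta or meta[n] in (None, "")]
    if missing:
        raise ValidationError(f"nodes without category: {missing[:5]}")
    cats = sorted({meta[n] for n in nodes})
    code = {c: i for i, c in enumerate(cats)}
    labels = np.array([code[meta[n]] for n in nodes])
    index = {n: i for i, n in enumerate(nodes)}
    u = np.array([index[a] for a, b in network.graph.edges])
    v = np.array([index[b] for a, b in network.graph.edges])
    return cats, labels, u, v


def _pair_counts(labels: np.ndarray, u: np.ndarray, v: np.ndarray, n_cats: int) -> np.ndarray:
    """Edge counts per unordered category pair, as a flat (K*K) bincount."""
    cu, cv = labels[u], labels[v]
    lo = np.minimum(cu, cv)
    hi = np.maximum(cu, cv)
    return np.bincount(lo * n_cats + hi, minlength=n_cats * n_cats)


def category_edge_counts(
    network: FeatureNetwork, meta: Mapping[str, str] | None = None
) -> dict[tuple[str, str], int]:
    """Observed edge count per unordered category pair (within-category included).

    Each edge lands in exactly one bucket, so the counts sum to the edge
    count.  With ``meta=None`` the node ``category`` attributes are used.
    """
    if meta is None:
        meta = {n: network.graph.nodes[n].get("category") for n in network.graph.nodes}
    if network.graph.number_of_edges() == 0:
        return {}
    cats, labels, u, v = _edge_arrays(network, meta)
    counts = _pair_counts(labels, u, v, len(cats))
    out = {}
    for i, a in enumerate(cats):
        for j, b in enumerate(cats[i:], start=i):
            c = int(counts[i * len(cats) + j])
            if c:
                out[(a, b)] = c
    return out


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(list(pvals), dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def category_permutation_test(
    network: FeatureNetwork,
    meta: Mapping[str, str] | None = None,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[CategoryAssociationResult]:
    """Permutation test of edge enrichment/depletion between categories.

    The graph is held fixed while node -> category assignments are
    shuffled ``n_perm`` times; for every unordered category pair the
    edge count under each shuffle is compared with the observed count.
    Empirical p-values use add-one smoothing,
    ``p = (1 + #extreme) / (n_perm + 1)``, and the enriched and depleted
    p-value families are BH-corrected separately.
    """
    if meta is None:
        meta = {n: network.graph.nodes[n].get("category") for n in network.graph.nodes}
    if network.graph.number_of_edges() == 0:
        raise ValidationError("empty network")
    cats, labels, u, v = _edge_arrays(network, meta)
    if len(cats) < 2:
        raise ValidationError("need at least 2 categories for a permutation test")
    k = len(cats)
    pair_idx = [(i, j) for i in range(k) for j in range(i, k)]
    flat = [i * k + j for i, j in pair_idx]

    observed = _pair_counts(labels, u, v, k)[flat]
    rng = np.random.default_rng(seed)
    ge = np.zeros(len(flat), dtype=np.int64)
    le = np.zeros(len(flat), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        counts = _pair_counts(perm, u, v, k)[flat]
        ge += counts >= observed
        le += counts <= observed
    p_enr = (1 + ge) / (n_perm + 1)
    p_dep = (1 + le) / (n_perm + 1)
    q_enr = bh_adjust(p_enr)
    q_dep = bh_adjust(p_dep)

    results = []
    for idx, (i, j) in enumerate(pair_idx):
        if q_enr[idx] < alpha:
            verdict = "enriched"
        elif q_dep[idx] < alpha:
            verdict = "depleted"
        else:
            verdict = "ns"
        results.append(
            CategoryAssociationResult(
                cat_a=cats[i],
                cat_b=cats[j],
                observed=int(observed[idx]),
                p_enriched=float(p_enr[idx]),
                p_depleted=float(p_dep[idx]),
                q_enriched=float(q_enr[idx]),
                q_depleted=float(q_dep[idx]),
                verdict=verdict,
            )
        )
    n_sig = sum(r.verdict != "ns" for r in results)
    logger.info("permutation test: %d/%d category pairs significant at alpha=%g",
                n_sig, len(results), alpha)
    return results


def associations_dataframe(results: Sequence[CategoryAssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cat_a": [r.cat_a for r in results],
            "cat_b": [r.cat_b for r in results],
            "observed": [r.observed for r in results],
            "p_enriched": [r.p_enriched for r in results],
            "q_enriched": [r.q_enriched for r in results],
            "p_depleted": [r.p_depleted for r in results],
            "q_depleted": [r.q_depleted for r in results],
            "verdict": [r.verdict for r in results],
        }
    )
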