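"""Mutual-rank network construction from feature-importance vectors.

For every well-predicted target the nonzero importances are converted to
ranks (rank 1 = most important, ties averaged).  For a feature pair
(A, B) the mutual rank is the geometric mean of the two directional
ranks,

    MR(AB) = sqrt(Rank(A -> B) * Rank(B -> A)),

where Rank(A -> B) is the rank of A among the predictors of B's model.
Small MR means the two features are mutually top predictors of each
other.  The strongest fraction of pairs (smallest MR) forms the feature
importance network; edge weights invert the ascending MR order so that
the strongest pair carries the largest weight, and each edge gets the
sign of the Spearman correlation between its endpoint columns.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import ConstantInputWarning, rankdata, spearmanr

from finnet.dataset import FeatureMatrix, ValidationError
from finnet.models import TargetModelResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MutualRankPair:
    """An unordered feature pair with both directional ranks and their MR.

    The pair is stored in canonical (lexicographic) order;
    ``rank_ab`` = Rank(A -> B), the rank of feature_a in feature_b's
    model, and ``rank_ba`` the converse.  ``mr`` is their geometric mean.
    """

    feature_a: str
    feature_b: str
    rank_ab: float
    rank_ba: float
    mr: float

    def __post_init__(self) -> None:
        if self.feature_a >= self.feature_b:
            raise ValidationError("pair must be in lexicographic order")
        if self.rank_ab < 1 or self.rank_ba < 1:
            raise ValidationError("directional ranks start at 1")

    @classmethod
    def from_ranks(cls, feature_a: str, feature_b: str, rank_ab: float, rank_ba: float):
        if feature_a > feature_b:  # canonicalise, swapping rank orientation
            feature_a, feature_b = feature_b, feature_a
            rank_ab, rank_ba = rank_ba, rank_ab
        return cls(
            feature_a=feature_a,
            feature_b=feature_b,
            rank_ab=rank_ab,
            rank_ba=rank_ba,
            mr=math.sqrt(rank_ab * rank_ba),
        )


@dataclass
class FeatureNetwork:
    """The thresholded, weighted, optionally signed feature network.

    A thin wrapper around an undirected :class:`networkx.Graph` whose
    nodes carry ``category`` and ``score`` attributes and whose edges
    carry ``rank_ab``, ``rank_ba``, ``mr``, ``weight`` and (after
    :func:`assign_edge_signs`) ``sign``.
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_dataframe(self):
        import pandas as pd

        rows = []
        for u, v, data in sorted(self.graph.edges(data=True)):
            a, b = (u, v) if u < v else (v, u)
            rows.append(
                {
                    "feature_a": a,
                    "feature_b": b,
                    "rank_ab": data["rank_ab"],
                    "rank_ba": data["rank_ba"],
                    "mr": data["mr"],
                    "weight": data["weight"],
                    "sign": data.get("sign", ""),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.edges_dataframe().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        """GraphML export with node/edge attributes, for Cytoscape import."""
        g = self.graph.copy()
        for _, _, data in g.edges(data=True):
            data.pop("flagged", None)
            if "sign" in data and data["sign"] is None:
                data["sign"] = 0
        nx.write_graphml(g, path)


def network_from_tsv(path, categories: Mapping[str, str] | None = None) -> FeatureNetwork:
    """Rebuild a :class:`FeatureNetwork` from its edge-list TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        attrs = dict(rank_ab=float(row.rank_ab), rank_ba=float(row.rank_ba),
                     mr=float(row.mr), weight=int(row.weight))
        sign = getattr(row, "sign", "")
        if sign not in ("", None) and not (isinstance(sign, float) and np.isnan(sign)):
            attrs["sign"] = int(sign)
        graph.add_edge(row.feature_a, row.feature_b, **attrs)
    for node in graph.nodes:
        graph.nodes[node]["category"] = (
            categories.get(node, "unknown") if categories else "unknown"
        )
    return FeatureNetwork(graph=graph)


def importance_ranks(result: TargetModelResult) -> dict[str, float]:
    """Ranks of the nonzero importances of one model (1 = most important).

    Ties receive the average of the rank positions they span; zero
    importances are excluded, so an all-zero vector gives an empty map.
    """
    items = [(name, imp) for name, imp in result.importances.items() if imp > 0]
    if not items:
        return {}
    names = [n for n, _ in items]
    values = np.array([v for _, v in items])
    ranks = rankdata(-values, method="average")
    return dict(zip(names, ranks.astype(float)))


def mutual_ranks(
    results: Sequence[TargetModelResult], score_cutoff: float = 0.4
) -> list[MutualRankPair]:
    """All mutual-rank pairs among sufficiently predictable features.

    Features scoring below ``score_cutoff`` (OOB F1 or R², raw value, no
    clipping) are discarded.  A pair is emitted only when each feature
    has nonzero importance in the other's model — the mutual-rank
    formula needs both directional ranks, and importance vectors, unlike
    complete similarity matrices, do not define a fallback rank.
    """
    seen = set()
    for r in results:
        if r.target in seen:
            raise ValidationError(f"duplicate result for target {r.target!r}")
        seen.add(r.target)
    kept = [r for r in results if r.score >= score_cutoff]
    ranks = {r.target: importance_ranks(r) for r in kept}
    names = sorted(ranks)
    logger.info("%d of %d features pass score cutoff %.2f", len(kept), len(results),
                score_cutoff)

    pairs = []
    for i, a in enumerate(names):
        ranks_in_a = ranks[a]
        for b in names[i + 1:]:
            rank_ab = ranks[b].get(a)  # rank of A in B's model
            rank_ba = ranks_in_a.get(b)  # rank of B in A's model
            if rank_ab is None or rank_ba is None:
                continue
            pairs.append(MutualRankPair.from_ranks(a, b, rank_ab=rank_ab, rank_ba=rank_ba))
    return pairs


def build_fin(
    pairs: Sequence[MutualRankPair],
    top_fraction: float = 0.1,
    results: Sequence[TargetModelResult] | None = None,
    meta: Mapping[str, str] | None = None,
) -> FeatureNetwork:
    """Threshold the pair list to its strongest fraction and build the graph.

    Pairs are sorted by ascending MR (ties by lexicographic pair order)
    and the first ``floor(top_fraction * n_pairs)`` become edges.  Edge
    weights invert the ascending order: the i-th kept pair (1-based)
    weighs ``k - i + 1``, so the smallest MR gets weight k — a larger
    weight means a stronger association.  Node attributes ``category``
    and ``score`` are filled from ``meta`` and ``results`` when given.
    """
    if not (0 < top_fraction <= 1):
        raise ValidationError("top_fraction must be in (0, 1]")
    if not pairs:
        raise ValidationError("no mutual-rank pairs to threshold")
    k = int(len(pairs) * top_fraction)
    if k == 0:
        raise ValidationError("threshold leaves empty network; raise top_fraction")
    ordered = sorted(pairs, key=lambda p: (p.mr, p.feature_a, p.feature_b))[:k]

    scores = {r.target: r.score for r in results} if results else {}
    graph = nx.Graph()
    for i, p in enumerate(ordered, start=1):
        graph.add_edge(
            p.feature_a, p.feature_b,
            rank_ab=p.rank_ab, rank_ba=p.rank_ba, mr=p.mr, weight=k - i + 1,
        )
    for node in graph.nodes:
        graph.nodes[node]["category"] = meta.get(node, "unknown") if meta else "unknown"
        if node in scores:
            graph.nodes[node]["score"] = scores[node]
    net = FeatureNetwork(graph=graph)
    logger.info("FIN built: %d nodes, %d edges (top %.0f%% of %d pairs)",
                net.n_nodes, net.n_edges, 100 * top_fraction, len(pairs))
    return net


def assign_edge_signs(network: FeatureNetwork, matrix: FeatureMatrix) -> FeatureNetwork:
    """Attach the sign of the Spearman correlation to every edge.

    +1 for positively associated endpoint columns, -1 for negative;
    an undefined or numerically zero correlation (constant column)
    yields sign 0 with a ``flagged`` marker.  Spearman is used because
    the columns mix binary indicators and continuous values.
    """
    if not matrix.preprocessed:
        raise ValidationError("matrix must be preprocessed before sign assignment")
    have = set(matrix.feature_names)
    for u, v, data in network.graph.edges(data=True):
        if u not in have or v not in have:
            missing = u if u not in have else v
            raise ValidationError(f"edge endpoint {missing!r} absent from matrix")
        with warnings.catch_warnings():
            # constant columns are handled explicitly below (sign 0, flagged)
            warnings.simplefilter("ignore", ConstantInputWarning)
            rho = spearmanr(matrix.values[u], matrix.values[v]).statistic
        if rho is None or np.isnan(rho) or abs(rho) < 1e-12:
            data["sign"] = 0
            data["flagged"] = True
        else:
            data["sign"] = 1 if rho > 0 else -1
    return network
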