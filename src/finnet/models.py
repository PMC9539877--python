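"""Per-target random-forest models with out-of-bag scoring.

Every eligible feature in turn becomes the prediction target of a
random forest trained on all genes with bootstrap sampling; the
remaining (leakage-filtered) features are the predictors.  Performance
is measured out-of-bag: each gene is predicted only by the trees whose
bootstrap sample excluded it, giving an honest score without a held-out
split.  Categorical targets are scored with the F1 of the positive
class, continuous targets with R².  Mean-decrease-in-impurity feature
importances are kept for downstream mutual-rank network construction.

Out-of-bag votes are tallied per tree from the forest's bootstrap
indices so that the majority-vote tie rule (tie -> positive class) and
the exclusion of never-out-of-bag genes are explicit.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import f1_score

from finnet.dataset import CATEGORICAL, FeatureMatrix, ValidationError
from finnet.ontology import OntologyDAG, TargetSpec, build_target_spec, eligible_targets

logger = logging.getLogger(__name__)

#: hyperparameters used for the production run over all targets
DEFAULT_HP_VALUES = dict(ccp_alpha=0.001, max_features=0.2, n_estimators=50, max_depth=200)

#: calibration grid (declaration order is the tie-break order)
DEFAULT_GRID: dict[str, list] = {
    "ccp_alpha": [0.0, 0.1, 0.001],
    "max_features": ["sqrt", 0.1, 0.2, 0.3, 0.4, 0.5, 0.75],
    "n_estimators": [50, 100, 200, 500],
    "max_depth": [20, 50, 100, 200, None],
}

HIGH_THRESHOLD = 0.7
MEDIUM_THRESHOLD = 0.5


@dataclass(frozen=True)
class HPSet:
    """One random-forest hyperparameter configuration.

    ``max_features`` is either the string ``"sqrt"`` (square root of the
    predictor count) or a fraction in (0, 1], mapped to
    ``ceil(fraction * n_predictors)`` features per split.  ``max_depth``
    of None means unlimited depth.
    """

    ccp_alpha: float = 0.001
    max_features: float | str = 0.2
    n_estimators: int = 50
    max_depth: int | None = 200

    def __post_init__(self) -> None:
        if self.ccp_alpha < 0:
            raise ValidationError("ccp_alpha must be >= 0")
        if self.max_features != "sqrt" and not (0 < float(self.max_features) <= 1):
            raise ValidationError("max_features must be 'sqrt' or a fraction in (0, 1]")
        if self.n_estimators < 1:
            raise ValidationError("n_estimators must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValidationError("max_depth must be positive or None")

    def resolve_max_features(self, n_predictors: int) -> int:
        if self.max_features == "sqrt":
            return max(1, int(round(math.sqrt(n_predictors))))
        return max(1, math.ceil(float(self.max_features) * n_predictors))

    def as_dict(self) -> dict:
        return {
            "ccp_alpha": self.ccp_alpha,
            "max_features": self.max_features,
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
        }


DEFAULT_HP = HPSet(**DEFAULT_HP_VALUES)


@dataclass
class TargetModelResult:
    """Outcome of one per-target forest: OOB score and importance vector.

    ``importances`` maps each predictor with nonzero mean-decrease-in-
    impurity importance to its value; the stored values are the forest's
    normalised importances, so they sum to at most 1.  ``n_oob_scored``
    counts genes that received at least one out-of-bag prediction.
    """

    target: str
    kind: str
    hp: HPSet
    score: float
    importances: dict[str, float]
    n_oob_scored: int
    seed: int
    n_positive: int | None = None


@dataclass(frozen=True)
class HPCalibrationResult:
    """Best configuration found for one calibration target."""

    target: str
    best_hp: HPSet
    best_score: float
    group: str  # high / medium / low

    def __post_init__(self) -> None:
        expected = performance_group(self.best_score)
        if self.group != expected:
            raise ValidationError(
                f"group {self.group!r} inconsistent with score {self.best_score}"
            )


def performance_group(oob_f1_score: float) -> str:
    """Fixed performance strata: high >= 0.7, medium in [0.5, 0.7), low < 0.5."""
    if oob_f1_score >= HIGH_THRESHOLD:
        return "high"
    if oob_f1_score >= MEDIUM_THRESHOLD:
        return "medium"
    return "low"


def target_seed(base_seed: int, target: str) -> int:
    """Stable per-target seed: hash of (base_seed, target name), < 2**31.

    Independent of scheduling order, so parallel and serial runs agree.
    """
    digest = hashlib.blake2b(f"{base_seed}:{target}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


def oob_f1(oob_votes: np.ndarray, labels: np.ndarray) -> float:
    """F1 of the positive class from per-gene out-of-bag vote tallies.

    ``oob_votes`` is an (n_genes, 2) array of [negative, positive] vote
    counts over the trees for which each gene was out of bag.  Genes
    with no votes are excluded; a tied vote predicts the positive class.
    """
    votes = np.asarray(oob_votes)
    labels = np.asarray(labels)
    scored = votes.sum(axis=1) > 0
    if not scored.any():
        raise ValidationError("no gene has OOB votes; increase n_estimators")
    pred = (votes[scored, 1] >= votes[scored, 0]).astype(int)  # tie -> positive
    return float(f1_score(labels[scored].astype(int), pred, zero_division=0.0))


def oob_r2(oob_predictions: np.ndarray, y: np.ndarray) -> float:
    """R² over out-of-bag-scored genes: 1 - SS_res / SS_tot.

    ``oob_predictions`` holds the mean OOB tree output per gene, NaN for
    genes never out of bag (these are excluded).  Negative values mean
    the model is worse than always predicting the mean of the target.
    """
    preds = np.asarray(oob_predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    scored = ~np.isnan(preds)
    if scored.sum() < 2:
        raise ValidationError("need at least 2 OOB-scored genes for R²")
    yt = y[scored]
    ss_tot = float(((yt - yt.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValidationError("target is constant over OOB-scored genes")
    ss_res = float(((yt - preds[scored]) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def _collect_oob(forest, X: np.ndarray, classification: bool) -> np.ndarray:
    """Per-gene OOB vote tallies (classifier) or mean predictions (regressor).

    Each tree contributes only to the rows absent from its bootstrap
    sample, recovered from ``estimators_samples_``.
    """
    n = X.shape[0]
    if classification:
        votes = np.zeros((n, 2), dtype=np.int64)
        classes = forest.classes_
        for tree, sampled in zip(forest.estimators_, forest.estimators_samples_):
            oob_mask = np.ones(n, dtype=bool)
            oob_mask[sampled] = False
            if not oob_mask.any():
                continue
            pred = classes[
                np.argmax(tree.predict_proba(X[oob_mask]), axis=1)
            ].astype(int)
            rows = np.flatnonzero(oob_mask)
            votes[rows[pred == 0], 0] += 1
            votes[rows[pred == 1], 1] += 1
        return votes
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    for tree, sampled in zip(forest.estimators_, forest.estimators_samples_):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[sampled] = False
        if not oob_mask.any():
            continue
        sums[oob_mask] += tree.predict(X[oob_mask])
        counts[oob_mask] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means


def train_target_model(
    matrix: FeatureMatrix, spec: TargetSpec, hp: HPSet = DEFAULT_HP, seed: int = 0
) -> TargetModelResult:
    """Fit one OOB-scored random forest for ``spec.target``.

    A classifier for categorical targets (scored by OOB F1 of the
    positive class), a regressor for continuous ones (scored by OOB R²).
    All genes are used for training via bootstrap sampling; scoring uses
    only out-of-bag predictions.
    """
    if not matrix.preprocessed:
        raise ValidationError("matrix must be preprocessed before model training")
    if not spec.predictors:
        raise ValidationError(f"target {spec.target!r}: empty predictor set")
    kind = matrix.meta(spec.target).kind
    X = matrix.values[list(spec.predictors)].to_numpy()
    y = matrix.values[spec.target].to_numpy()
    classification = kind == CATEGORICAL

    params = dict(
        n_estimators=hp.n_estimators,
        max_depth=hp.max_depth,
        max_features=hp.resolve_max_features(len(spec.predictors)),
        ccp_alpha=hp.ccp_alpha,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    if classification:
        y = y.astype(int)
        if len(np.unique(y)) < 2:
            raise ValidationError(f"degenerate target {spec.target!r}: single class")
        forest = RandomForestClassifier(**params).fit(X, y)
        oob = _collect_oob(forest, X, classification=True)
        score = oob_f1(oob, y)
        n_scored = int((oob.sum(axis=1) > 0).sum())
    else:
        forest = RandomForestRegressor(**params).fit(X, y)
        oob = _collect_oob(forest, X, classification=False)
        score = oob_r2(oob, y)
        n_scored = int((~np.isnan(oob)).sum())

    imp = forest.feature_importances_
    importances = {
        name: float(v) for name, v in zip(spec.predictors, imp) if v > 0
    }
    return TargetModelResult(
        target=spec.target,
        kind=kind,
        hp=hp,
        score=float(score),
        importances=importances,
        n_oob_scored=n_scored,
        seed=seed,
        n_positive=spec.n_positive,
    )


def _grid_product(grid: Mapping[str, Sequence]) -> list[HPSet]:
    """Cartesian product of the grid, in declaration order."""
    keys = list(grid)
    combos = []
    for values in itertools.product(*(grid[k] for k in keys)):
        combos.append(HPSet(**dict(zip(keys, values))))
    return combos


def random_search_hp(
    matrix: FeatureMatrix,
    calibration_targets: Sequence[str],
    grid: Mapping[str, Sequence] | None = None,
    n_iter: int = 20,
    seed: int = 0,
    dag: OntologyDAG | None = None,
) -> list[HPCalibrationResult]:
    """Random search over the hyperparameter grid for each calibration target.

    Per target, ``n_iter`` configurations are drawn uniformly without
    replacement from the grid's Cartesian product (with replacement only
    when the product is smaller than ``n_iter``); the configuration with
    the best OOB F1 is kept and the target is assigned to the high /
    medium / low performance group.
    """
    grid = dict(grid) if grid is not None else dict(DEFAULT_GRID)
    if any(len(v) == 0 for v in grid.values()):
        raise ValidationError("empty hyperparameter range in grid")
    combos = _grid_product(grid)
    results = []
    for target in calibration_targets:
        spec = build_target_spec(matrix, target, dag)
        rng = np.random.default_rng(target_seed(seed, target))
        replace = len(combos) < n_iter
        idx = rng.choice(len(combos), size=min(n_iter, len(combos)) if not replace else n_iter,
                         replace=replace)
        best_hp, best_score = None, -np.inf
        for i in idx:
            hp = combos[int(i)]
            res = train_target_model(matrix, spec, hp, seed=target_seed(seed, f"{target}:{i}"))
            if res.score > best_score:
                best_hp, best_score = hp, res.score
        results.append(
            HPCalibrationResult(
                target=target,
                best_hp=best_hp,
                best_score=float(best_score),
                group=performance_group(best_score),
            )
        )
        logger.info("calibrated %r: best OOB F1 %.3f (%s)", target, best_score,
                    results[-1].group)
    return results


def _mode(values: list, order: list | None) -> object:
    """Most frequent value; ties broken by position in ``order`` (or first seen)."""
    counts = Counter(values)
    if order is not None:
        ranking = {v: i for i, v in enumerate(order)}
        return max(counts, key=lambda v: (counts[v], -ranking.get(v, len(ranking))))
    first_seen = {v: i for i, v in reversed(list(enumerate(values)))}
    return max(counts, key=lambda v: (counts[v], -first_seen[v]))


def select_frequent_hp(
    results: Sequence[HPCalibrationResult],
    method: str = "individual",
    grid: Mapping[str, Sequence] | None = None,
) -> HPSet:
    """Consensus hyperparameters from the high-performing calibration group.

    ``method="individual"`` takes the per-hyperparameter mode over the
    best configurations of high-group targets and assembles them into
    one configuration; ``method="group"`` takes the modal complete
    configuration.  Ties break by grid declaration order when a grid is
    given, else by first appearance.  If no target reached the high
    group, all results are used (logged).
    """
    if not results:
        raise ValidationError("no calibration results")
    if method not in ("individual", "group"):
        raise ValidationError(f"unknown method {method!r}")
    pool = [r for r in results if r.group == "high"]
    if not pool:
        logger.warning("no high-group calibration target; falling back to all %d results",
                       len(results))
        pool = list(results)
    hps = [r.best_hp for r in pool]
    if method == "individual":
        fields = {}
        for name in ("ccp_alpha", "max_features", "n_estimators", "max_depth"):
            order = list(grid[name]) if grid is not None and name in grid else None
            fields[name] = _mode([getattr(h, name) for h in hps], order)
        return HPSet(**fields)
    order = _grid_product(grid) if grid is not None else None
    return _mode(hps, order)


def run_all_targets(
    matrix: FeatureMatrix,
    dag: OntologyDAG | None = None,
    hp: HPSet = DEFAULT_HP,
    base_seed: int = 0,
    n_jobs: int = 1,
    min_ontology_positives: int = 10,
) -> tuple[list[TargetModelResult], dict[str, str]]:
    """Train one OOB-scored forest per eligible target.

    Per-target seeds derive from ``base_seed`` and the target name, so
    results are identical across reruns and parallelism levels.  Returns
    the results in eligible-target order together with a target -> error
    map of failed fits (never silently dropped).
    """
    if not matrix.preprocessed:
        raise ValidationError("matrix must be preprocessed")
    targets = eligible_targets(matrix, min_ontology_positives)

    def _one(target: str):
        spec = build_target_spec(matrix, target, dag)
        try:
            return target, train_target_model(matrix, spec, hp, target_seed(base_seed, target)), None
        except ValidationError as exc:
            return target, None, str(exc)

    outcomes = Parallel(n_jobs=n_jobs)(delayed(_one)(t) for t in targets)
    results, failures = [], {}
    for target, res, err in outcomes:
        if res is not None:
            results.append(res)
        else:
            failures[target] = err
            logger.warning("target %r failed: %s", target, err)
    logger.info("trained %d/%d target models", len(results), len(targets))
    return results, failures


def write_scores_tsv(results: Sequence[TargetModelResult], path) -> None:
    """Serialise per-target scores (target, kind, score, n_positive, seed)."""
    import pandas as pd

    pd.DataFrame(
        {
            "target": [r.target for r in results],
            "kind": [r.kind for r in results],
            "score": [r.score for r in results],
            "n_positive": [r.n_positive if r.n_positive is not None else "" for r in results],
            "seed": [r.seed for r in results],
        }
    ).to_csv(path, sep="\t", index=False)


def read_results_tsv(scores_path, importances_path) -> list[TargetModelResult]:
    """Rebuild per-target results from the scores and importance TSVs.

    The hyperparameter set is not serialised per target; reloaded
    results carry the default production HPSet and are suitable for
    network construction (which uses only scores and importances).
    """
    import pandas as pd

    scores = pd.read_csv(scores_path, sep="\t")
    triples = pd.read_csv(importances_path, sep="\t")
    by_target: dict[str, dict[str, float]] = {}
    for target, pred, imp in triples.itertuples(index=False):
        by_target.setdefault(target, {})[pred] = float(imp)
    results = []
    for row in scores.itertuples(index=False):
        n_pos = getattr(row, "n_positive", None)
        results.append(
            TargetModelResult(
                target=row.target,
                kind=row.kind,
                hp=DEFAULT_HP,
                score=float(row.score),
                importances=by_target.get(row.target, {}),
                n_oob_scored=0,
                seed=int(row.seed),
                n_positive=int(n_pos) if n_pos not in (None, "") and not pd.isna(n_pos) else None,
            )
        )
    return results


def write_importances_tsv(results: Sequence[TargetModelResult], path) -> None:
    """Serialise sparse importance triples (target, predictor, importance > 0)."""
    import pandas as pd

    rows = [
        (r.target, pred, imp)
        for r in results
        for pred, imp in sorted(r.importances.items(), key=lambda kv: -kv[1])
    ]
    pd.DataFrame(rows, columns=["target", "predictor", "importance"]).to_csv(
        path, sep="\t", index=False
    )
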