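"""Loading, validation and preprocessing of the gene x feature matrix.

The machine-learning dataset is a numeric matrix with genes as rows and
heterogeneous biological features as columns.  Features are either
*categorical* (binary 0/1 membership indicators such as ontology terms,
differential-expression calls or domain presence) or *continuous*
(expression levels, specificity measures, evolutionary ages ...).

Preprocessing follows a fixed recipe: features with more than half of
their values missing are dropped, missing categorical entries are filled
with 0, missing continuous entries are filled with the column mean, and
continuous columns are z-score standardised.  Missing values are carried
as an explicit NaN mask until imputation, never as a numeric sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"

#: strings read as missing in the TSV dialect (plus the empty cell)
MISSING_TOKENS = ("", "NA")


class ValidationError(ValueError):
    """A matrix or metadata invariant is violated."""


@dataclass(frozen=True)
class FeatureMeta:
    """Metadata for one feature column.

    Parameters
    ----------
    name : unique feature name (column header in the values table).
    category : feature category used for network-level association tests.
    kind : ``"categorical"`` (0/1 indicator) or ``"continuous"``.
    ontology_id : term identifier when the feature is an ontology-term
        membership column; such features take part in parent/child
        leakage filtering and in the minimum-positives target rule.
    """

    name: str
    category: str = "unknown"
    kind: str = CONTINUOUS
    ontology_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, CONTINUOUS):
            raise ValidationError(
                f"feature {self.name!r}: kind must be "
                f"'categorical' or 'continuous', got {self.kind!r}"
            )


@dataclass
class FeatureMatrix:
    """A genes x features numeric grid with per-feature metadata.

    ``values`` is a float DataFrame indexed by gene identifier with one
    column per feature; missing entries are NaN.  ``features`` holds one
    :class:`FeatureMeta` per column, in column order.  ``preprocessed``
    flags whether imputation/standardisation has been applied.
    """

    values: pd.DataFrame
    features: list[FeatureMeta]
    preprocessed: bool = False

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if list(self.values.columns) != names:
            raise ValidationError("metadata order does not match value columns")
        if len(set(names)) != len(names):
            raise ValidationError("duplicate feature names")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene IDs: {list(dups)[:5]}")
        self._validate_categorical()

    def _validate_categorical(self) -> None:
        for meta in self.features:
            if meta.kind != CATEGORICAL:
                continue
            col = self.values[meta.name]
            bad = col.dropna()[~col.dropna().isin([0.0, 1.0])]
            if len(bad):
                raise ValidationError(
                    f"feature {meta.name!r} declared categorical but contains "
                    f"{bad.iloc[0]!r} (gene {bad.index[0]!r})"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def meta(self, name: str) -> FeatureMeta:
        try:
            return self._meta_index()[name]
        except KeyError:
            raise KeyError(f"unknown feature {name!r}") from None

    def _meta_index(self) -> dict[str, FeatureMeta]:
        cached = getattr(self, "_meta_cache", None)
        if cached is None or len(cached) != len(self.features):
            cached = {f.name: f for f in self.features}
            object.__setattr__(self, "_meta_cache", cached)
        return cached

    def continuous_features(self) -> list[str]:
        return [f.name for f in self.features if f.kind == CONTINUOUS]

    def categorical_features(self) -> list[str]:
        return [f.name for f in self.features if f.kind == CATEGORICAL]

    def categories(self) -> dict[str, str]:
        return {f.name: f.category for f in self.features}

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        keep = set(names)
        metas = [f for f in self.features if f.name in keep]
        return FeatureMatrix(
            values=self.values[[m.name for m in metas]].copy(),
            features=metas,
            preprocessed=self.preprocessed,
        )

    def to_tsv(self, values_path, meta_path) -> None:
        """Write the values and metadata tables in the package TSV dialect."""
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(values_path, sep="\t", na_rep="NA")
        meta = pd.DataFrame(
            {
                "feature": [f.name for f in self.features],
                "category": [f.category for f in self.features],
                "kind": [f.kind for f in self.features],
                "ontology_id": [f.ontology_id or "" for f in self.features],
            }
        )
        meta.to_csv(meta_path, sep="\t", index=False)
        logger.info(
            "wrote %d genes x %d features to %s", self.n_genes, self.n_features, values_path
        )


@dataclass(frozen=True)
class ColumnStats:
    """Per-continuous-feature mean and sample sd used for imputation/z-scoring.

    ``source`` records which gene subset produced the statistics (``"all"``
    for the default out-of-bag workflow, where every gene is training data).
    Standard deviations use the n-1 denominator.
    """

    mean: pd.Series
    sd: pd.Series
    source: str = "all"

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValidationError("mean and sd cover different features")
        if (self.sd < 0).any():
            raise ValidationError("negative standard deviation")


def infer_feature_kind(column: pd.Series | np.ndarray) -> str:
    """Classify a column as categorical iff all non-missing values are 0 or 1.

    Raises
    ------
    ValidationError
        if the column has no non-missing value (kind undeterminable).
    """
    col = pd.Series(np.asarray(column, dtype=float))
    nonmiss = col.dropna()
    if nonmiss.empty:
        raise ValidationError("kind undeterminable: column is entirely missing")
    return CATEGORICAL if nonmiss.isin([0.0, 1.0]).all() else CONTINUOUS


def load_feature_table(values_path, meta_path=None) -> FeatureMatrix:
    """Read the values TSV (genes x features) and optional metadata TSV.

    The values file has gene IDs in the first column and feature names in
    the header; an empty cell or the literal ``NA`` marks a missing value.
    Features absent from the metadata (or the whole table, when
    ``meta_path`` is None) get their kind inferred and category
    ``"unknown"``.
    """
    raw = pd.read_csv(
        values_path, sep="\t", index_col=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    if raw.index.has_duplicates:
        raise ValidationError(f"{values_path}: duplicate gene IDs")
    if raw.columns.has_duplicates:
        raise ValidationError(f"{values_path}: duplicate feature names")

    values = pd.DataFrame(index=raw.index)
    for name in raw.columns:
        col = raw[name].str.strip()
        col = col.where(~col.isin(MISSING_TOKENS), other=np.nan)
        try:
            values[name] = pd.to_numeric(col)
        except (ValueError, TypeError):
            bad = col.dropna()[pd.to_numeric(col.dropna(), errors="coerce").isna()]
            raise ValidationError(
                f"{values_path}: non-numeric value {bad.iloc[0]!r} "
                f"at gene {bad.index[0]!r}, feature {name!r}"
            ) from None
    values = values.astype(float)

    declared: dict[str, FeatureMeta] = {}
    if meta_path is not None:
        meta = pd.read_csv(
            meta_path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
        )
        required = {"feature", "category", "kind"}
        if not required.issubset(meta.columns):
            raise ValidationError(
                f"{meta_path}: metadata needs columns {sorted(required)}"
            )
        for _, row in meta.iterrows():
            onto = row.get("ontology_id", "") or None
            declared[row["feature"]] = FeatureMeta(
                name=row["feature"],
                category=row["category"],
                kind=row["kind"],
                ontology_id=onto if onto else None,
            )

    features = []
    for name in values.columns:
        if name in declared:
            features.append(declared[name])
        else:
            features.append(
                FeatureMeta(name=name, category="unknown", kind=infer_feature_kind(values[name]))
            )
    matrix = FeatureMatrix(values=values, features=features, preprocessed=False)
    logger.info(
        "loaded %d genes x %d features from %s", matrix.n_genes, matrix.n_features, values_path
    )
    return matrix


def drop_high_missing(matrix: FeatureMatrix, max_missing_frac: float = 0.5) -> FeatureMatrix:
    """Remove features whose missing fraction exceeds ``max_missing_frac``.

    The fraction is strict ("> 50%" keeps a feature at exactly half) and
    its denominator is the total gene count.
    """
    frac = matrix.values.isna().sum(axis=0) / matrix.n_genes
    dropped = [n for n in matrix.feature_names if frac[n] > max_missing_frac]
    for name in dropped:
        logger.info("dropping %r: %.1f%% missing", name, 100 * frac[name])
    kept = [f for f in matrix.features if f.name not in set(dropped)]
    if not kept:
        raise ValidationError("all features exceed the missing-value threshold")
    return FeatureMatrix(
        values=matrix.values[[f.name for f in kept]].copy(),
        features=kept,
        preprocessed=matrix.preprocessed,
    )


def compute_column_stats(
    matrix: FeatureMatrix, gene_subset: Iterable[str] | None = None
) -> ColumnStats:
    """Imputation/standardisation statistics per continuous feature.

    The mean is taken over non-missing values; the standard deviation is
    the sample sd (n-1) of the mean-imputed column, matching the
    fill-then-standardise order so that preprocessing yields exactly
    unit-variance columns and is idempotent.  For fully observed columns
    this is the ordinary sample sd.

    With ``gene_subset=None`` all genes are used (the out-of-bag workflow
    trains on every gene, so there is no held-out set to protect).  A
    subset is accepted so that users adding held-out evaluation can
    compute statistics on training genes only.
    """
    if gene_subset is None:
        sub = matrix.values
        source = "all"
    else:
        subset = list(gene_subset)
        if not subset:
            raise ValidationError("empty gene subset")
        unknown = set(subset) - set(matrix.genes)
        if unknown:
            raise ValidationError(f"genes not in matrix: {sorted(unknown)[:5]}")
        sub = matrix.values.loc[subset]
        source = f"subset[{len(subset)}]"

    cont = matrix.continuous_features()
    block = sub[cont]
    n_obs = block.notna().sum(axis=0)
    allmiss = n_obs[n_obs == 0]
    if len(allmiss):
        raise ValidationError(
            f"feature {allmiss.index[0]!r} is entirely missing within the subset"
        )
    mean = block.mean(axis=0, skipna=True)
    filled = block.fillna(mean)  # sd of the imputed column; ddof=1; single obs -> sd 0
    sd = filled.std(axis=0, ddof=1).fillna(0.0)
    return ColumnStats(mean=mean, sd=sd, source=source)


def preprocess(matrix: FeatureMatrix, stats: ColumnStats | None = None) -> FeatureMatrix:
    """Impute and standardise: categorical NaN -> 0, continuous NaN -> mean,
    then z-score continuous columns with the given statistics.

    Constant continuous columns (sd = 0) are mapped to all-zero rather
    than dividing by zero.  Imputation happens before standardisation;
    the two commute when the statistics come from the same gene set.
    """
    if stats is None:
        stats = compute_column_stats(matrix)
    cont = matrix.continuous_features()
    missing_stats = [n for n in cont if n not in stats.mean.index]
    if missing_stats:
        raise ValidationError(f"stats missing continuous features: {missing_stats[:5]}")

    values = matrix.values.copy()
    cat = matrix.categorical_features()
    values[cat] = values[cat].fillna(0.0)
    if cont:
        mean = stats.mean[cont]
        sd = stats.sd[cont]
        filled = values[cont].fillna(mean)
        z = (filled - mean) / sd.replace(0.0, 1.0)
        constant = [c for c in cont if sd[c] == 0]
        if constant:
            z[constant] = 0.0
        values[cont] = z
    return FeatureMatrix(values=values, features=list(matrix.features), preprocessed=True)


def shuffle_columns(matrix: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Independently permute each column across genes (negative control).

    Per-column value multisets — hence means and standard deviations —
    are preserved exactly; any across-column association is destroyed.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    arr = matrix.values.to_numpy().copy()
    for j in range(arr.shape[1]):
        rng.shuffle(arr[:, j])
    values = pd.DataFrame(arr, index=matrix.values.index, columns=matrix.values.columns)
    return FeatureMatrix(
        values=values, features=list(matrix.features), preprocessed=matrix.preprocessed
    )


class MatrixPreprocessor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer for the imputation/standardisation recipe.

    ``fit`` records per-continuous-column means and sample standard
    deviations (optionally over a training-gene subset, to avoid leakage
    into a held-out set); ``transform`` zero-fills categorical missing
    values, mean-imputes continuous ones and z-scores continuous columns.

    Parameters
    ----------
    max_missing_frac : features missing more than this fraction of genes
        are dropped during ``fit`` (strict inequality).
    """

    def __init__(self, max_missing_frac: float = 0.5):
        self.max_missing_frac = max_missing_frac

    def fit(self, X: FeatureMatrix, y=None, gene_subset: Iterable[str] | None = None):
        if not isinstance(X, FeatureMatrix):
            raise TypeError("MatrixPreprocessor operates on FeatureMatrix inputs")
        filtered = drop_high_missing(X, self.max_missing_frac)
        self.feature_names_ = filtered.feature_names
        self.stats_ = compute_column_stats(filtered, gene_subset)
        self.n_features_in_ = X.n_features
        return self

    def transform(self, X: FeatureMatrix) -> FeatureMatrix:
        if not hasattr(self, "stats_"):
            raise RuntimeError("MatrixPreprocessor is not fitted")
        kept = [n for n in X.feature_names if n in set(self.feature_names_)]
        return preprocess(X.select_features(kept), self.stats_)

    def fit_transform(self, X: FeatureMatrix, y=None, **fit_params) -> FeatureMatrix:
        return self.fit(X, y, **fit_params).transform(X)
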