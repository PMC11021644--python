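"""Balanced random-forest subsampling ensemble and cross-validation.

Immunogenic peptides are rare (~2-3% of a screen), so a single forest
trained on the raw data degenerates to the majority class.  Instead,
the model trains many forests, each on *all* positives plus a fresh
without-replacement draw of negatives (default 50 draws of 500), and
averages their positive-class probabilities.  Hyperparameters are fixed
(depth-6 trees, 2,000 per forest, min leaf 6); the cross-validation
loop re-runs feature selection and imputation inside each training fold
so no test information leaks into either.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import datasets
from .partition import PartitionAssignment, dedup_train

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters of the balanced subsampling ensemble."""

    max_depth: int = 6
    n_estimators: int = 2000
    min_samples_leaf: int = 6
    n_subsamples: int = 50
    n_negatives_per_subsample: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_depth", "n_estimators", "min_samples_leaf",
                     "n_subsamples", "n_negatives_per_subsample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @classmethod
    def test_profile(cls, seed: int = 0) -> "EnsembleConfig":
        """Reduced-size profile (200 trees, 10 subsamples) for fast runs."""
        return cls(n_estimators=200, n_subsamples=10, seed=seed)

    def with_seed(self, seed: int) -> "EnsembleConfig":
        return replace(self, seed=seed)


@dataclass
class TrainedEnsemble:
    forests: list[RandomForestClassifier]
    features: list[str]
    imputation_means: pd.Series
    config: EnsembleConfig
    fold: Optional[int] = None

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"schema": 1, "ensemble": self}, fh)

    @staticmethod
    def load(path) -> "TrainedEnsemble":
        with open(path, "rb") as fh:
            bundle = pickle.load(fh)
        return bundle["ensemble"]


@dataclass
class CVResult:
    scores: pd.Series                    # out-of-fold score per peptide_id
    fold_of: dict[str, int]
    fold_features: dict[int, list[str]]
    fold_importances: dict[int, pd.Series]
    labels: pd.Series = field(default_factory=pd.Series)
    patients: pd.Series = field(default_factory=pd.Series)


def train_balanced_ensemble(
    train_table: pd.DataFrame,
    features: Sequence[str],
    config: EnsembleConfig,
) -> TrainedEnsemble:
    """Fit the subsampling ensemble on an imputed training table.

    Every forest sees all positives; each one draws its negatives
    independently, without replacement within the draw.  If fewer
    negatives exist than the draw size, every draw uses all of them.
    """
    features = list(features)
    x = train_table[features]
    if x.isna().any().any():
        missing = x.columns[x.isna().any()].tolist()
        raise ValueError(f"training table must be imputed; NaNs in {missing}")
    y = train_table["label"].to_numpy()
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) == 0:
        raise ValueError("training data contains no positive examples")
    draw = config.n_negatives_per_subsample
    if len(neg_idx) < draw:
        logger.warning(
            "only %d negatives available (< %d); each draw uses all of them",
            len(neg_idx), draw,
        )
        draw = len(neg_idx)

    # one child RNG stream per subsample keeps draws independent and
    # reproducible regardless of how many subsamples are requested
    children = np.random.SeedSequence(config.seed).spawn(config.n_subsamples)
    forests = []
    xv = x.to_numpy(float)
    for child in children:
        rng = np.random.default_rng(child)
        chosen = rng.choice(neg_idx, size=draw, replace=False)
        rows = np.concatenate([pos_idx, chosen])
        forest = RandomForestClassifier(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(xv[rows], y[rows])
        forests.append(forest)
    means = x.mean()
    return TrainedEnsemble(forests, features, means, config)


def predict(ensemble: TrainedEnsemble, table: pd.DataFrame) -> np.ndarray:
    """Mean positive-class probability over the ensemble's forests."""
    missing = [f for f in ensemble.features if f not in table.columns]
    if missing:
        raise ValueError(f"table lacks model features: {missing}")
    x = table[ensemble.features].fillna(ensemble.imputation_means).to_numpy(float)
    probs = np.zeros(len(table))
    for forest in ensemble.forests:
        pos_col = int(np.flatnonzero(forest.classes_ == 1)[0])
        probs += forest.predict_proba(x)[:, pos_col]
    return probs / len(ensemble.forests)


def cross_validate(
    table: pd.DataFrame,
    partitions: PartitionAssignment,
    config: EnsembleConfig,
    feature_set: str | Sequence[str] = "improve",
    correlation_threshold: float = 0.7,
) -> CVResult:
    """Out-of-fold scoring under the leakage-aware partition.

    Per fold: correlation-filter and mean-impute on training rows only,
    drop training peptides whose sequence recurs in the test fold, fit
    the balanced ensemble, score the held-out fold.  Every peptide ends
    up scored exactly once, by the model that never saw its patient.
    """
    features = datasets.resolve_feature_set(feature_set)
    table = table.set_index("peptide_id", drop=False)
    fold_series = pd.Series(partitions.fold_of)
    missing_rows = table.index.difference(fold_series.index)
    if len(missing_rows):
        raise ValueError(f"peptides without fold assignment: {list(missing_rows)[:5]}")

    scores = pd.Series(np.nan, index=table.index, dtype=float)
    fold_features: dict[int, list[str]] = {}
    fold_importances: dict[int, pd.Series] = {}
    sequences = table["mut_seq"].to_dict()

    for fold in range(partitions.n_folds):
        test_ids = [p for p in table.index if partitions.fold_of[p] == fold]
        train_ids = [p for p in table.index if partitions.fold_of[p] != fold]
        if not test_ids or not train_ids:
            raise ValueError(f"fold {fold} is empty")
        train_ids = dedup_train(train_ids, test_ids, sequences)
        train = table.loc[train_ids]
        test = table.loc[test_ids]

        usable = [f for f in features if train[f].notna().any()]
        kept = datasets.correlation_filter(
            train, train["label"], usable, threshold=correlation_threshold
        )
        train_imp, _ = datasets.impute_mean(train, train, kept)
        fold_config = config.with_seed(_fold_seed(config.seed, fold))
        ensemble = train_balanced_ensemble(train_imp, kept, fold_config)
        ensemble.fold = fold
        scores.loc[test_ids] = predict(ensemble, test)

        fold_features[fold] = kept
        imp = np.mean([f.feature_importances_ for f in ensemble.forests], axis=0)
        fold_importances[fold] = pd.Series(imp, index=kept)
        logger.info("fold %d: %d train rows, %d features, %d test rows",
                    fold, len(train_ids), len(kept), len(test_ids))

    assert not scores.isna().any()
    return CVResult(
        scores=scores,
        fold_of=dict(partitions.fold_of),
        fold_features=fold_features,
        fold_importances=fold_importances,
        labels=table["label"],
        patients=table["patient_id"],
    )


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31 - 1))


def feature_importance(cv_result: CVResult) -> pd.Series:
    """Mean impurity importance across folds, descending.

    A feature deselected in some fold contributes 0 for that fold, so
    features that survive selection everywhere are favoured.
    """
    all_features = sorted({f for fs in cv_result.fold_features.values() for f in fs})
    total = pd.Series(0.0, index=all_features)
    for fold, imp in cv_result.fold_importances.items():
        total = total.add(imp.reindex(all_features, fill_value=0.0))
    return (total / len(cv_result.fold_importances)).sort_values(ascending=False)
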