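"""K-fold cross-validation with a Spearman metric and grid search.

Each fold partitions the data into test / validation / training subsets at
roughly 10% / 9% / 81% (for k = 10): the test sets are the k blocks of a
single seeded shuffle and therefore partition the dataset across folds; the
validation set is one tenth of each fold's remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import MPRADataset
from .exceptions import ConfigError, MulticonvError, UndefinedCorrelationError
from .model import (
    ModelConfig,
    TrainedModel,
    build_multinomial_cnn,
    predict,
    train,
)

__all__ = [
    "CVResult",
    "FoldSplit",
    "cross_validate",
    "hyperparameter_search",
    "make_folds",
    "spearman",
    "write_cv_report",
]


def spearman(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Spearman rank-order correlation (average ranks for ties).

    Raises :class:`UndefinedCorrelationError` when either vector is constant.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ConfigError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    if y.size < 2:
        raise ConfigError("spearman requires n >= 2")
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(stats.spearmanr(y, y_hat).statistic)


@dataclass(frozen=True)
class FoldSplit:
    """Disjoint id sets for one cross-validation fold."""

    fold_index: int
    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.validation_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(set.union(*sets)) != total:
            raise ConfigError(f"fold {self.fold_index}: overlapping id sets")


def make_folds(data: MPRADataset, k: int = 10, seed: int = 0) -> list[FoldSplit]:
    """Deterministic k-fold splits whose test sets partition the dataset.

    Ids are shuffled once with ``seed``; fold ``f`` takes shuffled block ``f``
    as its test set and the first tenth of the remaining ids (in shuffled
    order) as its validation set.  For n = 100, k = 10 this yields the
    10 / 9 / 81 test / validation / train sizes.
    """
    n = len(data)
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    if k > n:
        raise ConfigError(f"k = {k} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ids = np.asarray(data.ids, dtype=object)[order]
    blocks = np.array_split(ids, k)
    folds = []
    for f in range(k):
        test = tuple(blocks[f])
        remainder = np.concatenate([blocks[g] for g in range(k) if g != f])
        n_val = max(1, len(remainder) // 10)
        validation = tuple(remainder[:n_val])
        training = tuple(remainder[n_val:])
        folds.append(
            FoldSplit(
                fold_index=f,
                train_ids=training,
                validation_ids=validation,
                test_ids=test,
            )
        )
    return folds


@dataclass
class CVResult:
    """Per-fold and mean Spearman correlations for one configuration."""

    per_fold_spearman: list[float]
    config: ModelConfig
    fold_models: list[TrainedModel] = field(default_factory=list, repr=False)

    @property
    def mean_spearman(self) -> float:
        return float(np.mean(self.per_fold_spearman))


def _index_by_id(data: MPRADataset) -> dict[str, int]:
    return {sid: i for i, sid in enumerate(data.ids)}


def cross_validate(
    data: MPRADataset,
    config: ModelConfig,
    k: int = 10,
    seed: int = 0,
    keep_models: bool = False,
    model_builder=build_multinomial_cnn,
) -> CVResult:
    """Train one model per fold and score Spearman on each held-out test set.

    Per-fold training seeds are derived from the master seed and the fold
    index, so folds are independent but the whole procedure is reproducible.
    """
    folds = make_folds(data, k=k, seed=seed)
    lookup = _index_by_id(data)
    per_fold: list[float] = []
    models: list[TrainedModel] = []
    for fold in folds:
        fold_seed = int(
            np.random.SeedSequence([seed, fold.fold_index]).generate_state(1)[0]
            % (2**31)
        )
        fold_config = replace(config, seed=fold_seed)
        network = model_builder(fold_config)
        try:
            model = train(
                network,
                data.subset([lookup[i] for i in fold.train_ids]),
                data.subset([lookup[i] for i in fold.validation_ids]),
            )
            test = data.subset([lookup[i] for i in fold.test_ids])
            rho = spearman(test.activities, predict(model, test.sequences))
        except MulticonvError as err:
            raise type(err)(f"fold {fold.fold_index}: {err}") from err
        per_fold.append(rho)
        if keep_models:
            models.append(model)
    return CVResult(per_fold_spearman=per_fold, config=config, fold_models=models)


def hyperparameter_search(
    data: MPRADataset,
    grid: Sequence[ModelConfig],
    k: int = 10,
    seed: int = 0,
) -> list[CVResult]:
    """Cross-validate every config; rank by mean Spearman (descending).

    Ties are broken by fewer parameters, then by position in the grid.
    """
    grid = list(grid)
    if not grid:
        raise ConfigError("hyperparameter grid is empty")
    results = [cross_validate(data, config, k=k, seed=seed) for config in grid]
    order = sorted(
        range(len(results)),
        key=lambda i: (-results[i].mean_spearman, grid[i].n_parameters(), i),
    )
    return [results[i] for i in order]


def write_cv_report(result: CVResult, path: str | Path) -> None:
    """Tab-delimited report: one row per fold plus a mean row."""
    rows = [
        {"fold": i, "spearman": rho}
        for i, rho in enumerate(result.per_fold_spearman)
    ]
    rows.append({"fold": "mean", "spearman": result.mean_spearman})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
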