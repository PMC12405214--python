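"""Filter-based feature ranking, top-k selection, and frequency reporting.

Ranking happens strictly on the outer-fold training + validation samples;
a leakage guard rejects any call whose samples include test-fold patients.
The default statistic is the one-way ANOVA F score (mutual information is
available as an alternative); constant features score 0 and perfectly
separating features receive a large finite sentinel so sorting stays total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif, mutual_info_classif

from .radiomics.catalog import DEFAULT_CATALOG, FeatureCatalog

#: finite sentinel replacing an infinite F (zero within-class variance)
INF_SCORE = 1e12


class LeakageError(RuntimeError):
    """Test-fold samples reached a training-only computation."""


@dataclass
class SelectionResult:
    """Per-fold outcome: scores over all features, the top-k names, and the
    training-set standardization statistics for the selected features."""

    fold_id: int
    scores: np.ndarray
    selected: tuple[str, ...]
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None
    catalog: FeatureCatalog = DEFAULT_CATALOG


def guard_against_leakage(sample_patients: Sequence[str] | None,
                          test_patients: Iterable[str] | None) -> None:
    if sample_patients is None or test_patients is None:
        return
    overlap = set(sample_patients) & set(test_patients)
    if overlap:
        raise LeakageError(
            f"test-fold patients present in training-only data: {sorted(overlap)[:5]}"
        )


def rank_features(feature_table: np.ndarray, labels: np.ndarray,
                  method: str = "anova",
                  sample_patients: Sequence[str] | None = None,
                  test_patients: Iterable[str] | None = None,
                  random_state: int = 0) -> np.ndarray:
    """Univariate class-separation score per feature.

    ``sample_patients`` / ``test_patients`` thread the fold bookkeeping
    through so leakage is caught at the point of computation.
    """
    guard_against_leakage(sample_patients, test_patients)
    X = np.asarray(feature_table, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need samples from both classes")
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")
    if method == "anova":
        with np.errstate(divide="ignore", invalid="ignore"):
            scores, _ = f_classif(X, y)
    elif method == "mutual_info":
        scores = mutual_info_classif(X, y, random_state=random_state)
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    scores = np.asarray(scores, dtype=np.float64)
    scores[~np.isfinite(scores)] = 0.0
    # constant features: no information
    scores[X.std(axis=0) == 0] = 0.0
    # perfect separators (zero within-class variance, nonzero between)
    perfect = scores == 0.0
    if perfect.any():
        for j in np.nonzero(perfect)[0]:
            col = X[:, j]
            within = sum(col[y == c].var() for c in classes)
            between = np.var([col[y == c].mean() for c in classes])
            if within == 0 and between > 0:
                scores[j] = INF_SCORE
    scores[scores > INF_SCORE] = INF_SCORE
    return scores


def select_top_k(scores: np.ndarray, k: int = 50, fold_id: int = 0,
                 catalog: FeatureCatalog = DEFAULT_CATALOG) -> SelectionResult:
    """The k highest-scoring features; ties break by catalog order."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(scores):
        raise ValueError("k exceeds the number of features")
    order = np.lexsort((np.arange(len(scores)), -np.asarray(scores)))
    top = order[:k]
    names = tuple(catalog.names[i] for i in top)
    return SelectionResult(fold_id=fold_id, scores=np.asarray(scores),
                           selected=names, catalog=catalog)


def fit_scaler(result: SelectionResult, train_table: pd.DataFrame) -> SelectionResult:
    """Attach per-feature (mean, sd) computed on training samples only."""
    X = train_table[list(result.selected)].to_numpy(dtype=np.float64)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    result.scaler_mean = X.mean(axis=0)
    result.scaler_sd = sd
    return result


def apply_scaler(result: SelectionResult, table: pd.DataFrame) -> np.ndarray:
    """Standardize the selected features of any table with the stored stats."""
    if result.scaler_mean is None:
        raise ValueError("scaler not fitted")
    X = table[list(result.selected)].to_numpy(dtype=np.float64)
    return (X - result.scaler_mean) / result.scaler_sd


def selection_frequency(results: Sequence[SelectionResult]) -> pd.DataFrame:
    """Per-feature count of folds in which it was selected.

    Columns mirror the supplementary-style report: feature name, image
    source, feature class, frequency; sorted by frequency (descending) then
    catalog order.
    """
    if not results:
        raise ValueError("need at least one fold")
    catalog = results[0].catalog
    for r in results:
        if r.catalog.names != catalog.names:
            raise ValueError("inconsistent catalogs across folds")
    counts = {name: 0 for name in catalog.names}
    for r in results:
        for name in r.selected:
            counts[name] += 1
    entries = catalog.entries
    df = pd.DataFrame(
        dict(feature_name=e.name, image_source=e.source, feature_class=e.family,
             frequency=counts[e.name], catalog_index=i)
        for i, e in enumerate(entries)
    )
    df = df.sort_values(["frequency", "catalog_index"],
                        ascending=[False, True]).drop(columns="catalog_index")
    return df.reset_index(drop=True)
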