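"""Full 378-feature extraction for one ROI and tabulation over a cohort."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ..phantom import RoiSample
from ..preprocess import DEFAULT_LOG_SCALES, LogScale, log_filter
from .catalog import DEFAULT_CATALOG, FeatureCatalog
from .firstorder import firstorder_features
from .shape2d import shape2d_features
from .texture import TEXTURE_KINDS, discretize, texture_features, texture_matrix


@dataclass
class FeatureVector:
    """378 ordered feature values for one ROI, catalog-aligned."""

    values: np.ndarray
    sample: RoiSample
    catalog: FeatureCatalog

    def __post_init__(self) -> None:
        if len(self.values) != len(self.catalog):
            raise ValueError("feature vector length must match the catalog")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.catalog.names, self.values))


def _source_features(image: np.ndarray, mask: np.ndarray, source: str,
                     n_bins: int) -> dict[str, float]:
    feats: dict[str, float] = {}
    for name, v in firstorder_features(image, mask, source_kind=source,
                                       n_bins=n_bins).items():
        feats[f"{source}_firstorder_{name}"] = v
    if source == "original":
        for name, v in shape2d_features(mask).items():
            feats[f"{source}_shape2d_{name}"] = v
    q = discretize(image, mask, n_bins=n_bins)
    n_pixels = int(q.mask.sum())
    for kind in TEXTURE_KINDS:
        try:
            mat = texture_matrix(kind, q)
            for name, v in texture_features(kind, mat, n_pixels=n_pixels).items():
                feats[f"{source}_{kind}_{name}"] = v
        except Exception as exc:  # pragma: no cover - context for debugging
            raise RuntimeError(f"{source}/{kind} feature failure") from exc
    return feats


def extract_all(sample: RoiSample,
                scales: Sequence[LogScale] = DEFAULT_LOG_SCALES,
                catalog: FeatureCatalog = DEFAULT_CATALOG,
                n_bins: int = 32) -> FeatureVector:
    """Concatenate features over the original image and the three LoG scales."""
    images = {"original": sample.image}
    for s in scales:
        images[f"log_{s.name}"] = log_filter(sample.image, s)
    feats: dict[str, float] = {}
    for source, img in images.items():
        feats.update(_source_features(img, sample.mask, source, n_bins))
    values = np.array([feats[name] for name in catalog.names])
    return FeatureVector(values=values, sample=sample, catalog=catalog)


def extract_table(cohort: Iterable[RoiSample],
                  scales: Sequence[LogScale] = DEFAULT_LOG_SCALES,
                  catalog: FeatureCatalog = DEFAULT_CATALOG,
                  n_bins: int = 32) -> pd.DataFrame:
    """One row per ROI: identifier columns plus the 378 named features."""
    rows = []
    for s in cohort:
        fv = extract_all(s, scales=scales, catalog=catalog, n_bins=n_bins)
        row = dict(patient_id=s.patient_id, label=s.label, region=s.region,
                   hemisphere=s.hemisphere)
        row.update(fv.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
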