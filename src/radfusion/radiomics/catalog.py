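"""Feature catalog: the fixed, ordered inventory of all 378 features.

Sources are the original image plus three LoG scales (fine / medium /
coarse). Shape features exist only for the original image; Total Energy is
omitted on filtered images (whose signed response makes a volume-weighted
energy redundant with Energy), giving 18 first-order features on the
original source and 17 per LoG source:

    original: 18 + 9 + 24 + 16 + 16 + 5 + 14 = 102
    each LoG: 17 + 24 + 16 + 16 + 5 + 14     =  92
    total:    102 + 3 x 92                   = 378
"""

from __future__ import annotations

from dataclasses import dataclass

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)

SHAPE2D_NAMES = (
    "MeshSurface", "PixelSurface", "Perimeter", "PerimeterSurfaceRatio",
    "Sphericity", "MaximumDiameter", "MajorAxisLength", "MinorAxisLength",
    "Elongation",
)

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

FAMILY_NAMES = {
    "firstorder": FIRSTORDER_NAMES,
    "shape2d": SHAPE2D_NAMES,
    "glcm": GLCM_NAMES,
    "glszm": GLSZM_NAMES,
    "glrlm": GLRLM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}

IMAGE_SOURCES = ("original", "log_fine", "log_medium", "log_coarse")

#: Alternative physical-units labeling used in some reports for the LoG
#: scales (fine ~ 2 mm, medium ~ 4 mm); informational only.
LOG_SCALE_MM_LABELS = {"log_fine": "2mm", "log_medium": "4mm", "log_coarse": "6mm"}


@dataclass(frozen=True)
class CatalogEntry:
    name: str  # fully qualified, e.g. "log_fine_glcm_Contrast"
    family: str
    source: str
    feature: str  # bare feature name within the family


def _source_families(source: str):
    if source == "original":
        yield "firstorder", FIRSTORDER_NAMES
        yield "shape2d", SHAPE2D_NAMES
    else:
        yield "firstorder", tuple(n for n in FIRSTORDER_NAMES if n != "TotalEnergy")
    for fam in ("glcm", "glszm", "glrlm", "ngtdm", "gldm"):
        yield fam, FAMILY_NAMES[fam]


class FeatureCatalog:
    """Ordered list of the 378 (source, family, feature) entries."""

    def __init__(self) -> None:
        entries: list[CatalogEntry] = []
        for source in IMAGE_SOURCES:
            for family, names in _source_families(source):
                for feat in names:
                    entries.append(
                        CatalogEntry(f"{source}_{family}_{feat}", family,
                                     source, feat)
                    )
        self.entries = tuple(entries)
        counts = self.family_counts()
        assert counts[("original", None)] == 102
        assert sum(v for (src, fam), v in counts.items()
                   if src != "original" and fam is None) == 276
        assert len(self.entries) == 378

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def family_counts(self) -> dict:
        """Counts keyed by (source, family) plus (source, None) subtotals."""
        counts: dict = {}
        for e in self.entries:
            counts[(e.source, e.family)] = counts.get((e.source, e.family), 0) + 1
            counts[(e.source, None)] = counts.get((e.source, None), 0) + 1
        return counts

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                dict(name=e.name, source=e.source, family=e.family,
                     feature=e.feature,
                     mm_label=LOG_SCALE_MM_LABELS.get(e.source, ""))
                for e in self.entries
            ]
        )


DEFAULT_CATALOG = FeatureCatalog()
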