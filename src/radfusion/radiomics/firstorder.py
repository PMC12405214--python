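"""First-order (intensity histogram and moment) features over the ROI."""

from __future__ import annotations

import numpy as np

from .texture import discretize


def firstorder_features(image: np.ndarray, mask: np.ndarray,
                        source_kind: str = "original",
                        n_bins: int = 32,
                        pixel_area: float = 1.0) -> dict[str, float]:
    """Intensity statistics over in-mask pixels.

    The original image yields 18 features; filtered (LoG) sources omit
    Total Energy, yielding 17. Entropy and Uniformity are computed on the
    ``n_bins`` equal-width discretization of the in-mask intensities;
    moments use population (biased) normalization, and Kurtosis is the
    plain fourth standardized moment (3 for a Gaussian, not excess).
    """
    if not mask.any():
        raise ValueError("empty mask")
    x = image[mask.astype(bool)].astype(np.float64)
    n = x.size

    mean = x.mean()
    centered = x - mean
    m2 = np.mean(centered**2)
    m3 = np.mean(centered**3)
    m4 = np.mean(centered**4)

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    q = discretize(image, mask, n_bins=n_bins)
    counts = np.bincount(q.levels[mask.astype(bool)], minlength=n_bins + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]

    feats = {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(pixel_area * np.sum(x**2)),
        "Entropy": float(-np.sum(nz * np.log2(nz))),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(centered).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }
    if source_kind != "original":
        del feats["TotalEnergy"]
    assert len(feats) == (18 if source_kind == "original" else 17)
    return feats
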