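"""Synthetic phantom cohort generator.

Emulates the structure of the clinical cohort the pipeline expects: a balanced
two-class set of patients (infection vs. control), each contributing two
bilateral ROIs (left / right) in each of two anatomical regions (ventricular
system, sub-lentiform nucleus parenchyma), drawn on 2D T2-like intensity
slices.

Class separation is expressed through exactly the statistics the downstream
radiomics features measure: infected ROIs have a mean-intensity offset
(``class_contrast``) and a different correlation length of their within-ROI
texture (``class_texture_scale``), on top of a darker parenchyma-like
background. ROIs are ellipses with randomized axes and orientation so that 2D
shape features are non-degenerate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

REGIONS = ("ventricle", "sublentiform")
HEMISPHERES = ("left", "right")
LABELS = ("control", "infection")

#: 16-bit quantization grid used at write time; generated intensities are
#: snapped to this grid so that PNG round-trips are exactly lossless.
_QMAX = 65535


class PhantomParamError(ValueError):
    """Invalid phantom parameters."""


class ManifestError(ValueError):
    """Manifest refers to missing or inconsistent files."""


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the synthetic cohort.

    Parameters
    ----------
    n_patients_per_class:
        Patients per class; the cohort has twice this many patients.
    image_size:
        Side of the square slice, pixels.
    roi_radius_range:
        (min, max) semi-axis length of the elliptical ROIs, pixels.
    class_contrast:
        Mean-intensity offset added inside infected ROIs (intensity units,
        images live in [0, 1]).
    class_texture_scale:
        Gaussian correlation length (pixels) of the within-ROI texture for
        infected ROIs; controls the granularity of the correlated noise.
    noise_sd:
        Standard deviation of the within-ROI texture field.
    seed:
        Master seed; expanded into per-patient substreams so enlarging the
        cohort never perturbs existing patients.
    """

    n_patients_per_class: int = 52
    image_size: int = 128
    roi_radius_range: tuple[float, float] = (8.0, 16.0)
    class_contrast: float = 0.3
    class_texture_scale: float = 2.0
    control_texture_scale: float = 1.0
    noise_sd: float = 0.05
    background_level: float = 0.35
    roi_level: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients_per_class < 1:
            raise PhantomParamError("n_patients_per_class must be >= 1")
        lo, hi = self.roi_radius_range
        if not (0 < lo <= hi):
            raise PhantomParamError("roi_radius_range must satisfy 0 < lo <= hi")
        # ROI centers sit at quadrant centers (+-size/4); the ellipse must fit.
        if hi >= self.image_size / 4:
            raise PhantomParamError(
                f"roi radius {hi} does not fit in a {self.image_size}px image"
            )
        if self.noise_sd < 0:
            raise PhantomParamError("noise_sd must be non-negative")


@dataclass
class RoiSample:
    """One segmented region: image slice plus binary ROI mask."""

    patient_id: str
    label: str
    region: str
    hemisphere: str
    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("mask shape must equal image shape")
        if not self.mask.any():
            raise ValueError("mask must contain at least one foreground pixel")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def _correlated_field(rng: np.random.Generator, shape, corr_len: float,
                      sd: float) -> np.ndarray:
    """White noise smoothed to correlation length ``corr_len``, rescaled to sd."""
    white = rng.standard_normal(shape)
    if corr_len <= 0:
        return white * sd
    smooth = ndimage.gaussian_filter(white, corr_len, mode="wrap")
    s = smooth.std()
    if s == 0:
        return np.zeros(shape)
    return smooth * (sd / s)


def _ellipse_mask(shape, center, axes, theta) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


# ROI centers per (region, hemisphere): quadrants of the slice.
_CENTER_FRAC = {
    ("ventricle", "left"): (0.25, 0.25),
    ("ventricle", "right"): (0.25, 0.75),
    ("sublentiform", "left"): (0.75, 0.25),
    ("sublentiform", "right"): (0.75, 0.75),
}


def _make_sample(rng: np.random.Generator, params: PhantomParams,
                 patient_id: str, label: str, region: str,
                 hemisphere: str) -> RoiSample:
    n = params.image_size
    # parenchyma-like background: flat level + slow spatial drift + mild noise
    img = np.full((n, n), params.background_level)
    img += _correlated_field(rng, (n, n), corr_len=8.0, sd=0.02)
    img += _correlated_field(rng, (n, n), corr_len=0.0, sd=0.01)

    lo, hi = params.roi_radius_range
    axes = rng.uniform(lo, hi, size=2)
    theta = rng.uniform(0, np.pi)
    cf = _CENTER_FRAC[(region, hemisphere)]
    jitter = rng.uniform(-2, 2, size=2)
    center = (cf[0] * n + jitter[0], cf[1] * n + jitter[1])
    mask = _ellipse_mask((n, n), center, axes, theta)

    infected = label == "infection"
    level = params.roi_level + (params.class_contrast if infected else 0.0)
    corr = params.class_texture_scale if infected else params.control_texture_scale
    texture = _correlated_field(rng, (n, n), corr_len=corr, sd=params.noise_sd)
    img[mask] = level + texture[mask]

    img = np.clip(img, 0.0, 1.0)
    # snap to the 16-bit grid so write/read round-trips are bit-exact
    img = np.round(img * _QMAX) / _QMAX
    return RoiSample(patient_id, label, region, hemisphere, img, mask)


def generate_cohort(params: PhantomParams) -> list[RoiSample]:
    """Generate the full synthetic cohort.

    Returns a flat list of ``RoiSample``; every patient contributes
    2 regions x 2 hemispheres = 4 samples. Deterministic in ``params.seed``.
    """
    samples: list[RoiSample] = []
    for label_idx, label in enumerate(LABELS):
        for i in range(params.n_patients_per_class):
            ss = np.random.SeedSequence(params.seed, spawn_key=(label_idx, i))
            rng = np.random.default_rng(ss)
            pid = f"{'C' if label == 'control' else 'P'}{i:03d}"
            for region in REGIONS:
                for hemi in HEMISPHERES:
                    samples.append(
                        _make_sample(rng, params, pid, label, region, hemi)
                    )
    return samples


def cohort_patients(cohort: Iterable[RoiSample]) -> pd.DataFrame:
    """One row per patient: (patient_id, label)."""
    rows = {(s.patient_id, s.label) for s in cohort}
    return (
        pd.DataFrame(sorted(rows), columns=["patient_id", "label"])
        .reset_index(drop=True)
    )


def write_cohort(cohort: Iterable[RoiSample], directory: str) -> str:
    """Persist images/masks as 16-bit / 8-bit PNG plus a CSV manifest.

    Returns the manifest path. Images round-trip bit-for-bit because
    generated intensities already live on the 16-bit grid.
    """
    os.makedirs(directory, exist_ok=True)
    img_dir = os.path.join(directory, "images")
    os.makedirs(img_dir, exist_ok=True)
    rows = []
    for s in cohort:
        stem = f"{s.patient_id}_{s.region}_{s.hemisphere}"
        img_path = os.path.join("images", stem + ".png")
        mask_path = os.path.join("images", stem + "_mask.png")
        iio.imwrite(
            os.path.join(directory, img_path),
            np.round(s.image * _QMAX).astype(np.uint16),
        )
        iio.imwrite(
            os.path.join(directory, mask_path),
            (s.mask.astype(np.uint8) * 255),
        )
        rows.append(
            dict(patient_id=s.patient_id, label=s.label, region=s.region,
                 hemisphere=s.hemisphere, image=img_path, mask=mask_path)
        )
    manifest = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path: str) -> list[RoiSample]:
    """Load a cohort from a manifest CSV; validates that every file exists."""
    df = pd.read_csv(manifest_path)
    required = {"patient_id", "label", "region", "hemisphere", "image", "mask"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(manifest_path))
    samples = []
    for row in df.itertuples(index=False):
        img_path = os.path.join(base, row.image)
        mask_path = os.path.join(base, row.mask)
        for p in (img_path, mask_path):
            if not os.path.exists(p):
                raise ManifestError(f"file referenced by manifest not found: {p}")
        img = iio.imread(img_path).astype(np.float64) / _QMAX
        mask = iio.imread(mask_path) > 0
        samples.append(
            RoiSample(row.patient_id, row.label, row.region, row.hemisphere,
                      img, mask)
        )
    return samples
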