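"""2D shape features from the binary ROI mask.

Area and perimeter come from the marching-squares polygonal contour of the
mask (largest connected component); diameters and axis lengths from pixel
center coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n <= 1:
        return mask.astype(bool)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def _smooth_closed(poly: np.ndarray, k: int = 3) -> np.ndarray:
    """Moving average over a closed polygon; reduces the staircase bias of
    marching squares on binary masks (a digital disk otherwise reads ~7%
    too long in perimeter)."""
    if len(poly) <= k:
        return poly
    kernel = np.ones(k) / k
    out = np.empty_like(poly)
    half = k // 2
    for i in range(2):
        ext = np.r_[poly[-half:, i], poly[:, i], poly[: half, i]]
        out[:, i] = np.convolve(ext, kernel, mode="valid")[: len(poly)]
    return out


def _contours(mask: np.ndarray):
    padded = np.pad(mask.astype(float), 1)
    return [_smooth_closed(c) for c in measure.find_contours(padded, 0.5)]


def _polygon_area(poly: np.ndarray) -> float:
    r, c = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def _polygon_perimeter(poly: np.ndarray) -> float:
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def shape2d_features(mask: np.ndarray) -> dict[str, float]:
    """The 9 shape descriptors of the (largest-component) ROI."""
    if not np.asarray(mask).any():
        raise ValueError("empty mask")
    mask = _largest_component(np.asarray(mask).astype(bool))

    contours = _contours(mask)
    # outer contour has the largest area; holes subtract from the surface
    areas = [_polygon_area(c) for c in contours]
    outer = int(np.argmax(areas))
    mesh_surface = areas[outer] - sum(a for i, a in enumerate(areas) if i != outer)
    perimeter = sum(_polygon_perimeter(c) for c in contours)

    coords = np.column_stack(np.nonzero(mask)).astype(np.float64)
    npix = coords.shape[0]

    if npix >= 3 and not np.allclose(coords, coords[0]):
        try:
            hull = ConvexHull(coords)
            pts = coords[hull.vertices]
        except Exception:  # degenerate (collinear) masks
            pts = coords
    else:
        pts = coords
    diff = pts[:, None, :] - pts[None, :, :]
    max_diam = float(np.sqrt((diff**2).sum(-1)).max())

    if npix > 1:
        cov = np.cov(coords, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0, None)
    else:
        eig = np.zeros(2)
    major = float(4 * np.sqrt(eig[0]))
    minor = float(4 * np.sqrt(eig[1]))
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0

    sphericity = (
        float(2 * np.sqrt(np.pi * mesh_surface) / perimeter)
        if perimeter > 0 else 0.0
    )
    return {
        "MeshSurface": float(mesh_surface),
        "PixelSurface": float(npix),
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / mesh_surface if mesh_surface else 0.0,
        "Sphericity": sphericity,
        "MaximumDiameter": max_diam,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Elongation": elongation,
    }
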