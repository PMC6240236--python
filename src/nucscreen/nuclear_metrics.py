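"""Nucleus segmentation and per-nucleus shape / intensity metrics.

Nuclei are segmented from the DAPI channel with a standard pipeline
(Gaussian blur, Otsu threshold, hole filling, distance-transform watershed,
area and border filters).  From each nucleus boundary we compute twelve
shape metrics — area, perimeter, circularity, best-fit-ellipse axes and
eccentricity, solidity, tortuosity, and four statistics of the signed
boundary curvature including the number of invaginations — and, for each
fluorescence channel, three intensity metrics evaluated inside the
DAPI-derived mask.

Conventions: 0-based pixel coordinates with x = column and y = row;
contours are stored counterclockwise (positive shoelace area in (x, y)).
Curvature is signed, positive where the boundary is locally convex and
negative in invaginations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage import measure, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu

from .io_model import ContractError

__all__ = [
    "NucleusContour",
    "segment_nuclei",
    "extract_contour",
    "contour_curvature",
    "shape_metrics",
    "intensity_metrics",
]


class ComputationError(ValueError):
    """A metric could not be computed (degenerate geometry)."""


@dataclass
class NucleusContour:
    """Closed boundary polygon of one nucleus.

    ``points`` is an (N, 2) float array of (x, y) vertices, not repeating the
    first vertex, oriented counterclockwise.  ``pixel_size`` converts pixel
    units to physical units (microns per pixel); metrics are reported in
    pixel units by default.
    """

    points: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if len(self.points) < 8:
            raise ValueError("a contour needs at least 8 vertices")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        area = _shoelace(self.points)
        if area == 0:
            raise ValueError("contour encloses zero area")
        if area < 0:  # enforce counterclockwise orientation
            self.points = self.points[::-1].copy()
        poly = Polygon(self.points)
        if not poly.is_simple:
            raise ValueError("contour is self-intersecting")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(
    dapi_image: np.ndarray,
    min_area: int = 500,
    max_area: int = 15000,
    sigma: float = 2.0,
    min_peak_distance: int = 10,
) -> np.ndarray:
    """Segment nuclei from a DAPI image into a labeled mask.

    Pipeline: Gaussian blur (``sigma`` px), Otsu threshold, hole filling,
    watershed split on the distance transform, removal of objects outside
    ``[min_area, max_area]`` pixels or touching the image border.  Labels
    are relabeled contiguously from 1.  A constant image yields an empty
    mask rather than an error.
    """
    img = np.asarray(dapi_image, dtype=float)
    if img.ndim != 2:
        raise ContractError("dapi_image must be a single-channel 2-D array")
    out = np.zeros(img.shape, dtype=np.int32)
    if img.max() == img.min():
        return out
    smooth = gaussian(img, sigma=sigma, preserve_range=True)
    bw = smooth > threshold_otsu(smooth)
    bw = ndi.binary_fill_holes(bw)
    if not bw.any():
        return out
    dist = ndi.distance_transform_edt(bw)
    # smooth the distance map: pixel plateaus otherwise seed spurious
    # watershed splits inside elongated nuclei
    dist_s = ndi.gaussian_filter(dist, sigma=2.0)
    peaks = peak_local_max(dist_s, min_distance=min_peak_distance, labels=bw)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-dist, markers, mask=bw)
    labels = segmentation.clear_border(labels)
    # area filter + contiguous relabel
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for lab, count in zip(*np.unique(labels, return_counts=True)):
        if lab != 0 and min_area <= count <= max_area:
            keep[lab] = True
    relabel = np.zeros(labels.max() + 1, dtype=np.int32)
    relabel[keep] = np.arange(1, int(keep.sum()) + 1)
    out = relabel[labels]
    return out


def extract_contour(
    mask: np.ndarray,
    label: int,
    pixel_size: float = 1.0,
    smooth_window: int = 5,
) -> NucleusContour:
    """Extract the closed boundary polygon of one labeled nucleus.

    The contour is traced at the 0.5 level of the binary label image
    (subpixel, via marching squares), resampled to ~1 px arc-length
    spacing and lightly smoothed with a circular moving average of
    ``smooth_window`` vertices to suppress the pixel staircase (which
    otherwise inflates perimeter-based metrics by several percent).
    Returned counterclockwise in (x, y) = (column, row) coordinates; set
    ``smooth_window=0`` for the raw traced polygon.
    """
    binary = np.asarray(mask) == label
    if not binary.any():
        raise KeyError(f"label {label} not present in mask")
    contours = measure.find_contours(binary.astype(float), 0.5)
    longest = max(contours, key=len)
    pts = longest[:, ::-1]  # (row, col) -> (x, y)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if smooth_window and len(pts) >= 2 * smooth_window:
        pts = _resample_closed(pts, 1.0)
        pts = np.column_stack(
            [
                _circular_smooth(pts[:, 0], smooth_window),
                _circular_smooth(pts[:, 1], smooth_window),
            ]
        )
    return NucleusContour(points=pts, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def _resample_closed(pts: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed polygon to (approximately) equal arc-length spacing."""
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(round(total / spacing)), 8)
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def _circular_smooth(v: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    ext = np.concatenate([v[-pad:], v, v[:pad]])
    return np.convolve(ext, kernel, mode="valid")


def contour_curvature(
    contour: NucleusContour,
    smoothing_window: int = 9,
    spacing: float = 1.0,
) -> np.ndarray:
    """Signed curvature (1/pixel) along the nucleus boundary.

    The contour is resampled to equal arc-length spacing (default 1 px),
    the coordinate functions are smoothed with a circular moving average of
    ``smoothing_window`` vertices, and curvature is evaluated as
    kappa = (x'y'' - y'x'') / (x'^2 + y'^2)^{3/2} with periodic central
    differences.  Positive curvature marks locally convex boundary
    (bulging outward), negative curvature marks invaginations.  One value
    per resampled vertex is returned.
    """
    if smoothing_window < 3 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be an odd integer >= 3")
    pts = _resample_closed(contour.points, spacing)
    if len(pts) < smoothing_window:
        raise ValueError(
            f"contour has {len(pts)} resampled vertices, fewer than the "
            f"smoothing window {smoothing_window}"
        )
    x = _circular_smooth(pts[:, 0], smoothing_window)
    y = _circular_smooth(pts[:, 1], smoothing_window)
    h = spacing
    xp = (np.roll(x, -1) - np.roll(x, 1)) / (2 * h)
    yp = (np.roll(y, -1) - np.roll(y, 1)) / (2 * h)
    xpp = (np.roll(x, -1) - 2 * x + np.roll(x, 1)) / h**2
    ypp = (np.roll(y, -1) - 2 * y + np.roll(y, 1)) / h**2
    denom = (xp**2 + yp**2) ** 1.5
    denom[denom == 0] = np.nan
    kappa = (xp * ypp - yp * xpp) / denom
    return kappa / contour.pixel_size


def count_invaginations(
    kappa: np.ndarray, kappa_min: float = 0.02, min_run: int = 3
) -> int:
    """Count maximal circular runs of curvature below ``-kappa_min``.

    Runs shorter than ``min_run`` vertices are treated as pixel noise.
    """
    neg = kappa < -kappa_min
    if neg.all():
        return 1 if len(kappa) >= min_run else 0
    if not neg.any():
        return 0
    # rotate so the sequence starts outside a run, making runs non-wrapping
    start = int(np.argmin(neg))
    neg = np.roll(neg, -start)
    edges = np.diff(neg.astype(int))
    run_starts = np.nonzero(edges == 1)[0]
    run_ends = np.nonzero(edges == -1)[0]
    if len(run_ends) < len(run_starts):
        run_ends = np.append(run_ends, len(neg) - 1)
    lengths = run_ends - run_starts
    return int(np.sum(lengths >= min_run))


# ---------------------------------------------------------------------------
# shape metrics
# ---------------------------------------------------------------------------

def _polygon_moments(pts: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """Area, centroid and central second-moment (covariance) matrix of a
    simple counterclockwise polygon, via Green's theorem."""
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + x1) * cross) / (6 * a)
    cy = np.sum((y + y1) * cross) / (6 * a)
    # second moments about the origin
    ixx = np.sum(cross * (y**2 + y * y1 + y1**2)) / 12  # integral of y^2 dA
    iyy = np.sum(cross * (x**2 + x * x1 + x1**2)) / 12  # integral of x^2 dA
    ixy = np.sum(cross * (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y)) / 24
    mxx = iyy / a - cx**2
    myy = ixx / a - cy**2
    mxy = ixy / a - cx * cy
    cov = np.array([[mxx, mxy], [mxy, myy]])
    return float(a), float(cx), float(cy), cov


def shape_metrics(
    contour: NucleusContour,
    smoothing_window: int = 9,
    kappa_min: float = 0.02,
    min_run: int = 3,
) -> dict[str, float]:
    """Compute the twelve nuclear-shape metrics for one contour.

    Returns Area, Circularity (P^2 / 4 pi A, equal to 1 for a circle),
    Eccentricity / Major / Minor Axis Length (best-fit ellipse via second
    moments of the enclosed region), Invaginations, Mean / Mean Negative /
    Std of Curvature, Perimeter, Solidity (area fraction of the convex
    hull) and Tortuosity (boundary length over convex-hull perimeter,
    equal to 1 for convex shapes).
    """
    poly = contour.polygon
    area = poly.area
    if area <= 0:
        raise ComputationError("degenerate contour with non-positive area")
    perimeter = poly.length
    hull = poly.convex_hull
    s = contour.pixel_size

    _, _, _, cov = _polygon_moments(contour.points)
    evals = np.linalg.eigvalsh(cov)
    lam2, lam1 = max(evals[0], 0.0), max(evals[1], 0.0)
    major = 4.0 * np.sqrt(lam1)
    minor = 4.0 * np.sqrt(lam2)
    ecc = float(np.sqrt(1.0 - lam2 / lam1)) if lam1 > 0 else 0.0

    kappa = contour_curvature(contour, smoothing_window=smoothing_window)
    kappa = kappa[np.isfinite(kappa)]
    if len(kappa) == 0:
        raise ComputationError("curvature could not be evaluated")
    negative = kappa[kappa < 0]
    mean_negative = float(negative.mean()) if len(negative) else 0.0

    return {
        "Area": area * s**2,
        "Circularity": perimeter**2 / (4 * np.pi * area),
        "Eccentricity": ecc,
        "Invaginations": float(
            count_invaginations(kappa * s, kappa_min=kappa_min, min_run=min_run)
        ),
        "Major Axis Length": major * s,
        "Mean Curvature": float(kappa.mean()),
        "Mean Negative Curvature": mean_negative,
        "Minor Axis Length": minor * s,
        "Perimeter": perimeter * s,
        "Solidity": area / hull.area,
        "Std of Curvature": float(kappa.std()),
        "Tortuosity": perimeter / hull.length,
    }


# ---------------------------------------------------------------------------
# intensity metrics
# ---------------------------------------------------------------------------

def intensity_metrics(
    mask: np.ndarray,
    label: int,
    channel_image: np.ndarray,
    band_width: int = 2,
) -> dict[str, float]:
    """Intensity metrics of one nucleus on one channel image.

    Mean Intensity and Std of Intensity are taken over all interior pixels
    of the label; BP Intensity is the mean over the boundary band — pixels
    of the mask within ``band_width`` px of its boundary (inward).  The
    DAPI-derived mask is applied unchanged to the other channels.
    """
    mask = np.asarray(mask)
    img = np.asarray(channel_image, dtype=float)
    if mask.shape != img.shape:
        raise ContractError(
            f"mask shape {mask.shape} != channel image shape {img.shape}"
        )
    region = mask == label
    if not region.any():
        raise KeyError(f"label {label} not present in mask")
    interior = img[region]
    eroded = ndi.binary_erosion(region, morphology.disk(band_width))
    band = region & ~eroded
    bp = img[band]
    return {
        "BP Intensity": float(bp.mean()) if len(bp) else float(interior.mean()),
        "Mean Intensity": float(interior.mean()),
        "Std of Intensity": float(interior.std()),
    }
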