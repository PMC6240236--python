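"""Synthetic screens with known ground truth, at two levels.

* Feature level: per-channel two-class Gaussian feature distributions with
  configurable overlap, assembled into a 384-well screen (12 expressing +
  12 repressed control wells, 320 siRNA wells, 4 replicate plates, 500-2000
  cells per well) where every siRNA well has a planted ``rescue_fraction``
  — the probability that a cell is drawn from the healthy-like class.
  Control wells are heterogeneous mixtures (repressed controls default to
  90% healthy-like cells, expressing controls to 10%), reproducing the
  overlapping single-cell distributions that make naive per-cell
  classification unstable.

* Image level: rendered multi-channel nucleus images (filled DAPI-like
  shapes with optional sinusoidal lobes, a lamin-like boundary band, a
  uniform progerin-like level, and focal spots for a DNA-damage-like
  channel) with ground-truth masks and contours, so the segmentation and
  morphometry stages can be tested against analytic truth.

Feature values are generated on a standardized (z-like) scale: class
separations are expressed directly in pooled-SD units.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm as normal_dist
from skimage.draw import polygon as draw_polygon

from .io_model import (
    ROLE_EXPRESSING,
    ROLE_REPRESSED,
    ROLE_SIRNA,
    ChannelSpec,
    PlateMap,
    WellEntry,
    default_channel_spec,
    well_name,
)

__all__ = [
    "ClassParams",
    "SyntheticScreenConfig",
    "SyntheticNucleusSpec",
    "default_class_params",
    "weak_channel_params",
    "sample_two_class",
    "generate_feature_screen",
    "render_nucleus_image",
    "overlap_coefficient",
]

HEALTHY = "healthy_like"
PROGERIA = "progeria_like"

#: Per-channel metric that carries the strong class separation by default.
STRONG_METRIC = {
    "dapi": "Std of Curvature",
    "lamin_b1": "lamin_b1 Mean Intensity",
    "progerin": "progerin Mean Intensity",
    "gh2ax": "gh2ax Std of Intensity",
}
#: Per-channel metric with the weak separation.
WEAK_METRIC = {
    "dapi": "Circularity",
    "lamin_b1": "lamin_b1 BP Intensity",
    "progerin": "progerin BP Intensity",
    "gh2ax": "gh2ax Mean Intensity",
}


@dataclass
class ClassParams:
    """Class-conditional Gaussian feature model over all metrics.

    ``mean`` maps class label -> mean vector (aligned with
    ``metric_names``); ``cov`` maps class label -> covariance matrix
    (identity by default).
    """

    metric_names: list[str]
    mean: dict[str, np.ndarray]
    cov: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        k = len(self.metric_names)
        for label in (HEALTHY, PROGERIA):
            m, c = self.mean[label], self.cov[label]
            if m.shape != (k,) or c.shape != (k, k):
                raise ValueError("parameter shapes do not match metric_names")
            np.linalg.cholesky(c)  # raises unless positive-definite

    def chol(self, label: str) -> np.ndarray:
        return np.linalg.cholesky(self.cov[label])


def _build_params(
    spec: ChannelSpec, deltas: dict[str, float]
) -> ClassParams:
    """Gaussian class params with class means split by ``deltas[metric]``
    pooled SDs (healthy low, disease high) and unit variances."""
    names = list(spec.metric_names)
    mean_h = np.zeros(len(names))
    mean_p = np.zeros(len(names))
    for i, m in enumerate(names):
        d = deltas.get(m, 0.0)
        mean_h[i] = -d / 2
        mean_p[i] = +d / 2
    eye = np.eye(len(names))
    return ClassParams(
        metric_names=names,
        mean={HEALTHY: mean_h, PROGERIA: mean_p},
        cov={HEALTHY: eye.copy(), PROGERIA: eye.copy()},
    )


def default_class_params(
    spec: ChannelSpec | None = None,
    strong_delta: float = 1.5,
    weak_delta: float = 0.3,
) -> ClassParams:
    """Default feature structure: in every channel one strongly separating
    metric (1.5 pooled SD), one weakly separating (0.3 SD), the rest
    uninformative — overlapping marginals like a real heterogeneous screen."""
    spec = spec or default_channel_spec()
    deltas: dict[str, float] = {}
    for ch in spec.channel_names:
        metrics = spec.metrics_of(ch)
        strong = STRONG_METRIC.get(ch, metrics[0])
        weak = WEAK_METRIC.get(ch, metrics[min(1, len(metrics) - 1)])
        deltas[strong] = strong_delta
        if weak != strong:
            deltas[weak] = weak_delta
    return _build_params(spec, deltas)


def weak_channel_params(
    spec: ChannelSpec | None = None,
    target_channel: str = "progerin",
    delta: float = 0.3,
) -> ClassParams:
    """Weak-separation setting: only the target channel's leading metric
    separates the classes (by ``delta`` pooled SD); every other metric is
    uninformative."""
    spec = spec or default_channel_spec()
    strong = STRONG_METRIC.get(target_channel, spec.metrics_of(target_channel)[0])
    return _build_params(spec, {strong: delta})


def sample_class(
    n: int, label: str, params: ClassParams, rng: np.random.Generator
) -> np.ndarray:
    z = rng.standard_normal((n, len(params.metric_names)))
    return params.mean[label] + z @ params.chol(label).T


def sample_two_class(
    n_per_class: int,
    params: ClassParams,
    rng: np.random.Generator | int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pure-class control populations (healthy frame, disease frame)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    h = sample_class(n_per_class, HEALTHY, params, rng)
    p = sample_class(n_per_class, PROGERIA, params, rng)
    names = params.metric_names
    return pd.DataFrame(h, columns=names), pd.DataFrame(p, columns=names)


def sample_mixture(
    n: int,
    healthy_fraction: float | dict[str, float],
    params: ClassParams,
    rng: np.random.Generator,
    spec: ChannelSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a mixture sample; returns (features, healthy labels).

    A scalar ``healthy_fraction`` draws one latent class per cell shared by
    all channels (the realistic setting: a single rescue variable drives
    every marker).  A dict channel -> fraction draws the per-channel class
    labels independently, for tests of the integration layer.
    """
    k = len(params.metric_names)
    if isinstance(healthy_fraction, dict):
        if spec is None:
            raise ValueError("spec required for per-channel fractions")
        x = np.empty((n, k))
        labels = np.zeros(n, dtype=bool)  # per-channel mode has no single label
        h_all = sample_class(n, HEALTHY, params, rng)
        p_all = sample_class(n, PROGERIA, params, rng)
        names = params.metric_names
        for ch, frac in healthy_fraction.items():
            idx = [names.index(m) for m in spec.metrics_of(ch)]
            is_h = rng.random(n) < frac
            x[:, idx] = np.where(is_h[:, None], h_all[:, idx], p_all[:, idx])
        return x, labels
    is_h = rng.random(n) < healthy_fraction
    x = np.empty((n, k))
    nh = int(is_h.sum())
    if nh:
        x[is_h] = sample_class(nh, HEALTHY, params, rng)
    if n - nh:
        x[~is_h] = sample_class(n - nh, PROGERIA, params, rng)
    return x, is_h


@dataclass
class SyntheticScreenConfig:
    """Design of a synthetic multi-plate screen.

    Defaults emulate a 384-well screen: 4 replicate plates, 12 + 12 control
    wells and 320 siRNA wells per plate, 500-2000 cells per well, repressed
    controls 90% healthy-like and expressing controls 10%.
    ``rescue_fractions`` assigns each siRNA well its planted probability of
    drawing a healthy-like cell; unlisted siRNA wells sit at the
    expressing-control level (null).
    """

    n_plates: int = 4
    n_sirna: int = 320
    n_expressing: int = 12
    n_repressed: int = 12
    cells_per_well: tuple[int, int] = (500, 2000)
    expressing_healthy_fraction: float = 0.1
    repressed_healthy_fraction: float = 0.9
    rescue_fractions: dict[str, float] = field(default_factory=dict)
    params: ClassParams | None = None
    channel_spec: ChannelSpec = field(default_factory=default_channel_spec)
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.expressing_healthy_fraction, self.repressed_healthy_fraction,
                  *self.rescue_fractions.values()):
            if not 0.0 <= f <= 1.0:
                raise ValueError("all fractions must lie in [0, 1]")
        if self.params is None:
            self.params = default_class_params(self.channel_spec)


def screen_layout(config: SyntheticScreenConfig) -> list[tuple[str, str, float, str | None]]:
    """Deterministic well layout: (well, role, healthy_fraction, sirna_name).

    Controls sit in the outer columns (expressing in column 1, repressed in
    column 24); siRNA wells fill columns 3-22 row-major.
    """
    layout: list[tuple[str, str, float, str | None]] = []
    for i in range(config.n_expressing):
        layout.append(
            (well_name(i, 0), ROLE_EXPRESSING, config.expressing_healthy_fraction, None)
        )
    for i in range(config.n_repressed):
        layout.append(
            (well_name(i, 23), ROLE_REPRESSED, config.repressed_healthy_fraction, None)
        )
    for j in range(config.n_sirna):
        w = well_name(j % 16, 2 + j // 16)
        name = f"si{j:03d}"
        frac = config.rescue_fractions.get(
            name, config.expressing_healthy_fraction
        )
        layout.append((w, ROLE_SIRNA, frac, name))
    return layout


def generate_feature_screen(
    config: SyntheticScreenConfig,
) -> tuple[pd.DataFrame, PlateMap, pd.DataFrame]:
    """Generate the feature table, plate map and truth table of a screen.

    Per cell, a latent class label is drawn from its well's healthy
    fraction, then the metric vector from that class's Gaussian.  The truth
    table records every well's planted fraction.  Output is bit-identical
    under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    params = config.params
    layout = screen_layout(config)
    names = params.metric_names
    pm = PlateMap()
    truth_rows = []
    blocks = []
    lo, hi = config.cells_per_well
    for p in range(1, config.n_plates + 1):
        plate = f"P{p}"
        for w, role, frac, sirna in layout:
            pm.add(plate, w, WellEntry(role=role, sirna_name=sirna))
            n = int(rng.integers(lo, hi + 1))
            x, is_h = sample_mixture(n, frac, params, rng)
            block = pd.DataFrame(x, columns=names)
            block.insert(0, "plate", plate)
            block.insert(1, "replicate", p)
            block.insert(2, "well", w)
            block.insert(3, "field", 1 + (np.arange(n) % 6))
            block.insert(4, "cell_id", np.arange(n))
            blocks.append(block)
            truth_rows.append(
                {
                    "plate": plate,
                    "well": w,
                    "role": role,
                    "sirna_name": sirna or "",
                    "healthy_fraction": frac,
                    "n_cells": n,
                }
            )
    features = pd.concat(blocks, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return features, pm, truth


def overlap_coefficient(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Analytic overlap coefficient of two univariate Gaussian densities.

    For equal variances this is 2 Phi(-|mu1 - mu2| / (2 sd)); the general
    case integrates the pointwise minimum of the two densities exactly via
    their crossing points.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if mu1 == mu2 and sd1 == sd2:
        return 1.0
    if sd1 == sd2:
        d = abs(mu1 - mu2) / (2 * sd1)
        return float(2 * normal_dist.cdf(-d))
    # crossing points of the two densities: quadratic in x
    a = 1 / (2 * sd2**2) - 1 / (2 * sd1**2)
    b = mu1 / sd1**2 - mu2 / sd2**2
    c = mu2**2 / (2 * sd2**2) - mu1**2 / (2 * sd1**2) + np.log(sd2 / sd1)
    r1, r2 = sorted(np.roots([a, b, c]).real)
    # order so density 1 is the narrower one
    f1 = normal_dist(mu1, sd1)
    f2 = normal_dist(mu2, sd2)
    narrow, wide = (f1, f2) if sd1 < sd2 else (f2, f1)
    # min density piecewise: wide outside [r1, r2] has smaller density in the
    # middle?  evaluate and integrate the smaller branch on each piece
    mid = (r1 + r2) / 2
    lo_branch = narrow if narrow.pdf(r1 - 1) < wide.pdf(r1 - 1) else wide
    mid_branch = narrow if narrow.pdf(mid) < wide.pdf(mid) else wide
    hi_branch = narrow if narrow.pdf(r2 + 1) < wide.pdf(r2 + 1) else wide
    return float(
        lo_branch.cdf(r1)
        + (mid_branch.cdf(r2) - mid_branch.cdf(r1))
        + (1 - hi_branch.cdf(r2))
    )


# ---------------------------------------------------------------------------
# rendered images
# ---------------------------------------------------------------------------

@dataclass
class SyntheticNucleusSpec:
    """Ground-truth description of one rendered nucleus.

    The boundary is an ellipse with radii (a, b) modulated by ``m`` radial
    sinusoidal lobes of relative amplitude ``lobe_amplitude`` (a fraction
    of the local radius); intensities define the DAPI-like interior, the
    lamin-like boundary band and focal spots for the DNA-damage-like
    channel.
    """

    center: tuple[float, float]
    a: float = 40.0
    b: float = 30.0
    lobe_count: int = 0
    lobe_amplitude: float = 0.0
    interior_intensity: float = 1000.0
    band_intensity: float = 2000.0
    focus_count: int = 0
    focus_intensity: float = 3000.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("radii must be positive")
        if not 0 <= self.lobe_amplitude < 1:
            raise ValueError("lobe_amplitude is a fraction of radius in [0, 1)")

    def boundary_points(self, n: int = 720) -> np.ndarray:
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r_ell = (self.a * self.b) / np.sqrt(
            (self.b * np.cos(theta)) ** 2 + (self.a * np.sin(theta)) ** 2
        )
        r = r_ell * (1 + self.lobe_amplitude * np.cos(self.lobe_count * theta))
        x = self.center[0] + r * np.cos(theta)
        y = self.center[1] + r * np.sin(theta)
        return np.column_stack([x, y])


def render_nucleus_image(
    specs: list[SyntheticNucleusSpec],
    image_size: tuple[int, int] = (512, 512),
    seed: int = 0,
    band_width: int = 2,
) -> dict:
    """Render per-channel images and ground truth for a set of nuclei.

    Returns a dict with keys ``images`` (channel -> float image), ``mask``
    (labeled int image, nucleus k = spec k+1), ``contours`` (list of (N, 2)
    boundary polygons) and ``specs``.  Raises if any two specs overlap.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    mask = np.zeros((h, w), dtype=np.int32)
    dapi = np.zeros((h, w))
    lamin = np.zeros((h, w))
    progerin = np.zeros((h, w))
    gh2ax = np.zeros((h, w))
    contours = []
    from scipy import ndimage as ndi
    from skimage.morphology import disk

    for k, spec in enumerate(specs, start=1):
        pts = spec.boundary_points()
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=(h, w))
        if np.any(mask[rr, cc] != 0):
            raise ValueError(f"nucleus spec {k} overlaps a previous nucleus")
        mask[rr, cc] = k
        region = mask == k
        band = region & ~ndi.binary_erosion(region, disk(band_width))
        dapi[region] += spec.interior_intensity
        lamin[region] += 0.2 * spec.interior_intensity
        lamin[band] = spec.band_intensity
        progerin[region] += spec.interior_intensity
        gh2ax[region] += 0.2 * spec.interior_intensity
        if spec.focus_count:
            ys, xs = np.nonzero(ndi.binary_erosion(region, disk(4)))
            if len(ys):
                pick = rng.choice(len(ys), size=min(spec.focus_count, len(ys)),
                                  replace=False)
                for y0, x0 in zip(ys[pick], xs[pick]):
                    yy, xx = np.ogrid[-4:5, -4:5]
                    blob = spec.focus_intensity * np.exp(-(yy**2 + xx**2) / (2 * 1.5**2))
                    ys0, ys1 = y0 - 4, y0 + 5
                    xs0, xs1 = x0 - 4, x0 + 5
                    gh2ax[ys0:ys1, xs0:xs1] += blob
        contours.append(pts)
    images = {"dapi": dapi, "lamin_b1": lamin, "progerin": progerin, "gh2ax": gh2ax}
    noise_sd = max((s.noise_sd for s in specs), default=0.0)
    if noise_sd > 0:
        for ch in images:
            img = rng.poisson(np.clip(images[ch], 0, None)).astype(float)
            img += rng.normal(0, noise_sd, size=img.shape)
            images[ch] = np.clip(img, 0, None)
    return {"images": images, "mask": mask, "contours": contours, "specs": specs}
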