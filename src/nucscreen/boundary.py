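"""Linear classification boundaries between typical control cores.

A linear SVM trained on the z-scored typical cells of the two control
classes yields a hyperplane w . x + b = 0 whose unit normal ``w`` gives the
relative weight of every metric and whose signed Euclidean distance scores
each cell: positive distances are healthy-like, negative disease-like.

The stability of the boundary direction is quantified by bootstrap:
retraining on resampled cells and measuring the angle between each
bootstrap normal and the reference normal (trained once on the original,
non-resampled selection), per channel subspace.  Typical-cell selection
produces markedly more stable directions than equally sized random cell
samples when the class distributions overlap — the core motivation for
anchoring classification on typical cells.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io_model import ChannelSpec, ContractError
from .reference_cells import Normalization, fit_normalization, select_typical

__all__ = [
    "Boundary",
    "StabilityReport",
    "train_boundary",
    "signed_distance",
    "boundary_angle",
    "bootstrap_stability",
    "project_sample_shift",
    "metric_importance",
]


class TrainingError(RuntimeError):
    """SVM training failed to produce a usable separating direction."""


@dataclass
class Boundary:
    """A trained linear classifier in z-scored metric space.

    ``w`` is stored as a unit vector, with the SVM's scaling folded into the
    offset ``b``, so that ``w . z + b`` is the signed Euclidean distance of
    a z-scored cell ``z`` from the hyperplane.  Sign convention: positive =
    healthy-like.
    """

    metric_names: list[str]
    w: np.ndarray
    b: float
    normalization: Normalization
    channel: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        norm = np.linalg.norm(self.w)
        if not np.isfinite(norm) or norm == 0:
            raise TrainingError("boundary normal has zero length")
        if abs(norm - 1.0) > 1e-9:
            self.b = float(self.b / norm)
            self.w = self.w / norm

    def signed_distances(self, features: pd.DataFrame) -> np.ndarray:
        """Vectorized signed distance for a frame of cells."""
        z = self.normalization.apply(features[self.metric_names])
        return z @ self.w + self.b

    def to_json(self, path: str | Path) -> None:
        doc = {
            "metric_names": self.metric_names,
            "w": self.w.tolist(),
            "b": self.b,
            "normalization": {
                "center": self.normalization.center[self.metric_names].tolist(),
                "scale": self.normalization.scale[self.metric_names].tolist(),
            },
            "channel": self.channel,
            "sign_convention": "positive = healthy-like",
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Boundary":
        doc = json.loads(Path(path).read_text())
        names = doc["metric_names"]
        norm = Normalization(
            center=pd.Series(doc["normalization"]["center"], index=names),
            scale=pd.Series(doc["normalization"]["scale"], index=names),
        )
        return cls(
            metric_names=names,
            w=np.array(doc["w"]),
            b=doc["b"],
            normalization=norm,
            channel=doc.get("channel"),
            provenance=doc.get("provenance", {}),
        )


def train_boundary(
    typical_healthy: pd.DataFrame,
    typical_progeria: pd.DataFrame,
    normalization: Normalization,
    c_param: float = 1.0,
    channel: str | None = None,
    metrics: Sequence[str] | None = None,
) -> Boundary:
    """Fit the linear SVM separating the two typical cores.

    Cells are z-scored with ``normalization`` before fitting; the returned
    boundary has a unit normal and positive distances on the healthy-like
    side (verified against the healthy core mean).
    """
    names = list(metrics) if metrics is not None else normalization.metric_names
    if len(typical_healthy) < 2 or len(typical_progeria) < 2:
        raise ContractError("each class needs at least 2 cells")
    zh = normalization.apply(typical_healthy[names])
    zp = normalization.apply(typical_progeria[names])
    x = np.vstack([zh, zp])
    y = np.concatenate([np.ones(len(zh)), -np.ones(len(zp))])
    svc = SVC(kernel="linear", C=c_param)
    svc.fit(x, y)
    w = svc.coef_.ravel().astype(float)
    b = float(svc.intercept_[0])
    norm = np.linalg.norm(w)
    if not np.isfinite(norm) or norm < 1e-12:
        raise TrainingError("degenerate training set: zero separating direction")
    boundary = Boundary(
        metric_names=names, w=w, b=b, normalization=normalization, channel=channel
    )
    # enforce the sign convention: healthy core mean on the positive side
    if float(zh.mean(axis=0) @ boundary.w + boundary.b) < 0:
        boundary.w = -boundary.w
        boundary.b = -boundary.b
    return boundary


def signed_distance(
    cell: Mapping[str, float] | pd.Series, boundary: Boundary, channel: str | None = None
) -> float:
    """Signed Euclidean distance of one cell from the boundary (z-space).

    Positive = healthy-like.  ``channel`` is informational; the boundary
    itself fixes which metrics are used.
    """
    try:
        z = boundary.normalization.apply(cell)
    except KeyError as e:
        raise ContractError(f"cell is missing boundary metric {e}") from None
    return float(z @ boundary.w + boundary.b)


def metric_importance(boundary: Boundary) -> dict[str, float]:
    """Relative importance of each metric: |w_i| / sum_j |w_j| (sums to 1)."""
    mags = np.abs(boundary.w)
    shares = mags / mags.sum()
    return dict(zip(boundary.metric_names, shares))


def group_importance(boundary: Boundary, channel_spec: ChannelSpec) -> dict[str, float]:
    """Metric importance aggregated per channel group."""
    shares = metric_importance(boundary)
    return {
        ch: float(sum(shares.get(m, 0.0) for m in channel_spec.metrics_of(ch)))
        for ch in channel_spec.channel_names
    }


def boundary_angle(
    w1: np.ndarray | Mapping[str, float],
    w2: np.ndarray | Mapping[str, float],
    subspace_metrics: Sequence[str] | None = None,
    metric_names: Sequence[str] | None = None,
) -> float:
    """Angle in degrees, in [0, 90], between two boundary directions.

    The vectors are restricted to ``subspace_metrics`` (a channel's metric
    coordinates) before the cosine is taken; the absolute cosine is used so
    that orientation flips between trainings do not register as large
    angles.  Raises on a zero-length restriction.
    """
    def restrict(w) -> np.ndarray:
        if hasattr(w, "keys"):
            keys = subspace_metrics if subspace_metrics is not None else list(w.keys())
            return np.array([w[k] for k in keys], dtype=float)
        w = np.asarray(w, dtype=float)
        if subspace_metrics is None:
            return w
        if metric_names is None:
            raise ContractError("metric_names required to restrict a plain vector")
        idx = [list(metric_names).index(m) for m in subspace_metrics]
        return w[idx]

    v1, v2 = restrict(w1), restrict(w2)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length restriction: angle undefined in subspace")
    cos = abs(float(v1 @ v2)) / (n1 * n2)
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


@dataclass
class StabilityReport:
    """Bootstrap distribution of boundary-direction angles per channel."""

    mode: str
    n_cells: int
    n_bootstrap: int
    angles: dict[str, np.ndarray]  # channel -> angles (degrees), len n_bootstrap

    def mean_angle(self, channel: str) -> float:
        return float(np.mean(self.angles[channel]))

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "channel": ch,
                "mode": self.mode,
                "mean_angle": float(np.mean(a)),
                "sd_angle": float(np.std(a, ddof=1)),
                "min_angle": float(np.min(a)),
                "max_angle": float(np.max(a)),
            }
            for ch, a in self.angles.items()
        ]
        return pd.DataFrame(rows)


def _fit_on_selection(
    healthy: pd.DataFrame,
    progeria: pd.DataFrame,
    channel_spec: ChannelSpec,
    c_param: float,
    channel: str | None = None,
    n_typical: int | None = None,
    prescale: bool = True,
) -> Boundary:
    """Train on one channel's metrics (or all, channel=None); typical cores
    are selected within the same metric scope when ``n_typical`` is set."""
    metrics = list(
        channel_spec.metrics_of(channel) if channel is not None
        else channel_spec.metric_names
    )
    if n_typical is not None:
        th = select_typical(healthy, channel, n_typical, channel_spec,
                            class_label="healthy_like", prescale=prescale)
        tp = select_typical(progeria, channel, n_typical, channel_spec,
                            class_label="progeria_like", prescale=prescale)
        healthy = healthy.loc[th.cell_indices]
        progeria = progeria.loc[tp.cell_indices]
    norm = fit_normalization(healthy, progeria, metrics)
    return train_boundary(healthy, progeria, norm, c_param=c_param, channel=channel)


def bootstrap_stability(
    healthy: pd.DataFrame,
    progeria: pd.DataFrame,
    channel_spec: ChannelSpec,
    selection_mode: Literal["typical", "random"],
    n_cells: int = 300,
    n_bootstrap: int = 200,
    seed: int = 0,
    c_param: float = 1.0,
    prescale: bool = True,
    train_scope: Literal["per_channel", "full"] = "per_channel",
) -> StabilityReport:
    """Bootstrap the whole boundary-construction procedure and report the
    per-channel angles to the reference boundary.

    ``random`` mode draws ``n_cells`` per class uniformly without
    replacement per bootstrap; ``typical`` mode resamples the full control
    population with replacement and reapplies typical-cell selection, so
    that the stability of the entire procedure is measured.  The reference
    boundary is trained once on the original (non-resampled) selection.

    With ``train_scope="per_channel"`` (default) typical selection and SVM
    training run within each channel's own metrics and the angle is taken
    between the per-channel normals; with ``"full"`` a single SVM is
    trained on all metrics simultaneously and the angles are measured
    between the restrictions of the full-space normals to each channel's
    coordinates.  The per-channel scope is the default because the weight
    noise of a channel's uninformative metrics inside a full-space normal
    dominates its subspace restriction, masking the stability of the
    channel's own boundary.
    """
    if selection_mode not in ("typical", "random"):
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    if train_scope not in ("per_channel", "full"):
        raise ValueError(f"unknown train_scope {train_scope!r}")
    if n_cells > min(len(healthy), len(progeria)):
        raise ValueError(
            f"n_cells={n_cells} exceeds population size "
            f"{min(len(healthy), len(progeria))}"
        )
    rng = np.random.default_rng(seed)
    metrics = list(channel_spec.metric_names)
    channels = list(channel_spec.channel_names)
    scopes: list[str | None] = channels if train_scope == "per_channel" else [None]

    def fit_all(hpop: pd.DataFrame, ppop: pd.DataFrame, typical: bool) -> dict:
        return {
            sc: _fit_on_selection(
                hpop, ppop, channel_spec, c_param, channel=sc,
                n_typical=n_cells if typical else None, prescale=prescale,
            )
            for sc in scopes
        }

    if selection_mode == "typical":
        reference = fit_all(healthy, progeria, typical=True)
    else:
        ih = rng.choice(len(healthy), size=n_cells, replace=False)
        ip = rng.choice(len(progeria), size=n_cells, replace=False)
        reference = fit_all(healthy.iloc[ih], progeria.iloc[ip], typical=False)

    angles: dict[str, list[float]] = {ch: [] for ch in channels}
    for _ in range(n_bootstrap):
        if selection_mode == "random":
            ih = rng.choice(len(healthy), size=n_cells, replace=False)
            ip = rng.choice(len(progeria), size=n_cells, replace=False)
            boot = fit_all(healthy.iloc[ih], progeria.iloc[ip], typical=False)
        else:
            ih = rng.integers(0, len(healthy), size=len(healthy))
            ip = rng.integers(0, len(progeria), size=len(progeria))
            boot = fit_all(
                healthy.iloc[ih].reset_index(drop=True),
                progeria.iloc[ip].reset_index(drop=True),
                typical=True,
            )
        for ch in channels:
            sub = channel_spec.metrics_of(ch)
            if train_scope == "per_channel":
                angles[ch].append(boundary_angle(reference[ch].w, boot[ch].w))
            else:
                angles[ch].append(
                    boundary_angle(
                        reference[None].w, boot[None].w,
                        subspace_metrics=sub, metric_names=metrics,
                    )
                )
    return StabilityReport(
        mode=selection_mode,
        n_cells=n_cells,
        n_bootstrap=n_bootstrap,
        angles={ch: np.asarray(a) for ch, a in angles.items()},
    )


def project_sample_shift(
    sample_cells: pd.DataFrame, boundary: Boundary, channel: str | None = None
) -> tuple[float, float]:
    """Decompose a sample's mean z-scored vector relative to the boundary.

    Returns ``(perpendicular, parallel)``: the signed component of the mean
    along the boundary normal and the norm of the residual within the
    boundary's metric subspace.  Perturbations that move cells across the
    boundary shift perpendicular; shifts parallel to the boundary change
    metrics the classifier considers uninformative.
    """
    if len(sample_cells) == 0:
        raise ContractError("sample is empty")
    z = boundary.normalization.apply(sample_cells[boundary.metric_names])
    m = z.mean(axis=0)
    perp = float(m @ boundary.w)
    residual = m - perp * boundary.w
    return perp, float(np.linalg.norm(residual))
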