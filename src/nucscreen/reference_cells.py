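"""Typical-cell selection and the normalization it anchors.

Within each control population, "typical cells" are the core of the
``n_typical`` cells closest to the per-channel population mean under the
L1 (Manhattan) distance.  The cores of the two control classes — healthy-like
(repressed control) and disease-like (expressing control) — then define the
z-score normalization used to rescale every cell before classification.

Selection operates on raw metric values, before any z-scoring, because the
z-scoring itself is defined from the selected cells.  By default each metric
is divided by its population standard deviation inside the L1 sum so that no
single high-magnitude metric dominates the distance; set
``prescale=False`` for the plain unweighted L1 distance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import ChannelSpec, ContractError

log = logging.getLogger("nucscreen")

__all__ = ["TypicalSet", "Normalization", "l1_distance", "select_typical",
           "fit_normalization"]


class SelectionError(ValueError):
    """Typical-cell selection was asked of an unusable population."""


@dataclass
class TypicalSet:
    """The L1 core of one control population in one channel.

    ``cell_indices`` index into the population frame the selection was run
    on (closest cell first); ``distances`` are the matching L1 distances to
    the population mean, nondecreasing along the list.
    """

    channel: str | None
    class_label: str
    cell_indices: np.ndarray
    distances: np.ndarray
    population_mean: pd.Series

    def __post_init__(self) -> None:
        if np.any(np.diff(self.distances) < 0):
            raise ValueError("distances must be nondecreasing")
        if len(self.cell_indices) != len(self.distances):
            raise ValueError("cell_indices and distances must be equal length")


@dataclass
class Normalization:
    """Per-metric z-score transform anchored on pooled typical cells."""

    center: pd.Series
    scale: pd.Series

    def __post_init__(self) -> None:
        bad = self.scale.index[self.scale <= 0]
        if len(bad):
            raise ValueError(f"zero-variance metric(s): {list(bad)}")

    @property
    def metric_names(self) -> list[str]:
        return list(self.center.index)

    def apply(self, features: pd.DataFrame | pd.Series | Mapping[str, float]) -> np.ndarray:
        """Return z-scored features as an array (cells x metrics)."""
        names = self.metric_names
        if isinstance(features, pd.DataFrame):
            x = features[names].to_numpy(dtype=float)
        elif isinstance(features, pd.Series):
            x = features[names].to_numpy(dtype=float)
        else:
            x = np.array([features[n] for n in names], dtype=float)
        return (x - self.center.to_numpy()) / self.scale.to_numpy()


def l1_distance(
    features_a: Mapping[str, float] | pd.Series,
    features_b: Mapping[str, float] | pd.Series,
) -> float:
    """L1 (Manhattan) distance between two metric vectors with equal keys."""
    keys_a = set(features_a.keys() if hasattr(features_a, "keys") else features_a.index)
    keys_b = set(features_b.keys() if hasattr(features_b, "keys") else features_b.index)
    if keys_a != keys_b:
        raise ContractError(
            f"metric sets differ: {sorted(keys_a ^ keys_b)} not shared"
        )
    return float(sum(abs(float(features_a[k]) - float(features_b[k])) for k in keys_a))


def _metric_columns(
    channel: str | None, channel_spec: ChannelSpec | None, cells: pd.DataFrame
) -> list[str]:
    if channel is None:
        if channel_spec is not None:
            return list(channel_spec.metric_names)
        from .io_model import ID_COLUMNS

        return [c for c in cells.columns if c not in ID_COLUMNS]
    if channel_spec is None:
        raise ContractError("channel_spec is required when selecting by channel")
    return list(channel_spec.metrics_of(channel))


def select_typical(
    cells: pd.DataFrame,
    channel: str | None,
    n_typical: int,
    channel_spec: ChannelSpec | None = None,
    class_label: str = "",
    prescale: bool = True,
) -> TypicalSet:
    """Select the ``n_typical`` cells closest to the population mean (L1).

    ``channel=None`` selects on the concatenation of all metrics (used for
    the combined-channel analysis).  If the population is smaller than
    ``n_typical`` every cell is selected and a warning is logged.  Ties in
    distance are broken by ascending (well, cell_id) when those columns are
    present, by row position otherwise.
    """
    if len(cells) < 2:
        raise SelectionError("population must contain at least 2 cells")
    metrics = _metric_columns(channel, channel_spec, cells)
    x = cells[metrics].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    dev = np.abs(x - mean)
    if prescale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        dev = dev / sd
    dist = dev.sum(axis=1)
    if "well" in cells.columns and "cell_id" in cells.columns:
        wells = cells["well"].to_numpy()
        cids = cells["cell_id"].to_numpy()
        order = np.lexsort((cids, wells, dist))
    else:
        order = np.lexsort((np.arange(len(dist)), dist))
    n = min(n_typical, len(cells))
    if n < n_typical:
        log.warning(
            "population of %d smaller than n_typical=%d; selecting all",
            len(cells), n_typical,
        )
    chosen = order[:n]
    return TypicalSet(
        channel=channel,
        class_label=class_label,
        cell_indices=cells.index.to_numpy()[chosen],
        distances=dist[chosen],
        population_mean=pd.Series(mean, index=metrics),
    )


def fit_normalization(
    typical_healthy: pd.DataFrame,
    typical_progeria: pd.DataFrame,
    metrics: Sequence[str] | None = None,
) -> Normalization:
    """Per-metric mean/SD over the pooled typical cells of both classes.

    The resulting transform rescales all metrics to zero mean and unit
    (sample) variance on the pooled cores, and is applied both before SVM
    training and to every cell scored against the boundary.
    """
    if len(typical_healthy) == 0 or len(typical_progeria) == 0:
        raise ContractError("both typical sets must be non-empty")
    if metrics is None:
        metrics = [c for c in typical_healthy.columns if c in typical_progeria.columns]
        from .io_model import ID_COLUMNS

        metrics = [c for c in metrics if c not in ID_COLUMNS]
    pooled = pd.concat(
        [typical_healthy[list(metrics)], typical_progeria[list(metrics)]],
        axis=0,
        ignore_index=True,
    )
    center = pooled.mean()
    scale = pooled.std(ddof=1)
    bad = scale.index[~(scale > 0)]
    if len(bad):
        raise ValueError(f"zero-variance metric(s): {list(bad)}")
    return Normalization(center=center, scale=scale)


def write_typical_csv(
    typical_sets: Sequence[tuple[str, TypicalSet, pd.DataFrame]], path
) -> None:
    """Audit CSV of selected typical cells: plate, channel, class, well,
    cell_id, l1_distance.  Each tuple is (plate_id, set, population frame)."""
    rows = []
    for plate, ts, pop in typical_sets:
        sub = pop.loc[ts.cell_indices]
        for (idx, row), d in zip(sub.iterrows(), ts.distances):
            rows.append(
                {
                    "plate": plate,
                    "channel": ts.channel or "all",
                    "class": ts.class_label,
                    "well": row.get("well", ""),
                    "cell_id": row.get("cell_id", idx),
                    "l1_distance": d,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
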