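"""Integration of single-cell classifications across fluorescence channels.

A cell classified healthy-like in one channel can be disease-like in
another; the integration layer quantifies this by (a) per-cell channel
profiles and the fraction of cells healthy-like in *all* channels, (b) the
fraction healthy-like in the three channels other than a chosen primary
one, and (c) a combined analysis that re-runs the whole typical-cell /
boundary pipeline on the concatenation of every channel's metrics, whose
normal-vector weights show which channels carry the discriminating signal.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .boundary import Boundary, train_boundary
from .io_model import ContractError, RunConfig
from .reference_cells import fit_normalization, select_typical

__all__ = [
    "CellChannelProfile",
    "classify_cell_all_channels",
    "channel_flags",
    "other_channels_fraction",
    "all_channels_fraction",
    "combined_boundary",
    "hit_overlap",
]


@dataclass
class CellChannelProfile:
    """Per-channel healthy flags of one cell plus their conjunction."""

    healthy_by_channel: dict[str, bool]

    @property
    def all_channel_healthy(self) -> bool:
        return all(self.healthy_by_channel.values())


def classify_cell_all_channels(
    cell: Mapping[str, float] | pd.Series, boundaries: Mapping[str, Boundary]
) -> CellChannelProfile:
    """Classify one cell in every channel by boundary-distance sign."""
    from .boundary import signed_distance

    if not boundaries:
        raise ContractError("no channel boundaries provided")
    flags = {ch: signed_distance(cell, b) > 0 for ch, b in boundaries.items()}
    return CellChannelProfile(healthy_by_channel=flags)


def channel_flags(
    cells: pd.DataFrame, boundaries: Mapping[str, Boundary]
) -> pd.DataFrame:
    """Per-cell healthy flags for every channel (vectorized), plus the
    ``all_channels`` conjunction column."""
    if not boundaries:
        raise ContractError("no channel boundaries provided")
    out = pd.DataFrame(index=cells.index)
    for ch, b in boundaries.items():
        out[ch] = b.signed_distances(cells) > 0
    out["all_channels"] = out.all(axis=1)
    return out


def all_channels_fraction(
    cells: pd.DataFrame, boundaries: Mapping[str, Boundary]
) -> float:
    """Percentage of cells healthy-like in every configured channel."""
    flags = channel_flags(cells, boundaries)
    return 100.0 * float(flags["all_channels"].mean())


def other_channels_fraction(
    cells: pd.DataFrame, primary: str, boundaries: Mapping[str, Boundary]
) -> float:
    """Percentage of cells healthy-like in all channels except ``primary``."""
    others = {ch: b for ch, b in boundaries.items() if ch != primary}
    if primary not in boundaries:
        raise ContractError(f"primary channel {primary!r} has no boundary")
    if not others:
        raise ContractError("need at least two channels for an 'others' fraction")
    flags = channel_flags(cells, others)
    return 100.0 * float(flags["all_channels"].mean())


def combined_boundary(
    healthy_pop: pd.DataFrame,
    progeria_pop: pd.DataFrame,
    config: RunConfig,
    reuse_cores: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> Boundary:
    """Run the full pipeline once on the concatenated metric vector.

    Typical cells are re-selected on the concatenation of all channels'
    metrics (pass ``reuse_cores`` to supply externally selected cores
    instead), the normalization is fit on the pooled cores and the SVM
    trained on all metrics.  ``metric_importance`` /
    ``group_importance`` on the result show each channel's share of the
    classification direction.
    """
    spec = config.channel_spec
    metrics = list(spec.metric_names)
    if reuse_cores is not None:
        core_h, core_p = reuse_cores
    else:
        th = select_typical(healthy_pop, None, config.n_typical, spec,
                            class_label="healthy_like", prescale=config.l1_prescale)
        tp = select_typical(progeria_pop, None, config.n_typical, spec,
                            class_label="progeria_like", prescale=config.l1_prescale)
        core_h = healthy_pop.loc[th.cell_indices]
        core_p = progeria_pop.loc[tp.cell_indices]
    norm = fit_normalization(core_h, core_p, metrics)
    return train_boundary(core_h, core_p, norm, c_param=config.svm_c, channel=None)


def hit_overlap(
    hits_combined: set[str], hits_per_channel: Mapping[str, set[str]]
) -> tuple[float, float]:
    """Overlap between combined-analysis hits and the per-channel hit union.

    Returns ``(fraction_combined_in_union, fraction_union_in_combined)``.
    An empty combined set (or union) makes the corresponding fraction
    vacuously 1.0.
    """
    union: set[str] = set()
    for s in hits_per_channel.values():
        union |= s
    inter = hits_combined & union
    f_combined = len(inter) / len(hits_combined) if hits_combined else 1.0
    f_union = len(inter) / len(union) if union else 1.0
    return f_combined, f_union


def integration_table(
    features: pd.DataFrame,
    platemap,
    boundaries_by_plate: Mapping[tuple[str, str], Boundary],
    channels: list[str],
) -> pd.DataFrame:
    """Per-sample integration summary averaged over replicate plates.

    Columns: per-channel %, ``others_<ch>`` (healthy in the three channels
    other than <ch>), and ``all_channels`` %.  Cells are integrated within
    each plate using that plate's boundaries, then averaged over plates.
    """
    rows = []
    for plate in sorted(features["plate"].unique()):
        sub = features[features["plate"] == plate]
        bnds = {ch: boundaries_by_plate[(plate, ch)] for ch in channels}
        flags = channel_flags(sub, bnds)
        flags = flags.assign(well=sub["well"].to_numpy())
        for well, grp in flags.groupby("well", sort=True):
            entry = platemap.entries.get((plate, well))
            if entry is None:
                continue
            row = {"plate": plate, "well": well, "role": entry.role}
            for ch in channels:
                row[f"pct_{ch}"] = 100.0 * float(grp[ch].mean())
                others = [c for c in channels if c != ch]
                row[f"others_{ch}"] = 100.0 * float(grp[others].all(axis=1).mean())
            row["pct_all_channels"] = 100.0 * float(grp["all_channels"].mean())
            rows.append(row)
    per_plate = pd.DataFrame(rows)
    value_cols = [c for c in per_plate.columns if c.startswith(("pct_", "others_"))]
    return (
        per_plate.groupby(["well", "role"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )


def plot_integration(table: pd.DataFrame, primary: str, channels: list[str], path) -> None:
    """Scatter of primary-channel % vs other-three-channels %, circle size
    proportional to the all-channel %."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"repressed_control": "green", "expressing_control": "red"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for role, grp in table.groupby("role"):
        ax.scatter(
            grp[f"pct_{primary}"],
            grp[f"others_{primary}"],
            s=4 + grp["pct_all_channels"],
            alpha=0.6,
            color=colors.get(role, "steelblue"),
            label=role,
        )
    ax.set_xlabel(f"% healthy-like in {primary}")
    ax.set_ylabel("% healthy-like in the other channels")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
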