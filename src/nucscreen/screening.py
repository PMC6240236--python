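"""Per-sample healthy-like fractions, replicate aggregation and hit calling.

Every cell is classified by the sign of its distance to the per-plate,
per-channel boundary; a sample's score is the percentage of its cells on the
healthy-like side, computed separately on each replicate plate and then
averaged.  A perturbation is a hit in a channel when (1) its replicate-mean
percentage exceeds the expressing-control mean by at least
``hit_sd_multiplier`` (default 5) control standard deviations, and (2) the
false positive rate estimated from its replicate-to-replicate variation is
below ``fpr_threshold`` (default 0.05) — after excluding cytotoxic wells
whose cell count falls below half the repressed-control count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm as normal_dist
from scipy.stats import t as t_dist

from .boundary import Boundary, train_boundary
from .io_model import (
    ROLE_EXPRESSING,
    ROLE_REPRESSED,
    ContractError,
    PlateMap,
    RunConfig,
)
from .reference_cells import fit_normalization, select_typical

log = logging.getLogger("nucscreen")

__all__ = [
    "SampleScore",
    "HitCall",
    "fraction_healthy",
    "hit_threshold",
    "chebyshev_bound",
    "estimate_fpr",
    "cytotoxicity_filter",
    "call_hits",
    "score_screen",
    "run_screen",
]


class ScoreError(ValueError):
    """A score is undefined (e.g. empty sample)."""


@dataclass
class SampleScore:
    """Replicate-wise healthy-like percentages of one sample in one channel."""

    sample_id: str
    role: str
    channel: str
    replicate_percentages: list[float]
    n_cells: list[int]
    sirna_name: str | None = None

    def __post_init__(self) -> None:
        for p in self.replicate_percentages:
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"percentage {p} outside [0, 100]")

    @property
    def mean_percentage(self) -> float:
        return float(np.mean(self.replicate_percentages))

    @property
    def sd_percentage(self) -> float:
        if len(self.replicate_percentages) < 2:
            return float("nan")
        return float(np.std(self.replicate_percentages, ddof=1))

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.n_cells))


@dataclass
class HitCall:
    sample_id: str
    channel: str
    mean_percentage: float
    sd_percentage: float
    threshold_used: float
    fpr_estimate: float
    cytotoxic: bool
    is_hit: bool
    sirna_name: str | None = None


def fraction_healthy(
    sample_cells: pd.DataFrame, boundary: Boundary, channel: str | None = None
) -> float:
    """Percentage of a sample's cells with strictly positive signed distance."""
    if len(sample_cells) == 0:
        raise ScoreError("empty sample: healthy-like fraction undefined")
    d = boundary.signed_distances(sample_cells)
    return 100.0 * float(np.mean(d > 0))


def hit_threshold(expressing_control_scores: list[SampleScore] | list[float],
                  k: float = 5.0) -> float:
    """Hit threshold: control mean + k SD of the expressing-control sample
    means (default k = 5)."""
    if expressing_control_scores and isinstance(expressing_control_scores[0], SampleScore):
        means = [s.mean_percentage for s in expressing_control_scores]
    else:
        means = [float(s) for s in expressing_control_scores]
    if len(means) < 2:
        raise ScoreError("need at least 2 control samples for a threshold")
    return float(np.mean(means) + k * np.std(means, ddof=1))


def chebyshev_bound(k: float) -> float:
    """Distribution-free bound 1/k^2 on the probability of exceeding k SDs.

    At the default hit threshold of k = 5 the bound is 0.04: whatever the
    control-score distribution, fewer than 4% of null samples can exceed it.
    """
    if k <= 0:
        raise ValueError("k must be strictly positive")
    return 1.0 / k**2


def estimate_fpr(
    replicate_percentages: list[float] | np.ndarray,
    threshold: float,
    use_t: bool = False,
) -> float:
    """False-positive rate of a sample from its replicate variation.

    Models the replicate-mean percentage as normal with the observed
    replicate mean and SD and returns the lower-tail probability that the
    sample's true percentage lies at or below the threshold,
    Phi((threshold - m) / s).  With ``use_t`` a Student-t tail
    (df = n - 1) replaces the normal.  At s = 0 the limit is 0 if
    m > threshold and 1 otherwise.
    """
    p = np.asarray(replicate_percentages, dtype=float)
    if len(p) < 2:
        raise ScoreError("need at least 2 replicates to estimate an FPR")
    m, s = float(p.mean()), float(p.std(ddof=1))
    if s == 0:
        return 0.0 if m > threshold else 1.0
    z = (threshold - m) / s
    if use_t:
        return float(t_dist.cdf(z, df=len(p) - 1))
    return float(normal_dist.cdf(z))


def cytotoxicity_filter(
    sample_counts: list[int] | np.ndarray,
    repressed_control_mean_count: float,
    fraction: float = 0.5,
) -> bool:
    """True when the replicate-averaged cell count drops below ``fraction``
    of the repressed-control mean count (default 50%)."""
    if repressed_control_mean_count <= 0:
        raise ContractError("control mean count must be positive")
    return float(np.mean(sample_counts)) < fraction * repressed_control_mean_count


def call_hits(
    scores: list[SampleScore],
    expressing_controls: list[SampleScore],
    repressed_controls: list[SampleScore],
    config: RunConfig,
) -> tuple[list[HitCall], dict[str, float]]:
    """Apply the two hit criteria plus the cytotoxicity filter to one
    channel's sample scores.

    Returns the calls and a reference-lines dict: the hit threshold
    (expressing mean + k SD) and the repressed-control lower line
    (repressed mean - k SD), the latter reported for annotation only.
    """
    thr = hit_threshold(expressing_controls, k=config.hit_sd_multiplier)
    repressed_means = [s.mean_percentage for s in repressed_controls]
    repressed_line = float(
        np.mean(repressed_means)
        - config.hit_sd_multiplier * np.std(repressed_means, ddof=1)
    )
    control_count = float(np.mean([s.mean_count for s in repressed_controls]))
    calls = []
    for s in scores:
        toxic = cytotoxicity_filter(
            s.n_cells, control_count, fraction=config.cytotoxicity_fraction
        )
        fpr = estimate_fpr(s.replicate_percentages, thr)
        is_hit = (
            (not toxic)
            and s.mean_percentage > thr
            and fpr < config.fpr_threshold
        )
        calls.append(
            HitCall(
                sample_id=s.sample_id,
                channel=s.channel,
                mean_percentage=s.mean_percentage,
                sd_percentage=s.sd_percentage,
                threshold_used=thr,
                fpr_estimate=fpr,
                cytotoxic=toxic,
                is_hit=is_hit,
                sirna_name=s.sirna_name,
            )
        )
    lines = {"hit_threshold": thr, "repressed_line": repressed_line}
    return calls, lines


# ---------------------------------------------------------------------------
# screen orchestration
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Scores, boundaries and hit calls of a whole multi-plate screen."""

    scores: pd.DataFrame           # per (channel, plate, well): pct, n_cells
    boundaries: dict               # (plate, channel) -> Boundary
    sample_scores: dict            # channel -> list[SampleScore]
    hits: dict = field(default_factory=dict)        # channel -> list[HitCall]
    reference_lines: dict = field(default_factory=dict)  # channel -> lines

    def hits_frame(self) -> pd.DataFrame:
        rows = []
        for ch, calls in self.hits.items():
            for c in calls:
                rows.append(
                    {
                        "channel": ch,
                        "sample": c.sample_id,
                        "sirna_name": c.sirna_name or "",
                        "mean_pct": c.mean_percentage,
                        "sd_pct": c.sd_percentage,
                        "threshold": c.threshold_used,
                        "fpr": c.fpr_estimate,
                        "cytotoxic": c.cytotoxic,
                        "is_hit": c.is_hit,
                    }
                )
        return pd.DataFrame(rows)

    def hit_wells(self, channel: str) -> set[str]:
        return {c.sample_id for c in self.hits.get(channel, []) if c.is_hit}


def train_plate_boundaries(
    features: pd.DataFrame,
    platemap: PlateMap,
    config: RunConfig,
    plate: str,
    channels: list[str] | None = None,
) -> dict[str, Boundary]:
    """Per-channel boundaries for one plate from its pooled control wells.

    Control wells of each role are pooled, typical cells selected per
    channel, the z-score normalization fit on the pooled cores, and the SVM
    trained on the cores — independently for each replicate plate.
    """
    spec = config.channel_spec
    channels = channels if channels is not None else list(spec.channel_names)
    sub = features[features["plate"] == plate]
    exp_wells = {w for _, w in platemap.wells_with_role(ROLE_EXPRESSING, plate)}
    rep_wells = {w for _, w in platemap.wells_with_role(ROLE_REPRESSED, plate)}
    if not exp_wells or not rep_wells:
        raise ContractError(f"plate {plate!r} lacks control wells of both roles")
    progeria_pop = sub[sub["well"].isin(exp_wells)]
    healthy_pop = sub[sub["well"].isin(rep_wells)]
    boundaries: dict[str, Boundary] = {}
    for ch in channels:
        metrics = list(spec.metrics_of(ch))
        th = select_typical(healthy_pop, ch, config.n_typical, spec,
                            class_label="healthy_like", prescale=config.l1_prescale)
        tp = select_typical(progeria_pop, ch, config.n_typical, spec,
                            class_label="progeria_like", prescale=config.l1_prescale)
        core_h = healthy_pop.loc[th.cell_indices]
        core_p = progeria_pop.loc[tp.cell_indices]
        norm = fit_normalization(core_h, core_p, metrics)
        bnd = train_boundary(core_h, core_p, norm, c_param=config.svm_c, channel=ch)
        bnd.provenance = {"plate": plate, "n_typical": config.n_typical}
        boundaries[ch] = bnd
        log.info(
            "plate %s channel %s: boundary trained on %d + %d typical cells",
            plate, ch, len(core_h), len(core_p),
        )
    return boundaries


def score_screen(
    features: pd.DataFrame, platemap: PlateMap, config: RunConfig
) -> ScreenResult:
    """Score every well of every plate in every channel.

    Boundaries are trained per replicate plate (typical selection is carried
    out independently on each plate's pooled controls); each well's
    healthy-like percentage is computed per plate with that plate's
    boundary.
    """
    spec = config.channel_spec
    plates = sorted(features["plate"].unique())
    boundaries = {}
    rows = []
    for plate in plates:
        plate_bnds = train_plate_boundaries(features, platemap, config, plate)
        sub = features[features["plate"] == plate]
        well_codes, well_index = pd.factorize(sub["well"])
        for ch, bnd in plate_bnds.items():
            boundaries[(plate, ch)] = bnd
            healthy = bnd.signed_distances(sub) > 0
            counts = np.bincount(well_codes, minlength=len(well_index))
            pos = np.bincount(well_codes, weights=healthy, minlength=len(well_index))
            for w, n, p in zip(well_index, counts, pos):
                entry = platemap.entries.get((plate, w))
                if entry is None:
                    continue
                rows.append(
                    {
                        "channel": ch,
                        "plate": plate,
                        "well": w,
                        "role": entry.role,
                        "sirna_name": entry.sirna_name or "",
                        "pct_healthy": 100.0 * p / n if n else np.nan,
                        "n_cells": int(n),
                    }
                )
    scores = pd.DataFrame(rows)
    empty = scores["n_cells"] == 0
    if empty.any():
        log.warning("%d well x plate scores had no cells and were flagged", empty.sum())
    sample_scores = {
        ch: _aggregate_channel(scores[scores["channel"] == ch])
        for ch in spec.channel_names
    }
    return ScreenResult(scores=scores, boundaries=boundaries, sample_scores=sample_scores)


def _aggregate_channel(ch_scores: pd.DataFrame) -> list[SampleScore]:
    out = []
    for (well, role, sirna), grp in ch_scores.groupby(
        ["well", "role", "sirna_name"], sort=True
    ):
        ok = grp["n_cells"] > 0
        if not ok.all():
            log.warning("sample %s: %d empty replicate(s) dropped", well, (~ok).sum())
        grp = grp[ok]
        if len(grp) == 0:
            continue
        out.append(
            SampleScore(
                sample_id=str(well),
                role=str(role),
                channel=str(grp["channel"].iloc[0]),
                replicate_percentages=list(grp["pct_healthy"]),
                n_cells=list(grp["n_cells"]),
                sirna_name=str(sirna) or None,
            )
        )
    return out


def run_screen(
    features: pd.DataFrame, platemap: PlateMap, config: RunConfig
) -> ScreenResult:
    """Full screen analysis: score all samples, then call hits per channel."""
    result = score_screen(features, platemap, config)
    for ch, scores in result.sample_scores.items():
        expressing = [s for s in scores if s.role == ROLE_EXPRESSING]
        repressed = [s for s in scores if s.role == ROLE_REPRESSED]
        sirna = [s for s in scores if s.role not in (ROLE_EXPRESSING, ROLE_REPRESSED)]
        calls, lines = call_hits(sirna, expressing, repressed, config)
        result.hits[ch] = calls
        result.reference_lines[ch] = lines
        log.info(
            "channel %s: %d hits of %d samples (threshold %.2f%%)",
            ch, sum(c.is_hit for c in calls), len(calls), lines["hit_threshold"],
        )
    return result


def plot_screen(result: ScreenResult, channel: str, path) -> None:
    """Screen overview: per-sample mean % healthy-like with replicate error
    bars and the control-derived threshold lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = result.sample_scores[channel]
    order = {ROLE_REPRESSED: 0, ROLE_EXPRESSING: 1}
    scores = sorted(scores, key=lambda s: (order.get(s.role, 2), s.sample_id))
    colors = {ROLE_REPRESSED: "green", ROLE_EXPRESSING: "red"}
    xs = np.arange(len(scores))
    fig, ax = plt.subplots(figsize=(10, 4))
    for i, s in enumerate(scores):
        sd = s.sd_percentage
        ax.errorbar(
            i, s.mean_percentage, yerr=None if np.isnan(sd) else sd,
            fmt="o", ms=3, color=colors.get(s.role, "steelblue"), alpha=0.7,
        )
    lines = result.reference_lines.get(channel, {})
    if "hit_threshold" in lines:
        ax.axhline(lines["hit_threshold"], color="red", lw=1,
                   label="hit threshold (mean + 5 SD of expressing controls)")
    if "repressed_line" in lines:
        ax.axhline(lines["repressed_line"], color="green", ls="--", lw=1,
                   label="repressed-control lower line")
    ax.set_xlabel("sample")
    ax.set_ylabel("% healthy-like cells")
    ax.set_title(f"channel: {channel}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
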