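"""Domain types and plain-text I/O for screen feature tables and plate maps.

The pipeline's canonical in-memory container is a tidy :class:`pandas.DataFrame`
with one row per segmented nucleus: the identifier columns
``plate, replicate, well, field, cell_id`` followed by one column per metric.
:class:`CellRecord` is the record-level view of a single row; converters between
the two representations are lossless.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("nucscreen")

ID_COLUMNS = ("plate", "replicate", "well", "field", "cell_id")

ROLE_EXPRESSING = "expressing_control"
ROLE_REPRESSED = "repressed_control"
ROLE_SIRNA = "sirna"
VALID_ROLES = (ROLE_EXPRESSING, ROLE_REPRESSED, ROLE_SIRNA)

#: The twelve nuclear-shape metrics, computed on the DAPI-derived contour.
SHAPE_METRICS = (
    "Area",
    "Circularity",
    "Eccentricity",
    "Invaginations",
    "Major Axis Length",
    "Mean Curvature",
    "Mean Negative Curvature",
    "Minor Axis Length",
    "Perimeter",
    "Solidity",
    "Std of Curvature",
    "Tortuosity",
)

#: The three per-channel intensity metrics, computed inside the DAPI mask.
INTENSITY_METRICS = ("BP Intensity", "Mean Intensity", "Std of Intensity")


class SchemaError(ValueError):
    """A table does not conform to the expected column schema."""


class PlateMapError(ValueError):
    """A plate map is malformed (unknown role, duplicate well, bad design)."""


class ContractError(ValueError):
    """An operation was called with arguments violating its precondition."""


@dataclass(frozen=True)
class ChannelSpec:
    """Assignment of metric names to fluorescence channels.

    Each metric belongs to exactly one channel; the per-channel lists are
    ordered and non-empty.  The default design mirrors a four-channel
    progeria screen: DAPI carries the twelve shape metrics, the lamin B1,
    progerin and γH2AX channels carry three intensity metrics each.
    """

    channels: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for ch, metrics in self.channels.items():
            if len(metrics) == 0:
                raise ValueError(f"channel {ch!r} has an empty metric list")
            for m in metrics:
                if m in seen:
                    raise ValueError(
                        f"metric {m!r} assigned to both {seen[m]!r} and {ch!r}"
                    )
                seen[m] = ch

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def metric_names(self) -> tuple[str, ...]:
        """All metric names, in channel order then per-channel order."""
        return tuple(m for ms in self.channels.values() for m in ms)

    def metrics_of(self, channel: str) -> tuple[str, ...]:
        try:
            return self.channels[channel]
        except KeyError:
            raise KeyError(f"unknown channel {channel!r}") from None

    def channel_of(self, metric: str) -> str:
        for ch, metrics in self.channels.items():
            if metric in metrics:
                return ch
        raise KeyError(f"metric {metric!r} not in any channel")


def default_channel_spec() -> ChannelSpec:
    """Four-channel spec: DAPI shape metrics + three intensity channels."""
    channels: dict[str, tuple[str, ...]] = {"dapi": SHAPE_METRICS}
    for ch in ("lamin_b1", "progerin", "gh2ax"):
        channels[ch] = tuple(f"{ch} {m}" for m in INTENSITY_METRICS)
    return ChannelSpec(channels)


@dataclass
class CellRecord:
    """One segmented nucleus: identifiers plus its named metric values."""

    plate: str
    replicate: int
    well: str
    field: int
    cell_id: int
    features: dict[str, float]
    channel_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        for name, value in self.features.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite value for metric {name!r}")
            if name not in self.channel_of:
                raise ValueError(f"metric {name!r} has no channel assignment")


@dataclass(frozen=True)
class WellEntry:
    role: str
    sirna_name: str | None = None

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise PlateMapError(
                f"unknown role {self.role!r}; must be one of {VALID_ROLES}"
            )


@dataclass
class PlateMap:
    """Mapping (plate, well) -> experimental role of that well."""

    entries: dict[tuple[str, str], WellEntry] = field(default_factory=dict)

    def add(self, plate: str, well: str, entry: WellEntry) -> None:
        key = (plate, well)
        if key in self.entries:
            raise PlateMapError(f"duplicate plate map entry for {key}")
        self.entries[key] = entry

    def role_of(self, plate: str, well: str) -> WellEntry:
        return self.entries[(plate, well)]

    def plates(self) -> list[str]:
        return sorted({p for p, _ in self.entries})

    def wells_with_role(self, role: str, plate: str | None = None) -> list[tuple[str, str]]:
        return sorted(
            key
            for key, e in self.entries.items()
            if e.role == role and (plate is None or key[0] == plate)
        )

    def validate_screen_design(
        self, n_expressing: int = 12, n_repressed: int = 12
    ) -> None:
        """Check the per-plate control layout (default 12 + 12 control wells)."""
        for plate in self.plates():
            ne = len(self.wells_with_role(ROLE_EXPRESSING, plate))
            nr = len(self.wells_with_role(ROLE_REPRESSED, plate))
            if ne != n_expressing or nr != n_repressed:
                raise PlateMapError(
                    f"plate {plate!r}: expected {n_expressing} expressing and "
                    f"{n_repressed} repressed control wells, found {ne} and {nr}"
                )


@dataclass
class RunConfig:
    """Tunable constants of the pipeline.

    Defaults follow the screen design the pipeline was built around:
    a reference core of 300 typical cells per class, 200 bootstrap
    resamplings for boundary-stability analysis, a hit threshold 5 control
    standard deviations above the expressing-control mean, a replicate-based
    false-positive-rate cut-off of 0.05, and exclusion of wells whose cell
    count drops below 50% of the repressed-control count.
    """

    n_typical: int = 300
    n_bootstrap: int = 200
    hit_sd_multiplier: float = 5.0
    fpr_threshold: float = 0.05
    cytotoxicity_fraction: float = 0.5
    random_seed: int = 0
    svm_c: float = 1.0
    l1_prescale: bool = True
    channel_spec: ChannelSpec = field(default_factory=default_channel_spec)

    def __post_init__(self) -> None:
        if self.n_typical < 2:
            raise ValueError("n_typical must be >= 2")
        for name in ("n_bootstrap", "hit_sd_multiplier", "fpr_threshold",
                     "cytotoxicity_fraction", "svm_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["channel_spec"] = {c: list(m) for c, m in self.channel_spec.channels.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "channel_spec" in d:
            d["channel_spec"] = ChannelSpec(
                {c: tuple(m) for c, m in d["channel_spec"].items()}
            )
        return cls(**d)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def validate_feature_frame(df: pd.DataFrame, channel_spec: ChannelSpec) -> None:
    """Validate a feature frame against the schema and the channel spec."""
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    for metric in channel_spec.metric_names:
        if metric not in df.columns:
            raise SchemaError(f"missing required column {metric!r}")
    extra = set(df.columns) - set(ID_COLUMNS) - set(channel_spec.metric_names)
    if extra:
        raise SchemaError(f"unknown metric columns not in channel spec: {sorted(extra)}")
    for metric in channel_spec.metric_names:
        col = df[metric]
        if not pd.api.types.is_numeric_dtype(col):
            coerced = pd.to_numeric(col, errors="coerce")
            bad = int(np.nonzero(coerced.isna().to_numpy() & col.notna().to_numpy())[0][0])
            raise SchemaError(
                f"non-numeric value in column {metric!r} at row {bad}: {col.iloc[bad]!r}"
            )
        if not np.isfinite(col.to_numpy(dtype=float)).all():
            bad = int(np.nonzero(~np.isfinite(col.to_numpy(dtype=float)))[0][0])
            raise SchemaError(f"non-finite value in column {metric!r} at row {bad}")


def read_feature_frame(path: str | Path, channel_spec: ChannelSpec) -> pd.DataFrame:
    """Read a feature-table CSV into the canonical tidy frame (row order kept)."""
    df = pd.read_csv(path)
    validate_feature_frame(df, channel_spec)
    log.info("read %d cells from %s", len(df), path)
    return df


def write_feature_frame(df: pd.DataFrame, path: str | Path) -> None:
    cols = list(ID_COLUMNS) + [c for c in df.columns if c not in ID_COLUMNS]
    df.to_csv(path, index=False, columns=cols)
    log.info("wrote %d cells to %s", len(df), path)


def frame_to_records(df: pd.DataFrame, channel_spec: ChannelSpec) -> list[CellRecord]:
    metrics = channel_spec.metric_names
    channel_of = {m: channel_spec.channel_of(m) for m in metrics}
    records = []
    for row in df.itertuples(index=False, name=None):
        vals = dict(zip(df.columns, row))
        records.append(
            CellRecord(
                plate=str(vals["plate"]),
                replicate=int(vals["replicate"]),
                well=str(vals["well"]),
                field=int(vals["field"]),
                cell_id=int(vals["cell_id"]),
                features={m: float(vals[m]) for m in metrics},
                channel_of=channel_of,
            )
        )
    return records


def records_to_frame(records: Iterable[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "plate": r.plate,
            "replicate": r.replicate,
            "well": r.well,
            "field": r.field,
            "cell_id": r.cell_id,
        }
        row.update(r.features)
        rows.append(row)
    return pd.DataFrame(rows)


def read_feature_table(path: str | Path, channel_spec: ChannelSpec) -> list[CellRecord]:
    """Read a feature-table CSV as a list of :class:`CellRecord`."""
    return frame_to_records(read_feature_frame(path, channel_spec), channel_spec)


def write_feature_table(
    records: Iterable[CellRecord] | pd.DataFrame, path: str | Path
) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    write_feature_frame(df, path)


# ---------------------------------------------------------------------------
# plate maps
# ---------------------------------------------------------------------------

def read_plate_map(path: str | Path) -> PlateMap:
    """Read a plate-map CSV with columns plate,well,role[,sirna_name]."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("plate", "well", "role"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    pm = PlateMap()
    for i, row in df.iterrows():
        name = row.get("sirna_name", "") or None
        try:
            entry = WellEntry(role=row["role"], sirna_name=name)
        except PlateMapError as e:
            raise PlateMapError(f"row {i}: {e}") from None
        pm.add(row["plate"], row["well"], entry)
    return pm


def write_plate_map(pm: PlateMap, path: str | Path) -> None:
    rows = [
        {"plate": p, "well": w, "role": e.role, "sirna_name": e.sirna_name or ""}
        for (p, w), e in sorted(pm.entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def well_name(row: int, col: int) -> str:
    """384-well name from 0-based row/column indices, e.g. (1, 2) -> 'B03'."""
    return f"{chr(ord('A') + row)}{col + 1:02d}"
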