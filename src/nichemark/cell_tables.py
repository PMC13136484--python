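"""Per-cell quantification tables and observation windows.

The spatial analyses in this package consume tables exported from image
quantification software: one row per segmented nucleus, holding the cell's
apical-plane coordinates (μm), its nuclear volume (μm³), one column per
numeric mark channel (intensity sums, concentrations, apical areas,
transcript-dot counts, ...) and one column per binary flag (proliferation
status, reporter positivity, ...).  Each imaging field / hemisphere is an
independent sample identified by ``sample_id``; samples are segmented and
analyzed separately and only summary curves are ever pooled.

The observation window is the axis-aligned rectangle used by the
translation edge correction.  Imaging frames are rarely exported with the
table, so by default a per-sample window is derived from the data: the
bounding rectangle of the cells, expanded on every side by half the median
nearest-neighbour distance so that boundary cells do not sit exactly on
the window edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "CORE_COLUMNS",
    "CellRecord",
    "CellTable",
    "ObservationWindow",
    "read_cell_table",
    "write_cell_table",
    "project_to_apical_plane",
    "build_window",
    "build_windows",
    "median_nn_distance",
    "read_windows",
    "write_windows",
]

#: Mandatory columns of the on-disk cell-table format, in canonical order.
CORE_COLUMNS = ("cell_id", "sample_id", "x_um", "y_um", "volume_um3")

#: Optional depth coordinate, dropped by :func:`project_to_apical_plane`.
Z_COLUMN = "z_um"


@dataclass(frozen=True)
class ObservationWindow:
    """Axis-aligned rectangular observation window, in μm."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate window: [{self.x_min}, {self.x_max}] x "
                f"[{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "x_min": self.x_min,
            "x_max": self.x_max,
            "y_min": self.y_min,
            "y_max": self.y_max,
        }


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: identifier, position, volume, marks and flags."""

    cell_id: str
    sample_id: str
    x: float
    y: float
    volume: float
    z: float | None = None
    marks: Mapping[str, float] = field(default_factory=dict)
    flags: Mapping[str, bool] = field(default_factory=dict)


class CellTable:
    """Validated per-cell table, partitioned by ``sample_id``.

    Thin wrapper over a :class:`pandas.DataFrame` with the canonical
    columns of :data:`CORE_COLUMNS`, an optional ``z_um`` column, the mark
    channels named in ``mark_channels`` and the binary flag channels named
    in ``flag_channels``.

    Parameters
    ----------
    data
        Frame holding at least the core columns plus the named channels.
    mark_channels
        Names of the numeric mark columns.
    flag_channels
        Names of the binary (0/1) flag columns.
    count_channels
        Subset of ``mark_channels`` holding non-negative integer counts
        (transcript dots); validated as such.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        mark_channels: Sequence[str] = (),
        flag_channels: Sequence[str] = (),
        count_channels: Sequence[str] = (),
    ) -> None:
        self.mark_channels = tuple(mark_channels)
        self.flag_channels = tuple(flag_channels)
        self.count_channels = tuple(count_channels)
        self.data = data.reset_index(drop=True)
        self._validate()

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        df = self.data
        for col in CORE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing mandatory column: {col!r}")
        for col in self.mark_channels + self.flag_channels:
            if col not in df.columns:
                raise ValueError(f"missing channel column: {col!r}")
        coord_cols = ["x_um", "y_um"] + (
            [Z_COLUMN] if Z_COLUMN in df.columns else []
        )
        for col in coord_cols + ["volume_um3"] + list(self.mark_channels):
            values = pd.to_numeric(df[col], errors="raise")
            df[col] = values.astype(float)
            if not np.all(np.isfinite(values)):
                bad = df.loc[~np.isfinite(values), "cell_id"].iloc[0]
                raise ValueError(f"non-finite {col!r} for cell {bad!r}")
        nonpos = df["volume_um3"] <= 0
        if nonpos.any():
            bad = df.loc[nonpos, "cell_id"].iloc[0]
            raise ValueError(f"non-positive nuclear volume for cell {bad!r}")
        for col in self.count_channels:
            vals = df[col].to_numpy(dtype=float)
            if np.any(vals < 0) or np.any(vals != np.round(vals)):
                raise ValueError(f"count channel {col!r} must be integer >= 0")
        dup = df.duplicated(subset=["sample_id", "cell_id"])
        if dup.any():
            bad = df.loc[dup, ["sample_id", "cell_id"]].iloc[0]
            raise ValueError(
                f"duplicate cell_id {bad['cell_id']!r} in sample "
                f"{bad['sample_id']!r}"
            )

    # -- basic accessors -----------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def samples(self) -> list[str]:
        """Distinct sample identifiers, in order of first appearance."""
        return list(dict.fromkeys(self.data["sample_id"]))

    @property
    def has_z(self) -> bool:
        return Z_COLUMN in self.data.columns

    def sample(self, sample_id: str) -> pd.DataFrame:
        sub = self.data[self.data["sample_id"] == sample_id]
        if sub.empty:
            raise KeyError(f"unknown sample_id: {sample_id!r}")
        return sub

    def positions(self, sample_id: str) -> np.ndarray:
        """(n, 2) array of apical-plane coordinates for one sample."""
        sub = self.sample(sample_id)
        return sub[["x_um", "y_um"]].to_numpy(dtype=float)

    def marks(self, sample_id: str, channel: str) -> np.ndarray:
        if channel not in self.mark_channels:
            raise KeyError(f"unknown mark channel: {channel!r}")
        return self.sample(sample_id)[channel].to_numpy(dtype=float)

    def records(self) -> Iterator[CellRecord]:
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield CellRecord(
                cell_id=str(d["cell_id"]),
                sample_id=str(d["sample_id"]),
                x=float(d["x_um"]),
                y=float(d["y_um"]),
                volume=float(d["volume_um3"]),
                z=float(d[Z_COLUMN]) if Z_COLUMN in d else None,
                marks={c: float(d[c]) for c in self.mark_channels},
                flags={c: bool(d[c]) for c in self.flag_channels},
            )

    def copy_with(self, data: pd.DataFrame) -> "CellTable":
        return CellTable(
            data,
            mark_channels=self.mark_channels,
            flag_channels=self.flag_channels,
            count_channels=self.count_channels,
        )


# -- I/O ---------------------------------------------------------------


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    mark_channels: Sequence[str] | None = None,
    flag_channels: Sequence[str] | None = None,
    count_channels: Sequence[str] = (),
) -> CellTable:
    """Read a CSV/TSV cell table into a validated :class:`CellTable`.

    Parameters
    ----------
    path
        CSV (comma) or TSV (tab, chosen by ``.tsv`` suffix) file with a
        mandatory header row, UTF-8, ``.`` decimal separator.
    schema
        Optional mapping from file column names to canonical names
        (``cell_id``, ``sample_id``, ``x_um``, ``y_um``, ``z_um``,
        ``volume_um3`` or any channel name).
    mark_channels, flag_channels
        Explicit channel lists.  When omitted, every non-core column whose
        values are all in {0, 1} is treated as a flag and every other
        non-core numeric column as a mark.
    count_channels
        Mark channels validated as non-negative integers.

    Unparseable numeric fields raise rather than being dropped; missing
    values in a channel used by an analysis are rejected at validation
    time.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")
    if schema:
        df = df.rename(columns=dict(schema))
    for col in ("cell_id", "sample_id"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    extra = [c for c in df.columns if c not in CORE_COLUMNS and c != Z_COLUMN]
    if mark_channels is None and flag_channels is None:
        flag_channels = [
            c
            for c in extra
            if df[c].notna().all() and set(np.unique(df[c])) <= {0, 1}
        ]
        mark_channels = [c for c in extra if c not in flag_channels]
    elif mark_channels is None:
        mark_channels = [c for c in extra if c not in (flag_channels or ())]
    elif flag_channels is None:
        flag_channels = [c for c in extra if c not in mark_channels]
    return CellTable(
        df,
        mark_channels=mark_channels,
        flag_channels=flag_channels,
        count_channels=count_channels,
    )


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a cell table back to CSV/TSV (inverse of :func:`read_cell_table`)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cols = [c for c in CORE_COLUMNS]
    if table.has_z:
        cols.insert(4, Z_COLUMN)
    cols += list(table.mark_channels) + list(table.flag_channels)
    # shortest round-trip float representation keeps numeric fields bit-exact
    table.data[cols].to_csv(
        path, sep=sep, index=False, float_format=lambda v: repr(float(v))
    )


def read_windows(path: str | Path) -> dict[str, ObservationWindow]:
    """Read the per-sample window sidecar (JSON: sample_id -> rectangle)."""
    with open(path) as fh:
        raw = json.load(fh)
    return {sid: ObservationWindow(**rect) for sid, rect in raw.items()}


def write_windows(windows: Mapping[str, ObservationWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({sid: w.to_dict() for sid, w in windows.items()}, fh, indent=1)
        fh.write("\n")


# -- geometry ----------------------------------------------------------


def project_to_apical_plane(table: CellTable) -> CellTable:
    """Drop the depth coordinate, keeping apical-plane (x, y) positions.

    Nuclear centers are assimilated to their projection onto the apical
    plane; idempotent when no ``z_um`` column is present.
    """
    if not table.has_z:
        return table
    return table.copy_with(table.data.drop(columns=[Z_COLUMN]))


def median_nn_distance(positions: np.ndarray) -> float:
    """Median nearest-neighbour distance of a point set (n >= 2)."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        raise ValueError("need at least 2 points")
    d = pdist(positions)
    n = len(positions)
    square = np.full((n, n), np.inf)
    iu = np.triu_indices(n, k=1)
    square[iu] = d
    square.T[iu] = d
    return float(np.median(square.min(axis=1)))


def build_window(
    table: CellTable,
    sample_id: str,
    margin: float | str = "half_median_nn",
) -> ObservationWindow:
    """Derive a rectangular observation window for one sample.

    The window is the axis-aligned bounding rectangle of the sample's
    cells, expanded on each side by ``margin`` (a length in μm, or the
    default policy ``"half_median_nn"`` = half the median nearest-
    neighbour distance).  Raises for degenerate samples whose points are
    collinear with an axis.
    """
    pos = table.positions(sample_id)
    if len(pos) < 2:
        raise ValueError(f"sample {sample_id!r} has fewer than 2 cells")
    x, y = pos[:, 0], pos[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"degenerate sample {sample_id!r}: zero extent")
    if margin == "half_median_nn":
        m = 0.5 * median_nn_distance(pos)
    else:
        m = float(margin)
        if m < 0:
            raise ValueError("margin must be >= 0")
    return ObservationWindow(
        x_min=float(x.min() - m),
        x_max=float(x.max() + m),
        y_min=float(y.min() - m),
        y_max=float(y.max() + m),
    )


def build_windows(
    table: CellTable, margin: float | str = "half_median_nn"
) -> dict[str, ObservationWindow]:
    """Per-sample windows for every sample of the table."""
    return {sid: build_window(table, sid, margin) for sid in table.samples}
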