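"""Nuclear lineage track tables.

The lingua franca between the simulator, the synthetic fixtures, and the
metrics: one row per nucleus per frame, with binary-tree lineage links.
Frames are sampled at a fixed interval (default 1.5 min, matching 90-s
lightsheet acquisition).

Schema (CSV header, exactly)::

    nucleus_id,parent_id,frame,t_min,x_um,y_um,z_um

``parent_id`` is empty for root nuclei.  Root nuclei are *censored*: their
birth was not observed (imaging typically begins mid-cycle), so their
first-frame time is an observation start, not a birth, and they are
excluded from cycle-length statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

TRACK_COLUMNS = ["nucleus_id", "parent_id", "frame", "t_min", "x_um", "y_um", "z_um"]
POSITION_COLUMNS = ["x_um", "y_um", "z_um"]
DEFAULT_FRAME_INTERVAL_MIN = 1.5


@dataclass
class TrackTable:
    """Validated per-nucleus, per-frame positions with lineage links."""

    df: pd.DataFrame
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        df = df[TRACK_COLUMNS].copy()
        df["nucleus_id"] = df["nucleus_id"].astype(np.int64)
        df["parent_id"] = df["parent_id"].astype("Int64")
        df["frame"] = df["frame"].astype(np.int64)
        for c in ("t_min", *POSITION_COLUMNS):
            df[c] = df[c].astype(float)
        df = df.sort_values(["nucleus_id", "frame"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        dup = df.duplicated(["nucleus_id", "frame"])
        if dup.any():
            ids = sorted(df.loc[dup, "nucleus_id"].unique().tolist())
            raise SchemaError(f"duplicate (nucleus_id, frame) records for nuclei {ids}")
        if (df["frame"] < 0).any():
            raise SchemaError("negative frame numbers")
        g = df.groupby("nucleus_id")["frame"]
        contiguous = g.apply(lambda s: bool((np.diff(s.to_numpy()) == 1).all()) if len(s) > 1 else True)
        if not contiguous.all():
            ids = sorted(contiguous.index[~contiguous].tolist())
            raise SchemaError(f"non-contiguous frame ranges for nuclei {ids}")
        first = g.min()
        last = g.max()
        parents = df.groupby("nucleus_id")["parent_id"].first()
        has_parent = parents.notna()
        orphan = has_parent & ~parents[has_parent].isin(first.index).reindex(parents.index, fill_value=False)
        if orphan.any():
            ids = sorted(orphan.index[orphan].tolist())
            raise SchemaError(f"orphan parent_id for nuclei {ids}")
        children = parents[has_parent].astype(np.int64)
        n_children = children.groupby(children).size()
        bad = n_children[n_children != 2]
        if len(bad):
            raise SchemaError(
                f"lineage must be a binary forest (0 or 2 children); offending parents {sorted(bad.index.tolist())}"
            )
        link = pd.DataFrame({"daughter": children.index, "parent": children.to_numpy()})
        link["first_d"] = first.loc[link["daughter"]].to_numpy()
        link["last_p"] = last.loc[link["parent"]].to_numpy()
        broken = link[link["first_d"] != link["last_p"] + 1]
        if len(broken):
            raise SchemaError(
                "daughters' first frame must immediately follow the parent's last frame; "
                f"offending daughters {sorted(broken['daughter'].tolist())}"
            )

    # -- convenience --------------------------------------------------------
    @property
    def n_nuclei(self) -> int:
        return self.df["nucleus_id"].nunique()

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.df["frame"].unique())

    def positions_at(self, frame: int) -> pd.DataFrame:
        """Rows at a frame, indexed by nucleus_id."""
        sub = self.df[self.df["frame"] == frame]
        return sub.set_index("nucleus_id")[POSITION_COLUMNS + ["t_min"]]

    def counts_per_frame(self) -> pd.Series:
        return self.df.groupby("frame")["nucleus_id"].size()

    def roots(self) -> np.ndarray:
        p = self.df.groupby("nucleus_id")["parent_id"].first()
        return p.index[p.isna()].to_numpy()

    def summary(self) -> dict:
        df = self.df
        return {
            "n_nuclei": int(self.n_nuclei),
            "n_records": int(len(df)),
            "n_frames": int(df["frame"].nunique()),
            "t_min_range": [float(df["t_min"].min()), float(df["t_min"].max())],
            "n_divisions": int(len(division_events(self))),
            "frame_interval_min": float(self.frame_interval_min),
        }


@dataclass(frozen=True)
class DivisionEvent:
    """One internal node of the lineage tree."""

    parent_id: int
    daughter_ids: tuple[int, int]
    t_min: float  # time of the daughters' first frame
    position: tuple[float, float, float]  # parent's last recorded position


def read_tracks(path, frame_interval_min: float | None = None) -> TrackTable:
    """Read a track CSV, validate the schema, and infer the frame interval.

    The interval is inferred from consecutive in-track time stamps unless
    given explicitly.
    """
    df = pd.read_csv(path, dtype={"parent_id": "Int64"})
    if frame_interval_min is None:
        dt = df.sort_values(["nucleus_id", "frame"]).groupby("nucleus_id")["t_min"].diff().dropna()
        frame_interval_min = float(dt.median()) if len(dt) else DEFAULT_FRAME_INTERVAL_MIN
    return TrackTable(df, frame_interval_min=frame_interval_min)


def write_tracks(table: TrackTable, path) -> None:
    """Write the track CSV (positions at 0.001-um precision)."""
    out = table.df.copy()
    for c in POSITION_COLUMNS:
        out[c] = out[c].round(3)
    out["t_min"] = out["t_min"].round(3)
    out.to_csv(path, index=False)


def division_events(table: TrackTable) -> list[DivisionEvent]:
    """One event per internal lineage node, sorted by time."""
    df = table.df
    parents = df.groupby("nucleus_id")["parent_id"].first()
    kids = parents.dropna().astype(np.int64)
    events = []
    last_rows = df.loc[df.groupby("nucleus_id")["frame"].idxmax()].set_index("nucleus_id")
    first_t = df.groupby("nucleus_id")["t_min"].min()
    by_parent = pd.Series(kids.index, index=kids.to_numpy()).groupby(level=0).apply(list)
    for parent, daughters in by_parent.items():
        daughters = tuple(sorted(int(d) for d in daughters))
        row = last_rows.loc[parent]
        events.append(
            DivisionEvent(
                parent_id=int(parent),
                daughter_ids=daughters,
                t_min=float(first_t[daughters[0]]),
                position=(float(row["x_um"]), float(row["y_um"]), float(row["z_um"])),
            )
        )
    events.sort(key=lambda e: (e.t_min, e.parent_id))
    return events


def time_since_division(table: TrackTable) -> pd.DataFrame:
    """Minutes since birth for every record.

    Birth is a nucleus's first frame.  For root nuclei the reference is the
    start of observation and the rows are flagged ``censored``.
    """
    df = table.df
    birth_t = df.groupby("nucleus_id")["t_min"].transform("min")
    parents = df.groupby("nucleus_id")["parent_id"].transform("first")
    return pd.DataFrame(
        {
            "nucleus_id": df["nucleus_id"],
            "frame": df["frame"],
            "t_since_division_min": df["t_min"] - birth_t,
            "censored": parents.isna().to_numpy(),
        }
    )
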