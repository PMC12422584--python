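"""Track containers: the atom of all cell-migration analysis.

A :class:`Track` is one cell's time-ordered sequence of detections
(frame index, time in seconds, x/y position in micrometres). Missing
detections — frames where the tracker lost the cell — are encoded as absent
samples, never as NaN rows, so gaps are visible as jumps in the frame index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["cell_id", "frame", "t_seconds", "x_um", "y_um"]


@dataclass
class Track:
    """One cell's trajectory.

    Parameters
    ----------
    cell_id : str or int
        Identifier of the tracked cell.
    frame : ndarray of int
        Frame indices, strictly increasing. Gaps (lost tracking) appear as
        jumps larger than 1.
    t : ndarray of float
        Acquisition time of each detection, seconds.
    x, y : ndarray of float
        Position, micrometres.
    """

    cell_id: object
    frame: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frame)
        if not (len(self.t) == len(self.x) == len(self.y) == n):
            raise ValueError(f"track {self.cell_id!r}: ragged sample arrays")
        if n == 0:
            raise ValueError(f"track {self.cell_id!r}: empty track")
        if np.any(np.diff(self.frame) <= 0):
            raise ValueError(f"track {self.cell_id!r}: frames not strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"track {self.cell_id!r}: non-finite positions")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of x/y positions in µm."""
        return np.column_stack([self.x, self.y])

    @property
    def duration(self) -> float:
        """Elapsed time between first and last detection, seconds."""
        return float(self.t[-1] - self.t[0])

    def path_length(self) -> float:
        """Total path length summed over adjacent detections, µm."""
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    def step_lengths(self) -> np.ndarray:
        """Euclidean displacement between adjacent detections, µm."""
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def max_gap(self) -> int:
        """Largest number of consecutive missing frames (0 if none)."""
        if len(self.frame) < 2:
            return 0
        return int(np.max(np.diff(self.frame)) - 1)


@dataclass
class TrackSet:
    """An ordered collection of tracks from one field of view / well."""

    tracks: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def __getitem__(self, i):
        return self.tracks[i]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long-format table with one row per detection."""
        parts = [
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "frame": tr.frame,
                    "t_seconds": tr.t,
                    "x_um": tr.x,
                    "y_um": tr.y,
                }
            )
            for tr in self.tracks
        ]
        if not parts:
            return pd.DataFrame(columns=TRACK_COLUMNS)
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrackSet":
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df.sort_values(["cell_id", "frame"], kind="stable")
        tracks = []
        for cid, grp in df.groupby("cell_id", sort=True):
            tracks.append(
                Track(
                    cell_id=cid,
                    frame=grp["frame"].to_numpy(),
                    t=grp["t_seconds"].to_numpy(),
                    x=grp["x_um"].to_numpy(),
                    y=grp["y_um"].to_numpy(),
                )
            )
        return cls(tracks)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrackSet) or len(self) != len(other):
            return NotImplemented if not isinstance(other, TrackSet) else False
        for a, b in zip(self.tracks, other.tracks):
            if a.cell_id != b.cell_id:
                return False
            if not (
                np.array_equal(a.frame, b.frame)
                and np.allclose(a.t, b.t)
                and np.allclose(a.x, b.x)
                and np.allclose(a.y, b.y)
            ):
                return False
        return True
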