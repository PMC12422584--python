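"""Track filtering and chemokinesis / chemotaxis quantification.

Implements the exclusion rules and summary statistics used to quantify cell
motility near a schistosome sporocyst and in plate-reader assays:

* spurious "floating cell" removal — reject tracks with any adjacent-frame
  step above a threshold (11.2 µm in the co-culture assay, 2.30 µm in the
  calcium assay) or tracking lost for more than 3 frames; gap filling is
  never performed;
* minimum track length (≥3 frames; ≥120 frames when scoring chemotaxis);
* annulus selection — cells 70–240 µm from the reference (prey) at their
  first detection: closer cells may already touch the prey via filopodia,
  farther cells sit near the field-of-view edge;
* chemokinesis window — step velocities pooled from cells 70–90 µm from the
  prey during the first 15 minutes, where the response is maximal;
* plate-reader mean velocity — per-cell average velocity over the
  subpopulation that migrated ≤60 µm total and was tracked ≥18 frames;
* distant cells — cells whose nearest neighbour is >60 µm away (beyond
  filopodial reach, so incapable of cell-cell contact);
* calcium-trace normalisation — per-cell initial-intensity subtraction,
  per-well averaging, mean ± SEM across wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tracks import Track, TrackSet

__all__ = [
    "FilterPolicy",
    "ReferencePoint",
    "filter_tracks",
    "step_velocities",
    "net_movement_toward",
    "chemokinesis_window",
    "mean_velocity",
    "distant_cells",
    "normalize_fluor",
    "SCHISTOSOME_POLICY",
    "CYTATION_POLICY",
    "FLUO4_POLICY",
]


@dataclass(frozen=True)
class ReferencePoint:
    """Location of the prey (schistosome centroid) in µm."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("reference point must be finite")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class FilterPolicy:
    """Named bundle of exclusion thresholds for one assay mode.

    ``None`` disables a rule. ``max_step`` applies to adjacent-frame pairs
    (frame difference exactly 1); ``max_gap`` is the largest tolerated run
    of consecutive missing frames; ``min_frames`` the minimum number of
    detections; the annulus bounds the distance from the reference at the
    track's first detection. ``max_total_path`` / ``min_frames_subpop``
    define the plate-reader "mean velocity" subpopulation, and
    ``min_frames_chemotaxis`` the extra duration cut applied only when the
    chemotaxis metric is requested.
    """

    max_step: float | None = None
    max_gap: int | None = None
    min_frames: int = 1
    annulus_min: float | None = None
    annulus_max: float | None = None
    max_total_path: float | None = None
    min_frames_subpop: int | None = None
    min_frames_chemotaxis: int | None = None

    def __post_init__(self) -> None:
        for name in ("max_step", "max_gap", "min_frames", "annulus_min",
                     "annulus_max", "max_total_path", "min_frames_subpop",
                     "min_frames_chemotaxis"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if (self.annulus_min is None) != (self.annulus_max is None):
            raise ValueError("annulus_min and annulus_max must be set together")
        if self.annulus_min is not None and self.annulus_min >= self.annulus_max:
            raise ValueError("annulus_min must be smaller than annulus_max")


#: Schistosome co-culture assay (Imaris tracking, 1 frame/min).
SCHISTOSOME_POLICY = FilterPolicy(
    max_step=11.2, max_gap=3, min_frames=3,
    annulus_min=70.0, annulus_max=240.0, min_frames_chemotaxis=120,
)

#: Plate-reader (Cytation/Gen5) chemokinesis assay: the spurious-reading
#: control is the ≤60 µm / ≥18 frame subpopulation itself.
CYTATION_POLICY = FilterPolicy(max_total_path=60.0, min_frames_subpop=18)

#: Fluo-4 calcium assay (Brownian tracking, 1 frame / 5 s).
FLUO4_POLICY = FilterPolicy(max_step=2.30, max_gap=3)


def _first_failing_rule(track: Track, policy: FilterPolicy,
                        ref: ReferencePoint | None,
                        chemotaxis: bool) -> str | None:
    """Name of the first violated rule, or None if the track passes.

    Rule order (fixed, so rejection counts are well defined): step filter,
    gap filter, minimum length, chemotaxis duration, annulus.
    """
    if policy.max_step is not None and len(track) >= 2:
        adjacent = np.diff(track.frame) == 1
        if np.any(track.step_lengths()[adjacent] > policy.max_step):
            return "max_step"
    if policy.max_gap is not None and track.max_gap() > policy.max_gap:
        return "max_gap"
    if len(track) < policy.min_frames:
        return "min_frames"
    if chemotaxis and policy.min_frames_chemotaxis is not None \
            and len(track) < policy.min_frames_chemotaxis:
        return "min_frames_chemotaxis"
    if policy.annulus_min is not None:
        r = float(np.hypot(track.x[0] - ref.x, track.y[0] - ref.y))
        if not policy.annulus_min <= r <= policy.annulus_max:
            return "annulus"
    return None


def filter_tracks(tracks: TrackSet, policy: FilterPolicy,
                  ref: ReferencePoint | None = None,
                  chemotaxis: bool = False):
    """Apply an exclusion policy; return (kept TrackSet, rejection counts).

    A track is rejected if ANY adjacent-frame step exceeds ``max_step``,
    ANY gap exceeds ``max_gap``, it is shorter than ``min_frames`` (or
    ``min_frames_chemotaxis`` when ``chemotaxis=True``), or — when a
    reference is given — its first detection lies outside the annulus.
    Each rejected track is counted under the first rule it violates; the
    counts plus ``kept`` sum to the input size. Gap filling is never
    performed.
    """
    if policy.annulus_min is not None and ref is None:
        raise ValueError("policy has an annulus but no reference point was given")
    counts = {"max_step": 0, "max_gap": 0, "min_frames": 0,
              "min_frames_chemotaxis": 0, "annulus": 0, "kept": 0}
    kept = []
    for tr in tracks:
        rule = _first_failing_rule(tr, policy, ref, chemotaxis)
        if rule is None:
            kept.append(tr)
            counts["kept"] += 1
        else:
            counts[rule] += 1
    return TrackSet(kept), counts


def step_velocities(track: Track) -> np.ndarray:
    """Instantaneous velocities (µm/min) over adjacent-frame pairs.

    Pairs spanning a tracking gap (frame difference > 1) are skipped rather
    than averaged over the elapsed time — the counterpart of disabling gap
    filling. A single-sample track yields an empty array.
    """
    if len(track) < 2:
        return np.empty(0)
    adjacent = np.diff(track.frame) == 1
    d = track.step_lengths()[adjacent]
    dt = np.diff(track.t)[adjacent]
    return d / dt * 60.0


def net_movement_toward(track: Track, ref: ReferencePoint) -> float:
    """Net approach toward the reference, µm (negative = moved away).

    Distance from the reference at the first detection minus the distance
    at the last detection; path shape in between does not matter.
    """
    d0 = np.hypot(track.x[0] - ref.x, track.y[0] - ref.y)
    d1 = np.hypot(track.x[-1] - ref.x, track.y[-1] - ref.y)
    return float(d0 - d1)


def chemokinesis_window(tracks: TrackSet, ref: ReferencePoint,
                        r_lo: float = 70.0, r_hi: float = 90.0,
                        t_max: float = 900.0) -> np.ndarray:
    """Pool step velocities from a radial band and early time window.

    Velocities (µm/min) are collected from adjacent-frame pairs whose
    starting sample lies ``r_lo``–``r_hi`` µm from the reference and starts
    before ``t_max`` seconds — by default the 70–90 µm band during the
    first 15 minutes, where the chemokinesis response is maximal. An empty
    selection returns an empty array with a warning, never a zero.
    """
    pooled = []
    for tr in tracks:
        if len(tr) < 2:
            continue
        adjacent = np.diff(tr.frame) == 1
        r = np.hypot(tr.x[:-1] - ref.x, tr.y[:-1] - ref.y)
        sel = adjacent & (r >= r_lo) & (r <= r_hi) & (tr.t[:-1] < t_max)
        if sel.any():
            v = tr.step_lengths()[sel] / np.diff(tr.t)[sel] * 60.0
            pooled.append(v)
    if not pooled:
        warnings.warn("chemokinesis window selected no steps", stacklevel=2)
        return np.empty(0)
    return np.concatenate(pooled)


def mean_velocity(tracks: TrackSet, policy: FilterPolicy,
                  path_mode: str = "total") -> float:
    """Plate-reader 'mean velocity': two-level average over a subpopulation.

    The subpopulation keeps cells that migrated at most
    ``policy.max_total_path`` µm (total path by default; ``path_mode='net'``
    uses net displacement instead) and were tracked for at least
    ``policy.min_frames_subpop`` frames. Each cell's step velocities are
    averaged, then averaged across cells. Returns NaN with a warning when
    the subpopulation is empty.
    """
    if policy.max_total_path is None or policy.min_frames_subpop is None:
        raise ValueError("policy must set max_total_path and min_frames_subpop")
    if path_mode not in ("total", "net"):
        raise ValueError("path_mode must be 'total' or 'net'")
    per_cell = []
    for tr in tracks:
        if len(tr) < policy.min_frames_subpop:
            continue
        if path_mode == "total":
            migrated = tr.path_length()
        else:
            migrated = float(np.hypot(tr.x[-1] - tr.x[0], tr.y[-1] - tr.y[0]))
        if migrated > policy.max_total_path:
            continue
        v = step_velocities(tr)
        if v.size:
            per_cell.append(v.mean())
    if not per_cell:
        warnings.warn("mean_velocity subpopulation is empty", stacklevel=2)
        return float("nan")
    return float(np.mean(per_cell))


def distant_cells(tracks: TrackSet, radius: float = 60.0,
                  mode: str = "first_frame") -> TrackSet:
    """Cells farther than ``radius`` from every other cell.

    ``mode='first_frame'`` (default) measures nearest-neighbour distances
    at each track's first detection. ``mode='all_frames'`` is the strict
    variant: the separation must exceed ``radius`` at every frame where
    both cells are detected. The 60 µm default is a conservative bound on
    twice the filopodial reach (~24 µm), so distant cells cannot touch.
    """
    if mode not in ("first_frame", "all_frames"):
        raise ValueError("mode must be 'first_frame' or 'all_frames'")
    n = len(tracks)
    if n == 0:
        return TrackSet([])
    if n == 1:
        warnings.warn("single track is trivially distant", stacklevel=2)
        return TrackSet(list(tracks))

    if mode == "first_frame":
        p0 = np.array([[tr.x[0], tr.y[0]] for tr in tracks])
        d = np.hypot(p0[:, None, 0] - p0[None, :, 0],
                     p0[:, None, 1] - p0[None, :, 1])
        np.fill_diagonal(d, np.inf)
        keep = d.min(axis=1) > radius
        return TrackSet([tr for tr, k in zip(tracks, keep) if k])

    keep = np.ones(n, dtype=bool)
    frames = [dict(zip(tr.frame.tolist(), tr.positions)) for tr in tracks]
    for i in range(n):
        for j in range(i + 1, n):
            common = frames[i].keys() & frames[j].keys()
            for f in common:
                if np.hypot(*(frames[i][f] - frames[j][f])) <= radius:
                    keep[i] = keep[j] = False
                    break
    return TrackSet([tr for tr, k in zip(tracks, keep) if k])


def normalize_fluor(wells):
    """Normalise calcium traces and average within and across wells.

    ``wells`` is a sequence of (n_cells, n_frames) intensity arrays, one
    per well (a single array is treated as one well). Traces with missing
    frames (NaN) are removed — only complete tracks are analysed. Each
    remaining trace has its initial intensity subtracted, normalising every
    cell to zero at the first frame; traces are then averaged per frame
    within each well, and the per-well means averaged across wells.

    Returns ``(mean, sem, well_means)`` where ``mean`` and ``sem`` are
    per-frame arrays over wells (SEM is NaN for a single well) and
    ``well_means`` is the (n_wells, n_frames) matrix of per-well means.
    """
    if isinstance(wells, np.ndarray) and wells.ndim == 2:
        wells = [wells]
    well_means = []
    for w, traces in enumerate(wells):
        traces = np.asarray(traces, dtype=float)
        complete = ~np.isnan(traces).any(axis=1)
        traces = traces[complete]
        if traces.shape[0] == 0:
            raise ValueError(f"well {w}: no complete traces")
        normalized = traces - traces[:, :1]
        well_means.append(normalized.mean(axis=0))
    well_means = np.asarray(well_means)
    mean = well_means.mean(axis=0)
    if well_means.shape[0] > 1:
        sem = well_means.std(axis=0, ddof=1) / np.sqrt(well_means.shape[0])
    else:
        sem = np.full(well_means.shape[1], np.nan)
    return mean, sem, well_means
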