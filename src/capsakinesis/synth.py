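"""Synthetic data with known ground truth.

Three generators emulate the raw material of a chemokinesis study:

* :func:`generate_tracks` — persistent-random-walk cell tracks. Successive
  step directions differ by a symmetric truncated-normal turn angle (strong
  directional persistence); step lengths are either fixed (speed ×
  frame interval) or drawn from an exponential distribution, matching the
  filopodial step-length statistics of crawling *Capsaspora*. Tracking
  artifacts are injected on demand: spurious "floating-cell" jumps that
  exceed the step filter, and dropped detections (gaps).
* :func:`generate_dose_response` — mean-velocity readings over a dose grid
  following a saturating Hill curve with replicate noise.
* :func:`generate_fluorescence_traces` — per-cell calcium-indicator traces:
  a per-cell baseline plus a step transient when the stimulus is added.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import Track, TrackSet

#: Step filter used in the schistosome co-culture assay (µm per frame).
CHEMOTAXIS_STEP_THRESHOLD = 11.2

#: Injected artifact jumps are this multiple of the step threshold, so the
#: step filter catches every one of them by construction.
SPURIOUS_JUMP_FACTOR = 1.5


def truncated_normal(rng: np.random.Generator, sd: float, bound: float, size) -> np.ndarray:
    """Draw from a normal(0, sd) truncated to [-bound, bound].

    ``sd == 0`` degenerates to all zeros.
    """
    if sd == 0:
        return np.zeros(size)
    a, b = -bound / sd, bound / sd
    return stats.truncnorm.rvs(a, b, scale=sd, size=size, random_state=rng)


@dataclass
class TrackGenConfig:
    """Parameters of the persistent-random-walk track generator.

    Attributes
    ----------
    n_cells, n_frames : int
        Number of tracks and frames per track.
    frame_interval : float
        Seconds between frames.
    speed : float
        Nominal crawling speed, µm/min. When ``step_mean`` is None each
        frame's displacement is exactly ``speed * frame_interval``.
    turn_sd : float
        SD of the truncated-normal turn angle per frame, radians.
    turn_bound : float
        Symmetric truncation bound of the turn distribution, radians.
    step_mean : float or None
        If set, per-frame step lengths are exponential with this mean (µm)
        and ``speed`` is ignored for the step draw; the nominal speed is
        then ``step_mean / frame_interval``.
    drift_toward_ref : float
        Deterministic drift toward ``ref_point``, µm/min. 0 gives the pure
        chemokinesis (non-directional) case.
    ref_point : (float, float) or None
        Drift target; defaults to the arena centre.
    spurious_rate : float
        Per-frame probability of an artifact jump of length
        ``SPURIOUS_JUMP_FACTOR * CHEMOTAXIS_STEP_THRESHOLD`` µm.
    gap_rate : float
        Per-frame probability of a dropped detection.
    arena : (float, float)
        Width/height of the arena, µm; initial positions are uniform over
        it. Tracks may exit the arena (no reflection) — downstream analysis
        must tolerate that.
    seed : int
        RNG seed; identical config + seed gives bit-identical output.
    """

    n_cells: int = 100
    n_frames: int = 240
    frame_interval: float = 60.0
    speed: float = 1.0
    turn_sd: float = 0.3
    turn_bound: float = np.pi
    step_mean: float | None = None
    drift_toward_ref: float = 0.0
    ref_point: tuple | None = None
    spurious_rate: float = 0.0
    gap_rate: float = 0.0
    arena: tuple = (800.0, 800.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_frames <= 0:
            raise ValueError("n_cells and n_frames must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.step_mean is not None and self.step_mean <= 0:
            raise ValueError("step_mean must be positive when set")
        for name in ("spurious_rate", "gap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.turn_sd < 0 or self.turn_bound <= 0:
            raise ValueError("turn_sd must be >= 0 and turn_bound > 0")
        if self.arena[0] <= 0 or self.arena[1] <= 0:
            raise ValueError("arena dimensions must be positive")


def generate_tracks(cfg: TrackGenConfig) -> TrackSet:
    """Generate persistent-random-walk tracks with tracking artifacts.

    Returns a :class:`TrackSet` whose ``truth`` attribute records the
    injected ground truth: ``truth["artifact_cells"]`` is the set of
    cell_ids that received at least one spurious jump and
    ``truth["n_artifacts"]`` the total number of injected jumps.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_cells, cfg.n_frames
    dt_min = cfg.frame_interval / 60.0

    pos = np.empty((n, m, 2))
    pos[:, 0, 0] = rng.uniform(0, cfg.arena[0], n)
    pos[:, 0, 1] = rng.uniform(0, cfg.arena[1], n)
    heading = rng.uniform(-np.pi, np.pi, n)

    ref = np.asarray(cfg.ref_point if cfg.ref_point is not None else
                     (cfg.arena[0] / 2.0, cfg.arena[1] / 2.0), dtype=float)

    turns = truncated_normal(rng, cfg.turn_sd, cfg.turn_bound, (n, m - 1))
    if cfg.step_mean is not None:
        steps = rng.exponential(cfg.step_mean, (n, m - 1))
    else:
        steps = np.full((n, m - 1), cfg.speed * dt_min)

    spurious = rng.random((n, m - 1)) < cfg.spurious_rate
    spur_angle = rng.uniform(-np.pi, np.pi, (n, m - 1))
    jump_len = SPURIOUS_JUMP_FACTOR * CHEMOTAXIS_STEP_THRESHOLD

    for k in range(1, m):
        heading = heading + turns[:, k - 1]
        step = np.column_stack([steps[:, k - 1] * np.cos(heading),
                                steps[:, k - 1] * np.sin(heading)])
        p = pos[:, k - 1, :] + step
        if cfg.drift_toward_ref != 0.0:
            d = ref[None, :] - p
            dist = np.hypot(d[:, 0], d[:, 1])
            move = np.minimum(cfg.drift_toward_ref * dt_min, dist)
            nz = dist > 0
            p[nz] += d[nz] * (move[nz] / dist[nz])[:, None]
        jump = spurious[:, k - 1]
        if jump.any():
            a = spur_angle[jump, k - 1]
            p[jump, 0] += jump_len * np.cos(a)
            p[jump, 1] += jump_len * np.sin(a)
        pos[:, k, :] = p

    dropped = rng.random((n, m)) < cfg.gap_rate
    dropped[:, 0] = False  # keep the first detection so every track exists

    frames = np.arange(m)
    times = frames * cfg.frame_interval
    tracks = []
    artifact_cells = set()
    n_artifacts = 0
    width = len(str(n - 1))
    for i in range(n):
        cid = f"cell_{i:0{width}d}"
        keep = ~dropped[i]
        tracks.append(Track(cell_id=cid, frame=frames[keep], t=times[keep],
                            x=pos[i, keep, 0], y=pos[i, keep, 1]))
        if spurious[i].any():
            artifact_cells.add(cid)
            n_artifacts += int(spurious[i].sum())

    ts = TrackSet(tracks)
    ts.truth = {"artifact_cells": artifact_cells, "n_artifacts": n_artifacts,
                "ref_point": tuple(ref)}
    return ts


@dataclass
class DoseGenConfig:
    """Parameters of the saturating dose-response generator.

    ``velocity = v0 + (vmax - v0) * d**hill / (ec50**hill + d**hill) + noise``
    with independent normal noise per replicate reading.
    """

    doses: list = field(default_factory=lambda: [0.0, 0.1, 0.3, 1.0, 3.0, 10.0])
    v0: float = 1.0
    vmax: float = 3.0
    ec50: float = 1.0
    hill: float = 1.0
    noise_sd: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.doses) == 0:
            raise ValueError("dose list must not be empty")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.vmax < self.v0:
            raise ValueError("vmax must be >= v0")
        if self.hill <= 0:
            raise ValueError("hill must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def hill_velocity(dose, v0: float, vmax: float, ec50: float, hill: float):
    """Noise-free saturating response; vectorized over ``dose``."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d > 0, d**hill / (ec50**hill + d**hill), 0.0)
    return v0 + (vmax - v0) * frac


def generate_dose_response(cfg: DoseGenConfig) -> pd.DataFrame:
    """Dose-response table with columns (dose, velocity, replicate)."""
    rng = np.random.default_rng(cfg.seed)
    doses = np.repeat(np.asarray(cfg.doses, dtype=float), cfg.replicates)
    reps = np.tile(np.arange(cfg.replicates), len(cfg.doses))
    v = hill_velocity(doses, cfg.v0, cfg.vmax, cfg.ec50, cfg.hill)
    v = v + rng.normal(0.0, cfg.noise_sd, size=v.shape) if cfg.noise_sd > 0 else v
    return pd.DataFrame({"dose": doses, "velocity": v, "replicate": reps})


def generate_fluorescence_traces(
    n_cells: int,
    n_frames: int,
    baseline: float = 100.0,
    jump_time: float = 25.0,
    jump_height: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame_interval: float = 5.0,
    baseline_sd: float | None = None,
) -> np.ndarray:
    """Calcium-indicator traces: per-cell baseline + step transient + noise.

    Emulates a Fluo-4 assay read every ``frame_interval`` seconds where the
    stimulus is added at ``jump_time`` seconds after a baseline period. The
    per-cell resting intensity varies (``baseline_sd``, default 10% of
    ``baseline``); baseline subtraction downstream removes it.

    Returns an (n_cells, n_frames) array of raw intensities.
    """
    if n_cells <= 0 or n_frames <= 0:
        raise ValueError("n_cells and n_frames must be positive")
    if not 0 <= jump_time < n_frames * frame_interval:
        raise ValueError("jump_time must fall within the trace")
    rng = np.random.default_rng(seed)
    if baseline_sd is None:
        baseline_sd = 0.1 * baseline
    times = np.arange(n_frames) * frame_interval
    base = np.full(n_cells, baseline, dtype=float)
    if baseline_sd > 0:
        base += rng.normal(0.0, baseline_sd, n_cells)
    traces = np.broadcast_to(base[:, None], (n_cells, n_frames)).copy()
    traces[:, times >= jump_time] += jump_height
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, traces.shape)
    return traces
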