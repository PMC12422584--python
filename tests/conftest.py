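"""Shared fixtures: hand-built track sets with known filter outcomes."""

import numpy as np
import pytest

from capsakinesis.analysis import FilterPolicy, ReferencePoint
from capsakinesis.tracks import Track, TrackSet


def make_track(cell_id, xy, frames=None, frame_interval=60.0):
    """Build a track from a list of (x, y) positions, one per frame."""
    xy = np.asarray(xy, dtype=float)
    frames = np.arange(len(xy)) if frames is None else np.asarray(frames)
    return Track(cell_id=cell_id, frame=frames, t=frames * frame_interval,
                 x=xy[:, 0], y=xy[:, 1])


def straight(cell_id, start, step, n, frames=None):
    """Straight-line track: ``n`` detections advancing by ``step`` each."""
    start = np.asarray(start, dtype=float)
    step = np.asarray(step, dtype=float)
    xy = start + np.arange(n)[:, None] * step
    return make_track(cell_id, xy, frames=frames)


@pytest.fixture
def ref():
    return ReferencePoint(0.0, 0.0)


@pytest.fixture
def schisto_policy():
    return FilterPolicy(max_step=11.2, max_gap=3, min_frames=3,
                        annulus_min=70.0, annulus_max=240.0)


@pytest.fixture
def ten_track_fixture(schisto_policy):
    """Ten hand-built tracks spanning every exclusion rule.

    Returns (TrackSet, expected rejection counts, kept cell_ids). Rules are
    evaluated in the fixed order step → gap → length → annulus, and every
    expected count below was enumerated by hand from the constructions.
    """
    tracks = [
        # kept: 5 frames, 5 µm steps, starts 100 µm from origin
        straight("keep_a", (100, 0), (5, 0), 5),
        # kept: 3 frames (minimum), 5 µm steps, inside annulus
        straight("keep_b", (0, 80), (0, 5), 3),
        # kept: steps just below the 11.2 µm threshold
        straight("keep_c", (150, 0), (11.0, 0), 4),
        # rejected by step rule: one 12 µm jump
        make_track("step_x", [(100, 0), (105, 0), (117, 0), (122, 0)]),
        # rejected by step rule: diagonal 12.02 µm step
        make_track("step_y", [(90, 90), (95, 90), (103.5, 98.5), (108, 98.5)]),
        # rejected by gap rule: 4 missing frames (max tolerated is 3)
        straight("gap_x", (100, 0), (5, 0), 4, frames=[0, 1, 6, 7]),
        # gap of exactly 3 missing frames is tolerated -> kept
        straight("keep_d", (100, 0), (5, 0), 4, frames=[0, 1, 5, 6]),
        # rejected by length rule: 2 frames only
        straight("short_x", (100, 0), (5, 0), 2),
        # rejected by annulus: starts 50 µm from origin (< 70)
        straight("annulus_in", (50, 0), (5, 0), 5),
        # rejected by annulus: starts 300 µm from origin (> 240)
        straight("annulus_out", (300, 0), (5, 0), 5),
    ]
    expected_counts = {"max_step": 2, "max_gap": 1, "min_frames": 1,
                       "min_frames_chemotaxis": 0, "annulus": 2, "kept": 4}
    kept_ids = {"keep_a", "keep_b", "keep_c", "keep_d"}
    return TrackSet(tracks), expected_counts, kept_ids
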