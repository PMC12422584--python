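"""Track filtering and motility statistics against hand-computed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capsakinesis.analysis import (CYTATION_POLICY, FLUO4_POLICY,
                                   SCHISTOSOME_POLICY, FilterPolicy,
                                   ReferencePoint, chemokinesis_window,
                                   distant_cells, filter_tracks,
                                   mean_velocity, net_movement_toward,
                                   normalize_fluor, step_velocities)
from capsakinesis.synth import (TrackGenConfig, generate_fluorescence_traces,
                                generate_tracks)
from capsakinesis.tracks import Track, TrackSet

from conftest import make_track, straight


class TestFilterTracks:
    def test_hand_enumerated_fixture(self, ten_track_fixture, schisto_policy, ref):
        tracks, expected, kept_ids = ten_track_fixture
        kept, counts = filter_tracks(tracks, schisto_policy, ref)
        assert counts == expected
        assert {tr.cell_id for tr in kept} == kept_ids
        assert sum(counts.values()) == len(tracks)

    def test_step_threshold_is_strict(self, ref, schisto_policy):
        ok = straight("a", (100, 0), (11.0, 0), 3)
        too_fast = straight("b", (100, 0), (12.0, 0), 3)
        kept, counts = filter_tracks(TrackSet([ok, too_fast]),
                                     schisto_policy, ref)
        assert [tr.cell_id for tr in kept] == ["a"]
        assert counts["max_step"] == 1

    def test_idempotent(self, ten_track_fixture, schisto_policy, ref):
        tracks, _, _ = ten_track_fixture
        once, _ = filter_tracks(tracks, schisto_policy, ref)
        twice, counts = filter_tracks(once, schisto_policy, ref)
        assert [t.cell_id for t in twice] == [t.cell_id for t in once]
        assert counts["kept"] == len(once)

    def test_permutation_invariant_counts(self, ten_track_fixture,
                                          schisto_policy, ref):
        tracks, expected, kept_ids = ten_track_fixture
        rng = np.random.default_rng(0)
        perm = list(tracks)
        rng.shuffle(perm)
        kept, counts = filter_tracks(TrackSet(perm), schisto_policy, ref)
        assert counts == expected
        assert {tr.cell_id for tr in kept} == kept_ids

    def test_annulus_without_ref_errors(self, schisto_policy):
        with pytest.raises(ValueError, match="reference"):
            filter_tracks(TrackSet([straight("a", (100, 0), (1, 0), 3)]),
                          schisto_policy, None)

    def test_chemotaxis_duration_cut(self, ref):
        policy = FilterPolicy(min_frames=3, min_frames_chemotaxis=120,
                              annulus_min=70, annulus_max=240)
        short = straight("s", (100, 0), (0.5, 0), 60)
        long = straight("l", (100, 0), (0.5, 0), 120)
        kept_plain, _ = filter_tracks(TrackSet([short, long]), policy, ref)
        assert len(kept_plain) == 2
        kept_tax, counts = filter_tracks(TrackSet([short, long]), policy, ref,
                                         chemotaxis=True)
        assert [t.cell_id for t in kept_tax] == ["l"]
        assert counts["min_frames_chemotaxis"] == 1

    def test_generator_artifacts_fully_captured(self):
        cfg = TrackGenConfig(n_cells=200, n_frames=60, speed=1.0,
                             spurious_rate=0.02, seed=21)
        ts = generate_tracks(cfg)
        assert ts.truth["artifact_cells"]
        policy = FilterPolicy(max_step=11.2)
        kept, _ = filter_tracks(ts, policy)
        kept_ids = {tr.cell_id for tr in kept}
        # every track carrying an injected jump is removed (100% capture)
        assert not (kept_ids & ts.truth["artifact_cells"])
        # and nothing else is: clean 1 µm/min tracks never trip the filter
        assert kept_ids == {tr.cell_id for tr in ts} - ts.truth["artifact_cells"]


class TestStepVelocities:
    def test_stationary_zero(self):
        tr = make_track("a", [(5, 5)] * 4)
        assert np.allclose(step_velocities(tr), 0.0)

    def test_uniform_speed(self):
        tr = straight("a", (0, 0), (3, 0), 5)  # 3 µm per 60 s frame
        assert np.allclose(step_velocities(tr), 3.0)

    def test_gap_pairs_skipped(self):
        # 6 detections with one 2-frame gap -> 4 adjacent-frame velocities
        tr = straight("a", (0, 0), (2, 0), 6, frames=[0, 1, 2, 5, 6, 7])
        v = step_velocities(tr)
        assert len(v) == len(tr) - 2
        assert np.allclose(v, 2.0)

    def test_single_sample_empty(self):
        tr = make_track("a", [(0, 0)])
        assert step_velocities(tr).size == 0


class TestNetMovement:
    def test_stationary_zero(self, ref):
        assert net_movement_toward(make_track("a", [(50, 0)] * 3), ref) == 0.0

    def test_radial_approach_positive(self, ref):
        tr = make_track("a", [(100, 0), (75, 0), (50, 0)])
        assert net_movement_toward(tr, ref) == pytest.approx(50.0)

    def test_circular_path_zero(self, ref):
        theta = np.linspace(0, 1.5 * np.pi, 20)
        tr = make_track("a", np.column_stack([80 * np.cos(theta),
                                              80 * np.sin(theta)]))
        assert net_movement_toward(tr, ref) == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-np.pi, np.pi),
           st.integers(0, 2**31 - 1))
    def test_rotation_invariant_about_ref(self, angle, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(-100, 100, size=(6, 2))
        ref = ReferencePoint(10.0, -20.0)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        xy_rot = (xy - ref.xy) @ rot.T + ref.xy
        a = net_movement_toward(make_track("a", xy), ref)
        b = net_movement_toward(make_track("a", xy_rot), ref)
        assert a == pytest.approx(b, abs=1e-7)

    def test_drift_recovery_from_generator(self):
        # mean net approach grows linearly at the configured drift speed
        drift = 0.5  # µm/min
        cfg = TrackGenConfig(n_cells=400, n_frames=61, speed=0.5,
                             turn_sd=0.4, drift_toward_ref=drift,
                             arena=(800.0, 800.0), seed=13)
        ts = generate_tracks(cfg)
        ref = ReferencePoint(*ts.truth["ref_point"])
        for n_frames, minutes in [(31, 30.0), (61, 60.0)]:
            nets = []
            for tr in ts:
                sub = Track(tr.cell_id, tr.frame[:n_frames], tr.t[:n_frames],
                            tr.x[:n_frames], tr.y[:n_frames])
                nets.append(net_movement_toward(sub, ref))
            slope = np.mean(nets) / minutes
            assert abs(slope - drift) / drift < 0.15


class TestChemokinesisWindow:
    def test_all_outside_band_is_empty(self, ref):
        ts = TrackSet([straight("a", (200, 0), (1, 0), 10)])
        with pytest.warns(UserWarning):
            v = chemokinesis_window(ts, ref)
        assert v.size == 0

    def test_pooled_count_matches_construction(self, ref):
        # 80 µm radial start moving outward 1 µm/frame: pair starts at
        # 80..90 µm (inclusive band edge) are in band, all before 15 min
        tr = straight("a", (80, 0), (1, 0), 40)
        v = chemokinesis_window(TrackSet([tr]), ref, r_lo=70, r_hi=90,
                                t_max=900.0)
        assert len(v) == 11
        tr2 = straight("b", (70, 0), (1, 0), 40)
        v2 = chemokinesis_window(TrackSet([tr2]), ref)
        assert len(v2) == 15  # time window binds before the band does

    def test_stationary_in_time_mean(self, ref):
        ts = TrackSet([straight("a", (75, 0), (0.0, 0.5), 60)])
        v1 = chemokinesis_window(ts, ref, t_max=900.0)
        v2 = chemokinesis_window(ts, ref, t_max=1800.0)
        assert np.mean(v1) == pytest.approx(np.mean(v2))


class TestMeanVelocity:
    def test_uniform_compliant_population(self):
        ts = TrackSet([straight(i, (i * 100.0, 0), (2.0, 0), 20)
                       for i in range(4)])  # 2 µm/min, path 38 µm, 20 frames
        assert mean_velocity(ts, CYTATION_POLICY) == pytest.approx(2.0)

    def test_long_path_cell_excluded(self):
        compliant = [straight(i, (i * 100.0, 0), (2.0, 0), 20)
                     for i in range(3)]
        roamer = straight("fast", (900.0, 0), (6.0, 0), 20)  # 114 µm path
        ts = TrackSet(compliant + [roamer])
        assert mean_velocity(ts, CYTATION_POLICY) == pytest.approx(2.0)

    def test_two_level_hand_oracle(self):
        a = straight("a", (0, 0), (1.0, 0), 19)   # mean 1 µm/min, 18 µm path
        b = straight("b", (100, 0), (3.0, 0), 19)  # mean 3 µm/min, 54 µm
        short = straight("c", (200, 0), (1.0, 0), 5)  # < 18 frames: dropped
        ts = TrackSet([a, b, short])
        assert mean_velocity(ts, CYTATION_POLICY) == pytest.approx(2.0)

    def test_net_displacement_toggle(self):
        # zig-zag: 3 µm/min, total path 54 µm (> 60 is false), net ~ 3 µm
        xy = [(0 if i % 2 else 3, 0) for i in range(19)]
        zig = make_track("z", xy)
        ts = TrackSet([zig])
        policy = FilterPolicy(max_total_path=10.0, min_frames_subpop=18)
        with pytest.warns(UserWarning):
            assert np.isnan(mean_velocity(ts, policy, path_mode="total"))
        assert mean_velocity(ts, policy, path_mode="net") == pytest.approx(3.0)

    def test_empty_subpopulation_flagged(self):
        ts = TrackSet([straight("a", (0, 0), (9.0, 0), 20)])  # 171 µm path
        with pytest.warns(UserWarning):
            assert np.isnan(mean_velocity(ts, CYTATION_POLICY))


class TestDistantCells:
    def test_far_pair_both_distant(self):
        ts = TrackSet([straight("a", (0, 0), (1, 0), 3),
                       straight("b", (100, 0), (1, 0), 3)])
        assert len(distant_cells(ts, radius=60.0)) == 2

    def test_close_pair_neither(self):
        ts = TrackSet([straight("a", (0, 0), (1, 0), 3),
                       straight("b", (10, 0), (1, 0), 3)])
        assert len(distant_cells(ts, radius=60.0)) == 0

    def test_grid_plus_isolated(self):
        tracks = [straight(f"g{i}{j}", (50.0 * i, 50.0 * j), (0.5, 0), 3)
                  for i in range(3) for j in range(3)]
        tracks.append(straight("lone", (400.0, 400.0), (0.5, 0), 3))
        out = distant_cells(TrackSet(tracks), radius=60.0)
        assert [tr.cell_id for tr in out] == ["lone"]

    def test_all_frames_mode_stricter(self):
        # start 100 µm apart but converge to 20 µm by the last frame
        a = straight("a", (0, 0), (0, 0), 5)
        b = make_track("b", [(100, 0), (80, 0), (60, 0), (40, 0), (20, 0)])
        ts = TrackSet([a, b])
        assert len(distant_cells(ts, radius=60.0, mode="first_frame")) == 2
        assert len(distant_cells(ts, radius=60.0, mode="all_frames")) == 0

    def test_single_track_warned(self):
        ts = TrackSet([straight("a", (0, 0), (1, 0), 3)])
        with pytest.warns(UserWarning):
            out = distant_cells(ts)
        assert len(out) == 1


class TestNormalizeFluor:
    def test_identical_flat_traces_zero(self):
        wells = [np.full((10, 20), 7.0), np.full((8, 20), 3.0)]
        mean, sem, _ = normalize_fluor(wells)
        assert np.allclose(mean, 0.0)
        assert np.allclose(sem, 0.0)

    def test_step_traces_recover_height(self):
        tr = generate_fluorescence_traces(20, 30, baseline=50.0,
                                          jump_time=25.0, jump_height=12.0,
                                          noise_sd=0.0)
        mean, _, _ = normalize_fluor(tr)
        assert np.allclose(mean[:5], 0.0)
        assert np.allclose(mean[5:], 12.0)

    def test_noisy_recovery_within_sem_band(self):
        wells = [generate_fluorescence_traces(200, 36, jump_height=30.0,
                                              noise_sd=4.0, seed=s)
                 for s in (1, 2, 3)]
        mean, sem, _ = normalize_fluor(wells)
        post = mean[6:]
        assert np.all(np.abs(post - 30.0) < 3 * np.maximum(sem[6:], 0.3))

    def test_incomplete_traces_removed(self):
        traces = np.full((5, 10), 2.0)
        traces[0, 4] = np.nan
        mean, _, well_means = normalize_fluor(traces)
        assert well_means.shape == (1, 10)
        assert np.allclose(mean, 0.0)

    def test_no_complete_traces_errors(self):
        traces = np.full((3, 5), np.nan)
        with pytest.raises(ValueError, match="complete"):
            normalize_fluor(traces)


def test_fluo4_policy_uses_calcium_step_threshold():
    slow = straight("ok", (0, 0), (2.0, 0), 5)
    fast = straight("float", (50, 0), (2.5, 0), 5)
    kept, counts = filter_tracks(TrackSet([slow, fast]), FLUO4_POLICY)
    assert [tr.cell_id for tr in kept] == ["ok"]
    assert counts["max_step"] == 1


def test_schistosome_policy_matches_assay_thresholds():
    assert SCHISTOSOME_POLICY.max_step == 11.2
    assert SCHISTOSOME_POLICY.max_gap == 3
    assert SCHISTOSOME_POLICY.min_frames == 3
    assert (SCHISTOSOME_POLICY.annulus_min,
            SCHISTOSOME_POLICY.annulus_max) == (70.0, 240.0)
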