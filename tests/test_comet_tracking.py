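"""Detection, linking, circular direction statistics, and centre classes."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from asterpol import (
    CometAnnotation,
    SceneSpec,
    average_direction,
    classify_track,
    detect_comets,
    direction_color,
    link_tracks,
    render_scene,
    terminate_emanate_fractions,
)
from asterpol.comet_tracking import (
    INCOMING,
    OTHER,
    OUTGOING,
    Detection,
    Track,
    TrackClassifierParams,
)


def brute_force_links(prev, nxt, max_disp):
    """Exhaustive minimal-total-distance one-to-one matching oracle (<=4 dets)."""
    best, best_cost = [], math.inf
    idx_next = range(len(nxt))
    for k in range(min(len(prev), len(nxt)), -1, -1):
        for prev_sub in itertools.combinations(range(len(prev)), k):
            for nxt_perm in itertools.permutations(idx_next, k):
                pairs = list(zip(prev_sub, nxt_perm))
                dists = [
                    math.dist(prev[i].position, nxt[j].position) for i, j in pairs
                ]
                if any(d > max_disp for d in dists):
                    continue
                cost = sum(dists)
                if len(pairs) > len(best) or (
                    len(pairs) == len(best) and cost < best_cost
                ):
                    best, best_cost = pairs, cost
    return set(best)


def make_dets(positions):
    return [Detection(position=tuple(map(float, p)), axis_deg=0.0) for p in positions]


class TestDetectComets:
    def test_empty_noiseless_frame_gives_no_detections(self):
        assert detect_comets(np.full((64, 64), 7.0), 0.22) == []

    def test_single_rendered_comet_found_near_head(self):
        spec = SceneSpec(
            geometry="random_field", n_comets=0, n_frames=1, noise_sd=0.0
        )
        front = (30.0, 25.0)
        ann = CometAnnotation(0, 0, front, (28.0, 25.0))
        stack = render_scene([ann], spec)
        dets = detect_comets(stack.data[0, 0], spec.pixel_size_um)
        assert len(dets) == 1
        assert math.dist(dets[0].position, front) <= spec.pixel_size_um
        # the comet streak is horizontal: orientation axis near 0 (mod 180)
        axis = dets[0].axis_deg
        assert min(axis, 180 - axis) < 15

    def test_two_separated_comets(self):
        spec = SceneSpec(geometry="random_field", n_comets=0, n_frames=1, noise_sd=0.0)
        anns = [
            CometAnnotation(0, 0, (15.0, 30.0), (13.0, 30.0)),
            CometAnnotation(1, 0, (35.0, 30.0), (33.0, 30.0)),
        ]
        stack = render_scene(anns, spec)
        assert len(detect_comets(stack.data[0, 0], spec.pixel_size_um)) == 2


class TestLinkTracks:
    def test_single_mover_yields_one_full_track(self):
        frames = [make_dets([(float(t), 0.0)]) for t in range(6)]
        tracks = link_tracks(frames, max_displacement_um=2.0)
        assert len(tracks) == 1
        assert tracks[0].n_points == 6

    def test_two_parallel_movers_stay_separate(self):
        frames = [make_dets([(float(t), 0.0), (float(t), 15.0)]) for t in range(5)]
        tracks = link_tracks(frames, max_displacement_um=2.0)
        assert len(tracks) == 2
        assert all(t.n_points == 5 for t in tracks)

    def test_displacement_cap_breaks_tracks(self):
        frames = [make_dets([(0.0, 0.0)]), make_dets([(10.0, 0.0)])]
        tracks = link_tracks(frames, max_displacement_um=2.0)
        assert sorted(t.n_points for t in tracks) == [1, 1]

    def test_permuting_detections_within_frame_changes_nothing(self):
        f0 = make_dets([(0.0, 0.0), (5.0, 0.0), (9.0, 3.0)])
        f1 = make_dets([(0.5, 0.2), (5.5, 0.1), (9.5, 3.2)])
        t_a = link_tracks([f0, f1], 2.0)
        t_b = link_tracks([f0[::-1], f1[::-1]], 2.0)
        pts_a = sorted(tuple(t.points) for t in t_a)
        pts_b = sorted(tuple(t.points) for t in t_b)
        assert pts_a == pts_b

    def test_ambiguous_crossing_matches_exhaustive_assignment(self):
        """Two comets crossing within max_disp link like the brute-force match."""
        prev = make_dets([(0.0, 0.0), (1.0, 0.0)])
        nxt = make_dets([(0.4, 0.3), (1.4, 0.3)])
        tracks = link_tracks([prev, nxt], max_displacement_um=2.0)
        got = {
            (t.points[0][1], t.points[1][1]) for t in tracks if t.n_points == 2
        }
        oracle = brute_force_links(prev, nxt, 2.0)
        expected = {
            (prev[i].position, nxt[j].position) for i, j in oracle
        }
        assert got == expected

    @pytest.mark.parametrize("seed", range(20))
    def test_error_bounded_by_exhaustive_assignment_on_small_cases(self, seed):
        """Greedy linking loses at most one link vs the exhaustive oracle."""
        rng = np.random.default_rng(seed)
        n0, n1 = rng.integers(1, 5, size=2)
        prev = make_dets(rng.uniform(0, 10, size=(n0, 2)).round(3))
        nxt = make_dets(rng.uniform(0, 10, size=(n1, 2)).round(3))
        tracks = link_tracks([prev, nxt], max_displacement_um=3.0)
        got = set()
        pos_prev = {tuple(d.position): i for i, d in enumerate(prev)}
        pos_nxt = {tuple(d.position): j for j, d in enumerate(nxt)}
        for t in tracks:
            if t.n_points == 2:
                got.add((pos_prev[t.points[0][1]], pos_nxt[t.points[1][1]]))
        oracle = brute_force_links(prev, nxt, 3.0)
        assert len(oracle) - 1 <= len(got) <= len(oracle)
        if len(got) == len(oracle):
            cost = lambda pairs: sum(
                math.dist(prev[i].position, nxt[j].position) for i, j in pairs
            )
            # equal-cardinality greedy matching is near-optimal in cost
            assert cost(got) <= 1.5 * cost(oracle) + 1e-9


class TestAverageDirection:
    def test_straight_track_along_x(self):
        t = Track(0, [(i, (float(i), 0.0)) for i in range(4)])
        assert average_direction(t) == pytest.approx(0.0)

    def test_circular_mean_across_wrap(self):
        """Segments at 350 and 10 degrees average to 0, not the naive 180."""
        p0 = (0.0, 0.0)
        p1 = (math.cos(math.radians(350)), math.sin(math.radians(350)))
        p2 = (p1[0] + math.cos(math.radians(10)), p1[1] + math.sin(math.radians(10)))
        t = Track(0, [(0, p0), (1, p1), (2, p2)])
        got = average_direction(t)
        assert min(got, 360 - got) == pytest.approx(0.0, abs=1e-9)

    def test_single_segment(self):
        ang = math.radians(37.0)
        t = Track(0, [(0, (0.0, 0.0)), (1, (math.cos(ang), math.sin(ang)))])
        assert average_direction(t) == pytest.approx(37.0)

    def test_all_zero_segments_flagged_undefined(self):
        t = Track(0, [(0, (1.0, 1.0)), (1, (1.0, 1.0))])
        assert average_direction(t) is None

    @given(phi=st.floats(0, 360))
    def test_equivariant_under_rotation(self, phi):
        pts = [(0, (0.0, 0.0)), (1, (1.0, 0.3)), (2, (2.0, 0.1))]
        base = average_direction(Track(0, pts))
        r = math.radians(phi)
        c, s = math.cos(r), math.sin(r)
        rot = [
            (f, (c * x - s * y, s * x + c * y)) for f, (x, y) in pts
        ]
        got = average_direction(Track(0, rot))
        diff = (got - base - phi) % 360.0
        assert min(diff, 360.0 - diff) < 1e-6


class TestDirectionColor:
    def test_periodicity(self):
        assert direction_color(0.0) == direction_color(360.0)

    def test_injective_on_opposite_directions(self):
        assert direction_color(10.0) != direction_color(190.0)

    def test_continuity(self):
        a = np.array(direction_color(123.0))
        b = np.array(direction_color(123.0 + 1e-4))
        assert np.linalg.norm(a - b) < 1e-2


class TestClassifyTrack:
    params = TrackClassifierParams(center=(0.0, 0.0))

    def test_defaults_follow_counting_protocol(self):
        assert self.params.capture_radius_um == 10.0
        assert self.params.time_window_s == 180.0

    def test_incoming_terminating(self):
        t = Track(0, [(0, (20.0, 0.0)), (1, (12.0, 0.0)), (2, (5.0, 0.0))])
        assert classify_track(t, self.params) == INCOMING

    def test_outgoing(self):
        t = Track(0, [(0, (5.0, 0.0)), (1, (12.0, 0.0)), (2, (20.0, 0.0))])
        assert classify_track(t, self.params) == OUTGOING

    def test_orbit_is_other(self):
        pts = [
            (i, (15.0 * math.cos(a), 15.0 * math.sin(a)))
            for i, a in enumerate(np.linspace(0, math.pi, 6))
        ]
        assert classify_track(Track(0, pts), self.params) == OTHER

    def test_fraction_consistency_86_14(self):
        """86 incoming and 14 outgoing tracks give fractions (0.86, 0.14)."""
        tracks = [
            Track(i, [(0, (20.0, 0.0)), (1, (5.0, 0.0))]) for i in range(86)
        ] + [
            Track(100 + i, [(0, (5.0, 0.0)), (1, (20.0, 0.0))]) for i in range(14)
        ]
        f_in, f_out = terminate_emanate_fractions(tracks, self.params)
        assert (f_in, f_out) == (0.86, 0.14)
        assert f_in + f_out == 1.0

    def test_all_incoming(self):
        tracks = [Track(0, [(0, (20.0, 0.0)), (1, (5.0, 0.0))])]
        assert terminate_emanate_fractions(tracks, self.params) == (1.0, 0.0)

    def test_no_classifiable_tracks_rejected(self):
        tracks = [Track(0, [(0, (20.0, 0.0)), (1, (20.0, 1.0))])]
        with pytest.raises(ValueError):
            terminate_emanate_fractions(tracks, self.params)

    def test_mixture_recovered_within_binomial_interval(self):
        """A 0.7/0.3 incoming/outgoing mixture is recovered from the truth."""
        from scipy.stats import binomtest

        rng = np.random.default_rng(77)
        n = 200
        tracks = []
        for i in range(n):
            phi = rng.uniform(0, 2 * math.pi)
            u = np.array([math.cos(phi), math.sin(phi)])
            if rng.random() < 0.7:
                pts = [(t, tuple(16.0 * u - 1.5 * t * u)) for t in range(8)]
            else:
                pts = [(t, tuple(4.0 * u + 1.5 * t * u)) for t in range(8)]
            tracks.append(Track(i, pts))
        f_in, _ = terminate_emanate_fractions(tracks, self.params)
        k = round(f_in * n)
        ci = binomtest(k, n).proportion_ci(0.95, method="exact")
        assert ci.low <= 0.7 <= ci.high


class TestEndToEndRecovery:
    def _scene(self, noise_sd=4.0, seed=5):
        spec = SceneSpec(
            geometry="centripetal_aster",
            n_comets=0,
            n_frames=8,
            seed=seed,
            noise_sd=noise_sd,
        )
        anns, truth = [], {}
        cx, cy = spec.center
        step = spec.speed_um_s * spec.frame_interval_s
        for i in range(10):
            phi = 2 * math.pi * i / 10
            u = np.array([math.cos(phi), math.sin(phi)])
            if i < 6:
                start = np.array([cx, cy]) + 16 * u
                d = -u
                truth[i] = INCOMING
            else:
                start = np.array([cx, cy]) + 6 * u
                d = u
                truth[i] = OUTGOING
            for t in range(spec.n_frames):
                f = start + d * step * t
                r = f - d * spec.comet_length_um
                anns.append(CometAnnotation(i, t, tuple(f), tuple(r)))
        return spec, anns, truth

    def test_ninety_percent_of_tracks_recovered_with_correct_class(self):
        """Rendered scene at SNR >= 5: all ground-truth tracks recovered."""
        spec, anns, truth = self._scene()
        stack = render_scene(anns, spec)
        assert spec.comet_amplitude / spec.noise_sd >= 5
        dets = [
            detect_comets(stack.data[t, 0], stack.pixel_size_um)
            for t in range(stack.n_frames)
        ]
        tracks = link_tracks(dets, 2.0)
        params = TrackClassifierParams(center=spec.center)
        gt_paths = {
            i: np.array([a.front_tip for a in anns if a.comet_id == i])
            for i in truth
        }
        recovered = 0
        for i, path in gt_paths.items():
            for tr in tracks:
                if tr.n_points < 5:
                    continue
                by_frame = dict(tr.points)
                common = [f for f in range(spec.n_frames) if f in by_frame]
                if len(common) < 5:
                    continue
                err = np.mean(
                    [math.dist(by_frame[f], path[f]) for f in common]
                )
                if err < 1.5 and classify_track(tr, params) == truth[i]:
                    recovered += 1
                    break
        assert recovered / len(gt_paths) >= 0.9

    def test_direction_error_under_5_degrees_on_noiseless_tracks(self):
        spec, anns, truth = self._scene(noise_sd=0.0)
        stack = render_scene(anns, spec)
        dets = [
            detect_comets(stack.data[t, 0], stack.pixel_size_um)
            for t in range(stack.n_frames)
        ]
        tracks = link_tracks(dets, 2.0)
        params = TrackClassifierParams(center=spec.center)
        checked = 0
        for tr in tracks:
            if tr.n_points < 5 or classify_track(tr, params) == OTHER:
                continue
            got = average_direction(tr)
            pos = tr.positions()
            true_dir = math.degrees(
                math.atan2(pos[-1][1] - pos[0][1], pos[-1][0] - pos[0][0])
            ) % 360
            diff = abs((got - true_dir + 180) % 360 - 180)
            assert diff < 5.0
            checked += 1
        assert checked >= 9
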