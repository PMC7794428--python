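import itertools

import numpy as np
import pytest

from coralcasa import CasaSettings, link_detections, split_risk_report
from coralcasa.detection import Detection
from coralcasa.tracking import Track


def line_detections(speed_um_s, n_frames=45, frame_rate_hz=60.0, y=50.0):
    return [
        Detection(frame_index=i, x_um=i * speed_um_s / frame_rate_hz, y_um=y,
                  area_um2=15.0, mean_intensity=1.0)
        for i in range(n_frames)
    ]


def brute_force_link(detections, cell_travel_max):
    """Exhaustive per-frame-pair minimum-cost assignment oracle.

    For each consecutive frame pair, enumerate every injective assignment of
    open-track tails to current detections and keep the one maximising the
    number of within-bound links, breaking ties by total distance.  Only
    feasible for a handful of cells.
    """
    by_frame = {}
    for det in detections:
        by_frame.setdefault(det.frame_index, []).append(det)
    if not by_frame:
        return []
    first, last = min(by_frame), max(by_frame)
    tracks = []
    open_tracks = []
    for det in by_frame.get(first, []):
        tracks.append([det])
        open_tracks.append(tracks[-1])
    for frame in range(first + 1, last + 1):
        current = by_frame.get(frame, [])
        best = None
        if open_tracks and current:
            m, n = len(open_tracks), len(current)
            indices = range(n)
            for perm in itertools.permutations(indices, min(m, n)):
                links, total = [], 0.0
                for r, c in zip(range(m), perm):
                    tail = open_tracks[r][-1]
                    d = np.hypot(tail.x_um - current[c].x_um,
                                 tail.y_um - current[c].y_um)
                    if d <= cell_travel_max:
                        links.append((r, c))
                        total += d
                key = (-len(links), total)
                if best is None or key < best[0]:
                    best = (key, links)
        links = best[1] if best else []
        matched_cols = {c for _, c in links}
        next_open = []
        for r, c in links:
            open_tracks[r].append(current[c])
            next_open.append(open_tracks[r])
        for j, det in enumerate(current):
            if j not in matched_cols:
                tracks.append([det])
                next_open.append(tracks[-1])
        open_tracks = next_open
    return tracks


def random_instance(rng, cell_travel_max=5.0):
    """Well-separated random walks: unambiguous ground-truth correspondence."""
    n_cells = int(rng.integers(1, 7))
    n_frames = int(rng.integers(2, 11))
    spacing = 2 * cell_travel_max * (n_frames + 2)
    truth = []
    for c in range(n_cells):
        pos = np.array([c * spacing, 0.0])
        path = [pos.copy()]
        for _ in range(n_frames - 1):
            angle = rng.uniform(0, 2 * np.pi)
            radius = rng.uniform(0, 0.9 * cell_travel_max)
            pos = pos + radius * np.array([np.cos(angle), np.sin(angle)])
            path.append(pos.copy())
        truth.append(np.array(path))
    detections = []
    for frame in range(n_frames):
        order = rng.permutation(n_cells)  # shuffle within-frame ordering
        for c in order:
            x, y = truth[c][frame]
            detections.append(
                Detection(frame_index=frame, x_um=float(x), y_um=float(y),
                          area_um2=12.0, mean_intensity=1.0)
            )
    return detections, truth, n_cells


def as_partition(tracks):
    out = []
    for t in tracks:
        dets = t.detections if isinstance(t, Track) else t
        out.append(
            tuple((d.frame_index, round(d.x_um, 9), round(d.y_um, 9)) for d in dets)
        )
    return sorted(out)


class TestLinkDetections:
    def test_straight_line_at_300_stays_one_track(self):
        tracks = link_detections(line_detections(300.0), cell_travel_max_um=5.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 45

    def test_straight_line_above_300_splits(self):
        tracks = link_detections(line_detections(301.0), cell_travel_max_um=5.0)
        assert len(tracks) >= 2

    def test_stationary_detection_one_track_of_45(self):
        detections = [
            Detection(frame_index=i, x_um=10.0, y_um=10.0, area_um2=12.0,
                      mean_intensity=1.0)
            for i in range(45)
        ]
        tracks = link_detections(detections, cell_travel_max_um=5.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 45

    def test_empty_input_empty_output(self):
        assert link_detections([], cell_travel_max_um=5.0) == []

    def test_gap_starts_a_new_track(self):
        detections = [
            Detection(frame_index=i, x_um=10.0, y_um=10.0, area_um2=12.0,
                      mean_intensity=1.0)
            for i in (0, 1, 3, 4)  # frame 2 missing
        ]
        tracks = link_detections(detections, cell_travel_max_um=5.0)
        assert sorted(len(t) for t in tracks) == [2, 2]

    def test_oracle_equivalence_on_200_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            detections, truth, n_cells = random_instance(rng)
            tracks = link_detections(detections, cell_travel_max_um=5.0)
            oracle = brute_force_link(detections, cell_travel_max=5.0)
            assert len(tracks) == n_cells
            got = as_partition(tracks)
            expected = as_partition(oracle)
            assert got == expected
            # ground truth correspondence: each track follows one cell exactly
            truth_partition = sorted(
                tuple((f, round(float(x), 9), round(float(y), 9))
                      for f, (x, y) in enumerate(path))
                for path in truth
            )
            assert got == truth_partition

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        detections, _, _ = random_instance(rng)
        tracks = link_detections(detections, cell_travel_max_um=5.0)
        flattened = [d for t in tracks for d in t.detections]
        assert len(flattened) == len(detections)
        assert len(set(map(id, flattened))) == len(detections)

    def test_raising_travel_bound_never_increases_track_count(self):
        rng = np.random.default_rng(11)
        detections = []
        for frame in range(8):
            for _ in range(6):
                detections.append(
                    Detection(frame_index=frame, x_um=float(rng.uniform(0, 60)),
                              y_um=float(rng.uniform(0, 60)), area_um2=12.0,
                              mean_intensity=1.0)
                )
        counts = [
            len(link_detections(detections, cell_travel_max_um=bound))
            for bound in (1.0, 2.0, 5.0, 10.0, 30.0, 100.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_non_positive_bound_rejected(self):
        with pytest.raises(ValueError):
            link_detections([], cell_travel_max_um=0.0)

    def test_track_rejects_non_consecutive_frames(self):
        with pytest.raises(ValueError, match="consecutive"):
            Track(track_id=0, detections=[
                Detection(0, 0.0, 0.0, 10.0, 1.0),
                Detection(2, 1.0, 0.0, 10.0, 1.0),
            ])


class TestSplitRiskReport:
    def test_five_micron_bound_at_60hz(self):
        report = split_risk_report(CasaSettings(cell_travel_max_um=5.0))
        assert report.max_trackable_vcl_um_s == pytest.approx(300.0)

    def test_ten_micron_bound_at_60hz(self):
        report = split_risk_report(CasaSettings(cell_travel_max_um=10.0))
        assert report.max_trackable_vcl_um_s == pytest.approx(600.0)

    def test_five_micron_bound_at_30hz(self):
        report = split_risk_report(
            CasaSettings(cell_travel_max_um=5.0, frame_rate_hz=30.0,
                         capture_duration_s=1.5)
        )
        assert report.max_trackable_vcl_um_s == pytest.approx(150.0)

    def test_warning_when_bound_below_expected_speed(self):
        report = split_risk_report(
            CasaSettings(cell_travel_max_um=2.0, expected_max_speed_um_s=300.0)
        )
        assert report.at_risk
        assert "split" in report.message
        ok = split_risk_report(CasaSettings(cell_travel_max_um=10.0))
        assert not ok.at_risk
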