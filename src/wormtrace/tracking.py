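"""Multi-object tracking by per-frame distance minimization.

Per-frame components are linked into persistent neuron tracks with an
optimal one-to-one assignment between track heads and detections (total
Euclidean centroid distance minimized, pairs beyond a gate excluded).
Unmatched heads coast on their last centroid and record a gap; a gap run
longer than `max_gap` terminates the track.  For the paired-neuron
recordings, exactly two tracks are retained and named "left"/"right" by
median image column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .segmentation import FrameSegmentation

__all__ = [
    "Detection",
    "Track",
    "TrackingResult",
    "link_frame",
    "track_movie",
    "assign_pair_identity",
]

DEFAULT_GATE_PX = 15.0
DEFAULT_MAX_GAP = 10
DEFAULT_INIT_WINDOW = 10

_BIG = 1e9  # cost of a disallowed (out-of-gate) pairing


@dataclass
class Detection:
    frame: int
    centroid: tuple[float, float]
    area: int
    component_label: int


@dataclass
class Track:
    track_id: int
    entries: list[Detection | None]  # one slot per frame; None = gap
    identity: str = ""
    terminated: bool = False
    identity_tie_flag: bool = False

    @property
    def n_detections(self) -> int:
        return sum(e is not None for e in self.entries)

    @property
    def gap_run_max(self) -> int:
        run = best = 0
        started = False
        for e in self.entries:
            if e is None:
                if started:
                    run += 1
                    best = max(best, run)
            else:
                started = True
                run = 0
        return best

    def centroids(self) -> np.ndarray:
        return np.array([e.centroid for e in self.entries if e is not None])


@dataclass
class TrackingResult:
    tracks: list[Track]
    failed: bool = False
    failure_reason: str = ""
    n_frames: int = 0

    def to_json(self, path) -> None:
        payload = {
            "failed": self.failed,
            "failure_reason": self.failure_reason,
            "n_frames": self.n_frames,
            "tracks": [{
                "track_id": t.track_id,
                "identity": t.identity,
                "terminated": t.terminated,
                "entries": [
                    None if e is None else {
                        "frame": e.frame,
                        "centroid": list(e.centroid),
                        "area": e.area,
                        "component_label": e.component_label,
                    } for e in t.entries],
            } for t in self.tracks],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TrackingResult":
        with open(path) as fh:
            payload = json.load(fh)
        tracks = []
        for td in payload["tracks"]:
            entries = [
                None if e is None else Detection(
                    frame=e["frame"], centroid=tuple(e["centroid"]),
                    area=e["area"], component_label=e["component_label"])
                for e in td["entries"]]
            tracks.append(Track(track_id=td["track_id"], entries=entries,
                                identity=td["identity"],
                                terminated=td["terminated"]))
        return cls(tracks=tracks, failed=payload["failed"],
                   failure_reason=payload["failure_reason"],
                   n_frames=payload["n_frames"])


def link_frame(head_positions: np.ndarray, detection_positions: np.ndarray,
               gate_px: float = DEFAULT_GATE_PX) -> list[tuple[int, int]]:
    """Optimal gated one-to-one matching of track heads to detections.

    Returns (head_index, detection_index) pairs.  Among assignments that
    match the most pairs within the gate, the one with minimum total
    Euclidean distance is chosen (optimal bipartite assignment, not greedy
    nearest neighbor).
    """
    if gate_px <= 0:
        raise ValueError("gate_px must be positive")
    heads = np.atleast_2d(np.asarray(head_positions, dtype=float))
    dets = np.atleast_2d(np.asarray(detection_positions, dtype=float))
    if heads.size == 0 or dets.size == 0:
        return []
    dist = np.linalg.norm(heads[:, None, :] - dets[None, :, :], axis=2)
    cost = np.where(dist <= gate_px, dist, _BIG)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if dist[r, c] <= gate_px]


@dataclass
class _Head:
    track: Track
    position: tuple[float, float]  # last known centroid (coasts over gaps)
    gap_run: int = 0


def track_movie(segmentations: list[FrameSegmentation],
                expected_count: int = 2,
                gate_px: float = DEFAULT_GATE_PX,
                max_gap: int = DEFAULT_MAX_GAP,
                init_window: int = DEFAULT_INIT_WINDOW) -> TrackingResult:
    """Link per-frame segmentations into `expected_count` neuron tracks.

    Tracks are seeded in the first frames (initialization window); new
    candidate tracks open only inside that window.  If no frame within the
    window shows `expected_count` detections, the movie is flagged as a
    tracking failure (the automated stand-in for recordings that cannot be
    quantified because of uncontrolled animal movements).
    """
    if expected_count < 1:
        raise ValueError("expected_count must be >= 1")
    T = len(segmentations)
    if not any(len(seg.components) >= expected_count
               for seg in segmentations[:init_window]):
        return TrackingResult([], failed=True, n_frames=T,
                              failure_reason="initialization window never showed "
                                             f"{expected_count} detections")

    heads: list[_Head] = []
    next_id = 0
    for t, seg in enumerate(segmentations):
        dets = [Detection(t, c.centroid, c.area, c.label) for c in seg.components]
        active = [h for h in heads if not h.track.terminated]
        matches = link_frame(
            np.array([h.position for h in active]).reshape(-1, 2),
            np.array([d.centroid for d in dets]).reshape(-1, 2),
            gate_px,
        ) if active and dets else []
        matched_heads = {r for r, _ in matches}
        matched_dets = {c for _, c in matches}
        for r, c in matches:
            h = active[r]
            h.track.entries[t] = dets[c]
            h.position = dets[c].centroid
            h.gap_run = 0
        for i, h in enumerate(active):
            if i not in matched_heads:
                h.gap_run += 1
                if h.gap_run > max_gap:
                    h.track.terminated = True
        if t < init_window:
            for c, d in enumerate(dets):
                if c not in matched_dets:
                    tr = Track(track_id=next_id, entries=[None] * T)
                    next_id += 1
                    tr.entries[t] = d
                    heads.append(_Head(tr, d.centroid))

    tracks = sorted((h.track for h in heads),
                    key=lambda tr: (-tr.n_detections, tr.track_id))
    retained = tracks[:expected_count]
    if len(retained) < expected_count:
        return TrackingResult(retained, failed=True, n_frames=T,
                              failure_reason="fewer tracks than expected neurons")
    result = TrackingResult(retained, n_frames=T)
    if expected_count == 2:
        assign_pair_identity(result.tracks)
    else:
        for i, tr in enumerate(result.tracks):
            tr.identity = f"N{i + 1}"
    return result


def assign_pair_identity(tracks: list[Track]) -> list[Track]:
    """Name a track pair "left"/"right" by median image column.

    Image-frame naming, not anatomical: animals can sit in the trap in
    either orientation, so mapping to anatomical sides needs operator input.
    Ties on column are broken by median row and flagged.
    """
    if len(tracks) != 2:
        raise ValueError("pair identity needs exactly two tracks")
    med = []
    for tr in tracks:
        cen = tr.centroids()
        if cen.size == 0:
            raise ValueError("cannot name a track with no detections")
        med.append((float(np.median(cen[:, 1])), float(np.median(cen[:, 0]))))
    tie = med[0][0] == med[1][0]
    order = sorted(range(2), key=lambda i: med[i])
    tracks[order[0]].identity = "left"
    tracks[order[1]].identity = "right"
    for tr in tracks:
        tr.identity_tie_flag = tie
    return tracks
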