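"""Nearest-neighbor linking across time-lapse frames and dynamics calling.

Liposomes barely move between the 12-s frames, so tracking is a greedy
nearest-neighbor assignment against the frame-0 position (the anchor) with
a hard 5-um displacement ceiling.  A track whose per-frame localization
classes contain both class 1 (lumen) and class 2 (membrane) is called
*dynamic* -- the signature of an oscillating vesicle sampled at different
phases -- and becomes a photoactivation target.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detect import Detection
from .errors import ConfigurationError, InputError

__all__ = ["TrackerParams", "Track", "link_tracks", "classify_dynamics",
           "select_targets", "pulsing_detection_probability", "tracks_to_csv",
           "tracks_to_json"]


@dataclass
class TrackerParams:
    max_displacement_um: float = 5.0
    require_full_length: bool = True
    frame_count: int = 5
    match_to: str = "anchor"  # "anchor" (frame-0 position) or "previous"

    def __post_init__(self):
        if self.max_displacement_um <= 0:
            raise InputError("max_displacement_um must be > 0")
        if self.match_to not in ("anchor", "previous"):
            raise ConfigurationError(f"unknown match_to {self.match_to!r}")


@dataclass
class Track:
    track_id: int
    anchor_um: tuple[float, float]
    members: list  # ordered (frame_index, Detection)
    class_sequence: list = field(default_factory=list)
    dynamic: bool = False

    @property
    def last_position(self) -> tuple[float, float]:
        return self.members[-1][1].centroid_um


def _dist(a, b) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def link_tracks(
    per_frame_detections: Sequence[Sequence[Detection]],
    params: TrackerParams,
) -> list[Track]:
    """Link per-frame detections into tracks seeded from frame 0.

    For each later frame, candidate (track, detection) pairs within the
    displacement ceiling of the track's reference position are assigned
    greedily by ascending distance, one-to-one; ties below 1e-9 um break
    toward the lower detection index.  Unmatched detections never seed new
    tracks.  With ``require_full_length`` (the default) tracks missing any
    frame are dropped, and each surviving track gets its class sequence and
    dynamic/static call.
    """
    frames = list(per_frame_detections)
    if len(frames) != params.frame_count:
        raise InputError(
            f"got {len(frames)} frames, tracker configured for {params.frame_count}"
        )
    tracks = [
        Track(track_id=i, anchor_um=d.centroid_um, members=[(0, d)])
        for i, d in enumerate(frames[0])
    ]
    for f_idx in range(1, len(frames)):
        dets = frames[f_idx]
        candidates = []
        for t in tracks:
            ref = t.anchor_um if params.match_to == "anchor" else t.last_position
            for j, d in enumerate(dets):
                dist = _dist(ref, d.centroid_um)
                if dist <= params.max_displacement_um:
                    candidates.append((dist, j, t.track_id))
        candidates.sort(key=lambda c: (round(c[0] / 1e-9), c[1], c[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        by_id = {t.track_id: t for t in tracks}
        for dist, j, tid in candidates:
            if tid in used_tracks or j in used_dets:
                continue
            by_id[tid].members.append((f_idx, dets[j]))
            used_tracks.add(tid)
            used_dets.add(j)
    if params.require_full_length:
        tracks = [t for t in tracks if len(t.members) == len(frames)]
    for t in tracks:
        t.class_sequence = [d.cls for _, d in t.members]
        t.dynamic = classify_dynamics(t) == "dynamic"
    return tracks


def classify_dynamics(track: "Track | Sequence[int]") -> str:
    """Call a track static or dynamic from its class sequence.

    Dynamic iff the sequence contains both class 1 and class 2 -- the
    vesicle's reporter moved between lumen and membrane during the video.
    For full-length tracks this coincides with requiring a class change
    between some pair of consecutive frames.
    """
    seq = track.class_sequence if isinstance(track, Track) else list(track)
    if not seq:
        raise InputError("empty class sequence")
    return "dynamic" if (1 in seq and 2 in seq) else "static"


def select_targets(
    objects: Sequence,
    policy: str,
    fov_center_um: tuple[float, float] = (64.0, 64.0),
    rho_um: float = 20.0,
    qualifier=None,
) -> list[tuple[float, float]]:
    """Choose photostimulation coordinates among qualifying objects.

    ``objects`` may be Tracks (video mode: qualifying = dynamic) or
    Detections (static mode: qualifying = class 2, i.e. membrane-localized
    reporter; pass a custom ``qualifier`` for plain intensity screening
    where every detection qualifies).  ``center_only`` emulates stimulation
    restricted to the FOV center: at most one target per FOV, the
    qualifying object nearest the center within radius ``rho_um``;
    ``anywhere`` stimulates all qualifying objects.
    """
    if policy not in ("center_only", "anywhere"):
        raise ConfigurationError(f"unknown policy {policy!r}")

    def default_qualifier(obj):
        if isinstance(obj, Track):
            return obj.dynamic
        return obj.cls == 2

    qualify = qualifier or default_qualifier

    def position(obj):
        if isinstance(obj, Track):
            return obj.anchor_um
        return obj.centroid_um

    qualifying = [position(o) for o in objects if qualify(o)]
    if policy == "anywhere":
        return qualifying
    in_reach = [p for p in qualifying if _dist(p, fov_center_um) <= rho_um]
    if not in_reach:
        return []
    return [min(in_reach, key=lambda p: _dist(p, fov_center_um))]


def pulsing_detection_probability(period_s: float, frame_times_s: Sequence[float],
                                  n_grid: int = 200001) -> float:
    """Probability that a pulsing vesicle with uniform random phase is called dynamic.

    A pulsing vesicle is class 2 during the membrane-bound half of its
    square-wave cycle and class 1 otherwise, so the video misses it only
    when every frame samples the same half.  The probability is the phase
    integral 1 - P(all frames land in one half), evaluated on a dense phase
    grid (the indicator is piecewise constant, so the grid value converges
    to the exact integral).
    """
    u = np.linspace(0.0, 1.0, n_grid, endpoint=False)
    frac = (u[None, :] + np.asarray(frame_times_s, dtype=float)[:, None] / period_s) % 1.0
    high = frac < 0.5
    same = np.all(high, axis=0) | np.all(~high, axis=0)
    return 1.0 - float(same.mean())


def targets_to_csv(rows: Sequence[tuple[int, float, float, str]], path) -> None:
    """Write stimulation targets as CSV rows of (fov, x_um, y_um, reason)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fov", "x_um", "y_um", "reason"])
        for fov, x, y, reason in rows:
            w.writerow([fov, f"{x:.3f}", f"{y:.3f}", reason])


def tracks_to_csv(tracks: Sequence[Track], path, fov: int = 0) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fov", "track_id", "frame", "centroid_x_um", "centroid_y_um", "cls"])
        for t in tracks:
            for frame, d in t.members:
                w.writerow([fov, t.track_id, frame,
                            f"{d.centroid_um[0]:.3f}", f"{d.centroid_um[1]:.3f}", d.cls])


def tracks_to_json(tracks: Sequence[Track], path, fov: int = 0) -> None:
    payload = [
        {
            "fov": fov,
            "track_id": t.track_id,
            "anchor_um": list(t.anchor_um),
            "class_sequence": t.class_sequence,
            "dynamic": t.dynamic,
        }
        for t in tracks
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
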