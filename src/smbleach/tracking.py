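"""Frame-to-frame linking and intensity-trace extraction.

Particles are chemically fixed, so linking is a greedy nearest-neighbor
assignment with a tight displacement gate rather than a motion-model
tracker. Traces are read out with a fixed circular aperture anchored at the
track's mean position, with a median-annulus local background, and extend
over the whole movie so the post-bleach baseline is observed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import spatial

from .io import MovieStack

__all__ = [
    "Track",
    "FluorescenceTrace",
    "TraceQCRules",
    "link",
    "extract_trace",
    "extract_traces",
    "qc_filter_traces",
]


@dataclass
class Track:
    track_id: int
    frames: list[int] = field(default_factory=list)
    rows: list[float] = field(default_factory=list)
    cols: list[float] = field(default_factory=list)
    isolated: bool = True

    @property
    def start_frame(self) -> int:
        return self.frames[0]

    @property
    def end_frame(self) -> int:
        return self.frames[-1]

    @property
    def anchor(self) -> tuple[float, float]:
        """Mean sub-pixel position over all linked detections."""
        return float(np.mean(self.rows)), float(np.mean(self.cols))

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class FluorescenceTrace:
    """Background-subtracted (or raw simulated) per-frame intensity series."""

    track_id: int
    intensity: np.ndarray
    frame_interval: float = 50.0
    aperture_radius: float = 3.0
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 1 or self.intensity.size < 1:
            raise ValueError("trace intensity must be a non-empty 1D array")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("trace intensity must be finite")

    @property
    def n_frames(self) -> int:
        return self.intensity.size


def link(detections: pd.DataFrame, max_displacement: float = 2.0,
         max_gap: int = 0) -> list[Track]:
    """Greedy nearest-neighbor linking of per-frame detections.

    Frame by frame, candidate links between open tracks and new detections
    are sorted by distance and accepted greedily, rejecting any link longer
    than ``max_displacement``. Unmatched detections start new tracks; a track
    unmatched for more than ``max_gap`` consecutive frames is closed.
    """
    required = {"frame", "row", "col"}
    if not required.issubset(detections.columns):
        raise ValueError(f"detections must have columns {sorted(required)}")
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    next_id = 0
    frames = sorted(detections["frame"].unique())
    by_frame = {f: g for f, g in detections.groupby("frame")}
    for f in frames:
        g = by_frame[f]
        pts = g[["row", "col"]].to_numpy(dtype=float)
        iso = g["isolated"].to_numpy() if "isolated" in g else np.ones(len(g), bool)
        # drop tracks that have been dark too long
        open_tracks = [t for t in open_tracks if f - t.end_frame <= max_gap + 1]
        assigned_det: set[int] = set()
        assigned_trk: set[int] = set()
        if open_tracks and len(pts):
            anchors = np.array([[t.rows[-1], t.cols[-1]] for t in open_tracks])
            tree = spatial.cKDTree(pts)
            k = min(4, len(pts))
            dists, idxs = tree.query(anchors, k=k, distance_upper_bound=max_displacement)
            dists = np.atleast_2d(dists.reshape(len(anchors), -1))
            idxs = np.atleast_2d(idxs.reshape(len(anchors), -1))
            finite = np.isfinite(dists)
            ti, ci = np.nonzero(finite)
            order = np.argsort(dists[ti, ci], kind="stable")
            for kk in order:
                t_idx, d_idx = int(ti[kk]), int(idxs[ti[kk], ci[kk]])
                if t_idx in assigned_trk or d_idx in assigned_det:
                    continue
                t = open_tracks[t_idx]
                t.frames.append(int(f))
                t.rows.append(float(pts[d_idx, 0]))
                t.cols.append(float(pts[d_idx, 1]))
                t.isolated = t.isolated and bool(iso[d_idx])
                assigned_trk.add(t_idx)
                assigned_det.add(d_idx)
        for d_idx in range(len(pts)):
            if d_idx in assigned_det:
                continue
            t = Track(next_id, [int(f)], [float(pts[d_idx, 0])], [float(pts[d_idx, 1])],
                      isolated=bool(iso[d_idx]))
            next_id += 1
            open_tracks.append(t)
            tracks.append(t)
    return tracks


def merge_stationary_tracks(tracks: list[Track], radius: float = 1.5) -> list[Track]:
    """Merge track fragments whose anchors coincide within ``radius`` px.

    Fixed particles that drop out of detection for a frame split into
    fragments under strict gap closing; since they cannot move, fragments
    anchored at the same position are one particle. Detections are pooled
    (first detection wins on frame collisions) and the merged track keeps the
    lowest fragment id; isolation flags combine conjunctively.
    """
    if len(tracks) < 2:
        return tracks
    anchors = np.array([t.anchor for t in tracks])
    tree = spatial.cKDTree(anchors)
    parent = list(range(len(tracks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[Track]] = {}
    for i, t in enumerate(tracks):
        groups.setdefault(find(i), []).append(t)
    merged: list[Track] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        seen: dict[int, tuple[float, float]] = {}
        for t in sorted(members, key=lambda t: t.start_frame):
            for f, r, c in zip(t.frames, t.rows, t.cols):
                seen.setdefault(f, (r, c))
        frames = sorted(seen)
        merged.append(Track(
            min(t.track_id for t in members),
            frames,
            [seen[f][0] for f in frames],
            [seen[f][1] for f in frames],
            isolated=all(t.isolated for t in members),
        ))
    merged.sort(key=lambda t: t.track_id)
    return merged


def flag_crowded_tracks(tracks: list[Track], radius: float) -> set[int]:
    """Ids of tracks whose anchors lie within ``radius`` px of another track.

    The isolation requirement for fixed particles: both members of a close
    pair are flagged, since their apertures contaminate each other.
    """
    if len(tracks) < 2:
        return set()
    anchors = np.array([t.anchor for t in tracks])
    tree = spatial.cKDTree(anchors)
    crowded: set[int] = set()
    for i, j in tree.query_pairs(radius):
        crowded.add(tracks[i].track_id)
        crowded.add(tracks[j].track_id)
    return crowded


def _disc_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    dr, dc = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    keep = dr**2 + dc**2 <= radius**2
    return np.column_stack([dr[keep], dc[keep]])


def _annulus_offsets(inner: float, outer: float) -> np.ndarray:
    r = int(np.ceil(outer))
    dr, dc = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    d2 = dr**2 + dc**2
    keep = (d2 > inner**2) & (d2 <= outer**2)
    return np.column_stack([dr[keep], dc[keep]])


def extract_trace(movie: MovieStack, anchor, aperture_radius: float = 3.0,
                  annulus: tuple[float, float] = (5.0, 7.0),
                  track_id: int = 0) -> FluorescenceTrace:
    """Aperture-photometry trace at a fixed anchor, over every frame.

    Per frame: sum of counts in a disc of ``aperture_radius`` around the
    (rounded) anchor, minus the annulus median times the disc pixel count.
    Anchors whose annulus would cross the image border are flagged
    ``"border"`` and return a zero trace.
    """
    r0, c0 = int(round(anchor[0])), int(round(anchor[1]))
    rows, cols = movie.shape
    outer = int(np.ceil(annulus[1]))
    if r0 - outer < 0 or c0 - outer < 0 or r0 + outer >= rows or c0 + outer >= cols:
        return FluorescenceTrace(track_id, np.zeros(movie.n_frames),
                                 movie.frame_interval, aperture_radius,
                                 qc_flags=["border"])
    disc = _disc_offsets(aperture_radius)
    ann = _annulus_offsets(*annulus)
    disc_vals = movie.data[:, r0 + disc[:, 0], c0 + disc[:, 1]]
    ann_vals = movie.data[:, r0 + ann[:, 0], c0 + ann[:, 1]]
    bg = np.median(ann_vals, axis=1)
    intensity = disc_vals.sum(axis=1) - bg * len(disc)
    return FluorescenceTrace(track_id, intensity, movie.frame_interval, aperture_radius)


def extract_traces(movie: MovieStack, tracks: list[Track],
                   aperture_radius: float = 3.0,
                   annulus: tuple[float, float] = (5.0, 7.0),
                   flag_isolation: bool = True) -> list[FluorescenceTrace]:
    traces = []
    for t in tracks:
        tr = extract_trace(movie, t.anchor, aperture_radius, annulus, track_id=t.track_id)
        if flag_isolation and not t.isolated:
            tr.qc_flags.append("crowded")
        traces.append(tr)
    return traces


@dataclass
class TraceQCRules:
    """Explicit, loggable replacements for manual trace curation.

    ``unit_intensity`` is the per-fluorophore trace-level step height (after
    aperture losses); thresholds scale from it. ``end_tolerance`` is the
    absolute level a fully bleached trace must end below.
    """

    unit_intensity: float
    end_tolerance: float | None = None       # default 0.5 * unit_intensity
    rebright_fraction: float = 0.5           # of unit_intensity, rule (c)
    min_duration: int = 3                    # frames visible before final bleach
    tail_frames: int = 10                    # frames averaged to test the end level

    def __post_init__(self) -> None:
        if self.end_tolerance is None:
            self.end_tolerance = 0.5 * self.unit_intensity


def qc_filter_traces(traces: list[FluorescenceTrace], rules: TraceQCRules
                     ) -> tuple[list[FluorescenceTrace], pd.DataFrame]:
    """Apply trace-quality rules; return accepted traces and a rejection log.

    Rejection reasons: ``border`` / ``crowded`` (geometry flags set at
    extraction), ``not fully bleached`` (end plateau above tolerance),
    ``blinking`` (re-brightening after reaching background), and
    ``too short`` (visible for fewer than ``min_duration`` frames).
    """
    accepted: list[FluorescenceTrace] = []
    log: list[dict] = []
    for tr in traces:
        reason = None
        if tr.qc_flags:
            reason = tr.qc_flags[0]
        else:
            y = tr.intensity
            tail = y[-min(rules.tail_frames, y.size):]
            dark = y <= rules.end_tolerance
            if not dark.any() or float(tail.mean()) > rules.end_tolerance:
                reason = "not fully bleached"
            else:
                first_dark = int(np.argmax(dark))
                rebright = rules.rebright_fraction * rules.unit_intensity
                if np.any(y[first_dark:] > rules.end_tolerance + rebright):
                    reason = "blinking"
                elif first_dark < rules.min_duration:
                    reason = "too short"
        if reason is None:
            accepted.append(tr)
        else:
            log.append({"track_id": tr.track_id, "reason": reason})
    return accepted, pd.DataFrame(log, columns=["track_id", "reason"])
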