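"""Single-cell tracking of metabolic states across time-lapse frames.

ROIs are linked frame-to-frame by greedy nearest-centroid matching within a
displacement gate; state changes along a track become transition events
(Glycolytic -> OxPhos or back), with Indeterminate frames carrying the last
definite state; population summaries report per-frame state fractions and
survival relative to the first frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .btnr import GLYCOLYTIC, INDETERMINATE, OXPHOS, RoiMeasurement

__all__ = [
    "CellTrack",
    "TransitionEvent",
    "link_frames",
    "detect_transitions",
    "population_timecourse",
    "G_TO_O",
    "O_TO_G",
]

G_TO_O = "GlycolyticToOxPhos"
O_TO_G = "OxPhosToGlycolytic"


@dataclass
class TransitionEvent:
    """A state flip between two consecutive measured frames of one track."""

    track: int
    frame_from: int
    frame_to: int
    direction: str

    def __post_init__(self) -> None:
        if self.frame_from >= self.frame_to:
            raise ValueError("transition must move forward in time")
        if self.direction not in (G_TO_O, O_TO_G):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class CellTrack:
    """Time series of ROI measurements belonging to one cell."""

    track_id: int
    measurements: list[RoiMeasurement] = field(default_factory=list)
    birth_frame: int = 0
    death_frame: int | None = None

    def frames(self) -> list[int]:
        return [m.frame for m in self.measurements]

    def append(self, m: RoiMeasurement) -> None:
        if self.measurements and m.frame <= self.measurements[-1].frame:
            raise ValueError("frames must be strictly increasing within a track")
        self.measurements.append(m)


def link_frames(
    frames: list[list[RoiMeasurement]], max_displacement: float = 10.0
) -> list[CellTrack]:
    """Greedy nearest-centroid linking of per-frame ROI measurements.

    Candidate (track, ROI) pairs within the gate are matched in order of
    increasing distance, ties broken by smaller ROI id then track id.
    Unmatched open tracks are closed (death at the current frame);
    unmatched ROIs start new tracks.
    """
    if not frames:
        raise ValueError("need at least one frame")
    tracks: list[CellTrack] = []
    open_tracks: list[CellTrack] = []
    next_id = 1
    for fi, rois in enumerate(frames):
        if fi == 0:
            for m in rois:
                t = CellTrack(next_id, [m], birth_frame=m.frame)
                next_id += 1
                tracks.append(t)
                open_tracks.append(t)
            continue
        pairs = []
        for ti, t in enumerate(open_tracks):
            cy, cx = t.measurements[-1].centroid
            for ri, m in enumerate(rois):
                d = float(np.hypot(m.centroid[0] - cy, m.centroid[1] - cx))
                if d <= max_displacement:
                    pairs.append((d, m.roi, t.track_id, ti, ri))
        pairs.sort()
        used_t: set[int] = set()
        used_r: set[int] = set()
        for d, _, _, ti, ri in pairs:
            if ti in used_t or ri in used_r:
                continue
            open_tracks[ti].append(rois[ri])
            used_t.add(ti)
            used_r.add(ri)
        still_open: list[CellTrack] = []
        for ti, t in enumerate(open_tracks):
            if ti in used_t:
                still_open.append(t)
            else:
                t.death_frame = rois[0].frame if rois else fi
        for ri, m in enumerate(rois):
            if ri not in used_r:
                t = CellTrack(next_id, [m], birth_frame=m.frame)
                next_id += 1
                tracks.append(t)
                still_open.append(t)
        open_tracks = still_open
    return tracks


def detect_transitions(track: CellTrack, debounce: int = 1) -> list[TransitionEvent]:
    """Emit a transition whenever the state changes and persists.

    Indeterminate frames carry the previous definite state.  A change must
    persist for at least ``debounce`` consecutive measured frames before it
    is emitted (default 1: every definite change counts).
    """
    if not track.measurements:
        raise ValueError("track is empty")
    events: list[TransitionEvent] = []
    definite = [
        (m.frame, m.state) for m in track.measurements if m.state != INDETERMINATE
    ]
    if not definite:
        return events
    cur_frame, cur_state = definite[0]
    i = 1
    while i < len(definite):
        frame, state = definite[i]
        if state != cur_state:
            # require persistence over the debounce window
            run = definite[i : i + debounce]
            if len(run) >= debounce and all(s == state for _, s in run):
                events.append(
                    TransitionEvent(
                        track=track.track_id,
                        frame_from=cur_frame,
                        frame_to=frame,
                        direction=G_TO_O if state == OXPHOS else O_TO_G,
                    )
                )
                cur_state = state
                cur_frame = frame
            # a non-persistent blip is ignored; keep the previous state
            else:
                cur_frame = cur_frame
        else:
            cur_frame = frame
        i += 1
    return events


def population_timecourse(tracks: list[CellTrack]) -> pd.DataFrame:
    """Per-frame population state counts, percentages, and survival.

    Survival is live tracks at a frame over tracks at the first frame.
    Empty frames report NaN percentages.
    """
    if not tracks:
        raise ValueError("need at least one track")
    all_frames = sorted({m.frame for t in tracks for m in t.measurements})
    rows = []
    n0 = None
    for f in all_frames:
        states = [
            m.state for t in tracks for m in t.measurements if m.frame == f
        ]
        n = len(states)
        if n0 is None:
            n0 = n
        n_ox = states.count(OXPHOS)
        n_gl = states.count(GLYCOLYTIC)
        n_in = states.count(INDETERMINATE)
        rows.append(
            {
                "frame": f,
                "n_cells": n,
                "n_oxphos": n_ox,
                "n_glycolytic": n_gl,
                "n_indeterminate": n_in,
                "pct_oxphos": 100.0 * n_ox / n if n else np.nan,
                "pct_glycolytic": 100.0 * n_gl / n if n else np.nan,
                "pct_indeterminate": 100.0 * n_in / n if n else np.nan,
                "survival": n / n0 if n0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
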