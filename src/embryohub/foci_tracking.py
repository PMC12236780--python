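"""Nucleus tracking, LoG focus detection, and ON/OFF state calling.

The transcription readout is binary: a nucleus is ON at a frame when at
least one reporter (MCP) focus falls inside its (dilated) label.  Nuclei
are linked across frames by greedy nearest-centroid assignment and only
tracks present in every frame are retained, so cumulative ON/OFF curves
have a fixed denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

from .masking import LabelMovie

__all__ = [
    "NucleusTrack",
    "FocusEvent",
    "StateTrace",
    "link_nuclei",
    "detect_foci_log",
    "assign_foci",
    "call_states",
    "cumulative_transitions",
]


@dataclass
class NucleusTrack:
    """A nucleus identity followed across frames."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)  # per-frame region label
    centroids: list[tuple[float, float]] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return len(self.frames) > 0 and self.frames == list(
            range(self.frames[0], self.frames[-1] + 1)
        )


@dataclass
class FocusEvent:
    """A single scale-space blob detection."""

    frame: int
    y: float
    x: float
    sigma: float
    response: float
    nucleus: int | None = None  # filled by assign_foci; None = unassigned


@dataclass
class StateTrace:
    """Per-nucleus boolean ON series with derived transition frames."""

    track_id: int
    on: np.ndarray
    first_on: int | None
    first_off_after_on: int | None


def link_nuclei(labels: LabelMovie, max_displacement: float) -> list[NucleusTrack]:
    """Greedy nearest-centroid linking; keep only full-length tracks.

    Frame-to-frame assignments are made in order of increasing centroid
    distance, each capped at ``max_displacement``.  Tracks missing from any
    frame are discarded.
    """
    n_frames = labels.data.shape[0]
    per_frame = [
        labels.regions[labels.regions["frame"] == t] for t in range(n_frames)
    ]
    tracks: list[NucleusTrack] = []
    if n_frames == 0 or len(per_frame[0]) == 0:
        return []
    for i, row in enumerate(per_frame[0].itertuples()):
        tracks.append(
            NucleusTrack(
                track_id=i + 1,
                frames=[0],
                labels=[int(row.label)],
                centroids=[(float(row.centroid_y), float(row.centroid_x))],
            )
        )
    active = list(range(len(tracks)))
    for t in range(1, n_frames):
        df = per_frame[t]
        if len(df) == 0 or not active:
            active = []
            break
        prev = np.array([tracks[i].centroids[-1] for i in active])
        cur = df[["centroid_y", "centroid_x"]].to_numpy(dtype=float)
        cur_labels = df["label"].to_numpy()
        dist = cdist(prev, cur)
        dist[dist > max_displacement] = np.inf
        assigned_prev: set[int] = set()
        assigned_cur: set[int] = set()
        order = np.argsort(dist, axis=None)
        for flat in order:
            i, j = np.unravel_index(flat, dist.shape)
            if not np.isfinite(dist[i, j]):
                break
            if i in assigned_prev or j in assigned_cur:
                continue
            tr = tracks[active[i]]
            tr.frames.append(t)
            tr.labels.append(int(cur_labels[j]))
            tr.centroids.append((float(cur[j, 0]), float(cur[j, 1])))
            assigned_prev.add(int(i))
            assigned_cur.add(int(j))
        active = [active[i] for i in sorted(assigned_prev)]
    complete = [
        tr for tr in tracks if len(tr.frames) == n_frames and tr.frames[0] == 0
    ]
    return complete


def _log_response(image: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalised negative Laplacian of Gaussian (bright blobs > 0)."""
    return -(sigma**2) * ndi.gaussian_laplace(np.asarray(image, float), sigma)


def detect_foci_log(
    image: np.ndarray,
    sigma_range: tuple[float, float] = (1.5, 4.0),
    n_sigma: int = 6,
    threshold: float = 1.0,
    frame: int = 0,
) -> list[FocusEvent]:
    """Laplacian-of-Gaussian blob detection on a 2-D image.

    The scale-normalised LoG response ``-sigma^2 * LoG(image)`` is computed
    over a geometric ladder of ``n_sigma`` scales in ``sigma_range``; local
    maxima of the (y, x, scale) stack above ``threshold`` become events.
    """
    lo, hi = sigma_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid sigma_range {sigma_range}")
    sigmas = np.geomspace(lo, hi, n_sigma) if n_sigma > 1 else np.array([lo])
    stack = np.stack([_log_response(image, s) for s in sigmas])
    footprint = np.ones((3, 3, 3) if len(sigmas) > 1 else (1, 3, 3))
    maxima = ndi.maximum_filter(stack, footprint=footprint, mode="constant")
    peaks = (stack == maxima) & (stack > threshold)
    events = []
    for k, y, x in zip(*np.nonzero(peaks)):
        events.append(
            FocusEvent(
                frame=frame,
                y=float(y),
                x=float(x),
                sigma=float(sigmas[k]),
                response=float(stack[k, y, x]),
            )
        )
    return events


def assign_foci(
    foci: list[FocusEvent], labels: LabelMovie
) -> list[FocusEvent]:
    """Assign each focus to the label containing its coordinates.

    Labels are expected to be pre-dilated by the segmentation step so foci
    at the nuclear periphery land inside.  Foci on background get
    ``nucleus=None``.
    """
    out = []
    for ev in foci:
        lab = int(labels.data[ev.frame, int(round(ev.y)), int(round(ev.x))])
        out.append(
            FocusEvent(
                frame=ev.frame,
                y=ev.y,
                x=ev.x,
                sigma=ev.sigma,
                response=ev.response,
                nucleus=lab if lab > 0 else None,
            )
        )
    return out


def call_states(
    tracks: list[NucleusTrack],
    assigned_foci: list[FocusEvent],
    debounce: int = 1,
) -> list[StateTrace]:
    """Per-nucleus ON/OFF series from focus presence.

    ``on[t]`` is True when >=1 focus is assigned to the track's label at
    frame t.  ``first_off_after_on`` is recorded at the start of the first
    run of >= ``debounce`` consecutive OFF frames after ``first_on``.
    """
    by_frame_label: set[tuple[int, int]] = {
        (ev.frame, ev.nucleus) for ev in assigned_foci if ev.nucleus is not None
    }
    traces = []
    for tr in tracks:
        if not tr.complete:
            raise ValueError(f"track {tr.track_id} is not complete")
        on = np.array(
            [(t, lab) in by_frame_label for t, lab in zip(tr.frames, tr.labels)]
        )
        first_on = int(np.argmax(on)) if on.any() else None
        first_off = None
        if first_on is not None:
            run = 0
            for t in range(first_on + 1, len(on)):
                if not on[t]:
                    run += 1
                    if run >= debounce:
                        first_off = t - run + 1
                        break
                else:
                    run = 0
        traces.append(
            StateTrace(
                track_id=tr.track_id,
                on=on,
                first_on=first_on,
                first_off_after_on=first_off,
            )
        )
    return traces


def cumulative_transitions(
    traces: list[StateTrace], s_start: int, n_frames: int | None = None
) -> pd.DataFrame:
    """Cumulative ON and OFF percentages versus time since S-phase entry.

    ON%% at frame t = share of retained nuclei whose first focus appeared
    at or before t; OFF%% = share that subsequently lost their foci by t.
    Both use all retained nuclei as the denominator.  Columns: frame
    (relative to ``s_start``), time_s is left to the caller, on_pct,
    off_pct.
    """
    if not traces:
        raise ValueError("no state traces supplied")
    if n_frames is None:
        n_frames = len(traces[0].on)
    n = len(traces)
    on_counts = np.zeros(n_frames)
    off_counts = np.zeros(n_frames)
    for tr in traces:
        if tr.first_on is not None and tr.first_on - s_start < n_frames:
            on_counts[max(tr.first_on - s_start, 0) :] += 1
        if (
            tr.first_off_after_on is not None
            and tr.first_off_after_on - s_start < n_frames
        ):
            off_counts[max(tr.first_off_after_on - s_start, 0) :] += 1
    return pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "on_pct": 100.0 * on_counts / n,
            "off_pct": 100.0 * off_counts / n,
        }
    )
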