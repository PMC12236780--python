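"""Dual 5'/3' (MS2/PP7) transcription-spot analysis.

Nascent-transcript spots are detected on the sum of both reporter
channels (so a spot visible in either channel is found), quantified with
a 17x17-pixel window against a local 31x31 background, linked across
frames with gap closing (up to 5 missing frames), filtered, sorted by
emergence time, and laid out as track-by-time montages.  The lag between
5' (MCP) and 3' (PCP) signal onset within a track reads out elongation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

from .image_io import Projection

__all__ = [
    "SpotDetection",
    "SpotTrack",
    "Montage",
    "detect_spots_dog",
    "quantify_spot",
    "link_spots",
    "filter_tracks",
    "sort_tracks",
    "build_montage",
]

INNER = 17  # quantification window side, pixels
OUTER = 31  # background window side, pixels


@dataclass
class SpotDetection:
    frame: int
    y: float
    x: float
    response: float


@dataclass
class SpotTrack:
    """A gap-linked spot trajectory with per-channel quantification.

    Per-frame arrays are aligned with ``frames`` (detected frames only; gap
    frames carry no entries).  ``corrected[c] = raw_mean[c] - background[c]``.
    """

    track_id: int
    frames: list[int] = field(default_factory=list)
    ys: list[float] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    raw_mean: dict[str, list[float]] = field(default_factory=dict)
    background: dict[str, list[float]] = field(default_factory=dict)
    corrected: dict[str, list[float]] = field(default_factory=dict)
    border_touching: bool = False

    @property
    def first_appearance(self) -> int:
        return self.frames[0]

    def total(self, channel: str) -> float:
        """Summed corrected intensity of a channel over the track."""
        return float(np.sum(self.corrected.get(channel, [])))


@dataclass
class Montage:
    """Track-by-time tile grid, one per channel; tiles are 17x17 px."""

    data: np.ndarray  # (n_tracks * 17, n_frames * 17)
    channel: str
    n_tracks: int
    n_frames: int


def detect_spots_dog(
    proj: Projection,
    channels: tuple[int, int],
    blur_sigma: float = 1.0,
    dog_sigmas: tuple[float, float] = (1.5, 3.0),
    threshold: float = 1.0,
) -> list[SpotDetection]:
    """Difference-of-Gaussians spot detection on the summed channels.

    Per frame the two channels are summed and blurred; the DoG response
    ``G(s0)*I - G(s1)*I`` is computed and its local maxima above
    ``threshold`` are reported.
    """
    s0, s1 = dog_sigmas
    if not (0 < s0 < s1):
        raise ValueError(f"dog_sigmas must be increasing and positive, got {dog_sigmas}")
    c0, c1 = channels
    detections: list[SpotDetection] = []
    for t in range(proj.n_frames):
        summed = proj.data[t, c0].astype(float) + proj.data[t, c1].astype(float)
        if blur_sigma > 0:
            summed = ndi.gaussian_filter(summed, blur_sigma)
        dog = ndi.gaussian_filter(summed, s0) - ndi.gaussian_filter(summed, s1)
        maxima = ndi.maximum_filter(dog, size=3, mode="constant")
        peaks = (dog == maxima) & (dog > threshold)
        for y, x in zip(*np.nonzero(peaks)):
            detections.append(
                SpotDetection(frame=t, y=float(y), x=float(x), response=float(dog[y, x]))
            )
    return detections


def quantify_spot(
    image: np.ndarray, y: float, x: float, background_mode: str = "annulus"
) -> tuple[float, float, float, bool]:
    """Quantify one spot on one channel's frame.

    Returns ``(raw_mean, background, corrected, border_touching)``.
    ``raw_mean`` is the mean of the 17x17 square centred on (y, x);
    ``background`` the mean of the 31x31 square either excluding the inner
    17x17 (``"annulus"``, default) or including it (``"full"``);
    ``corrected = raw_mean - background`` and may be negative.  If the
    31x31 window leaves the image the spot is flagged border-touching and
    NaNs are returned.
    """
    if background_mode not in ("annulus", "full"):
        raise ValueError(f"unknown background_mode {background_mode!r}")
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    cy, cx = int(round(y)), int(round(x))
    ho = OUTER // 2
    hi = INNER // 2
    if cy - ho < 0 or cx - ho < 0 or cy + ho >= ny or cx + ho >= nx:
        return (np.nan, np.nan, np.nan, True)
    outer = image[cy - ho : cy + ho + 1, cx - ho : cx + ho + 1]
    inner = image[cy - hi : cy + hi + 1, cx - hi : cx + hi + 1]
    raw = float(inner.mean())
    if background_mode == "full":
        bg = float(outer.mean())
    else:
        total = outer.sum() - inner.sum()
        bg = float(total / (OUTER * OUTER - INNER * INNER))
    return (raw, bg, raw - bg, False)


def link_spots(
    detections: list[SpotDetection],
    max_displacement: float = 10.0,
    max_gap: int = 5,
) -> list[SpotTrack]:
    """Greedy nearest-neighbour linking with gap closing.

    A track may skip up to ``max_gap`` consecutive frames without a
    detection (a gap of exactly ``max_gap`` still links; one more splits
    the track).  Positions during gaps are not interpolated.  Each
    detection joins at most one track.
    """
    by_frame: dict[int, list[SpotDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    if not by_frame:
        return []
    tracks: list[SpotTrack] = []
    open_tracks: list[SpotTrack] = []
    next_id = 1
    for t in sorted(by_frame):
        dets = by_frame[t]
        # close tracks whose last detection is too old to bridge
        still_open = []
        for tr in open_tracks:
            if t - tr.frames[-1] - 1 > max_gap:
                tracks.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        if open_tracks:
            prev = np.array([(tr.ys[-1], tr.xs[-1]) for tr in open_tracks])
            cur = np.array([(d.y, d.x) for d in dets])
            dist = cdist(prev, cur)
            dist[dist > max_displacement] = np.inf
            used_tr: set[int] = set()
            used_det: set[int] = set()
            for flat in np.argsort(dist, axis=None):
                i, j = np.unravel_index(flat, dist.shape)
                if not np.isfinite(dist[i, j]):
                    break
                if i in used_tr or j in used_det:
                    continue
                tr = open_tracks[i]
                tr.frames.append(t)
                tr.ys.append(dets[j].y)
                tr.xs.append(dets[j].x)
                used_tr.add(int(i))
                used_det.add(int(j))
        else:
            used_det = set()
        for j, d in enumerate(dets):
            if j not in used_det:
                open_tracks.append(
                    SpotTrack(track_id=next_id, frames=[t], ys=[d.y], xs=[d.x])
                )
                next_id += 1
    tracks.extend(open_tracks)
    tracks.sort(key=lambda tr: tr.track_id)
    return tracks


def quantify_tracks(
    tracks: list[SpotTrack],
    proj: Projection,
    channels: dict[str, int],
    background_mode: str = "annulus",
) -> list[SpotTrack]:
    """Fill per-channel raw/background/corrected series for each track."""
    for tr in tracks:
        for name in channels:
            tr.raw_mean[name] = []
            tr.background[name] = []
            tr.corrected[name] = []
        for t, y, x in zip(tr.frames, tr.ys, tr.xs):
            for name, c in channels.items():
                raw, bg, corr, border = quantify_spot(
                    proj.data[t, c], y, x, background_mode
                )
                tr.raw_mean[name].append(raw)
                tr.background[name].append(bg)
                tr.corrected[name].append(corr)
                if border:
                    tr.border_touching = True
    return tracks


def filter_tracks(tracks: list[SpotTrack]) -> list[SpotTrack]:
    """Drop single-frame tracks and tracks ever flagged border-touching."""
    return [
        tr for tr in tracks if len(tr.frames) > 1 and not tr.border_touching
    ]


def sort_tracks(tracks: list[SpotTrack], pcp_channel: str = "pcp") -> list[SpotTrack]:
    """Stable sort: first appearance ascending, then total PCP descending."""
    return sorted(
        tracks, key=lambda tr: (tr.first_appearance, -tr.total(pcp_channel))
    )


def onset_lag(
    track: SpotTrack,
    mcp_channel: str = "mcp",
    pcp_channel: str = "pcp",
    threshold: float = 5.0,
) -> int | None:
    """3'-minus-5' onset lag of a track, in frames.

    Onset of a channel is the first detected frame whose corrected
    intensity exceeds ``threshold``; None when either channel never rises
    (e.g. elongation-defective spots that never acquire 3' signal).
    """
    m_on = p_on = None
    for i, t in enumerate(track.frames):
        if m_on is None and track.corrected[mcp_channel][i] > threshold:
            m_on = t
        if p_on is None and track.corrected[pcp_channel][i] > threshold:
            p_on = t
    if m_on is None or p_on is None:
        return None
    return p_on - m_on


def median_onset_lag(
    tracks: list[SpotTrack],
    mcp_channel: str = "mcp",
    pcp_channel: str = "pcp",
    threshold: float = 5.0,
) -> float:
    """Median onset lag over tracks where both channels turned on."""
    lags = [
        lag
        for tr in tracks
        if (lag := onset_lag(tr, mcp_channel, pcp_channel, threshold)) is not None
    ]
    if not lags:
        raise ValueError("no track shows onset in both channels")
    return float(np.median(lags))


def build_montage(
    proj: Projection,
    tracks: list[SpotTrack],
    channel: int,
    channel_name: str | None = None,
    n_tracks: int = 50,
    t_origin: int | None = None,
) -> Montage:
    """Track-by-time montage of 17x17 crops for one channel.

    Rows are the first ``n_tracks`` tracks (in the given order), columns
    are frames from ``t_origin`` (default: the earliest first appearance
    among the used tracks, i.e. the embryo-wide emergence time).  During
    gaps the last known position is cropped; columns before a track's
    first appearance are blank.
    """
    use = tracks[: min(n_tracks, len(tracks))]
    if not use:
        raise ValueError("no tracks to montage")
    if t_origin is None:
        t_origin = min(tr.first_appearance for tr in use)
    n_frames = proj.n_frames - t_origin
    grid = np.zeros((len(use) * INNER, n_frames * INNER), dtype=float)
    h = INNER // 2
    for r, tr in enumerate(use):
        pos = dict(zip(tr.frames, zip(tr.ys, tr.xs)))
        last = None
        for t in range(t_origin, proj.n_frames):
            if t in pos:
                last = pos[t]
            if last is None or t < tr.first_appearance:
                continue
            cy, cx = int(round(last[0])), int(round(last[1]))
            tile = proj.data[
                t, channel, cy - h : cy + h + 1, cx - h : cx + h + 1
            ]
            if tile.shape != (INNER, INNER):
                continue  # border crop; track should have been filtered
            col = t - t_origin
            grid[r * INNER : (r + 1) * INNER, col * INNER : (col + 1) * INNER] = tile
    return Montage(
        data=grid,
        channel=channel_name or proj.channel_names[channel],
        n_tracks=len(use),
        n_frames=n_frames,
    )
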