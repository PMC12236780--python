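"""Ground-truthed synthetic syncytial-embryo movies.

The simulator emulates the fluorescence dynamics of the early Drosophila
blastoderm as seen in max-projected spinning-disk movies: nuclear division
cycles that alternate S phase and mitosis with no gap phases, nucleus
doubling at each division, S-phase lengthening across cycles, bookmark
(Brd4-like) foci that persist through mitosis and disperse within about a
minute of S-phase onset, transient kinase (Cdc7-like) co-clusters at
S-phase entry, polymerase-like foci appearing a couple of minutes into S
phase, and telegraph (ON/OFF) transcription read out by 5' (MS2/MCP) and
3' (PP7/PCP) reporter foci separated by a fixed elongation delay.

Every rendered structure is logged to a :class:`GroundTruth` so each
analysis stage can be scored against the truth.  With a fixed seed the
movie and truth are bit-identical across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import MovieStack

__all__ = [
    "SimConfig",
    "CycleAnnotation",
    "GroundTruth",
    "schedule_cycles",
    "simulate_embryo_movie",
    "write_ground_truth",
    "read_ground_truth",
]

CHANNELS = ("histone", "bookmark", "kinase", "polymerase", "mcp", "pcp")


@dataclass
class SimConfig:
    """Parameters of a synthetic embryo movie.

    Times are in seconds unless stated otherwise.  Defaults reproduce an
    NC12->NC13-like pair of cycles at a 20-s frame interval: S phases of
    8.5 then 15.5 minutes separated by 3-minute mitoses, transcription
    turning on about 3 minutes into each S phase, and a 3'-reporter signal
    lagging the 5' signal by 10 frames (about 3.5 minutes).
    """

    shape: tuple[int, int] = (256, 256)
    frame_interval: float = 20.0
    #: per-cycle (S minutes, M minutes); the movie ends after the last block
    cycles: tuple[tuple[float, float], ...] = ((8.5, 3.0), (15.5, 3.0))
    n_initial_nuclei: int = 10
    nuclear_radius: float = 12.0
    #: nuclear radius shrink factor applied at each division
    radius_decay: float = 0.82
    drift_px_per_frame: float = 0.25
    channels: tuple[str, ...] = CHANNELS

    # rendering amplitudes (arbitrary units above a flat background)
    background: float = 5.0
    body_amplitudes: dict = field(
        default_factory=lambda: {
            "histone": 40.0,
            "bookmark": 10.0,
            "kinase": 8.0,
            "polymerase": 15.0,
            "mcp": 6.0,
            "pcp": 6.0,
        }
    )
    focus_amplitudes: dict = field(
        default_factory=lambda: {
            "bookmark": 60.0,
            "kinase": 50.0,
            "polymerase": 50.0,
            "mcp": 80.0,
            "pcp": 80.0,
        }
    )
    mitotic_condensation: float = 0.55  # chromosome blob radius / nuclear radius
    mitotic_gain: float = 1.6  # condensed-chromatin brightness factor

    # hub (focus) kinetics
    foci_per_nucleus: int = 2
    focus_sigma: float = 2.0
    hub_appear_s: float = 120.0  # bookmark hubs emerge ~2 min into S phase
    mitotic_persistence: bool = True  # bookmark foci persist through mitosis
    bookmark_dispersal_s: float = 60.0  # gone within ~1 min of next S onset
    #: per-cycle multiplicative gain on bookmark focus amplitude (bookmarks
    #: become more prominent in successive cycles)
    bookmark_cycle_gain: float = 1.4
    kinase_lead_s: float = 40.0  # kinase foci appear this long before S onset
    kinase_disperse_s: float = 60.0  # and disperse ~1 min into S phase
    polymerase_delay_s: float = 120.0  # polymerase foci ~2 min into S phase

    # telegraph transcription kinetics: ON waiting time after S-phase start
    # is shift + Exponential(mean); OFF events are geometric per frame
    on_shift_s: float = 120.0
    on_mean_s: float = 60.0
    off_prob_per_frame: float = 0.01
    elongation_delay_frames: int = 10

    # noise: Poisson(signal * photon_scale) / photon_scale + N(0, read_noise)
    photon_scale: float | None = 200.0
    read_noise_sigma: float = 2.0

    rng_seed: int = 0
    preset: str = "none"

    def __post_init__(self) -> None:
        if self.preset not in ("none", "cdc7i"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if any(s <= 0 or m <= 0 for s, m in self.cycles):
            raise ValueError("cycle durations must be positive")
        if self.frame_interval <= 0 or self.nuclear_radius <= 0:
            raise ValueError("frame_interval and nuclear_radius must be positive")
        if not 0.0 <= self.off_prob_per_frame <= 1.0:
            raise ValueError("off_prob_per_frame must be a probability")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}")

    def resolved(self) -> "SimConfig":
        """Apply the perturbation preset, returning the effective config.

        The ``cdc7i`` preset mimics Cdc7 inhibition: kinase recruitment is
        delayed, weakened and prolonged, bookmark foci persist well into S
        phase, and transcription becomes delayed and transient.
        """
        if self.preset != "cdc7i":
            return self
        eff = dataclasses.replace(
            self,
            kinase_lead_s=10.0,
            kinase_disperse_s=180.0,
            bookmark_dispersal_s=240.0,
            on_shift_s=self.on_shift_s + 120.0,
            on_mean_s=self.on_mean_s * 3.0,
            off_prob_per_frame=0.10,
        )
        eff.focus_amplitudes = dict(self.focus_amplitudes)
        eff.focus_amplitudes["kinase"] = self.focus_amplitudes["kinase"] * 0.5
        eff.focus_amplitudes["pcp"] = self.focus_amplitudes["pcp"] * 0.5
        return eff


@dataclass
class CycleAnnotation:
    """Per-frame phase labels and cycle boundary frames."""

    phase: np.ndarray  # array of "S"/"M" strings, one per frame
    s_starts: list[int]
    m_starts: list[int]
    cycle_index: np.ndarray  # 0-based cycle id per frame

    @property
    def n_frames(self) -> int:
        return len(self.phase)


@dataclass
class GroundTruth:
    """Everything the simulator rendered, as tidy tables.

    nuclei:  frame, track_id, y, x, radius, phase, cycle
    foci:    frame, track_id, channel, y, x, amplitude
    states:  frame, track_id, on (bool)
    events:  track_id, first_on (frame or -1), first_off_after_on (frame or -1)
    spots:   frame, track_id, y, x, mcp_true, pcp_true  (per transcription spot)
    cycles:  cycle, s_start, m_start, s_frames, m_frames
    """

    nuclei: pd.DataFrame
    foci: pd.DataFrame
    states: pd.DataFrame
    events: pd.DataFrame
    spots: pd.DataFrame
    cycles: pd.DataFrame


def schedule_cycles(config: SimConfig) -> CycleAnnotation:
    """Partition frames into alternating S and M blocks.

    Each cycle contributes an S block followed by an M block; durations are
    converted to whole frames (rounded to nearest).  The nucleus count
    doubles at each M->S boundary (enforced by the simulator).
    """
    phases: list[str] = []
    cyc_idx: list[int] = []
    s_starts, m_starts = [], []
    for i, (s_min, m_min) in enumerate(config.cycles):
        s_frames = max(1, int(round(s_min * 60.0 / config.frame_interval)))
        m_frames = max(1, int(round(m_min * 60.0 / config.frame_interval)))
        s_starts.append(len(phases))
        phases.extend("S" * s_frames)
        m_starts.append(len(phases))
        phases.extend("M" * m_frames)
        cyc_idx.extend([i] * (s_frames + m_frames))
    return CycleAnnotation(
        phase=np.array(phases),
        s_starts=s_starts,
        m_starts=m_starts,
        cycle_index=np.array(cyc_idx),
    )


def _hex_lattice(
    n: int, shape: tuple[int, int], radius: float, rng, margin_extra: float = 0.0
) -> np.ndarray:
    """Jittered hexagonal lattice of n points with minimum separation."""
    ny, nx = shape
    margin = radius + 2 + margin_extra
    spacing = max(
        2.2 * radius,
        np.sqrt((ny - 2 * margin) * (nx - 2 * margin) / max(n, 1) / 0.866),
    )
    pts = []
    row = 0
    y = margin
    while y < ny - margin:
        offset = (spacing / 2) if row % 2 else 0.0
        x = margin + offset
        while x < nx - margin:
            pts.append((y, x))
            x += spacing
        y += spacing * 0.866
        row += 1
    pts = np.asarray(pts, dtype=float)
    if len(pts) < n:
        raise ValueError(
            f"cannot place {n} nuclei of radius {radius} in image {shape}"
        )
    order = rng.permutation(len(pts))[:n]
    pts = pts[np.sort(order)]
    jitter = rng.uniform(-0.25 * spacing, 0.25 * spacing, size=pts.shape)
    pts = pts + jitter
    pts[:, 0] = np.clip(pts[:, 0], margin, ny - margin - 1)
    pts[:, 1] = np.clip(pts[:, 1], margin, nx - margin - 1)
    return pts


def _soft_disk(patch_shape, cy, cx, radius, amplitude, softness=1.5):
    """Analytic smoothed-disk profile: amp / (1 + exp((r - R)/softness))."""
    yy, xx = np.mgrid[0 : patch_shape[0], 0 : patch_shape[1]]
    r = np.hypot(yy - cy, xx - cx)
    return amplitude / (1.0 + np.exp((r - radius) / softness))


def _gaussian_spot(patch_shape, cy, cx, sigma, amplitude):
    yy, xx = np.mgrid[0 : patch_shape[0], 0 : patch_shape[1]]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return amplitude * np.exp(-d2 / (2.0 * sigma**2))


def _add_patch(img, cy, cx, extent, render):
    """Render a local patch centred at (cy, cx) and add it into img."""
    ny, nx = img.shape
    y0, y1 = int(np.floor(cy - extent)), int(np.ceil(cy + extent)) + 1
    x0, x1 = int(np.floor(cx - extent)), int(np.ceil(cx + extent)) + 1
    y0c, y1c = max(y0, 0), min(y1, ny)
    x0c, x1c = max(x0, 0), min(x1, nx)
    if y0c >= y1c or x0c >= x1c:
        return
    patch = render((y1c - y0c, x1c - x0c), cy - y0c, cx - x0c)
    img[y0c:y1c, x0c:x1c] += patch


class _Nucleus:
    __slots__ = ("track_id", "pos", "radius", "focus_offsets", "drift")

    def __init__(self, track_id, pos, radius, focus_offsets, drift):
        self.track_id = track_id
        self.pos = np.asarray(pos, dtype=float)
        self.radius = radius
        self.focus_offsets = focus_offsets  # (k, 2) offsets from centre
        self.drift = np.asarray(drift, dtype=float)


def _relax_positions(
    nuclei, radius, shape, margin, min_sep_factor=2.1, n_iter=40
):
    """Push overlapping nuclei apart until centre separations reach
    ``min_sep_factor * radius`` (deterministic pairwise relaxation).

    Real blastoderm nuclei pack densely but do not interpenetrate; after a
    division daughters from different parents can land too close, which
    this pass resolves.  ``margin`` keeps centres away from the borders.
    """
    min_sep = min_sep_factor * radius
    ny, nx = shape
    pos = np.array([n.pos for n in nuclei])
    for _ in range(n_iter):
        moved = False
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = pos[j] - pos[i]
                dist = np.linalg.norm(d)
                if dist >= min_sep:
                    continue
                moved = True
                if dist < 1e-6:
                    d = np.array([1.0, 0.0])
                    dist = 1.0
                shift = (min_sep - dist) / 2.0 * d / dist
                pos[i] -= shift
                pos[j] += shift
        pos[:, 0] = np.clip(pos[:, 0], margin, ny - margin - 1)
        pos[:, 1] = np.clip(pos[:, 1], margin, nx - margin - 1)
        if not moved:
            break
    for n, p in zip(nuclei, pos):
        n.pos = p


def _draw_focus_offsets(rng, k, radius):
    """Fixed sub-nuclear focus positions, within 0.6 R of the centre."""
    ang = rng.uniform(0, 2 * np.pi, size=k)
    rad = rng.uniform(0.2, 0.6, size=k) * radius
    return np.stack([rad * np.sin(ang), rad * np.cos(ang)], axis=1)


def simulate_embryo_movie(config: SimConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a synthetic embryo movie and its ground truth.

    All stochastic draws consume a single generator seeded from
    ``config.rng_seed`` in a fixed order (geometry, kinetics, then noise),
    so identical configs give bit-identical output.
    """
    eff = config.resolved()
    rng = np.random.default_rng(eff.rng_seed)
    ann = schedule_cycles(eff)
    n_frames = ann.n_frames
    ny, nx = eff.shape
    dt = eff.frame_interval
    n_ch = len(eff.channels)

    # --- geometry: nuclei per cycle (doubling at each division) ---------
    # Nuclei share one slow flow vector per movie (syncytial nuclei move
    # coherently with the cytoplasm rather than independently); placement
    # margins reserve the whole-movie drift budget so nuclei never leave
    # the field or hit the X-Y border mid-track.
    per_cycle_nuclei: list[list[_Nucleus]] = []
    radius = eff.nuclear_radius
    flow_angle = rng.uniform(0, 2 * np.pi)
    flow = (
        np.array([np.sin(flow_angle), np.cos(flow_angle)])
        * eff.drift_px_per_frame
    )
    drift_budget = eff.drift_px_per_frame * n_frames
    pts = _hex_lattice(
        eff.n_initial_nuclei, eff.shape, radius, rng, margin_extra=drift_budget
    )
    next_id = 1
    nuclei = []
    for p in pts:
        nuclei.append(
            _Nucleus(
                next_id,
                p,
                radius,
                _draw_focus_offsets(rng, eff.foci_per_nucleus, radius),
                flow,
            )
        )
        next_id += 1
    per_cycle_nuclei.append(nuclei)
    for _cycle in range(1, len(eff.cycles)):
        radius *= eff.radius_decay
        margin = radius + 2 + drift_budget
        daughters = []
        for nuc in per_cycle_nuclei[-1]:
            axis = rng.uniform(0, 2 * np.pi)
            sep = 1.1 * radius  # daughters end up ~2.2 radii apart
            d = np.array([np.sin(axis), np.cos(axis)]) * sep
            for sgn in (+1.0, -1.0):
                pos = nuc.pos + sgn * d
                pos[0] = np.clip(pos[0], margin, ny - margin - 1)
                pos[1] = np.clip(pos[1], margin, nx - margin - 1)
                daughters.append(
                    _Nucleus(
                        next_id,
                        pos,
                        radius,
                        _draw_focus_offsets(rng, eff.foci_per_nucleus, radius),
                        flow,
                    )
                )
                next_id += 1
        _relax_positions(daughters, radius, eff.shape, margin)
        per_cycle_nuclei.append(daughters)

    # --- transcription kinetics per cycle -------------------------------
    # ON waiting time after S start: shift + Exp(mean); OFF geometric.
    on_frame: dict[tuple[int, int], int] = {}  # (cycle, track) -> frame
    off_frame: dict[tuple[int, int], int] = {}
    for ci in range(len(eff.cycles)):
        s0 = ann.s_starts[ci]
        s_end = ann.m_starts[ci]
        for nuc in per_cycle_nuclei[ci]:
            wait_s = eff.on_shift_s + rng.exponential(eff.on_mean_s)
            f_on = s0 + int(np.ceil(wait_s / dt))
            if f_on >= s_end:
                continue
            on_frame[(ci, nuc.track_id)] = f_on
            # geometric OFF: first failure among the remaining S frames
            if eff.off_prob_per_frame > 0:
                n_rem = s_end - f_on - 1
                draws = rng.uniform(size=n_rem) if n_rem > 0 else np.array([])
                hits = np.nonzero(draws < eff.off_prob_per_frame)[0]
                if hits.size:
                    off_frame[(ci, nuc.track_id)] = f_on + 1 + int(hits[0])

    # --- per-frame rendering + truth logging ----------------------------
    movie = np.zeros((n_frames, 1, n_ch, ny, nx), dtype=float)
    nuc_rows, foci_rows, state_rows, spot_rows = [], [], [], []
    ch_index = {ch: i for i, ch in enumerate(eff.channels)}

    hub_appear_f = int(np.ceil(eff.hub_appear_s / dt))
    disp_f = max(1, int(np.ceil(eff.bookmark_dispersal_s / dt)))
    kin_lead_f = int(np.ceil(eff.kinase_lead_s / dt))
    kin_disp_f = int(np.ceil(eff.kinase_disperse_s / dt))
    pol_delay_f = int(np.ceil(eff.polymerase_delay_s / dt))
    cycle_ends = [
        int(np.max(np.nonzero(ann.cycle_index == ci)[0])) + 1
        for ci in range(len(eff.cycles))
    ]

    for t in range(n_frames):
        ci = int(ann.cycle_index[t])
        phase = str(ann.phase[t])
        s0, m0 = ann.s_starts[ci], ann.m_starts[ci]
        frame = movie[t, 0]
        frame += eff.background
        for nuc in per_cycle_nuclei[ci]:
            pos = nuc.pos + nuc.drift * (t - s0)
            cy, cx = float(pos[0]), float(pos[1])
            nuc_rows.append((t, nuc.track_id, cy, cx, nuc.radius, phase, ci))
            if phase == "S":
                body_r, gain = nuc.radius, 1.0
            else:
                body_r = nuc.radius * eff.mitotic_condensation
                gain = eff.mitotic_gain
            for ch in eff.channels:
                amp = eff.body_amplitudes.get(ch, 0.0) * gain
                if amp > 0:
                    _add_patch(
                        frame[ch_index[ch]],
                        cy,
                        cx,
                        body_r + 6,
                        lambda shp, py, px, a=amp, r=body_r: _soft_disk(
                            shp, py, px, r, a
                        ),
                    )

            # ----- focus visibility per channel ------------------------
            t_in_s = t - s0  # frames since S onset (negative never occurs)
            foci_amp: dict[str, float] = {}
            bk = eff.focus_amplitudes.get("bookmark", 0.0) * (
                eff.bookmark_cycle_gain**ci
            )
            if "bookmark" in ch_index and bk > 0:
                if phase == "S" and t_in_s >= hub_appear_f:
                    foci_amp["bookmark"] = bk
                elif phase == "M" and eff.mitotic_persistence:
                    foci_amp["bookmark"] = bk * eff.mitotic_gain
                elif phase == "S" and ci > 0 and t_in_s < disp_f:
                    # inherited bookmark dispersing after S onset
                    fade = 1.0 - (t_in_s + 1) / (disp_f + 1)
                    foci_amp["bookmark"] = bk * eff.mitotic_gain * fade
            if "kinase" in ch_index:
                in_late_m = phase == "M" and (cycle_ends[ci] - t) <= kin_lead_f
                in_early_s = phase == "S" and ci > 0 and t_in_s < kin_disp_f
                if in_late_m or in_early_s:
                    foci_amp["kinase"] = eff.focus_amplitudes.get("kinase", 0.0)
            if "polymerase" in ch_index and phase == "S" and t_in_s >= pol_delay_f:
                foci_amp["polymerase"] = eff.focus_amplitudes.get("polymerase", 0.0)

            key = (ci, nuc.track_id)
            is_on = (
                phase == "S"
                and key in on_frame
                and t >= on_frame[key]
                and (key not in off_frame or t < off_frame[key])
            )
            state_rows.append((t, nuc.track_id, bool(is_on)))
            if is_on and "mcp" in ch_index:
                foci_amp["mcp"] = eff.focus_amplitudes.get("mcp", 0.0)
            pcp_on = (
                is_on
                and "pcp" in ch_index
                and t >= on_frame[key] + eff.elongation_delay_frames
            )
            if pcp_on:
                foci_amp["pcp"] = eff.focus_amplitudes.get("pcp", 0.0)

            for k, off in enumerate(nuc.focus_offsets):
                fy, fx = cy + off[0], cx + off[1]
                for ch, amp in foci_amp.items():
                    if ch in ("mcp", "pcp") and k != 0:
                        continue  # one transcription spot per nucleus
                    a = amp if k == 0 else amp * 0.5  # minor foci are dimmer
                    _add_patch(
                        frame[ch_index[ch]],
                        fy,
                        fx,
                        4 * eff.focus_sigma,
                        lambda shp, py, px, a=a: _gaussian_spot(
                            shp, py, px, eff.focus_sigma, a
                        ),
                    )
                    foci_rows.append((t, nuc.track_id, ch, fy, fx, a))
            if is_on:
                fy, fx = cy + nuc.focus_offsets[0][0], cx + nuc.focus_offsets[0][1]
                spot_rows.append(
                    (
                        t,
                        nuc.track_id,
                        fy,
                        fx,
                        foci_amp.get("mcp", 0.0),
                        foci_amp.get("pcp", 0.0) if pcp_on else 0.0,
                    )
                )

    # --- noise (last) ----------------------------------------------------
    if eff.photon_scale:
        movie = rng.poisson(movie * eff.photon_scale) / eff.photon_scale
        movie = movie + rng.normal(0.0, eff.read_noise_sigma, size=movie.shape)
        movie = np.clip(movie, 0.0, None)

    stack = MovieStack(
        data=movie,
        frame_interval=dt,
        z_step=0.5,
        pixel_size=0.22,
        channel_names=list(eff.channels),
    )

    nuclei_df = pd.DataFrame(
        nuc_rows, columns=["frame", "track_id", "y", "x", "radius", "phase", "cycle"]
    )
    foci_df = pd.DataFrame(
        foci_rows, columns=["frame", "track_id", "channel", "y", "x", "amplitude"]
    )
    states_df = pd.DataFrame(state_rows, columns=["frame", "track_id", "on"])
    ev_rows = []
    all_ids = sorted({tid for _, tid in on_frame} | {
        n.track_id for cyc in per_cycle_nuclei for n in cyc
    })
    for tid in all_ids:
        ons = [f for (ci, i), f in on_frame.items() if i == tid]
        offs = [f for (ci, i), f in off_frame.items() if i == tid]
        ev_rows.append(
            (tid, min(ons) if ons else -1, min(offs) if offs else -1)
        )
    events_df = pd.DataFrame(
        ev_rows, columns=["track_id", "first_on", "first_off_after_on"]
    )
    spots_df = pd.DataFrame(
        spot_rows, columns=["frame", "track_id", "y", "x", "mcp_true", "pcp_true"]
    )
    cyc_rows = []
    for ci in range(len(eff.cycles)):
        s0, m0 = ann.s_starts[ci], ann.m_starts[ci]
        n_cyc = int(np.sum(ann.cycle_index == ci))
        cyc_rows.append((ci, s0, m0, m0 - s0, n_cyc - (m0 - s0)))
    cycles_df = pd.DataFrame(
        cyc_rows, columns=["cycle", "s_start", "m_start", "s_frames", "m_frames"]
    )
    truth = GroundTruth(
        nuclei=nuclei_df,
        foci=foci_df,
        states=states_df,
        events=events_df,
        spots=spots_df,
        cycles=cycles_df,
    )
    return stack, truth


_GT_TABLES = ("nuclei", "foci", "states", "events", "spots", "cycles")


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    """Write each truth table as ``<path>/<table>.csv`` (lossless round-trip)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in _GT_TABLES:
        getattr(gt, name).to_csv(path / f"{name}.csv", index=False)
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    kw = {}
    for name in _GT_TABLES:
        df = pd.read_csv(path / f"{name}.csv")
        if name == "states" and len(df):
            df["on"] = df["on"].astype(bool)
        kw[name] = df
    return GroundTruth(**kw)
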