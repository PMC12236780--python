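"""End-to-end pipelines driven by a single run configuration.

Three analyses are orchestrated: ``hubdyn`` (bookmark/kinase hub
dynamics), ``mcp`` (per-nucleus transcription ON/OFF kinetics) and
``dual`` (5'/3' dual-reporter spot tracking).  Each run writes its
resolved configuration, tidy CSVs and figure-style plots to the output
directory; CSVs are the contract and reruns with the same config and
seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dual_reporter, foci_tracking, hub_dynamics, masking
from .image_io import MovieStack, Projection, crop_region, preprocess_projection, read_movie
from .synthetic_movies import GroundTruth, SimConfig, simulate_embryo_movie, write_ground_truth

__all__ = ["RunConfig", "run_hubdyn", "run_mcp", "run_dual", "run_pipeline"]

log = logging.getLogger("embryohub")

PIPELINES = ("hubdyn", "mcp", "dual")

#: default stage parameters; every key can be overridden via RunConfig.params
DEFAULT_PARAMS: dict = {
    "rolling_ball_radius": None,  # sim movies have flat background
    "clip_percentile": 99.5,
    "blur_sigma": 2.0,
    "dilation_radius": 2,
    "min_peak_distance": 10,
    "window_seconds": 120.0,
    "max_displacement": None,  # default: one nuclear radius
    "log_sigma_range": (1.5, 4.0),
    "log_threshold": 5.0,
    "debounce": 1,
    "dog_blur_sigma": 1.0,
    "dog_sigmas": (1.5, 3.0),
    "dog_threshold": 3.0,
    "max_gap": 5,
    "spot_max_displacement": 6.0,
    "n_top_tracks": 50,
    "background_mode": "annulus",
    "hub_channels": ("bookmark", "kinase"),
    "nuclei_channel": "polymerase",
    "mcp_channel": "mcp",
    "pcp_channel": "pcp",
    "n_embryos": 1,
    "make_plots": True,
}


@dataclass
class RunConfig:
    """One configuration driving simulate + analyze.

    Either ``sim`` (a :class:`SimConfig`) or ``movie_path`` must be set.
    ``seed`` overrides the simulator seed so one run config can be re-run
    across replicate seeds.
    """

    pipeline: str
    out_dir: str = "results"
    sim: SimConfig | None = None
    movie_path: str | None = None
    axes: str | None = None
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pipeline not in PIPELINES:
            raise ValueError(
                f"pipeline must be one of {PIPELINES}, got {self.pipeline!r}"
            )
        if self.sim is None and self.movie_path is None:
            raise ValueError("config must set either 'sim' or 'movie_path'")
        unknown = set(self.params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameters {sorted(unknown)}")

    def param(self, key: str):
        return self.params.get(key, DEFAULT_PARAMS[key])

    # ---- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _listify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = sim_config_from_dict(d["sim"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj


def sim_config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a YAML/JSON mapping (lists become tuples)."""
    d = dict(d)
    for key in ("shape", "channels"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    if "cycles" in d:
        d["cycles"] = tuple(tuple(c) for c in d["cycles"])
    return SimConfig(**d)


def _load_input(config: RunConfig) -> tuple[MovieStack, GroundTruth | None]:
    if config.sim is not None:
        sim = config.sim
        if config.seed is not None:
            sim = dataclasses.replace(sim, rng_seed=config.seed)
        movie, truth = simulate_embryo_movie(sim)
        return movie, truth
    movie = read_movie(config.movie_path, axes=config.axes)
    return movie, None


def _channel_index(proj: Projection, name: str, fieldname: str) -> int:
    try:
        return proj.channel_index(name)
    except KeyError:
        raise ValueError(
            f"config field {fieldname!r}: channel {name!r} not present in "
            f"movie channels {proj.channel_names}"
        ) from None


def _write_resolved(config: RunConfig, out: Path) -> None:
    from . import __version__

    doc = {
        "config": config.to_dict(),
        "package_version": __version__,
        "seed": config.seed,
    }
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(doc, sort_keys=True)
    )


def _analysis_window(truth: GroundTruth | None, n_frames: int) -> tuple[int, int, int]:
    """(start, stop, s_start_rel) frames to analyze: the last S block of a
    simulated movie, or the whole movie for external input."""
    if truth is None or truth.cycles.empty:
        return 0, n_frames, 0
    last = truth.cycles.iloc[-1]
    start = int(last["s_start"])
    stop = start + int(last["s_frames"])
    return start, stop, 0


# ---------------------------------------------------------------------------
# hubdyn
# ---------------------------------------------------------------------------

def run_hubdyn(config: RunConfig) -> dict:
    """Hub-dynamics pipeline: masked mean/variance series and window peaks.

    Stages: preprocess -> combined chromatin mask -> masked mean/variance
    per channel -> recruitment onset -> peak in the 2-minute window, per
    cycle when cycle annotation is available; plus the per-nucleus branch
    (segmentation -> per-nucleus maxima).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    movie, truth = _load_input(config)
    proj = preprocess_projection(movie, config.param("rolling_ball_radius"))
    ch_names = config.param("hub_channels")
    chans = [_channel_index(proj, n, "hub_channels") for n in ch_names]

    masks = masking.combined_chromatin_mask(
        proj,
        channels=(chans[0], chans[1]),
        clip_percentile=config.param("clip_percentile"),
        blur_sigma=config.param("blur_sigma"),
    )
    log.info("hubdyn: %d frames masked", masks.data.shape[0])

    series_rows = []
    peak_rows = []
    window_s = config.param("window_seconds")
    if truth is not None and not truth.cycles.empty:
        onsets = [
            (int(r["cycle"]), int(r["s_start"])) for _, r in truth.cycles.iterrows()
        ]
    else:
        onsets = None
    all_series = {}
    for name, c in zip(ch_names, chans):
        for stat in ("mean", "variance"):
            ser = hub_dynamics.masked_stats(proj, masks, c, stat)
            all_series[(name, stat)] = ser
            for t, v in enumerate(ser.values):
                series_rows.append((name, stat, t, t * ser.frame_interval, v))
            if onsets is None:
                onset = hub_dynamics.detect_recruitment_onset(ser)
                cycle_onsets = [(0, onset)]
            else:
                cycle_onsets = onsets
            for cyc, onset in cycle_onsets:
                pk = hub_dynamics.peak_in_window(ser, onset, window_s)
                peak_rows.append((name, stat, cyc, onset, pk.frame, pk.peak))
    pd.DataFrame(
        series_rows, columns=["channel", "statistic", "frame", "time_s", "value"]
    ).to_csv(out / "series.csv", index=False)
    peaks = pd.DataFrame(
        peak_rows,
        columns=["channel", "statistic", "cycle", "onset", "peak_frame", "peak"],
    )
    peaks.to_csv(out / "peaks.csv", index=False)

    # per-nucleus branch
    nuc_ch = _channel_index(proj, config.param("nuclei_channel"), "nuclei_channel") \
        if config.param("nuclei_channel") in proj.channel_names else chans[0]
    labels = masking.segment_nuclei(
        proj,
        nuc_ch,
        clip_percentile=config.param("clip_percentile"),
        blur_sigma=config.param("blur_sigma"),
        dilation_radius=config.param("dilation_radius"),
        min_peak_distance=config.param("min_peak_distance"),
    )
    log.info("hubdyn: %d nuclear regions", len(labels.regions))
    tables = []
    for name, c in zip(ch_names, chans):
        tab = hub_dynamics.per_nucleus_intensities(proj, labels, c, "max")
        tab.insert(0, "channel", name)
        tables.append(tab)
    pernuc = pd.concat(tables, ignore_index=True)
    pernuc.to_csv(out / "per_nucleus.csv", index=False)

    if config.param("make_plots"):
        _plot_series(all_series, out / "series.png")
    _write_resolved(config, out)
    return {"series": all_series, "peaks": peaks, "per_nucleus": pernuc,
            "truth": truth, "out_dir": out}


# ---------------------------------------------------------------------------
# mcp
# ---------------------------------------------------------------------------

def _run_mcp_one(config: RunConfig, seed: int | None) -> dict:
    cfg = dataclasses.replace(config, seed=seed)
    movie, truth = _load_input(cfg)
    proj = preprocess_projection(movie, config.param("rolling_ball_radius"))
    start, stop, s_rel = _analysis_window(truth, proj.n_frames)
    crop = crop_region(proj, t_range=(start, stop))
    sub = Projection(
        data=crop.data,
        frame_interval=proj.frame_interval,
        pixel_size=proj.pixel_size,
        channel_names=proj.channel_names,
    )
    nuc_ch = _channel_index(sub, config.param("nuclei_channel"), "nuclei_channel")
    mcp_ch = _channel_index(sub, config.param("mcp_channel"), "mcp_channel")
    labels = masking.segment_nuclei(
        sub,
        nuc_ch,
        clip_percentile=config.param("clip_percentile"),
        blur_sigma=config.param("blur_sigma"),
        dilation_radius=config.param("dilation_radius"),
        min_peak_distance=config.param("min_peak_distance"),
    )
    max_disp = config.param("max_displacement")
    if max_disp is None:
        med_area = labels.regions["area"].median() if len(labels.regions) else 100.0
        max_disp = float(np.sqrt(med_area / np.pi))  # ~one nuclear radius
    tracks = foci_tracking.link_nuclei(labels, max_disp)
    if not tracks:
        raise ValueError("no nuclei retained across all analyzed frames")
    foci = []
    for t in range(sub.n_frames):
        foci.extend(
            foci_tracking.detect_foci_log(
                sub.data[t, mcp_ch],
                sigma_range=tuple(config.param("log_sigma_range")),
                threshold=config.param("log_threshold"),
                frame=t,
            )
        )
    assigned = foci_tracking.assign_foci(foci, labels)
    traces = foci_tracking.call_states(
        tracks, assigned, debounce=config.param("debounce")
    )
    curves = foci_tracking.cumulative_transitions(traces, s_start=s_rel)
    log.info(
        "mcp: %d tracks, %d foci, curves end ON=%.1f%% OFF=%.1f%%",
        len(tracks), len(foci),
        curves["on_pct"].iloc[-1], curves["off_pct"].iloc[-1],
    )
    return {
        "proj": sub,
        "labels": labels,
        "tracks": tracks,
        "foci": assigned,
        "traces": traces,
        "curves": curves,
        "truth": truth,
        "window": (start, stop),
    }


def run_mcp(config: RunConfig) -> dict:
    """MCP ON/OFF pipeline over one or more replicate embryos.

    Stages: preprocess -> nuclear segmentation -> tracking (complete
    tracks only) -> LoG focus detection -> focus-to-nucleus assignment ->
    state calling -> cumulative ON/OFF curves; replicate embryos (seeds
    seed, seed+1, ...) are aggregated as mean +/- SEM.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_embryos = int(config.param("n_embryos"))
    base_seed = config.seed
    if config.sim is not None and base_seed is None:
        base_seed = config.sim.rng_seed
    replicates = []
    for i in range(n_embryos):
        seed_i = None if base_seed is None else base_seed + i
        replicates.append(_run_mcp_one(config, seed_i))

    state_rows = []
    for i, rep in enumerate(replicates):
        for tr in rep["traces"]:
            state_rows.append(
                (
                    f"embryo{i}",
                    tr.track_id,
                    -1 if tr.first_on is None else tr.first_on,
                    -1 if tr.first_off_after_on is None else tr.first_off_after_on,
                )
            )
    pd.DataFrame(
        state_rows, columns=["embryo", "track_id", "first_on", "first_off_after_on"]
    ).to_csv(out / "states.csv", index=False)

    n_min = min(len(r["curves"]) for r in replicates)
    curve_df = replicates[0]["curves"].iloc[:n_min].copy()
    if n_embryos >= 2:
        from .stats_report import sem_curves

        on_mean, on_sem = sem_curves(
            [r["curves"]["on_pct"].to_numpy()[:n_min] for r in replicates]
        )
        off_mean, off_sem = sem_curves(
            [r["curves"]["off_pct"].to_numpy()[:n_min] for r in replicates]
        )
        curve_df = pd.DataFrame(
            {
                "frame": np.arange(n_min),
                "on_pct": on_mean,
                "on_sem": on_sem,
                "off_pct": off_mean,
                "off_sem": off_sem,
            }
        )
    curve_df.to_csv(out / "cumulative_curves.csv", index=False)
    if config.param("make_plots"):
        _plot_curves(curve_df, out / "cumulative_curves.png")
    _write_resolved(config, out)
    return {"replicates": replicates, "curves": curve_df, "out_dir": out}


# ---------------------------------------------------------------------------
# dual
# ---------------------------------------------------------------------------

def run_dual(config: RunConfig) -> dict:
    """Dual-reporter pipeline: DoG spots -> gap-linked tracks -> montages."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    movie, truth = _load_input(config)
    proj = preprocess_projection(movie, config.param("rolling_ball_radius"))
    start, stop, _ = _analysis_window(truth, proj.n_frames)
    crop = crop_region(proj, t_range=(start, stop))
    sub = Projection(
        data=crop.data,
        frame_interval=proj.frame_interval,
        pixel_size=proj.pixel_size,
        channel_names=proj.channel_names,
    )
    mcp_name = config.param("mcp_channel")
    pcp_name = config.param("pcp_channel")
    mcp_ch = _channel_index(sub, mcp_name, "mcp_channel")
    pcp_ch = _channel_index(sub, pcp_name, "pcp_channel")

    detections = dual_reporter.detect_spots_dog(
        sub,
        channels=(mcp_ch, pcp_ch),
        blur_sigma=config.param("dog_blur_sigma"),
        dog_sigmas=tuple(config.param("dog_sigmas")),
        threshold=config.param("dog_threshold"),
    )
    tracks = dual_reporter.link_spots(
        detections,
        max_displacement=config.param("spot_max_displacement"),
        max_gap=config.param("max_gap"),
    )
    tracks = dual_reporter.quantify_tracks(
        tracks,
        sub,
        channels={mcp_name: mcp_ch, pcp_name: pcp_ch},
        background_mode=config.param("background_mode"),
    )
    n_before = len(tracks)
    tracks = dual_reporter.filter_tracks(tracks)
    tracks = dual_reporter.sort_tracks(tracks, pcp_channel=pcp_name)
    log.info(
        "dual: %d detections, %d tracks (%d after filtering)",
        len(detections), n_before, len(tracks),
    )
    rows = []
    for tr in tracks:
        for i, t in enumerate(tr.frames):
            rows.append(
                (
                    tr.track_id, t, tr.ys[i], tr.xs[i],
                    tr.raw_mean[mcp_name][i], tr.background[mcp_name][i],
                    tr.corrected[mcp_name][i],
                    tr.raw_mean[pcp_name][i], tr.background[pcp_name][i],
                    tr.corrected[pcp_name][i],
                )
            )
    track_df = pd.DataFrame(
        rows,
        columns=[
            "track_id", "frame", "y", "x",
            "mcp_raw", "mcp_background", "mcp_corrected",
            "pcp_raw", "pcp_background", "pcp_corrected",
        ],
    )
    track_df.to_csv(out / "tracks.csv", index=False)

    montages = {}
    if tracks:
        n_top = config.param("n_top_tracks")
        for name, c in ((mcp_name, mcp_ch), (pcp_name, pcp_ch)):
            mont = dual_reporter.build_montage(sub, tracks, c, name, n_top)
            montages[name] = mont
            import tifffile

            tifffile.imwrite(
                out / f"montage_{name}.tif", mont.data.astype(np.float32)
            )
    _write_resolved(config, out)
    return {
        "detections": detections,
        "tracks": tracks,
        "track_table": track_df,
        "montages": montages,
        "truth": truth,
        "window": (start, stop),
        "out_dir": out,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Dispatch on ``config.pipeline``."""
    return {"hubdyn": run_hubdyn, "mcp": run_mcp, "dual": run_dual}[
        config.pipeline
    ](config)


# ---------------------------------------------------------------------------
# plots (conveniences; CSVs are the contract)
# ---------------------------------------------------------------------------

def _plot_series(all_series: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    for (name, stat), ser in all_series.items():
        ax = axes[0] if stat == "mean" else axes[1]
        ax.plot(ser.times / 60.0, ser.values, label=name)
    axes[0].set_ylabel("masked mean (a.u.)")
    axes[1].set_ylabel("masked variance (a.u.)")
    axes[1].set_xlabel("time (min)")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)


def _plot_curves(curve_df: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve_df["frame"], curve_df["on_pct"], label="MCP turned ON")
    ax.plot(curve_df["frame"], curve_df["off_pct"], label="MCP turned OFF")
    if "on_sem" in curve_df:
        ax.fill_between(
            curve_df["frame"],
            curve_df["on_pct"] - curve_df["on_sem"],
            curve_df["on_pct"] + curve_df["on_sem"],
            alpha=0.3,
        )
        ax.fill_between(
            curve_df["frame"],
            curve_df["off_pct"] - curve_df["off_sem"],
            curve_df["off_pct"] + curve_df["off_sem"],
            alpha=0.3,
        )
    ax.set_xlabel("frames since S-phase entry")
    ax.set_ylabel("% of nuclei")
    ax.set_ylim(0, 105)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
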