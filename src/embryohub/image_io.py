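"""Movie I/O and preprocessing.

Movies are time-lapse confocal z-stacks stored as TIFF/OME-TIFF with axes
(t, z, c, y, x).  Analysis operates on maximal-intensity projections with
rolling-ball background subtraction, i.e. the standard preprocessing chain
for spinning-disk embryo movies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "MovieStack",
    "Projection",
    "RegionCrop",
    "read_movie",
    "write_movie",
    "max_project",
    "rolling_ball_subtract",
    "crop_region",
]

#: canonical axis order for all in-memory movies
AXES = "TZCYX"


@dataclass
class MovieStack:
    """A multi-dimensional movie with physical metadata.

    Parameters
    ----------
    data
        Intensity array indexed ``(t, z, c, y, x)``; non-negative.
    frame_interval
        Time between frames, seconds.
    z_step
        Axial step size, micrometres (0.5 um for the source movies).
    pixel_size
        Lateral pixel size, micrometres.
    channel_names
        One label per channel, ordered as the c axis.
    """

    data: np.ndarray
    frame_interval: float = 20.0
    z_step: float = 0.5
    pixel_size: float = 0.22
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"movie data must be 5-D (t, z, c, y, x), got {self.data.ndim}-D"
            )
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("movie intensities must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[2])]
        if len(self.channel_names) != self.data.shape[2]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[2]} channels"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None


@dataclass
class Projection:
    """A z-collapsed movie, indexed ``(t, c, y, x)``."""

    data: np.ndarray
    frame_interval: float = 20.0
    pixel_size: float = 0.22
    channel_names: list[str] = field(default_factory=list)
    method: str = "max"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("projection data must be 4-D (t, c, y, x)")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None


@dataclass
class RegionCrop:
    """A sub-array addressed by half-open (t, y, x) intervals."""

    data: np.ndarray
    t_range: tuple[int, int]
    y_range: tuple[int, int]
    x_range: tuple[int, int]


def _canonicalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand ``data`` with axis string ``axes`` to (T, Z, C, Y, X)."""
    axes = axes.upper().replace("S", "C").replace("Q", "Z")
    if len(axes) != data.ndim:
        raise ValueError(f"axis string {axes!r} does not match {data.ndim}-D data")
    unknown = set(axes) - set(AXES)
    if unknown:
        raise ValueError(f"unsupported axes {sorted(unknown)} in {axes!r}")
    if len(set(axes)) != len(axes):
        raise ValueError(f"repeated axis in {axes!r}")
    for ax in AXES:
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in AXES]
    return np.transpose(data, order)


def read_movie(
    path: str | Path,
    axes: str | None = None,
    frame_interval: float = 20.0,
    z_step: float = 0.5,
    pixel_size: float = 0.22,
    channel_names: list[str] | None = None,
) -> MovieStack:
    """Read a TIFF/OME-TIFF movie into canonical (t, z, c, y, x) order.

    Axis order is taken from the TIFF series metadata when present;
    ``axes`` overrides it (required when the file does not declare axes).
    Missing axes are inserted with length 1.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            file_axes = series.axes
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise OSError(f"cannot read {path} as a TIFF movie: {exc}") from exc
    use_axes = axes if axes is not None else file_axes
    if use_axes is None or any(a not in AXES + "SQ" for a in use_axes.upper()):
        if axes is None:
            raise ValueError(
                f"cannot infer axes for {path} (file reports {file_axes!r}); "
                "pass axes= explicitly"
            )
    data = _canonicalize_axes(data, use_axes)
    return MovieStack(
        data=data,
        frame_interval=frame_interval,
        z_step=z_step,
        pixel_size=pixel_size,
        channel_names=channel_names or [],
    )


def write_movie(movie: MovieStack, path: str | Path) -> Path:
    """Write a MovieStack as an ImageJ-style TIFF with TZCYX axes."""
    path = Path(path)
    data = movie.data
    if not np.issubdtype(data.dtype, np.unsignedinteger):
        data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"axes": AXES})
    return path


def max_project(movie: MovieStack) -> Projection:
    """Maximal-intensity projection along z."""
    return Projection(
        data=movie.data.max(axis=1),
        frame_interval=movie.frame_interval,
        pixel_size=movie.pixel_size,
        channel_names=list(movie.channel_names),
        method="max",
    )


def _ball_structure(radius: int) -> np.ndarray:
    """Non-flat structuring element: the upper surface of a ball, <= 0.

    Entries outside the ball footprint are -inf so morphology ignores them.
    """
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = yy**2 + xx**2
    inside = d2 <= radius**2
    h = np.full(inside.shape, -np.inf)
    h[inside] = np.sqrt(radius**2 - d2[inside].astype(float)) - radius
    return h


def rolling_ball_subtract(image: np.ndarray, radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction of a 2-D image.

    The background is the grayscale opening of the image with a ball
    structuring element of the given radius (pixels outside the image are
    ignored rather than padded).  Output = image - background, clipped at 0.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("rolling_ball_subtract expects a 2-D image")
    se = _ball_structure(int(radius))
    eroded = ndi.grey_erosion(image, structure=se, mode="constant", cval=np.inf)
    background = ndi.grey_dilation(eroded, structure=se, mode="constant", cval=-np.inf)
    return np.clip(image - background, 0.0, None)


def preprocess_projection(
    movie: MovieStack, rolling_ball_radius: int | None = 50
) -> Projection:
    """Max-project a movie and background-subtract each (t, c) plane."""
    proj = max_project(movie)
    if rolling_ball_radius is None:
        return proj
    out = np.empty(proj.data.shape, dtype=float)
    for t in range(proj.data.shape[0]):
        for c in range(proj.data.shape[1]):
            out[t, c] = rolling_ball_subtract(proj.data[t, c], rolling_ball_radius)
    return replace(proj, data=out)


def crop_region(
    proj: Projection,
    t_range: tuple[int, int] | None = None,
    y_range: tuple[int, int] | None = None,
    x_range: tuple[int, int] | None = None,
) -> RegionCrop:
    """Crop a projection by half-open (t, y, x) intervals.

    The returned array is a copy, so mutating it cannot corrupt the source.
    """
    n_t, _, n_y, n_x = proj.data.shape
    t_range = t_range if t_range is not None else (0, n_t)
    y_range = y_range if y_range is not None else (0, n_y)
    x_range = x_range if x_range is not None else (0, n_x)
    for name, (lo, hi), n in (
        ("t", t_range, n_t),
        ("y", y_range, n_y),
        ("x", x_range, n_x),
    ):
        if not (0 <= lo <= hi <= n):
            raise IndexError(
                f"{name}_range [{lo}, {hi}) out of bounds for axis length {n}"
            )
    data = proj.data[
        t_range[0] : t_range[1], :, y_range[0] : y_range[1], x_range[0] : x_range[1]
    ].copy()
    return RegionCrop(data=data, t_range=t_range, y_range=y_range, x_range=x_range)
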