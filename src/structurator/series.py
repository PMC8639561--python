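"""Image time-series container and readers/writers.

An :class:`ImageSeries` is the carrier of the raw data: ``N`` equally
spaced grayscale frames of identical size ``H x W``, together with the
frame interval ``dt`` (seconds) and the physical ``pixel_size`` (meters).
Series are read either from a multi-page TIFF stack or from a directory
of numbered single-frame images (TIFF or PNG).

Pixel intensities are used exactly as stored, converted to a floating
representation without rescaling: the structure function rejects any
static background by differencing frames, so no preprocessing is applied
here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import DimensionError, InputError

_FRAME_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass
class ImageSeries:
    """Ordered stack of frames with uniform time step.

    Parameters
    ----------
    frames:
        Real array of shape ``(N, H, W)`` holding intensity counts.
    dt:
        Frame interval in seconds, strictly positive.
    pixel_size:
        Physical side of one pixel in meters, strictly positive.
    bit_depth:
        Informational bit depth of the source data (e.g. 16).
    """

    frames: np.ndarray
    dt: float
    pixel_size: float
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DimensionError(
                f"frames must be a (N, H, W) array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise InputError("an image series needs at least 2 frames")
        if not np.issubdtype(self.frames.dtype, np.floating):
            self.frames = self.frames.astype(np.float64)
        if not np.all(np.isfinite(self.frames)):
            raise InputError("frames contain non-finite pixel values")
        if not self.dt > 0:
            raise InputError(f"dt must be positive, got {self.dt}")
        if not self.pixel_size > 0:
            raise InputError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1], self.frames.shape[2]


def _numeric_token(name: str) -> str:
    """Last run of digits in a file stem, used as the frame index."""
    groups = re.findall(r"\d+", name)
    if not groups:
        raise InputError(
            f"frame filename {name!r} carries no numeric index; "
            "directory input needs zero-padded numbered filenames"
        )
    return groups[-1]


def _sorted_frame_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
    )
    if len(files) < 2:
        raise InputError(
            f"directory {directory} holds {len(files)} readable frames; need >= 2"
        )
    widths = {len(_numeric_token(p.stem)) for p in files}
    if len(widths) > 1:
        raise InputError(
            "mixed-width frame numbering in "
            f"{directory} (digit widths {sorted(widths)}); zero-pad the indices "
            "so lexicographic order equals numeric order"
        )
    return files


def _read_frame(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except InputError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with file name
        raise OSError(f"cannot read frame {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise DimensionError(f"frame {path} is not a single grayscale image")
    return arr


def load_series(path: str | Path, dt: float, pixel_size: float) -> ImageSeries:
    """Load an image series from a TIFF stack or a directory of frames.

    Frames are ordered by page index (stack) or by ascending zero-padded
    filename (directory). Values are promoted to float64 without
    rescaling.
    """
    path = Path(path)
    if path.is_dir():
        files = _sorted_frame_files(path)
        frames = [_read_frame(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise DimensionError(
                f"mixed frame sizes in {path}: {sorted(shapes)}"
            )
        stack = np.stack(frames)
        src_dtype = frames[0].dtype
    else:
        try:
            stack = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise OSError(f"cannot read image stack {path}: {exc}") from exc
        stack = np.asarray(stack)
        if stack.ndim == 2 or (stack.ndim == 3 and stack.shape[0] < 2):
            raise InputError(f"{path} holds fewer than 2 frames")
        if stack.ndim != 3:
            raise DimensionError(
                f"{path} is not a stack of grayscale frames (shape {stack.shape})"
            )
        src_dtype = stack.dtype
    bit_depth = src_dtype.itemsize * 8 if np.issubdtype(src_dtype, np.integer) else None
    return ImageSeries(
        frames=stack.astype(np.float64),
        dt=dt,
        pixel_size=pixel_size,
        bit_depth=bit_depth,
    )


def save_series(series: ImageSeries, path: str | Path) -> Path:
    """Write a series as a multi-page TIFF, preserving the array dtype."""
    path = Path(path)
    tifffile.imwrite(path, series.frames, photometric="minisblack")
    return path
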