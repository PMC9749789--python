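"""Image-stack and measurement-table I/O.

Images are TIFF (single- or multi-page, 8- or 16-bit grayscale per
channel).  Axes are normalized to ``(frame, channel, row, col)`` with
singleton axes inserted as needed; physical metadata (pixel size, frame
interval) is supplied by the caller rather than parsed from TIFF tags,
which vary too much between writers to be trusted.

Measurement tables are CSV with a header row and a leading ``#`` comment
line carrying the seed and configuration hash of the run that produced
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile


@dataclass
class ImageStack:
    """A fluorescence image stack with physical metadata.

    Attributes
    ----------
    pixels : ndarray
        Intensities indexed ``(frame, channel, row, col)``.
    channel_names : list of str
        One label per channel.
    pixel_size : float
        Micrometres per pixel (isotropic).
    frame_interval : float
        Seconds between frames; 0 for a single frame.
    bit_depth : int
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    channel_names: list = field(default_factory=lambda: ["ch0"])
    pixel_size: float = 1.0
    frame_interval: float = 0.0
    bit_depth: int = 16

    def __post_init__(self):
        self.pixels = normalize_axes(np.asarray(self.pixels))
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval < 0:
            raise ValueError("frame_interval must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[1]} channels"
            )
        lo, hi = self.pixels.min(), self.pixels.max()
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {2**self.bit_depth - 1}] "
                f"for bit depth {self.bit_depth}"
            )

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self):
        return self.pixels.shape

    def channel_index(self, channel) -> int:
        """Resolve a channel given by name or integer index."""
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise ValueError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise ValueError(
                f"channel {channel!r} not in {self.channel_names}"
            ) from None

    def plane(self, frame: int = 0, channel=0) -> np.ndarray:
        """A single (row, col) image plane."""
        return self.pixels[frame, self.channel_index(channel)]


def normalize_axes(pixels: np.ndarray) -> np.ndarray:
    """Promote a 2D/3D array to (frame, channel, row, col).

    2D planes become one frame of one channel; 3D stacks are interpreted
    as (frame, row, col) of a single channel.  Already-4D arrays pass
    through, so the operation is idempotent.
    """
    if pixels.ndim == 2:
        return pixels[None, None]
    if pixels.ndim == 3:
        return pixels[:, None]
    if pixels.ndim == 4:
        return pixels
    raise ValueError(f"cannot interpret {pixels.ndim}-dimensional image")


def read_image_stack(
    path,
    pixel_size: float = 1.0,
    frame_interval: float = 0.0,
    channel_names=None,
    channel_axis: int | None = None,
) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    Multi-page TIFFs are read as frames of a single channel unless
    ``channel_axis`` says which axis holds channels.  8-bit and 16-bit
    unsigned data are supported.

    Parameters
    ----------
    path : path-like
        Single- or multi-page TIFF.
    pixel_size : float
        Micrometres per pixel, supplied by the caller.
    frame_interval : float
        Seconds between frames (e.g. 0.25 for a 250 ms flicker movie).
    channel_names : list of str, optional
    channel_axis : int, optional
        Axis of the raw array that indexes channels, for 3D arrays whose
        pages are channels rather than time points.
    """
    try:
        raw = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise OSError(f"unreadable image file {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.size == 0:
        raise OSError(f"unreadable image file {path}: no image data")
    if raw.dtype == np.uint8:
        bit_depth = 8
    elif raw.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"unsupported bit depth/dtype {raw.dtype} in {path}")
    if channel_axis is not None and raw.ndim == 3:
        raw = np.moveaxis(raw, channel_axis, 0)[None]  # (1, C, R, Cc)
    pixels = normalize_axes(raw)
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(pixels.shape[1])]
    return ImageStack(
        pixels=pixels,
        channel_names=list(channel_names),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        bit_depth=bit_depth,
    )


def write_image_stack(stack: ImageStack, path) -> str:
    """Write the stack as a multi-page TIFF (frames x channels as pages)."""
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    data = np.round(stack.pixels).astype(dtype)
    tifffile.imwrite(path, data.reshape(-1, *data.shape[2:]))
    return str(path)


def write_measurements(records, path, seed: int | None = None, config_hash: str | None = None) -> str:
    """Write tabular measurements as CSV with a provenance comment line.

    ``records`` may be a DataFrame or a list of dicts/dataclasses; it must
    be non-empty.  The first line of the file is a ``#`` comment recording
    the seed and config hash.
    """
    frame = _as_frame(records)
    if frame.empty:
        raise ValueError("nothing to write: records are empty")
    with open(path, "w") as fh:
        fh.write(f"# nucleoquant seed={seed} config={config_hash}\n")
        frame.to_csv(fh, index=False)
    return str(path)


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV written by :func:`write_measurements`."""
    return pd.read_csv(path, comment="#")


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for rec in records:
        if hasattr(rec, "__dataclass_fields__"):
            import dataclasses

            rows.append(dataclasses.asdict(rec))
        else:
            rows.append(dict(rec))
    return pd.DataFrame(rows)
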