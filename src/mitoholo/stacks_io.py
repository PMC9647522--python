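"""Movie-stack I/O and the z-projection used to produce planar RI images.

A time-lapse experiment is stored as one multipage TIFF per channel (one
page per frame), matched frame-by-frame, plus a flat YAML metadata sidecar
binding the two channels (condition, drug-addition frame, frame interval,
seed). Raw holographic volumes are reduced to planar refractive-index (RI)
images by a maximum-intensity projection over the z-planes that contain
mitochondria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

VALID_CHANNELS = ("RI", "TMRM")


@dataclass
class FrameStack:
    """One channel of a time-lapse experiment.

    Attributes
    ----------
    pixels : (T, H, W) ndarray
        Nonnegative intensities, one page per frame. Integer dtypes are
        preserved through I/O; computation downstream is floating point.
    channel : {"RI", "TMRM"}
    frame_interval : float
        Seconds between frames (the assay acquires every 15 s).
    drug_frame : int
        0-based index of the frame at which the compound was added.
    pixel_size : float or None
        Micrometres per pixel, if known.
    provenance : str
        Free-text origin note (file path, simulator scenario, ...).
    """

    pixels: np.ndarray
    channel: str
    frame_interval: float = 15.0
    drug_frame: int = 0
    pixel_size: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 1:
            raise ValueError("pixels must be a T x H x W array with T >= 1")
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"channel must be one of {VALID_CHANNELS}, got {self.channel!r}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not (0 <= self.drug_frame < self.n_frames):
            raise ValueError(f"drug_frame {self.drug_frame} outside [0, {self.n_frames})")
        if np.any(np.asarray(self.pixels[:1]) < 0) or np.min(self.pixels) < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def times(self) -> np.ndarray:
        """Time of each frame in seconds; frame 0 is t = 0."""
        return np.arange(self.n_frames) * float(self.frame_interval)


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a FrameStack as an uncompressed multipage TIFF, one page per frame.

    Lossless for integer data; the dtype of ``stack.pixels`` is written as-is.
    """
    path = Path(path)
    pixels = np.asarray(stack.pixels)
    if np.min(pixels) < 0:
        raise ValueError("refusing to write negative intensities")
    tifffile.imwrite(path, pixels, photometric="minisblack")
    return path


def read_stack(
    path: str | Path,
    channel: str,
    frame_interval: float = 15.0,
    drug_frame: int = 0,
    pixel_size: float | None = None,
) -> FrameStack:
    """Read a multipage TIFF into a FrameStack, pages ordered as frames.

    Raises distinct diagnostics for unreadable files, zero pages and
    inconsistent page shapes (the offending page is named).
    """
    path = Path(path)
    try:
        tf = tifffile.TiffFile(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    with tf:
        pages = tf.pages
        if len(pages) == 0:
            raise ValueError(f"{path} contains zero pages")
        shapes = [p.shape for p in pages]
        for i, shp in enumerate(shapes):
            if shp != shapes[0]:
                raise ValueError(
                    f"{path}: page {i} has shape {shp}, inconsistent with page 0 shape {shapes[0]}"
                )
        pixels = np.stack([p.asarray() for p in pages])
    return FrameStack(
        pixels=pixels,
        channel=channel,
        frame_interval=frame_interval,
        drug_frame=drug_frame,
        pixel_size=pixel_size,
        provenance=str(path),
    )


def max_project(volume: np.ndarray, z_range: tuple[int, int] | None = None) -> np.ndarray:
    """Maximum-intensity projection of a Z x H x W volume over ``z_range``.

    ``z_range`` is a half-open (start, stop) plane selection; ``None`` uses
    the full depth. The projection is the pixelwise maximum over the selected
    planes, so projecting a single plane (or a projection) is the identity.
    """
    volume = np.asarray(volume)
    if volume.ndim == 2:  # already planar: idempotent
        return volume.copy()
    if volume.ndim != 3:
        raise ValueError("volume must be Z x H x W")
    z0, z1 = (0, volume.shape[0]) if z_range is None else z_range
    if not (0 <= z0 < z1 <= volume.shape[0]):
        raise ValueError(f"empty or out-of-range z_range ({z0}, {z1}) for depth {volume.shape[0]}")
    return volume[z0:z1].max(axis=0)


# ---------------------------------------------------------------------------
# metadata sidecar

def write_metadata(meta: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_metadata(path: str | Path) -> dict:
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise ValueError(f"{path}: metadata sidecar must be a flat mapping")
    return meta
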