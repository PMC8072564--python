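"""Calibrated two-channel micrograph I/O and pixel/physical unit conversion.

The unit of analysis is a two-channel 16-bit fluorescence micrograph: one
nuclear-stain channel (cell count, nucleus morphology) and one neurite-stain
channel (somata and arborized neurites).  Physical calibration is carried as
an explicit object rather than read from TIFF metadata, because metadata
dialects vary between acquisition systems; the default corresponds to a
1376x1038 px frame imaging 884.89 um x 667.52 um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

#: Printed frame geometry of the reference acquisition setup.
DEFAULT_FRAME_WIDTH_PX = 1376
DEFAULT_FRAME_HEIGHT_PX = 1038
DEFAULT_PHYSICAL_WIDTH_UM = 884.89
DEFAULT_PHYSICAL_HEIGHT_UM = 667.52

#: um per pixel edge at the reference calibration (~0.64309 um/px).
DEFAULT_PIXEL_SIZE_UM = DEFAULT_PHYSICAL_WIDTH_UM / DEFAULT_FRAME_WIDTH_PX


@dataclass(frozen=True)
class Calibration:
    """Isotropic physical calibration of a micrograph frame.

    Parameters
    ----------
    frame_width_px, frame_height_px
        Frame dimensions in pixels.
    physical_width_um, physical_height_um
        Physical extent of the frame in micrometres.

    The pixel edge length derived from width and height must agree to a
    relative tolerance of 1e-3 (isotropic pixels).
    """

    frame_width_px: int = DEFAULT_FRAME_WIDTH_PX
    frame_height_px: int = DEFAULT_FRAME_HEIGHT_PX
    physical_width_um: float = DEFAULT_PHYSICAL_WIDTH_UM
    physical_height_um: float = DEFAULT_PHYSICAL_HEIGHT_UM

    def __post_init__(self) -> None:
        if self.frame_width_px <= 0 or self.frame_height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.physical_width_um <= 0 or self.physical_height_um <= 0:
            raise ValueError("physical extents must be positive")
        px_w = self.physical_width_um / self.frame_width_px
        px_h = self.physical_height_um / self.frame_height_px
        if abs(px_w - px_h) > 1e-3 * px_w:
            raise ValueError(
                f"anisotropic calibration: {px_w:.6f} um/px (x) vs {px_h:.6f} um/px (y)"
            )

    @property
    def pixel_size_um(self) -> float:
        """Micrometres per pixel edge (isotropic)."""
        return self.physical_width_um / self.frame_width_px

    def with_frame_shape(self, height_px: int, width_px: int) -> "Calibration":
        """Calibration for a frame of different pixel dimensions at the same pixel size."""
        s = self.pixel_size_um
        return Calibration(width_px, height_px, width_px * s, height_px * s)


@dataclass(frozen=True)
class Condition:
    """Experimental condition labels attached to a frame."""

    compound: str = ""
    concentration_nM: float = 0.0
    is_control: bool = False
    experiment_id: str = ""


@dataclass
class MicrographFrame:
    """Calibrated two-channel 16-bit intensity raster."""

    nuclear_channel: np.ndarray
    neurite_channel: np.ndarray
    calibration: Calibration
    frame_id: str = ""
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self) -> None:
        nuc, neu = self.nuclear_channel, self.neurite_channel
        if nuc.ndim != 2 or neu.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        if nuc.shape != neu.shape:
            raise ValueError(f"channel shape mismatch: {nuc.shape} vs {neu.shape}")
        expected = (self.calibration.frame_height_px, self.calibration.frame_width_px)
        if nuc.shape != expected:
            raise ValueError(
                f"channel shape {nuc.shape} does not match calibration {expected}"
            )
        for name, ch in (("nuclear", nuc), ("neurite", neu)):
            if ch.dtype != np.uint16:
                raise TypeError(f"{name} channel must be 16-bit (uint16), got {ch.dtype}")

    @property
    def shape(self) -> tuple:
        return self.nuclear_channel.shape


def length_um(length_px: float, calibration: Calibration) -> float:
    """Convert a length in (source-frame) pixels to micrometres.

    At the default calibration 10 px corresponds to 6.43 um and the full
    1376 px frame width to 884.89 um.
    """
    if length_px < 0:
        raise ValueError("length_px must be non-negative")
    return float(length_px) * calibration.pixel_size_um


def area_um2(area_px: float, calibration: Calibration, scale_factor: int = 1) -> float:
    """Convert a pixel count to square micrometres.

    ``scale_factor`` accounts for masks upsampled relative to the source
    frame: the effective pixel edge is ``pixel_size_um / scale_factor``.
    """
    if area_px < 0:
        raise ValueError("area_px must be non-negative")
    edge = calibration.pixel_size_um / scale_factor
    return float(area_px) * edge * edge


def read_frame(
    path: str | Path,
    calibration: Calibration,
    condition: Condition = Condition(),
    frame_id: Optional[str] = None,
    nuclear_page: int = 0,
) -> MicrographFrame:
    """Read a two-page 16-bit TIFF as a calibrated two-channel frame.

    Page 0 is the nuclear stain and page 1 the neurite stain by default
    (override with ``nuclear_page=1``).  Files with any other page count or
    with non-16-bit samples are rejected; intensities are never rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        raise ValueError(f"{path}: expected a two-channel stack, found a single page")
    if data.ndim != 3 or data.shape[0] != 2:
        raise ValueError(f"{path}: expected exactly 2 channel pages, got shape {data.shape}")
    if data.dtype != np.uint16:
        raise TypeError(f"{path}: expected 16-bit samples, got {data.dtype}")
    nuc = data[nuclear_page]
    neu = data[1 - nuclear_page]
    return MicrographFrame(
        nuclear_channel=nuc,
        neurite_channel=neu,
        calibration=calibration,
        frame_id=frame_id if frame_id is not None else path.stem,
        condition=condition,
    )


def write_frame(frame: MicrographFrame, path: str | Path, nuclear_page: int = 0) -> Path:
    """Write a frame as a two-page 16-bit TIFF (inverse of :func:`read_frame`)."""
    path = Path(path)
    pages = [None, None]
    pages[nuclear_page] = frame.nuclear_channel
    pages[1 - nuclear_page] = frame.neurite_channel
    tifffile.imwrite(str(path), np.stack(pages), photometric="minisblack")
    return path


def write_overlay(
    frame: MicrographFrame,
    path: str | Path,
    neurite_mask: Optional[np.ndarray] = None,
    skeleton_mask: Optional[np.ndarray] = None,
    soma_mask: Optional[np.ndarray] = None,
) -> Path:
    """Write an 8-bit RGB QC overlay PNG.

    The neurite channel is shown as the grayscale base; the binary neurite
    mask is tinted green, the (downsampled) skeleton red and the soma mask
    blue.  All masks must be at source scale.
    """
    import imageio.v3 as iio

    base = (frame.neurite_channel.astype(np.float64) / 65535.0 * 255).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    if neurite_mask is not None:
        rgb[neurite_mask.astype(bool), 1] = 255
    if soma_mask is not None:
        rgb[soma_mask.astype(bool), 2] = 255
    if skeleton_mask is not None:
        rgb[skeleton_mask.astype(bool)] = (255, 0, 0)
    iio.imwrite(Path(path), rgb)
    return Path(path)
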