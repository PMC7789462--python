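"""Reading lung-segmentation mask stacks and turning them into contours.

Masks arrive as PNG stacks (one 2-D binary image per respiratory frame,
sorted lexicographically) or as a NIfTI volume whose third axis is time.
Pixel coordinates are mapped into the package's physical frame: row 0 of the
image is the cranial side (so ``y_mm`` decreases with row index), and the
``orientation_flag`` says whether the anterior chest wall is on the left or
the right of the image (anterior always ends up at smaller ``x_mm``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from skimage import measure

from .contour import ContourError, LungContour


class Orientation(str, enum.Enum):
    """Which side of the image the anterior chest wall faces."""

    ANTERIOR_LEFT = "anterior_left"
    ANTERIOR_RIGHT = "anterior_right"


class MaskError(ValueError):
    """Raised for unreadable or degenerate mask inputs."""


@dataclass
class MaskFrame:
    """One binary lung mask with its physical spacing.

    ``pixels[r, c]`` is nonzero inside the lung; ``spacing_mm`` is the
    (row, column) pixel size in mm.
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float]
    frame_index: int = 0
    orientation_flag: Orientation = Orientation.ANTERIOR_LEFT

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels) != 0
        sr, sc = self.spacing_mm
        if sr <= 0 or sc <= 0:
            raise MaskError(f"spacing must be positive, got {self.spacing_mm}")
        self.spacing_mm = (float(sr), float(sc))
        self.orientation_flag = Orientation(self.orientation_flag)


@dataclass
class FrameSeries:
    """Ordered respiratory sequence of lung contours for one subject.

    By default the first frame is end-expiration and the last frame is
    end-inspiration, matching an acquisition that starts at an expiratory
    breath-hold and ends at an inspiratory breath-hold.
    """

    contours: list[LungContour]
    end_expiration_index: int = 0
    end_inspiration_index: int | None = None
    subject_id: str = ""
    spacing_mm: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.contours) < 2:
            raise MaskError("a frame series needs at least 2 frames")
        if self.end_inspiration_index is None:
            self.end_inspiration_index = len(self.contours) - 1
        n = len(self.contours)
        for name, idx in (("end_expiration_index", self.end_expiration_index),
                          ("end_inspiration_index", self.end_inspiration_index)):
            if not (0 <= idx < n):
                raise MaskError(f"{name}={idx} out of range for {n} frames")
        if self.end_expiration_index == self.end_inspiration_index:
            raise MaskError("end-expiration and end-inspiration frames coincide")

    @property
    def n_frames(self) -> int:
        return len(self.contours)

    @property
    def end_expiration(self) -> LungContour:
        return self.contours[self.end_expiration_index]

    @property
    def end_inspiration(self) -> LungContour:
        return self.contours[self.end_inspiration_index]


def pixel_to_mm(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int],
                spacing_mm: tuple[float, float],
                orientation: Orientation) -> np.ndarray:
    """Map (row, col) image coordinates to (x_mm, y_mm) physical coordinates."""
    n_rows, n_cols = shape
    sr, sc = spacing_mm
    y = (n_rows - 1 - np.asarray(rows, float)) * sr
    if Orientation(orientation) is Orientation.ANTERIOR_LEFT:
        x = np.asarray(cols, float) * sc
    else:
        x = (n_cols - 1 - np.asarray(cols, float)) * sc
    return np.column_stack([x, y])


def extract_contour(frame: MaskFrame) -> LungContour:
    """Trace the outline of the largest foreground component at the 0.5 level.

    Sub-pixel iso-contouring (marching squares) is used rather than pixel-edge
    tracing, which removes most of the staircase bias in area and distance
    measurements.  Interior holes are discarded; of multiple foreground
    components the largest by pixel count wins (ties broken by earliest
    raster-scan order).
    """
    mask = frame.pixels
    if not mask.any():
        raise MaskError(f"frame {frame.frame_index}: no foreground pixels")
    labels, n = measure.label(mask, return_num=True)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        # np.argmax returns the first maximum, i.e. the component whose first
        # pixel comes earliest in raster-scan order
        keep = int(np.argmax(counts))
        mask = labels == keep
    # pad so the iso-contour closes even when the component touches the border
    padded = np.pad(mask.astype(float), 1)
    loops = measure.find_contours(padded, 0.5)
    if not loops:  # pragma: no cover - cannot happen with a nonempty mask
        raise MaskError(f"frame {frame.frame_index}: contour tracing failed")
    # outer boundary = loop with the largest enclosed area (holes are smaller)
    def loop_area(rc: np.ndarray) -> float:
        r, c = rc[:, 0], rc[:, 1]
        return abs(0.5 * np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c))

    outer = max(loops, key=loop_area)
    rows = outer[:, 0] - 1.0  # undo padding
    cols = outer[:, 1] - 1.0
    xy = pixel_to_mm(rows, cols, mask.shape, frame.spacing_mm,
                     frame.orientation_flag)
    try:
        return LungContour(xy)
    except ContourError as exc:
        raise MaskError(f"frame {frame.frame_index}: {exc}") from exc


def _read_png_frames(directory: Path) -> list[np.ndarray]:
    files = sorted(directory.glob("*.png"))
    if not files:
        raise MaskError(f"no PNG files found in {directory}")
    return [np.asarray(iio.imread(f)) for f in files]


def _read_nifti_frames(path: Path) -> tuple[list[np.ndarray], tuple[float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise MaskError(f"expected a 3-D (x, y, time) NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:2]
    frames = [data[:, :, t] for t in range(data.shape[2])]
    return frames, (float(zooms[0]), float(zooms[1]))


def read_mask_stack(path: str | Path,
                    spacing_mm: tuple[float, float] | None = None,
                    orientation: Orientation | str = Orientation.ANTERIOR_LEFT,
                    *,
                    end_expiration_index: int = 0,
                    end_inspiration_index: int | None = None,
                    subject_id: str | None = None) -> FrameSeries:
    """Read a mask stack (PNG directory or NIfTI volume) into a FrameSeries.

    PNG stacks require ``spacing_mm``; for NIfTI the header spacing is used
    unless ``spacing_mm`` overrides it.  Any nonzero pixel is foreground.
    """
    path = Path(path)
    orientation = Orientation(orientation)
    if path.is_dir():
        arrays = _read_png_frames(path)
        if spacing_mm is None:
            raise MaskError("spacing_mm is required for PNG stacks")
    elif path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        arrays, header_spacing = _read_nifti_frames(path)
        if spacing_mm is None:
            spacing_mm = header_spacing
    else:
        raise MaskError(f"cannot read masks from {path}: expected a directory "
                        "of PNGs or a .nii/.nii.gz volume")
    if len(arrays) < 2:
        raise MaskError(f"{path}: need at least 2 frames, found {len(arrays)}")

    contours = []
    for i, arr in enumerate(arrays):
        if arr.ndim == 3:  # RGB(A) PNG: any nonzero channel counts
            arr = arr.max(axis=2)
        frame = MaskFrame(arr, spacing_mm, frame_index=i,
                          orientation_flag=orientation)
        contours.append(extract_contour(frame))
    return FrameSeries(contours,
                       end_expiration_index=end_expiration_index,
                       end_inspiration_index=end_inspiration_index,
                       subject_id=subject_id or path.stem,
                       spacing_mm=tuple(spacing_mm))


def write_contours_csv(series: FrameSeries, path: str | Path) -> None:
    """Dump the per-frame contour vertices as a long-format CSV."""
    import pandas as pd

    rows = []
    for i, contour in enumerate(series.contours):
        for j, (x, y) in enumerate(contour.vertices):
            rows.append((series.subject_id, i, j, x, y))
    pd.DataFrame(rows, columns=["subject_id", "frame_index", "vertex_index",
                                "x_mm", "y_mm"]).to_csv(path, index=False)
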