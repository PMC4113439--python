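"""Fundus photographs, circular analysis regions, and per-channel statistics.

The quantification operates on an 8-bit RGB fundus photograph and a circular
region of interest (ROI) placed on the fovea–optic-disc axis.  The default
region is a disk of 250 pixel diameter centred at the midpoint of the two
landmarks: large retinal vessel arcades and the peripapillary conus lie
outside that area, so no vessel masking is applied inside it.

Coordinate conventions (fixed so every geometric result is reproducible):

* pixel indices are 0-based, ``x`` rightward (column), ``y`` downward (row);
* a pixel ``(px, py)`` occupies the unit square with centre
  ``(px + 0.5, py + 0.5)`` in continuous coordinates;
* a pixel belongs to a disk when its centre lies at Euclidean distance
  ``<= diameter / 2`` from the disk centre point (closed boundary).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import EmptyROIError, GeometryError, ImageReadError, UnsupportedDepthError

__all__ = [
    "FundusImage",
    "Landmarks",
    "CircularROI",
    "ChannelStats",
    "load_image",
    "default_roi",
    "roi_pixels",
    "channel_stats",
    "read_landmarks_csv",
]

#: Default analysis-disk diameter in pixels.
DEFAULT_ROI_DIAMETER = 250


@dataclass(frozen=True)
class FundusImage:
    """An 8-bit RGB fundus photograph.

    Attributes
    ----------
    pixels
        ``(height, width, 3)`` uint8 array, channels ordered R, G, B.
    eye_id
        Opaque identifier carried through to per-eye outputs.
    """

    pixels: np.ndarray
    eye_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise UnsupportedDepthError(
                f"expected 8-bit channels, got dtype {px.dtype}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Landmarks:
    """Fovea and optic-disc centre positions, integer pixel coordinates."""

    fovea: tuple[int, int]
    disc_center: tuple[int, int]

    def validate(self, image: FundusImage) -> None:
        for name, (x, y) in (("fovea", self.fovea), ("disc_center", self.disc_center)):
            if not (0 <= x < image.width and 0 <= y < image.height):
                raise GeometryError(
                    f"{name} {(x, y)} outside image bounds "
                    f"{image.width}x{image.height}"
                )
        if tuple(self.fovea) == tuple(self.disc_center):
            raise GeometryError("fovea and disc centre coincide")


@dataclass(frozen=True)
class CircularROI:
    """A closed disk of pixels; must fit entirely inside its image."""

    center: tuple[int, int]
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise GeometryError(f"diameter must be > 0, got {self.diameter}")

    def check_bounds(self, image: FundusImage) -> None:
        cx, cy = self.center
        r = self.diameter / 2.0
        # disk measured at pixel centres; centre point of pixel (cx, cy) is
        # (cx+0.5, cy+0.5), so the disk spans [c+0.5-r, c+0.5+r] in each axis
        if cx + 0.5 - r < 0 or cx + 0.5 + r > image.width:
            raise GeometryError(
                f"ROI (center={self.center}, diameter={self.diameter}) exceeds "
                f"image width {image.width}"
            )
        if cy + 0.5 - r < 0 or cy + 0.5 + r > image.height:
            raise GeometryError(
                f"ROI (center={self.center}, diameter={self.diameter}) exceeds "
                f"image height {image.height}"
            )


@dataclass(frozen=True)
class ChannelStats:
    """Histogram summary of the ROI, one row per color channel.

    ``mean``, ``sd``, ``minimum``, ``maximum``, ``median`` are 3-vectors in
    R, G, B order on the raw 0–255 intensity scale; ``count`` is the number
    of ROI pixels (identical across channels).  The standard deviation uses
    the population divisor ``n``, matching image-histogram software.
    """

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]
    minimum: tuple[float, float, float]
    maximum: tuple[float, float, float]
    median: tuple[float, float, float]
    count: int

    @property
    def mean_r(self) -> float:
        return self.mean[0]

    @property
    def mean_g(self) -> float:
        return self.mean[1]

    @property
    def mean_b(self) -> float:
        return self.mean[2]


def load_image(path: str | Path, eye_id: str | None = None) -> FundusImage:
    """Read a PNG/TIFF/JPEG fundus photograph as 8-bit RGB.

    Grayscale images are replicated across channels and an alpha channel is
    dropped; both conversions are deterministic.  Rasters deeper than 8 bits
    per channel are rejected rather than silently rescaled.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("I", "I;16", "I;16B", "I;16L", "I;16N", "F"):
                raise UnsupportedDepthError(
                    f"{path.name}: mode {im.mode!r} is not 8-bit; convert first"
                )
            if im.mode not in ("RGB", "L", "RGBA", "LA", "P"):
                raise UnsupportedDepthError(
                    f"{path.name}: unsupported mode {im.mode!r}"
                )
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.uint8)
    except UnsupportedDepthError:
        raise
    except (OSError, UnidentifiedImageError, SyntaxError) as exc:
        raise ImageReadError(f"cannot read {path}: {exc}") from exc
    return FundusImage(pixels=arr, eye_id=eye_id if eye_id is not None else path.stem)


def _round_half_away(v: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.floor(v + 0.5)) if v >= 0 else int(np.ceil(v - 0.5))


def default_roi(
    image: FundusImage,
    landmarks: Landmarks,
    diameter: float = DEFAULT_ROI_DIAMETER,
) -> CircularROI:
    """Place the analysis disk at the midpoint of the fovea–disc segment.

    The midpoint is rounded to the nearest integer pixel (halves away from
    zero).  Raises :class:`GeometryError` when the disk would leave the
    image — the photograph is too small or the landmarks sit near a border.
    """
    landmarks.validate(image)
    fx, fy = landmarks.fovea
    dx, dy = landmarks.disc_center
    center = (_round_half_away((fx + dx) / 2.0), _round_half_away((fy + dy) / 2.0))
    roi = CircularROI(center=center, diameter=diameter)
    roi.check_bounds(image)
    return roi


def roi_mask(image: FundusImage, roi: CircularROI) -> np.ndarray:
    """Boolean (H, W) membership mask of the ROI disk.

    A pixel is inside when its centre lies within ``diameter/2`` of the
    centre pixel's centre point (closed boundary).
    """
    cx, cy = roi.center
    r = roi.diameter / 2.0
    ys = np.arange(image.height, dtype=np.float64)[:, None]
    xs = np.arange(image.width, dtype=np.float64)[None, :]
    # pixel centres differ from the ROI centre pixel's centre by integer steps,
    # so the +0.5 offsets cancel
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r


def roi_pixels(image: FundusImage, roi: CircularROI) -> np.ndarray:
    """Extract ROI pixels as an ``(n, 3)`` uint8 array in row-major order."""
    roi.check_bounds(image)
    mask = roi_mask(image, roi)
    return image.pixels[mask]


def channel_stats(pixels: np.ndarray) -> ChannelStats:
    """Summarise an ``(n, 3)`` RGB pixel array channel by channel.

    Mean is the arithmetic mean of the raw 0–255 values; SD is the
    population standard deviation (divisor ``n``); the median of an even
    count is the midpoint of the two central values.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected (n, 3) pixel array, got shape {arr.shape}")
    if arr.shape[0] == 0:
        raise EmptyROIError("no pixels in region")
    return ChannelStats(
        mean=tuple(arr.mean(axis=0)),
        sd=tuple(arr.std(axis=0, ddof=0)),
        minimum=tuple(arr.min(axis=0)),
        maximum=tuple(arr.max(axis=0)),
        median=tuple(np.median(arr, axis=0)),
        count=arr.shape[0],
    )


LANDMARKS_COLUMNS = ["eye_id", "fovea_x", "fovea_y", "disc_x", "disc_y"]


def read_landmarks_csv(path: str | Path) -> dict[str, Landmarks]:
    """Read the landmarks table (``eye_id,fovea_x,fovea_y,disc_x,disc_y``)."""
    df = pd.read_csv(path, dtype={"eye_id": str})
    if list(df.columns) != LANDMARKS_COLUMNS:
        raise ValueError(
            f"landmarks CSV must have columns {LANDMARKS_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    return {
        row.eye_id: Landmarks(
            fovea=(int(row.fovea_x), int(row.fovea_y)),
            disc_center=(int(row.disc_x), int(row.disc_y)),
        )
        for row in df.itertuples()
    }


def write_landmarks_csv(path: str | Path, landmarks: dict[str, Landmarks]) -> None:
    rows = [
        {
            "eye_id": eid,
            "fovea_x": lm.fovea[0],
            "fovea_y": lm.fovea[1],
            "disc_x": lm.disc_center[0],
            "disc_y": lm.disc_center[1],
        }
        for eid, lm in landmarks.items()
    ]
    pd.DataFrame(rows, columns=LANDMARKS_COLUMNS).to_csv(path, index=False)
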