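"""Loading, orientation, and normalization of scanned race-tube pack images.

Every image entering the pipeline is reduced to the canonical internal
representation: an 8-bit greyscale grid of exactly 400 rows by 1160 columns,
growth direction left-to-right (inoculation end at ``x = 0``).  The fixed
size reflects the aspect ratio of the straight portion of a standard
six-pack of race tubes; downstream period estimates are expressed in hours
via the time-mark calibration, so moderate stretching introduced by the
resize does not propagate into the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import DegenerateInputError, ImageFormatError

#: Canonical normalized image size (width, height) in pixels.
TARGET_WIDTH = 1160
TARGET_HEIGHT = 400

#: ITU-R BT.601 luminance weights for RGB -> greyscale reduction.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Orientation transforms applied before greyscale conversion and resizing.
ORIENTATIONS = ("none", "rot90", "rot180", "rot270", "flip_h", "flip_v")

#: Raster formats accepted for upload. Configurable: any format Pillow can
#: decode will in fact load; this tuple documents the supported surface.
ACCEPTED_FORMATS = (".tif", ".tiff", ".png", ".jpg", ".jpeg", ".bmp", ".gif")


@dataclass
class RaceTubeImage:
    """A normalized greyscale race-tube pack image with provenance.

    Attributes
    ----------
    pixels
        ``(400, 1160)`` array of ``uint8`` brightness values (0 = black,
        255 = white).
    source_path
        Path of the original raster file ('' for synthetic images).
    pack_name
        User-facing name for this pack of tubes.
    orientation_applied
        Which member of :data:`ORIENTATIONS` was applied before resizing.
    """

    pixels: np.ndarray
    source_path: str = ""
    pack_name: str = ""
    orientation_applied: str = "none"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (TARGET_HEIGHT, TARGET_WIDTH):
            raise ValueError(
                f"normalized image must be {TARGET_HEIGHT}x{TARGET_WIDTH}, "
                f"got {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            if np.any(self.pixels < 0) or np.any(self.pixels > 255):
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.orientation_applied not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation_applied!r}")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


def to_greyscale(pixels: np.ndarray) -> np.ndarray:
    """Reduce a colour pixel grid to a single brightness channel in [0, 255].

    RGB channels are combined with the BT.601 luminance weights
    (0.299, 0.587, 0.114).  An alpha channel, if present, is dropped:
    flatbed scans carry no meaningful transparency.  Greyscale input is
    passed through unchanged (as float).
    """
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or arr.shape[2] not in (1, 2, 3, 4):
        raise ValueError(f"expected HxW or HxWxC (C in 1..4), got {arr.shape}")
    c = arr.shape[2]
    if c == 1:
        return arr[:, :, 0]
    if c == 2:  # grey + alpha
        return arr[:, :, 0]
    return arr[:, :, :3] @ LUMA_WEIGHTS


def _apply_orientation(im: Image.Image, orientation: str) -> Image.Image:
    if orientation == "none":
        return im
    ops = {
        # PIL rotate is counter-clockwise; expand to keep the full frame.
        "rot90": Image.Transpose.ROTATE_90,
        "rot180": Image.Transpose.ROTATE_180,
        "rot270": Image.Transpose.ROTATE_270,
        "flip_h": Image.Transpose.FLIP_LEFT_RIGHT,
        "flip_v": Image.Transpose.FLIP_TOP_BOTTOM,
    }
    try:
        return im.transpose(ops[orientation])
    except KeyError:
        raise ValueError(f"unknown orientation {orientation!r}") from None


def normalize_array(
    pixels: np.ndarray,
    *,
    source_path: str = "",
    pack_name: str = "",
    orientation_applied: str = "none",
) -> RaceTubeImage:
    """Normalize an arbitrary greyscale array to the canonical 1160x400 grid.

    Bicubic interpolation is used for the resize; resampling at native size
    is an exact identity.  Resampled values are rounded half-to-even and
    clipped to the 8-bit range.
    """
    arr = np.asarray(pixels, dtype=np.float32)
    if arr.ndim != 2:
        arr = to_greyscale(arr).astype(np.float32)
    if arr.size == 0:
        raise DegenerateInputError("zero-area image")
    if arr.shape == (TARGET_HEIGHT, TARGET_WIDTH):
        out = arr.astype(float)
    else:
        im = Image.fromarray(arr, mode="F")
        im = im.resize((TARGET_WIDTH, TARGET_HEIGHT), Image.Resampling.BICUBIC)
        out = np.asarray(im, dtype=float)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return RaceTubeImage(
        pixels=out,
        source_path=source_path,
        pack_name=pack_name,
        orientation_applied=orientation_applied,
    )


def load_image(
    path: str | Path,
    orientation: str = "none",
    pack_name: str | None = None,
) -> RaceTubeImage:
    """Load a raster file and normalize it to the canonical representation.

    Parameters
    ----------
    path
        Path to a TIFF/PNG/JPEG/BMP/GIF scan, colour or greyscale.
    orientation
        Rotation/flip applied *before* greyscale conversion and resizing so
        that growth runs left-to-right with tubes horizontal.
    pack_name
        Pack label; defaults to the file stem.

    Raises
    ------
    ImageFormatError
        If the file does not exist or cannot be decoded as a raster image.
    DegenerateInputError
        If the decoded image has zero area.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such file: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            im = _apply_orientation(im, orientation)
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"cannot decode {path} as a raster image") from exc
    if arr.size == 0:
        raise DegenerateInputError(f"zero-area image: {path}")
    grey = to_greyscale(arr)
    return normalize_array(
        grey,
        source_path=str(path),
        pack_name=pack_name if pack_name is not None else path.stem,
        orientation_applied=orientation,
    )


def save_normalized(img: RaceTubeImage, path: str | Path) -> Path:
    """Write the normalized greyscale grid as an 8-bit PNG (lossless)."""
    path = Path(path)
    Image.fromarray(img.pixels, mode="L").save(path, format="PNG")
    return path
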