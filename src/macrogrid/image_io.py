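"""Loading, validation and mirroring of macroarray scans.

Scans are single-channel TIFF images from a 16-bit scanner.  Lossy
compression is rejected because dot quantification sums raw pixel
values; lossless codecs (none, LZW, deflate, packbits) pass through
unchanged.  Depending on which face of the membrane was scanned the
image may need to be mirrored left-right before any processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ArrayImage",
    "ImageFormatError",
    "SaturationError",
    "SaturationReport",
    "load_image",
    "write_image",
    "mirror_image",
    "check_saturation",
]

# TIFF compression schemes that do not alter pixel values.
_LOSSLESS_COMPRESSION = {1, 5, 8, 32773, 32946}  # none, LZW, deflate(x2), packbits


class ImageFormatError(ValueError):
    """The input file is not an acceptable single-channel lossless scan."""


class SaturationError(RuntimeError):
    """Saturated pixels found while running in strict mode."""


@dataclass
class ArrayImage:
    """A validated single-channel scan held as a 2-D uint16 pixel grid."""

    pixels: np.ndarray
    source: str = "<memory>"
    mirrored: bool = False
    source_bit_depth: int = 16

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ImageFormatError(f"expected a single-channel image, got shape {self.pixels.shape}")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class SaturationReport:
    limit: int
    count: int
    coordinates: np.ndarray = field(repr=False)  # (n, 2) array of (x, y)

    @property
    def passed(self) -> bool:
        return self.count == 0


def load_image(path, mirror: bool = False, allow_png: bool = False) -> ArrayImage:
    """Load a grayscale scan from a lossless TIFF (optionally PNG).

    8-bit input is accepted and promoted onto the 16-bit scale (x257 so
    that full scale maps to full scale); the original bit depth is kept
    in the provenance.  Multi-channel or lossily compressed input raises
    :class:`ImageFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".png",):
        if not allow_png:
            raise ImageFormatError("PNG input requires allow_png=True (TIFF is the default)")
        import imageio.v3 as iio

        data = iio.imread(path)
    else:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            comp = int(page.compression)
            if comp not in _LOSSLESS_COMPRESSION:
                raise ImageFormatError(
                    f"unsupported (lossy or exotic) TIFF compression {page.compression!r}; "
                    "re-export without compression"
                )
            data = page.asarray()

    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if data.ndim != 2:
        raise ImageFormatError(
            f"expected a single-channel grayscale image, got shape {data.shape}"
        )

    if data.dtype == np.uint16:
        bit_depth = 16
        pixels = data
    elif data.dtype == np.uint8:
        bit_depth = 8
        pixels = data.astype(np.uint16) * 257  # promote full scale to full scale
    else:
        raise ImageFormatError(
            f"unsupported pixel type {data.dtype}; expected 8- or 16-bit unsigned integers"
        )

    if mirror:
        pixels = np.fliplr(pixels)
    return ArrayImage(
        pixels=np.ascontiguousarray(pixels),
        source=str(path),
        mirrored=mirror,
        source_bit_depth=bit_depth,
    )


def write_image(path, img: ArrayImage) -> None:
    """Write the pixel grid as an uncompressed 16-bit TIFF."""
    tifffile.imwrite(str(path), np.asarray(img.pixels, dtype=np.uint16))


def mirror_image(img: ArrayImage) -> ArrayImage:
    """Flip left-right; applying it twice restores the original grid."""
    return ArrayImage(
        pixels=np.fliplr(img.pixels),
        source=img.source,
        mirrored=not img.mirrored,
        source_bit_depth=img.source_bit_depth,
    )


def check_saturation(img: ArrayImage, limit: int = 65535, strict: bool = False) -> SaturationReport:
    """Count pixels at or above ``limit``.

    Saturated pixels sit outside the scanner's linear range, so any
    nonzero count is a data-quality warning; with ``strict`` it becomes
    a :class:`SaturationError`.
    """
    if limit > 65535:
        raise ValueError("saturation limit cannot exceed the 16-bit range")
    rows, cols = np.nonzero(img.pixels >= limit)
    coords = np.column_stack([cols, rows])  # (x, y)
    report = SaturationReport(limit=limit, count=len(coords), coordinates=coords)
    if strict and report.count:
        raise SaturationError(
            f"{report.count} pixel(s) at or above {limit}; rescan at lower exposure"
        )
    return report
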