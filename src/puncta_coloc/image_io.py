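"""Image loading, channel-role mapping, 8-bit RGB conversion and z-projection.

All downstream analysis runs on an 8-bit red/green/blue working form, so the
first step for any input image is to (a) assign each source channel to one of
the roles *red*, *green*, *blue* and (b) collapse z-stacks into grouped
maximum-intensity projections that are then analyzed as independent images.

Pixel coordinates are 0-based ``(row, col)``, origin top-left.
"""

from __future__ import annotations

import logging
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

logger = logging.getLogger(__name__)

ROLES = ("red", "green", "blue")


@dataclass
class ImageRecord:
    """A loaded multi-channel image or z-stack.

    Parameters
    ----------
    planes
        Mapping role -> 3-D ``(z, height, width)`` array of non-negative
        integer intensities.  All roles share one shape.
    channel_map
        Mapping role -> source channel index in the original file.
    bit_depth
        8 or 16.
    source_path
        Where the image came from (provenance only).
    pixel_size_um
        Optional physical pixel size in microns; metadata only, never used
        in computation.
    """

    planes: dict[str, np.ndarray]
    channel_map: dict[str, int]
    bit_depth: int
    source_path: str = ""
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"unsupported bit depth: {self.bit_depth} (must be 8 or 16)")
        if "red" not in self.planes or "green" not in self.planes:
            raise ValueError("red and green roles must both be assigned")
        shapes = {role: p.shape for role, p in self.planes.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"all channels must share one (z, h, w) shape, got {shapes}")
        for role, p in self.planes.items():
            if p.ndim != 3:
                raise ValueError(f"channel {role!r} must be 3-D (z, h, w), got {p.ndim}-D")
        indices = list(self.channel_map.values())
        if len(indices) != len(set(indices)):
            raise ValueError("channel_map roles must map to distinct source channels")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def z(self) -> int:
        return next(iter(self.planes.values())).shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        s = next(iter(self.planes.values())).shape
        return (s[1], s[2])

    @property
    def name(self) -> str:
        """Basename without extension (taken up to the *last* dot)."""
        base = os.path.basename(self.source_path)
        if base.count(".") > 1:
            warnings.warn(
                f"filename {base!r} contains multiple '.' characters; "
                "using the basename up to the last dot",
                stacklevel=2,
            )
        stem, _, _ = base.rpartition(".")
        return stem or base


@dataclass
class RGB8Image:
    """A single 2-D working image with 8-bit red, green and blue planes."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def __post_init__(self) -> None:
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError("red, green and blue planes must share one shape")
        for name in ("red", "green", "blue"):
            plane = getattr(self, name)
            if plane.ndim != 2:
                raise ValueError(f"{name} plane must be 2-D")
            if plane.dtype != np.uint8:
                if np.any(plane < 0) or np.any(plane > 255):
                    raise ValueError(f"{name} plane has values outside [0, 255]")
                setattr(self, name, plane.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]

    def plane(self, role: str) -> np.ndarray:
        return getattr(self, role)

    def to_array(self) -> np.ndarray:
        """Stack into an ``(h, w, 3)`` uint8 array (for writing to disk)."""
        return np.stack([self.red, self.green, self.blue], axis=-1)


def _read_channel_stack(path: str) -> np.ndarray:
    """Read any supported file into a canonical ``(z, c, h, w)`` array."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:  # single grayscale plane
        return arr[None, None, :, :]
    if arr.ndim == 3:
        # Channel-last (h, w, c) for small trailing axis, else (z|c, h, w).
        if arr.shape[-1] <= 4 and arr.shape[-1] < min(arr.shape[:2]):
            return np.moveaxis(arr, -1, 0)[None, :, :, :]
        # Ambiguous (n, h, w): TIFF pages. Treat a small leading axis as
        # channels, otherwise as z-planes of a single channel.
        if arr.shape[0] <= 4:
            return arr[None, :, :, :]
        return arr[:, None, :, :]
    if arr.ndim == 4:
        # (z, c, h, w) or (z, h, w, c)
        if arr.shape[-1] <= 4 and arr.shape[-1] < arr.shape[-2]:
            return np.moveaxis(arr, -1, 1)
        return arr
    raise ValueError(f"cannot interpret image with shape {arr.shape}")


def load_image(path: str, channel_map: Mapping[str, int]) -> ImageRecord:
    """Load a TIFF/PNG/BMP image and assign channels to color roles.

    Parameters
    ----------
    path
        Image file.  Multi-page TIFFs are read as z-stacks; a page or sample
        axis of length <= 4 is interpreted as channels.
    channel_map
        Role -> source channel index, e.g. ``{"red": 0, "green": 1}``.
        ``red`` and ``green`` are mandatory, ``blue`` optional.

    Returns
    -------
    ImageRecord with ``z >= 1``; single-plane images get ``z = 1``.
    """
    if not os.path.isfile(path):
        raise FileNotFoundError(f"unreadable file: {path}")
    for role in channel_map:
        if role not in ROLES:
            raise ValueError(f"unknown channel role {role!r}; expected one of {ROLES}")
    if "red" not in channel_map or "green" not in channel_map:
        raise ValueError(
            "channel_map must assign both the red and the green role "
            "(a single grayscale channel cannot provide two roles)"
        )
    try:
        stack = _read_channel_stack(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface reader errors uniformly
        raise OSError(f"unreadable file: {path}: {exc}") from exc

    n_channels = stack.shape[1]
    for role, idx in channel_map.items():
        if not (0 <= idx < n_channels):
            raise IndexError(
                f"channel index out of range: role {role!r} -> {idx}, "
                f"file has {n_channels} channel(s)"
            )

    if stack.dtype == np.uint8:
        bit_depth = 8
    elif stack.dtype == np.uint16:
        bit_depth = 16
    elif np.issubdtype(stack.dtype, np.integer):
        vmax = int(stack.max(initial=0))
        bit_depth = 8 if vmax <= 255 else 16
        if vmax > 65535:
            raise ValueError(f"unsupported bit depth in {path}: max value {vmax}")
    else:
        raise ValueError(f"unsupported bit depth (dtype {stack.dtype}) in {path}")

    planes = {role: np.ascontiguousarray(stack[:, idx]) for role, idx in channel_map.items()}
    return ImageRecord(
        planes=planes,
        channel_map=dict(channel_map),
        bit_depth=bit_depth,
        source_path=str(path),
    )


def to_rgb8(
    planes: ImageRecord | Mapping[str, np.ndarray],
    *,
    bit_depth: int | None = None,
    mode: str = "fixed",
) -> RGB8Image:
    """Convert single-plane channel data to the 8-bit RGB working form.

    ``mode="fixed"`` (default) maps 16-bit values with ``v -> floor(v / 256)``,
    which is deterministic and comparable across images; ``mode="minmax"``
    stretches each plane's ``[min, max]`` onto ``[0, 255]`` the way
    display-range based converters do.  8-bit input passes through unchanged
    in either mode.  A missing blue role yields an all-zero blue plane.
    """
    if isinstance(planes, ImageRecord):
        if planes.z > 1:
            raise ValueError(
                f"image still has z={planes.z} planes; z-project before RGB conversion"
            )
        bit_depth = planes.bit_depth
        data = {role: p[0] for role, p in planes.planes.items()}
    else:
        data = {}
        for role, p in planes.items():
            p = np.asarray(p)
            if p.ndim == 3:
                if p.shape[0] != 1:
                    raise ValueError(f"channel {role!r} still has z={p.shape[0]} planes")
                p = p[0]
            elif p.ndim != 2:
                raise ValueError(f"channel {role!r} must be 2-D")
            data[role] = p
        if bit_depth is None:
            vmax = max(int(p.max(initial=0)) for p in data.values())
            bit_depth = 8 if vmax <= 255 else 16
    if mode not in ("fixed", "minmax"):
        raise ValueError(f"unknown conversion mode {mode!r}")

    def convert(plane: np.ndarray) -> np.ndarray:
        if mode == "minmax":
            lo, hi = float(plane.min()), float(plane.max())
            if hi == lo:
                return np.zeros(plane.shape, dtype=np.uint8)
            return np.floor((plane.astype(np.float64) - lo) / (hi - lo) * 255.0 + 0.5).astype(np.uint8)
        if bit_depth == 8:
            return plane.astype(np.uint8)
        return (plane.astype(np.uint32) // 256).astype(np.uint8)

    shape = next(iter(data.values())).shape
    out = {role: convert(data[role]) for role in data}
    if "blue" not in out:
        out["blue"] = np.zeros(shape, dtype=np.uint8)
    return RGB8Image(red=out["red"], green=out["green"], blue=out["blue"])


def zproject_groups(img: ImageRecord, group_size: int) -> list[dict[str, np.ndarray]]:
    """Partition z-planes into consecutive groups and max-project each group.

    Planes are grouped in z-order into runs of ``group_size``; each group
    yields the per-pixel maximum across its planes, per channel.  A trailing
    incomplete group (``z mod group_size != 0``) is projected from its
    remaining planes and flagged in the log so users can exclude it.

    Returns a list of ``ceil(z / group_size)`` mappings role -> 2-D plane;
    each projection is analyzed downstream as a separate image.
    """
    if group_size < 1:
        raise ValueError(f"group_size must be >= 1, got {group_size}")
    z = img.z
    n_groups = math.ceil(z / group_size)
    projections: list[dict[str, np.ndarray]] = []
    for g in range(n_groups):
        lo, hi = g * group_size, min((g + 1) * group_size, z)
        if hi - lo < group_size:
            logger.warning(
                "image %s: trailing z-group %d projected from %d plane(s) "
                "instead of %d", img.source_path or "<memory>", g, hi - lo, group_size,
            )
        projections.append({role: p[lo:hi].max(axis=0) for role, p in img.planes.items()})
    return projections
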