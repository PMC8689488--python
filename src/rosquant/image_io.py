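"""Reading and writing multi-channel z-stacks and binary masks.

Channel-role convention: CH1 carries shell autofluorescence (``shell``),
CH2 carries the ROS stain (``ros``), CH3 carries gut autofluorescence
(``gut``).  CH1 and CH2 are mandatory for quantification; CH3 is carried
through when present but never enters the analysis.

Two on-disk dialects are supported:

* OME-TIFF written by :func:`write_stack` (axes ``CZYX``, channel names in
  the OME metadata).  OME channel names, when present and recognisable,
  override any declared ``channel_order``.
* Plain multi-page TIFF: pages are slices with channels cycling fastest
  (``Z*C`` pages), or a bare 4-D array; the channel order must then be
  declared by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

SHELL = "shell"
ROS = "ros"
GUT = "gut"

#: Default acquisition order: CH1 (shell), CH2 (ROS), CH3 (gut).
DEFAULT_CHANNEL_ORDER: tuple[str, ...] = (SHELL, ROS, GUT)

_ROLE_ALIASES: Mapping[str, str] = {
    "shell": SHELL,
    "ros": ROS,
    "gut": GUT,
    "ch1": SHELL,
    "ch2": ROS,
    "ch3": GUT,
    "blue": SHELL,
    "green": ROS,
    "red": GUT,
}

MASK_ROLES = ("shell_roi", "ros_positive", "truth_shell", "truth_ros")


class StackFormatError(ValueError):
    """Raised when file content does not match the declared stack layout."""


class StackIOError(IOError):
    """Raised when a stack or mask file cannot be read or written."""


def canonical_role(name: str) -> str:
    key = str(name).strip().lower()
    try:
        return _ROLE_ALIASES[key]
    except KeyError:
        raise StackFormatError(f"unknown channel role {name!r}") from None


def canonical_roles(order: Iterable[str]) -> tuple[str, ...]:
    roles = tuple(canonical_role(r) for r in order)
    if len(set(roles)) != len(roles):
        raise StackFormatError(f"duplicate channel roles in {tuple(order)!r}")
    return roles


@dataclass(frozen=True)
class ZStack:
    """A 3-D multi-channel acquisition, one individual (or field) per stack.

    Parameters
    ----------
    voxels
        Unsigned-integer array of shape ``(channels, slices, rows, cols)``.
    channels
        Role per channel axis entry; must include ``shell`` and ``ros``.
    pixel_size_um
        Lateral pixel size in micrometres, if known.
    bit_depth
        Source dynamic range in bits.  Defaults to the container dtype width.
    source
        Free-form provenance label (file path or phantom id).
    """

    voxels: np.ndarray
    channels: tuple[str, ...] = DEFAULT_CHANNEL_ORDER
    pixel_size_um: float | None = None
    bit_depth: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels)
        if voxels.ndim != 4:
            raise StackFormatError(
                f"voxels must be (channels, slices, rows, cols); got shape {voxels.shape}"
            )
        if not np.issubdtype(voxels.dtype, np.unsignedinteger):
            if np.issubdtype(voxels.dtype, np.signedinteger) and voxels.min() >= 0:
                voxels = voxels.astype(np.uint16)
            else:
                raise StackFormatError(
                    f"stack intensities must be non-negative integers; got dtype {voxels.dtype}"
                )
        roles = canonical_roles(self.channels)
        if voxels.shape[0] != len(roles):
            raise StackFormatError(
                f"declared {len(roles)} channels but voxel array has {voxels.shape[0]}"
            )
        if SHELL not in roles or ROS not in roles:
            raise StackFormatError("stack must contain at least the shell (CH1) and ros (CH2) channels")
        if voxels.shape[1] < 1:
            raise StackFormatError("stack must contain at least one slice")
        bit_depth = self.bit_depth
        if bit_depth is None:
            bit_depth = voxels.dtype.itemsize * 8
        elif voxels.max(initial=0) > 2**bit_depth - 1:
            raise StackFormatError(
                f"intensities exceed the declared {bit_depth}-bit dynamic range"
            )
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "channels", roles)
        object.__setattr__(self, "bit_depth", int(bit_depth))

    # -- accessors ---------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[2], self.voxels.shape[3]

    def has_channel(self, role: str) -> bool:
        return canonical_role(role) in self.channels

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(slices, rows, cols)`` volume for one channel role."""
        role = canonical_role(role)
        try:
            idx = self.channels.index(role)
        except ValueError:
            raise KeyError(f"stack has no {role!r} channel") from None
        return self.voxels[idx]

    def with_source(self, source: str) -> "ZStack":
        return replace(self, source=source)


@dataclass(frozen=True)
class ProjectionSet:
    """Per-channel 2-D maximum-intensity projections of one stack."""

    images: Mapping[str, np.ndarray]
    source: str = ""

    def __post_init__(self) -> None:
        images = {canonical_role(k): np.asarray(v) for k, v in self.images.items()}
        shapes = {v.shape for v in images.values()}
        if len(shapes) > 1:
            raise StackFormatError(f"projection channels disagree in shape: {shapes}")
        for img in images.values():
            if img.ndim != 2:
                raise StackFormatError("projections must be 2-D")
        object.__setattr__(self, "images", images)

    def __contains__(self, role: str) -> bool:
        return canonical_role(role) in self.images

    def __getitem__(self, role: str) -> np.ndarray:
        return self.images[canonical_role(role)]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape


@dataclass(frozen=True)
class MaskImage:
    """A binary pixel mask aligned with a projection."""

    pixels: np.ndarray
    role: str = "shell_roi"

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.ndim != 2:
            raise StackFormatError("mask must be 2-D")
        if self.role not in MASK_ROLES:
            raise StackFormatError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")
        object.__setattr__(self, "pixels", pixels.astype(bool))

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


# ---------------------------------------------------------------------------
# stack I/O


def write_stack(stack: ZStack, path: str | Path) -> Path:
    """Write ``stack`` as an OME-TIFF (axes CZYX, lossless integer data)."""
    path = Path(path)
    metadata: dict = {
        "axes": "CZYX",
        "Channel": {"Name": list(stack.channels)},
    }
    if stack.pixel_size_um is not None:
        metadata.update(
            PhysicalSizeX=float(stack.pixel_size_um),
            PhysicalSizeXUnit="µm",
            PhysicalSizeY=float(stack.pixel_size_um),
            PhysicalSizeYUnit="µm",
        )
    try:
        # minisblack: small frames must not be guessed as RGB samples
        tifffile.imwrite(path, stack.voxels, ome=True, metadata=metadata, photometric="minisblack")
    except OSError as exc:
        raise StackIOError(f"cannot write stack to {path}: {exc}") from exc
    return path


def _parse_ome(ome_xml: str) -> tuple[tuple[str, ...] | None, float | None]:
    """Extract (channel roles, pixel size µm) from OME-XML, best effort."""
    try:
        meta = tifffile.xml2dict(ome_xml)
        image = meta["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        pixels = image["Pixels"]
    except (KeyError, TypeError, ValueError):
        return None, None
    size = pixels.get("PhysicalSizeX")
    pixel_size = float(size) if size is not None else None
    channels = pixels.get("Channel")
    if channels is None:
        return None, pixel_size
    if not isinstance(channels, list):
        channels = [channels]
    names = [c.get("Name") for c in channels if isinstance(c, dict)]
    if len(names) != len(channels) or any(n is None for n in names):
        return None, pixel_size
    try:
        roles = canonical_roles(names)
    except StackFormatError:
        return None, pixel_size
    return roles, pixel_size


def read_stack(
    path: str | Path,
    channel_order: Sequence[str] | None = None,
) -> ZStack:
    """Read a z-stack, assigning channel roles.

    ``channel_order`` declares the roles for files without OME channel
    metadata; OME names, when present and recognisable, take precedence.
    """
    path = Path(path)
    declared = canonical_roles(channel_order) if channel_order is not None else None
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            arr = np.asarray(series.asarray())
            axes = series.axes
            ome_xml = tf.ome_metadata
    except FileNotFoundError as exc:
        raise StackIOError(f"stack file not found: {path}") from exc
    except (tifffile.TiffFileError, OSError, ValueError) as exc:
        raise StackIOError(f"cannot read stack from {path}: {exc}") from exc

    ome_roles, pixel_size = (None, None)
    if ome_xml:
        ome_roles, pixel_size = _parse_ome(ome_xml)

    arr, n_channels_in_file = _normalise_axes(arr, axes, declared, ome_roles, path)

    roles = ome_roles if ome_roles is not None else declared
    if roles is None:
        roles = DEFAULT_CHANNEL_ORDER[:n_channels_in_file]
    if len(roles) != n_channels_in_file:
        raise StackFormatError(
            f"{path}: declared {len(roles)} channels but file contains {n_channels_in_file}"
        )
    return ZStack(
        voxels=arr,
        channels=roles,
        pixel_size_um=pixel_size,
        source=str(path),
    )


def _normalise_axes(
    arr: np.ndarray,
    axes: str,
    declared: tuple[str, ...] | None,
    ome_roles: tuple[str, ...] | None,
    path: Path,
) -> tuple[np.ndarray, int]:
    """Coerce a tifffile series to (C, Z, Y, X); return it with channel count."""
    # drop singleton axes tifffile sometimes adds (samples, time, ...)
    keep = [i for i, (a, n) in enumerate(zip(axes, arr.shape)) if a in "CZYX" or n > 1]
    axes = "".join(axes[i] for i in keep)
    arr = arr.reshape([arr.shape[i] for i in keep])

    # restore squeezed singleton C/Z axes on labelled (OME/ImageJ) series
    if set(axes) <= set("CZYX"):
        for missing in ("C", "Z"):
            if missing not in axes and ("C" in axes or "Z" in axes):
                arr = arr[None]
                axes = missing + axes

    if "C" in axes and "Z" in axes and set(axes) <= set("CZYX"):
        order = [axes.index(a) for a in "CZYX"]
        arr = arr.transpose(order)
        return arr, arr.shape[0]

    n_declared = len(ome_roles or declared or DEFAULT_CHANNEL_ORDER)
    if arr.ndim == 4:
        # undocumented 4-D layout: try (Z, C, Y, X) then (C, Z, Y, X)
        if arr.shape[1] == n_declared:
            arr = arr.transpose(1, 0, 2, 3)
            return arr, arr.shape[0]
        if arr.shape[0] == n_declared:
            return arr, arr.shape[0]
        raise StackFormatError(
            f"{path}: expected {n_declared} channels but file shape {arr.shape} "
            "matches neither (Z,C,Y,X) nor (C,Z,Y,X)"
        )
    if arr.ndim == 3:
        if declared is None:
            raise StackFormatError(
                f"{path}: plain multi-page TIFF needs an explicit channel_order"
            )
        pages = arr.shape[0]
        k = len(declared)
        if pages % k:
            raise StackFormatError(
                f"{path}: expected a multiple of {k} pages (channels cycling fastest) "
                f"but found {pages}"
            )
        arr = arr.reshape(pages // k, k, *arr.shape[1:]).transpose(1, 0, 2, 3)
        return arr, k
    raise StackFormatError(f"{path}: unsupported array layout with shape {arr.shape}")


# ---------------------------------------------------------------------------
# mask I/O


def write_mask(mask: MaskImage, path: str | Path) -> Path:
    """Write a binary mask as single-channel 8-bit TIFF (0/255)."""
    path = Path(path)
    try:
        tifffile.imwrite(path, np.where(mask.pixels, 255, 0).astype(np.uint8))
    except OSError as exc:
        raise StackIOError(f"cannot write mask to {path}: {exc}") from exc
    return path


def read_mask(path: str | Path, role: str = "shell_roi") -> MaskImage:
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError as exc:
        raise StackIOError(f"mask file not found: {path}") from exc
    except (tifffile.TiffFileError, OSError, ValueError) as exc:
        raise StackIOError(f"cannot read mask from {path}: {exc}") from exc
    return MaskImage(pixels=np.asarray(arr) > 0, role=role)
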