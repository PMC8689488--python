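"""Per-individual ROS area quantification.

The computation chain, per stack: per-channel maximum-intensity projection;
shell footprint segmentation from the shell channel (CH1); optional
computational gain balancing; subtraction of the scaled shell channel from
the stain channel (CH2) to remove non-specific signal; thresholding of the
subtracted image inside the shell footprint; and the area summary

    ros_percent = 100 * ros_positive_area / shell_footprint_area

which standardises the stain readout by the projected area of the
individual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .image_io import (
    GUT,
    ROS,
    SHELL,
    MaskImage,
    ProjectionSet,
    ZStack,
    read_stack,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A quantification stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class NoShellError(PipelineError):
    def __init__(self, message: str = "no shell found"):
        super().__init__("segment_shell", message)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation stages.

    ``shell_threshold`` and ``ros_threshold`` are either the string
    ``"otsu"`` (data-driven, scale-invariant) or a fixed intensity.  The
    ROS threshold is always computed from pixels inside the shell mask
    only.  ``ros_floor_fraction`` guards the data-driven ROS threshold
    against scenes with no true foci (where Otsu would otherwise promote
    the dim tissue baseline to "positive"): the threshold is never allowed
    below this fraction of the shell autofluorescence level, the scene's
    internal intensity reference, which keeps the guard scale-invariant.
    Set it to 0 to disable.  ``gain`` scales CH1 before subtraction; when
    ``equalize_gain`` is set the gain is instead estimated from the
    shell-signal pixels of the projection.
    """

    shell_threshold: float | str = "otsu"
    ros_threshold: float | str = "otsu"
    ros_floor_fraction: float = 0.25
    closing_radius: int = 2
    min_shell_size: int = 100
    min_ros_size: int = 0
    fill_holes: bool = True
    equalize_gain: bool = False
    gain: float = 1.0

    def __post_init__(self) -> None:
        for name in ("shell_threshold", "ros_threshold"):
            value = getattr(self, name)
            if isinstance(value, str):
                if value != "otsu":
                    raise ValueError(f"{name} must be 'otsu' or a number; got {value!r}")
            elif float(value) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.closing_radius < 0 or self.min_shell_size < 0 or self.min_ros_size < 0:
            raise ValueError("morphology sizes must be non-negative")
        if self.ros_floor_fraction < 0:
            raise ValueError("ros_floor_fraction must be non-negative")
        if self.gain < 0:
            raise ValueError("gain must be non-negative")


@dataclass(frozen=True)
class RosQuantification:
    """Per-individual quantification result with the thresholds applied."""

    individual_id: str
    shell_area_px: int
    ros_area_px: int
    ros_percent: float
    shell_threshold: float
    ros_threshold: float
    gain_factor: float

    def __post_init__(self) -> None:
        if self.shell_area_px <= 0:
            raise ValueError("shell_area_px must be positive for a successful quantification")
        if not 0 <= self.ros_area_px <= self.shell_area_px:
            raise ValueError("ros_area_px must lie in [0, shell_area_px]")


class ShellSegmentation(NamedTuple):
    mask: MaskImage
    threshold: float


class RosSegmentation(NamedTuple):
    mask: MaskImage
    threshold: float


def max_projection(stack: ZStack) -> ProjectionSet:
    """Maximum-intensity projection over slices, per channel."""
    if stack.n_slices < 1:
        raise PipelineError("max_projection", "stack has no slices")
    images = {role: stack.channel(role).max(axis=0) for role in stack.channels}
    return ProjectionSet(images=images, source=stack.source)


def equalize_shell_gain(proj: ProjectionSet, shell_mask: MaskImage) -> float:
    """Estimate the CH2/CH1 gain from shell-signal pixels.

    The instrument protocol matches the shell level between CH1 and CH2 at
    acquisition; this recovers a residual imbalance as the ratio of channel
    medians over the supplied shell-signal pixels (typically the thresholded
    shell ring, not the filled footprint, so that interior tissue does not
    dilute the CH1 median).
    """
    mask = shell_mask.pixels
    if not mask.any():
        raise PipelineError("equalize_shell_gain", "shell mask is empty")
    ch1 = np.median(proj[SHELL][mask].astype(np.float64))
    ch2 = np.median(proj[ROS][mask].astype(np.float64))
    if ch1 <= 0:
        raise PipelineError(
            "equalize_shell_gain",
            "CH1 median under the shell mask is zero; acquisition cannot be balanced",
        )
    return float(ch2 / ch1)


def subtract_channels(proj: ProjectionSet, gain: float = 1.0) -> np.ndarray:
    """``max(0, CH2 - gain * CH1)`` in floating point."""
    ch1 = proj[SHELL].astype(np.float64)
    ch2 = proj[ROS].astype(np.float64)
    if ch1.shape != ch2.shape:
        raise PipelineError(
            "subtract_channels", f"channel shapes differ: {ch1.shape} vs {ch2.shape}"
        )
    return np.clip(ch2 - float(gain) * ch1, 0.0, None)


def _resolve_threshold(image: np.ndarray, setting: float | str, stage: str) -> float:
    if isinstance(setting, str):
        values = np.asarray(image, dtype=np.float64)
        if values.size == 0 or np.ptp(values) == 0:
            raise PipelineError(stage, "cannot compute Otsu threshold on constant data")
        return float(threshold_otsu(values))
    return float(setting)


def _drop_small(labels: np.ndarray, min_size: int) -> np.ndarray:
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return label(keep[labels], connectivity=2)


def _footprint_components(image: np.ndarray, config: SegmentationConfig, threshold: float) -> np.ndarray:
    fg = np.asarray(image, dtype=np.float64) >= threshold
    if config.closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=disk(config.closing_radius))
    if config.fill_holes:
        fg = ndimage.binary_fill_holes(fg)
    labels = label(fg, connectivity=2)
    if config.min_shell_size > 1:
        labels = _drop_small(labels, config.min_shell_size)
    return labels


def segment_shell(
    proj_ch1: np.ndarray, config: SegmentationConfig | None = None
) -> ShellSegmentation:
    """Segment the filled projected footprint of the individual from CH1.

    Threshold, morphological closing, hole filling, then the largest
    connected component.  Ties on area are broken by total CH1 intensity,
    then by label index.
    """
    config = config or SegmentationConfig()
    image = np.asarray(proj_ch1, dtype=np.float64)
    if np.ptp(image) == 0:
        raise NoShellError("image is constant")
    threshold = _resolve_threshold(image, config.shell_threshold, "segment_shell")
    labels = _footprint_components(image, config, threshold)
    n = labels.max()
    if n == 0:
        raise NoShellError()
    best = None
    for region in regionprops(labels, intensity_image=image):
        key = (region.area, region.image_intensity.sum(), -region.label)
        if best is None or key > best[0]:
            best = (key, region.label)
    mask = labels == best[1]
    return ShellSegmentation(MaskImage(mask, role="shell_roi"), threshold)


def segment_individuals(
    proj_ch1: np.ndarray, config: SegmentationConfig | None = None
) -> list[ShellSegmentation]:
    """Like :func:`segment_shell` but keeps every sufficiently large
    component, for frames containing several individuals."""
    config = config or SegmentationConfig()
    image = np.asarray(proj_ch1, dtype=np.float64)
    if np.ptp(image) == 0:
        raise NoShellError("image is constant")
    threshold = _resolve_threshold(image, config.shell_threshold, "segment_shell")
    labels = _footprint_components(image, config, threshold)
    n = labels.max()
    if n == 0:
        raise NoShellError()
    return [
        ShellSegmentation(MaskImage(labels == i, role="shell_roi"), threshold)
        for i in range(1, n + 1)
    ]


def segment_ros(
    sub_image: np.ndarray,
    shell_mask: MaskImage,
    config: SegmentationConfig | None = None,
    reference_level: float | None = None,
) -> RosSegmentation:
    """Threshold the subtracted image inside the shell footprint.

    The threshold is computed from in-mask pixels only; the output mask is
    always a subset of the shell mask.  An all-zero subtracted image yields
    an empty mask (the unstressed limit), not an error.  When
    ``reference_level`` (the shell autofluorescence intensity, in the same
    units as ``sub_image``) is supplied, a data-driven threshold is floored
    at ``config.ros_floor_fraction * reference_level``.
    """
    config = config or SegmentationConfig()
    mask = shell_mask.pixels
    if not mask.any():
        raise PipelineError("segment_ros", "shell mask is empty")
    sub = np.asarray(sub_image, dtype=np.float64)
    if sub.shape != mask.shape:
        raise PipelineError(
            "segment_ros", f"image shape {sub.shape} does not match mask shape {mask.shape}"
        )
    inside = sub[mask]
    if inside.max() <= 0:
        return RosSegmentation(MaskImage(np.zeros_like(mask), role="ros_positive"), 0.0)
    if isinstance(config.ros_threshold, str) and np.ptp(inside) == 0:
        # constant positive signal saturates the whole footprint
        threshold = float(inside[0])
    else:
        threshold = _resolve_threshold(inside, config.ros_threshold, "segment_ros")
    if (
        isinstance(config.ros_threshold, str)
        and reference_level is not None
        and config.ros_floor_fraction > 0
    ):
        threshold = max(threshold, config.ros_floor_fraction * float(reference_level))
    ros = (sub >= threshold) & mask
    if config.min_ros_size > 1:
        ros = _drop_small(label(ros, connectivity=2), config.min_ros_size) > 0
    return RosSegmentation(MaskImage(ros, role="ros_positive"), threshold)


def _quantify_component(
    proj: ProjectionSet,
    shell: ShellSegmentation,
    config: SegmentationConfig,
    individual_id: str,
) -> tuple[RosQuantification, MaskImage]:
    ch1 = np.asarray(proj[SHELL], dtype=np.float64)
    ring = MaskImage((ch1 >= shell.threshold) & shell.mask.pixels, role="shell_roi")
    if config.equalize_gain:
        gain = equalize_shell_gain(proj, ring)
    else:
        gain = float(config.gain)
    sub = subtract_channels(proj, gain=gain)
    # shell autofluorescence level, mapped to CH2 units by the gain, anchors
    # the floor under the data-driven ROS threshold
    reference = gain * float(np.median(ch1[ring.pixels])) if ring.pixels.any() else None
    ros = segment_ros(sub, shell.mask, config, reference_level=reference)
    shell_area = shell.mask.area_px
    ros_area = ros.mask.area_px
    result = RosQuantification(
        individual_id=individual_id,
        shell_area_px=shell_area,
        ros_area_px=ros_area,
        ros_percent=100.0 * ros_area / shell_area,
        shell_threshold=shell.threshold,
        ros_threshold=ros.threshold,
        gain_factor=gain,
    )
    return result, ros.mask


def quantify_individual(
    stack: ZStack,
    config: SegmentationConfig | None = None,
    individual_id: str | None = None,
) -> RosQuantification:
    """Run the full chain on one stack and return the area summary."""
    config = config or SegmentationConfig()
    individual_id = individual_id or stack.source or "individual"
    proj = max_projection(stack)
    shell = segment_shell(proj[SHELL], config)
    result, _ = _quantify_component(proj, shell, config, individual_id)
    return result


@dataclass
class QuantificationFailure:
    file: str
    stage: str
    message: str


RESULT_COLUMNS = [
    "individual_id",
    "file",
    "treatment",
    "container",
    "shell_area_px",
    "ros_area_px",
    "ros_percent",
    "shell_threshold",
    "ros_threshold",
    "gain_factor",
]


def quantify_batch(
    paths: Sequence[str | Path],
    config: SegmentationConfig | None = None,
    labels: pd.DataFrame | Mapping[str, Mapping[str, str]] | None = None,
    channel_order: Sequence[str] | None = None,
    multi_individual: bool = False,
    mask_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[QuantificationFailure]]:
    """Quantify a batch of stack files into a tidy table.

    ``labels`` maps file names to treatment/container labels (a DataFrame
    with ``file``, ``treatment``, ``container`` columns, or a mapping).
    Per-file failures are collected, not fatal.
    """
    if len(paths) == 0:
        raise ValueError("quantify_batch requires at least one input path")
    config = config or SegmentationConfig()
    label_map = _label_lookup(labels)
    rows: list[dict] = []
    failures: list[QuantificationFailure] = []
    from .image_io import write_mask  # local import to avoid cycle at module load

    for path in paths:
        path = Path(path)
        try:
            stack = read_stack(path, channel_order=channel_order)
            proj = max_projection(stack)
            if multi_individual:
                shells = segment_individuals(proj[SHELL], config)
            else:
                shells = [segment_shell(proj[SHELL], config)]
            for i, shell in enumerate(shells):
                ind_id = path.stem if len(shells) == 1 else f"{path.stem}-{i + 1}"
                result, ros_mask = _quantify_component(proj, shell, config, ind_id)
                if mask_dir is not None:
                    mask_dir = Path(mask_dir)
                    mask_dir.mkdir(parents=True, exist_ok=True)
                    write_mask(shell.mask, mask_dir / f"{ind_id}_shell.tif")
                    write_mask(ros_mask, mask_dir / f"{ind_id}_ros.tif")
                meta = label_map.get(path.name, label_map.get(path.stem, {}))
                rows.append(
                    {
                        "individual_id": result.individual_id,
                        "file": path.name,
                        "treatment": meta.get("treatment", ""),
                        "container": meta.get("container", ""),
                        "shell_area_px": result.shell_area_px,
                        "ros_area_px": result.ros_area_px,
                        "ros_percent": result.ros_percent,
                        "shell_threshold": result.shell_threshold,
                        "ros_threshold": result.ros_threshold,
                        "gain_factor": result.gain_factor,
                    }
                )
        except PipelineError as exc:
            logger.warning("quantification failed for %s: %s", path, exc)
            failures.append(QuantificationFailure(str(path), exc.stage, str(exc)))
        except Exception as exc:  # I/O and format errors: isolate per file
            logger.warning("could not process %s: %s", path, exc)
            failures.append(QuantificationFailure(str(path), "read_stack", str(exc)))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return table, failures


def _label_lookup(
    labels: pd.DataFrame | Mapping[str, Mapping[str, str]] | None,
) -> dict[str, dict[str, str]]:
    if labels is None:
        return {}
    if isinstance(labels, pd.DataFrame):
        required = {"file", "treatment", "container"}
        missing = required - set(labels.columns)
        if missing:
            raise ValueError(f"labels table is missing columns: {sorted(missing)}")
        return {
            str(row.file): {"treatment": str(row.treatment), "container": str(row.container)}
            for row in labels.itertuples()
        }
    return {k: dict(v) for k, v in labels.items()}
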