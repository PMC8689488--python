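"""Strict YAML configuration loading.

Every section rejects unknown keys so that typos cannot silently fall back
to defaults; the defaults actually applied are materialised into the run
manifest by the CLI.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .image_io import canonical_roles
from .pipeline import SegmentationConfig
from .synth import ExperimentDesign, PhantomSpec, TreatmentSpec, default_phantom


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _check_keys(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


_SEGMENTATION_KEYS = {
    "shell_threshold",
    "ros_threshold",
    "ros_floor_fraction",
    "closing_radius",
    "min_shell_size",
    "min_ros_size",
    "fill_holes",
    "equalize_gain",
    "gain",
    "channel_order",
}


def segmentation_from_dict(section: Mapping[str, Any]) -> tuple[SegmentationConfig, tuple[str, ...] | None]:
    """Build a SegmentationConfig (plus optional channel order) from YAML."""
    _check_keys(section, _SEGMENTATION_KEYS, "segmentation")
    section = dict(section)
    channel_order = section.pop("channel_order", None)
    if channel_order is not None:
        channel_order = canonical_roles(channel_order)
    try:
        return SegmentationConfig(**section), channel_order
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid segmentation config: {exc}") from exc


_PHANTOM_KEYS = {
    "image_shape",
    "n_slices",
    "shell_semi_axes",
    "shell_orientation_deg",
    "ring_thickness_px",
    "shell_intensity_ch1",
    "shell_intensity_ch2",
    "tissue_intensity",
    "ros_fraction",
    "ros_object_count",
    "ros_intensity",
    "gut_present",
    "gut_intensity",
    "noise_sd",
    "bit_depth",
    "pixel_size_um",
    "seed",
}


def phantom_from_dict(section: Mapping[str, Any]) -> PhantomSpec:
    _check_keys(section, _PHANTOM_KEYS, "phantom")
    section = dict(section)
    shape = tuple(section.pop("image_shape", (512, 512)))
    for key in ("shell_semi_axes",):
        if key in section:
            section[key] = tuple(section[key])
    try:
        if "shell_semi_axes" in section or "ring_thickness_px" in section:
            return PhantomSpec(image_shape=shape, **section)
        return default_phantom(shape, **section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid phantom config: {exc}") from exc


_DESIGN_KEYS = {"treatments", "containers_per_treatment", "individuals_per_container", "seed"}
_TREATMENT_KEYS = {"label", "mean_fraction", "between_container_sd", "within_container_sd"}


def design_from_dict(section: Mapping[str, Any]) -> ExperimentDesign:
    _check_keys(section, _DESIGN_KEYS, "design")
    section = dict(section)
    raw_treatments = section.pop("treatments", None)
    if not raw_treatments:
        raise ConfigError("design requires a non-empty 'treatments' list")
    treatments = []
    for i, t in enumerate(raw_treatments):
        if not isinstance(t, Mapping):
            raise ConfigError(f"design.treatments[{i}] must be a mapping")
        _check_keys(t, _TREATMENT_KEYS, f"design.treatments[{i}]")
        try:
            treatments.append(TreatmentSpec(**t))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid treatment spec at index {i}: {exc}") from exc
    try:
        return ExperimentDesign(treatments=tuple(treatments), **section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid design: {exc}") from exc


_STATS_KEYS = {"transform", "alpha", "posthoc"}


@dataclass(frozen=True)
class StatsOptions:
    transform: str = "arcsine-sqrt"
    alpha: float = 0.05
    posthoc: str = "tukey"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")


def stats_from_dict(section: Mapping[str, Any]) -> StatsOptions:
    _check_keys(section, _STATS_KEYS, "stats")
    return StatsOptions(**section)


_RUN_KEYS = {
    "seed",
    "out_dir",
    "design",
    "phantom",
    "segmentation",
    "stats",
    "multi_individual",
    "save_stacks",
    "save_masks",
    "verbosity",
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for an end-to-end run."""

    seed: int
    out_dir: Path
    design: ExperimentDesign
    phantom: PhantomSpec
    segmentation: SegmentationConfig
    channel_order: tuple[str, ...] | None
    stats: StatsOptions
    multi_individual: bool = False
    save_stacks: bool = False
    save_masks: bool = False
    verbosity: str = "info"

    def manifest(self) -> dict:
        """Every default materialised, for reproducibility records."""
        return {
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "design": {
                "treatments": [asdict(t) for t in self.design.treatments],
                "containers_per_treatment": self.design.containers_per_treatment,
                "individuals_per_container": self.design.individuals_per_container,
                "seed": self.design.seed,
            },
            "phantom": asdict(self.phantom),
            "segmentation": asdict(self.segmentation),
            "channel_order": list(self.channel_order) if self.channel_order else None,
            "stats": asdict(self.stats),
            "multi_individual": self.multi_individual,
            "save_stacks": self.save_stacks,
            "save_masks": self.save_masks,
        }


def run_config_from_yaml(path: str | Path, seed: int | None = None) -> RunConfig:
    data = load_yaml(path)
    _check_keys(data, _RUN_KEYS, str(path))
    if "design" not in data:
        raise ConfigError("run config requires a 'design' section")
    run_seed = int(seed if seed is not None else data.get("seed", 0))
    design_section = dict(data["design"])
    phantom_section = dict(data.get("phantom", {}))
    if seed is not None:
        # an explicit override beats any seed buried in the sections
        design_section["seed"] = run_seed
        phantom_section["seed"] = run_seed
    else:
        design_section.setdefault("seed", run_seed)
        phantom_section.setdefault("seed", run_seed)
    design = design_from_dict(design_section)
    phantom = phantom_from_dict(phantom_section)
    segmentation, channel_order = segmentation_from_dict(data.get("segmentation", {}))
    stats = stats_from_dict(data.get("stats", {}))
    return RunConfig(
        seed=run_seed,
        out_dir=Path(data.get("out_dir", "rosquant-run")),
        design=design,
        phantom=phantom,
        segmentation=segmentation,
        channel_order=channel_order,
        stats=stats,
        multi_individual=bool(data.get("multi_individual", False)),
        save_stacks=bool(data.get("save_stacks", False)),
        save_masks=bool(data.get("save_masks", False)),
        verbosity=str(data.get("verbosity", "info")),
    )
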